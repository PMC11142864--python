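"""Exception hierarchy.

All package errors derive from :class:`PhenothermError` so callers can catch
one base class; subclasses distinguish configuration problems (bad model
parameters), data problems (malformed or gappy inputs), and numerical /
identifiability failures raised during fitting.
"""


class PhenothermError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhenothermError):
    """Invalid model or scenario parameters (e.g. T_min >= T_opt)."""


class DataError(PhenothermError):
    """Malformed, gappy or misaligned input data."""


class RangeError(PhenothermError):
    """A requested target lies outside the reachable range of a series."""


class IdentifiabilityError(PhenothermError):
    """The data cannot identify the requested parameters."""


class FitError(PhenothermError):
    """Numerical failure during model fitting or training."""


class SplitError(PhenothermError):
    """A requested train/test split cannot be constructed."""


class MetricError(PhenothermError):
    """A prediction metric is undefined for the given inputs."""
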