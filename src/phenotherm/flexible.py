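"""Semiparametric temperature-response regressors.

Two drop-in alternatives to the parametric dose-response families:

* a **hierarchical P-spline** over temperature — a population curve plus
  per-genotype and per-replication deviation curves, all on a shared
  B-spline basis with difference penalties (deviations additionally carry a
  ridge penalty so they shrink to zero when genotypes do not differ);
  smoothing weights are chosen by generalized cross-validation;
* a **small multi-output neural network** — a [1, 5, 5, 1] sigmoid trunk
  regressing temperature on growth rate, pretrained on pooled data, then
  extended by a linear (unactivated) genotype head of size n_genotypes and
  fine-tuned with an L1 penalty on the head and early stopping.

The genotype head is parametrized as deviations from the shared trunk
response, ``output_g = (1 + dw_g) * trunk(T) + db_g``, so an infinite L1
weight collapses every genotype onto the shared curve.

Either model can be wrapped by :func:`as_response_function` into a plain
``rate(T)`` callable (clipped at zero) and used wherever a parametric
:class:`~phenotherm.dose_response.DoseResponseModel` is accepted, including
inside the temperature-compensation integral.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import DataError, FitError, IdentifiabilityError

__all__ = [
    "SplineResponse", "NeuralResponse",
    "fit_hierarchical_spline", "fit_neural_response", "as_response_function",
]


# ---------------------------------------------------------------------------
# hierarchical splines

def _bspline_basis(T, lo, hi, n_knots, degree=3):
    # uniform knots extended beyond the domain (classic P-spline basis:
    # the difference-penalty null space is then exactly the polynomials)
    h = (hi - lo) / (n_knots - 1)
    tk = lo + h * np.arange(-degree, n_knots + degree)
    Tc = np.clip(T, lo, hi)
    B = BSpline.design_matrix(Tc, tk, degree).toarray()
    return B, tk


@dataclass
class SplineResponse:
    knots: np.ndarray
    degree: int
    t_range: tuple[float, float]
    population_coefficients: np.ndarray
    genotype_coefficients: dict            # cultivar -> deviation coefs
    replication_coefficients: dict
    penalty_weights: dict
    gcv: float

    def _basis(self, T):
        Tc = np.clip(np.asarray(T, dtype=float), *self.t_range)
        return BSpline.design_matrix(Tc, self.knots, self.degree).toarray()

    def predict(self, T, genotype=None, replication=None) -> np.ndarray:
        """Fitted response at temperature(s) T; boundary-value extrapolation."""
        B = self._basis(T)
        coef = self.population_coefficients.copy()
        if genotype is not None:
            if genotype not in self.genotype_coefficients:
                raise KeyError(f"unknown genotype {genotype!r}")
            coef = coef + self.genotype_coefficients[genotype]
        if replication is not None:
            coef = coef + self.replication_coefficients[replication]
        return B @ coef


def fit_hierarchical_spline(T, rate, genotype=None, replication=None, *,
                            n_knots: int = 10, degree: int = 3,
                            lambdas=None, ridge_factors=None) -> SplineResponse:
    """Fit population + genotype (+ replication) response curves.

    Parameters
    ----------
    T, rate : arrays of temperature / growth-rate pairs.
    genotype, replication : optional label arrays; genotype and replication
        curves are deviations from the population curve.
    lambdas : candidate smoothing weights for the GCV grid.
    ridge_factors : candidate ridge weights (relative to the smoothing
        weight) applied to deviation coefficients.
    """
    T = np.asarray(T, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if T.shape != rate.shape:
        raise DataError("temperature/rate misaligned")
    if len(np.unique(np.round(T, 3))) < 10:
        raise IdentifiabilityError("need >= 10 distinct temperatures")
    lo, hi = float(T.min()), float(T.max())
    B, tk = _bspline_basis(T, lo, hi, n_knots, degree)
    nb = B.shape[1]

    genos = [] if genotype is None else sorted(set(genotype))
    reps = [] if replication is None else sorted(set(replication))
    if genotype is not None and len(genos) < 2:
        genos = []  # hierarchy collapses to the population fit
    blocks = [B]
    for g in genos:
        Zg = B * (np.asarray(genotype) == g)[:, None]
        blocks.append(Zg)
    for r in reps:
        Zr = B * (np.asarray(replication) == r)[:, None]
        blocks.append(Zr)
    A = np.hstack(blocks)
    n, ptot = A.shape

    D = np.diff(np.eye(nb), 2, axis=0)
    DtD = D.T @ D
    lambdas = np.asarray([0.01, 0.1, 1.0, 10.0, 100.0] if lambdas is None
                         else lambdas, dtype=float)
    ridge_factors = np.asarray([0.1, 1.0, 10.0] if ridge_factors is None
                               else ridge_factors, dtype=float)

    AtA = A.T @ A
    Aty = A.T @ rate
    n_dev = len(genos) + len(reps)
    best = None
    for lam in lambdas:
        for rf in (ridge_factors if n_dev else [ridge_factors[0]]):
            P = np.zeros((ptot, ptot))
            P[:nb, :nb] = lam * DtD
            for k in range(n_dev):
                s = nb * (k + 1)
                P[s:s + nb, s:s + nb] = lam * DtD + lam * rf * np.eye(nb)
            M = AtA + P
            try:
                coef = np.linalg.solve(M, Aty)
                edf = np.trace(np.linalg.solve(M, AtA))
            except np.linalg.LinAlgError:
                continue
            resid = rate - A @ coef
            denom = max(n - edf, 1.0)
            gcv = n * float(resid @ resid) / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam, rf, coef)
    if best is None:
        raise FitError("every smoothing candidate was singular")
    gcv, lam, rf, coef = best

    pop = coef[:nb]
    gc, rc, pos = {}, {}, nb
    for g in genos:
        gc[g] = coef[pos:pos + nb]
        pos += nb
    for r in reps:
        rc[r] = coef[pos:pos + nb]
        pos += nb
    return SplineResponse(knots=tk, degree=degree, t_range=(lo, hi),
                          population_coefficients=pop, genotype_coefficients=gc,
                          replication_coefficients=rc,
                          penalty_weights={"lambda": float(lam), "ridge": float(rf)},
                          gcv=float(gcv))


# ---------------------------------------------------------------------------
# neural response

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class NeuralResponse:
    """Trunk MLP [1,5,5,1] with an affine genotype head (deviation form)."""

    weights: dict
    genotypes: list
    training_meta: dict = field(default_factory=dict)

    def trunk(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float).reshape(-1, 1)
        W = self.weights
        h1 = _sigmoid(T @ W["W1"] + W["b1"])
        h2 = _sigmoid(h1 @ W["W2"] + W["b2"])
        return (h2 @ W["W3"] + W["b3"]).ravel()

    def predict(self, T, genotype=None) -> np.ndarray:
        out = self.trunk(T)
        if genotype is None:
            return out
        if genotype not in self.genotypes:
            raise KeyError(f"unknown genotype {genotype!r}")
        gi = self.genotypes.index(genotype)
        return (1.0 + self.weights["dw"][gi]) * out + self.weights["db"][gi]

    def loss_hash(self) -> str:
        h = hashlib.sha256()
        for x in self.training_meta.get("pre_losses", []):
            h.update(np.float64(x).tobytes())
        for x in self.training_meta.get("fine_losses", []):
            h.update(np.float64(x).tobytes())
        return h.hexdigest()


class _Adam:
    def __init__(self, params, lr=0.05, betas=(0.9, 0.999), eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.lr, self.b1, self.b2, self.eps, self.t = lr, *betas, eps, 0

    def step(self, params, grads, lr):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _trunk_forward_backward(W, x, y_target, head=None, gidx=None, l1=0.0):
    """MSE loss and gradients; optional genotype head in deviation form."""
    n = len(x)
    h1a = x @ W["W1"] + W["b1"]
    h1 = _sigmoid(h1a)
    h2a = h1 @ W["W2"] + W["b2"]
    h2 = _sigmoid(h2a)
    out = (h2 @ W["W3"] + W["b3"]).ravel()
    if head is not None:
        gain = 1.0 + head["dw"][gidx]
        pred = gain * out + head["db"][gidx]
    else:
        gain = 1.0
        pred = out
    err = pred - y_target
    loss = float(err @ err) / n

    d_pred = 2.0 * err / n
    grads_head = None
    if head is not None:
        grads_head = {
            "dw": np.bincount(gidx, weights=d_pred * out,
                              minlength=len(head["dw"]))
                  + l1 * np.sign(head["dw"]),
            "db": np.bincount(gidx, weights=d_pred, minlength=len(head["db"]))
                  + l1 * np.sign(head["db"]),
        }
    d_out = (d_pred * gain)[:, None]
    gW3 = h2.T @ d_out
    gb3 = d_out.sum(0)
    d_h2 = (d_out @ W["W3"].T) * h2 * (1 - h2)
    gW2 = h1.T @ d_h2
    gb2 = d_h2.sum(0)
    d_h1 = (d_h2 @ W["W2"].T) * h1 * (1 - h1)
    gW1 = x.T @ d_h1
    gb1 = d_h1.sum(0)
    grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3}
    return loss, out, grads, grads_head


def fit_neural_response(T, rate, genotype, *, seed: int,
                        pre_epochs: int = 1500, fine_epochs: int = 800,
                        lr: float = 0.05, gamma: float = 0.996,
                        l1: float = 1e-3, batch_size: int = 2000,
                        patience: int = 40, min_delta: float = 1e-4,
                        val_fraction: float = 0.1) -> NeuralResponse:
    """Two-phase training of the neural temperature-response regressor.

    Phase 1 pretrains the single-output trunk on the pooled data (MSE,
    Adam, initial lr 0.05 with exponential decay gamma=0.996 per epoch).
    Phase 2 appends the genotype head and fine-tunes everything with an L1
    penalty on the head deviations and early stopping on a 9:1
    train/validation split (patience 40 epochs, minimum improvement 1e-4).
    All randomness (init, split, batches) derives from ``seed``.
    """
    T = np.asarray(T, dtype=float).reshape(-1, 1)
    rate = np.asarray(rate, dtype=float)
    n = len(rate)
    if n < 500:
        raise DataError("need >= 500 observations to train the network")
    genos = sorted(set(genotype))
    gidx = np.array([genos.index(g) for g in genotype])

    rng = np.random.default_rng(seed)
    # temperature standardized inside the net input weights via init scale
    t_mu, t_sd = float(T.mean()), float(T.std() + 1e-12)
    x = (T - t_mu) / t_sd

    W = {
        "W1": rng.normal(0, 1.0, (1, 5)), "b1": np.zeros(5),
        "W2": rng.normal(0, 1.0, (5, 5)), "b2": np.zeros(5),
        "W3": rng.normal(0, 0.5, (5, 1)), "b3": np.zeros(1),
    }
    perm = rng.permutation(n)
    n_val = max(int(round(n * val_fraction)), 1)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    opt = _Adam(W, lr=lr)
    pre_losses = []
    cur_lr = lr
    for epoch in range(pre_epochs):
        order = rng.permutation(tr_idx)
        ep_loss, nb = 0.0, 0
        for s in range(0, len(order), batch_size):
            b = order[s:s + batch_size]
            loss, _, grads, _ = _trunk_forward_backward(W, x[b], rate[b])
            if not np.isfinite(loss):
                raise FitError(f"pretraining diverged at epoch {epoch}")
            opt.step(W, grads, cur_lr)
            ep_loss += loss
            nb += 1
        cur_lr *= gamma
        pre_losses.append(ep_loss / nb)

    head = {"dw": np.zeros(len(genos)), "db": np.zeros(len(genos))}
    opt2 = _Adam({**W, **head}, lr=cur_lr)
    fine_losses, best_val, since_best = [], np.inf, 0
    best_state = None
    for epoch in range(fine_epochs):
        order = rng.permutation(tr_idx)
        for s in range(0, len(order), batch_size):
            b = order[s:s + batch_size]
            loss, _, grads, ghead = _trunk_forward_backward(
                W, x[b], rate[b], head=head, gidx=gidx[b], l1=l1)
            if not np.isfinite(loss):
                raise FitError(f"fine-tuning diverged at epoch {epoch}")
            opt2.step({**W, **head}, {**grads, **ghead}, cur_lr)
        cur_lr *= gamma
        vloss, _, _, _ = _trunk_forward_backward(
            W, x[val_idx], rate[val_idx], head=head, gidx=gidx[val_idx], l1=0.0)
        fine_losses.append(vloss)
        if vloss < best_val - min_delta:
            best_val, since_best = vloss, 0
            best_state = ({k: v.copy() for k, v in W.items()},
                          {k: v.copy() for k, v in head.items()})
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_state is not None:
        W, head = best_state

    # fold input standardization into the first layer
    Wout = {k: v.copy() for k, v in W.items()}
    Wout["b1"] = W["b1"] - (t_mu / t_sd) * W["W1"].ravel()
    Wout["W1"] = W["W1"] / t_sd
    Wout.update({"dw": head["dw"].copy(), "db": head["db"].copy()})
    meta = {"seed": seed, "pre_epochs_run": pre_epochs,
            "fine_epochs_run": len(fine_losses),
            "pre_losses": pre_losses, "fine_losses": fine_losses,
            "final_val_mse": float(best_val)}
    return NeuralResponse(weights=Wout, genotypes=genos, training_meta=meta)


# ---------------------------------------------------------------------------

def as_response_function(model, genotype=None):
    """Wrap a fitted semiparametric model as a clipped ``rate(T)`` callable.

    The result is deterministic and non-negative, usable everywhere a
    parametric model is (notably inside ``compensate_time``).  Splines
    extrapolate with their boundary value; the network extrapolates with its
    own output (flagged in the wrapper's ``extrapolation`` attribute).
    """
    if isinstance(model, SplineResponse):
        def f(Tq):
            return np.maximum(model.predict(Tq, genotype=genotype), 0.0)
        f.extrapolation = "boundary-value"
    elif isinstance(model, NeuralResponse):
        if genotype is not None and genotype not in model.genotypes:
            raise KeyError(f"unknown genotype {genotype!r}")

        def f(Tq):
            return np.maximum(model.predict(Tq, genotype=genotype), 0.0)
        f.extrapolation = "network-output"
    else:
        raise TypeError(f"not a semiparametric response: {type(model)!r}")
    return f
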