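"""The central contrast: does thermal time inflate estimated G×E?

Phenology periods generated by cultivar-specific responses are linearized
under thermal time, the species-level model, and the genotypes' own
models; a mixed model then decomposes the compensated durations into
genotype, year, and genotype-by-year variance.
"""

from phenotherm import DoseResponseModel, ScenarioConfig, gxe_contrast, \
    generate_scenario

cfg = ScenarioConfig(seed=3)
sc = generate_scenario(cfg)
model_sets = {
    "thermal_time": DoseResponseModel.thermal_time("wheat"),
    "species": DoseResponseModel("asymptotic", **cfg.species_params),
    "cultivar": sc.cultivars,
}

for stage in ("vegetative", "generative"):
    per = sc.periods[sc.periods.stage_pair == stage]
    tab = gxe_contrast(per, model_sets, sc.air_by_year)
    print(f"\n{stage} period ({len(per)} observations)")
    print(tab[["pct_gxe", "spearman_min", "rmse_days"]].round(2))

print("\npct_gxe is the share of genotypic variance attributed to "
      "genotype-by-year interaction. Linearizing with each cultivar's own "
      "response leaves almost none; forcing a common thermal-time clock "
      "manufactures spurious interaction and weaker year-to-year rank "
      "correlations, while calendar-day prediction errors stay within a "
      "day of each other.")
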