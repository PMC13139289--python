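"""Regression stage on a synthetic cohort with known effects.

Synthesizes a cohort with the published distributional shape (right-skewed,
age-correlated S and T) and a known standardized effect of S on a regional
brain volume, then fits Models 1-3 (volume on S, on T, on both, controlling
for age, sex, population and total intracranial volume) with BH-FDR.
"""

import calcmorph as cm

spec = cm.SyntheticCohortSpec(
    n=1232,
    seed=42,
    regions={"subcortical": cm.RegionEffects(beta_s=-0.14, beta_t=0.0)},
)
table = cm.synthesize_cohort(spec)

d_s, d_t = cm.describe(table["S"]), cm.describe(table["T"])
print(f"S: median {d_s['median']:.2f} mm2, IQR {d_s['iqr']:.2f} mm2")
print(f"T: median {d_t['median']:.2f} mm,  IQR {d_t['iqr']:.2f} mm")
print(f"Spearman S-T: {cm.spearman(table['S'], table['T']):.3f}, "
      f"age-S: {cm.spearman(table['age'], table['S']):.3f}")
print()

fits = cm.fit_models(table, ["subcortical"], models=(1, 2, 3))
rows = fits[fits.predictor.isin(["S", "T"])]
print(rows[["model", "predictor", "beta_std", "se_std", "p_adj", "vif"]]
      .to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print()
print("The true standardized effect is beta*_S = -0.14 with no direct T")
print("effect; Model 1 should recover it within ~2 SE, and the Model-2 T")
print("coefficient (inflated by the S-T correlation) should shrink toward")
print("zero once S enters in Model 3.")
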