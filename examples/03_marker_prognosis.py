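"""Evaluate a candidate marker's prognostic value in a tumor cohort.

Simulates a 159-sample cohort whose marker, when above the cohort median,
multiplies the hazard by 1.57 (with subtype-specific hazards on top);
dichotomizes the marker at the median; and reports the Kaplan-Meier/log-rank
comparison plus univariate and subtype-adjusted Cox models.
"""
import numpy as np

from monomark import (
    CohortSimConfig,
    SurvivalCohort,
    km_curve,
    logrank_test,
    marker_univariate,
    median_dichotomize,
    simulate_survival_cohort,
    subtype_adjusted_analysis,
)

cfg = CohortSimConfig(seed=19)
sim = simulate_survival_cohort(cfg)
df = sim.cohort.data.copy()
df["marker_group"] = median_dichotomize(df["marker"].to_numpy())
cohort = SurvivalCohort(df)

lr = logrank_test(cohort, by="marker_group")
curves = km_curve(cohort, by="marker_group")
print(f"n = {cohort.n}, events = {cohort.n_events}")
for group, curve in sorted(curves.items()):
    median_row = curve[curve["survival"] <= 0.5].head(1)
    med = float(median_row["time"].iloc[0]) if len(median_row) else np.nan
    print(f"  {group}: median survival time {med:.2f}")
print(f"log-rank: chi2 = {lr.statistic:.3f}, p = {lr.p:.4f}")

uni = marker_univariate(cohort, "dichotomized")
row = uni.summary.loc["marker_high"]
print(f"\nunivariate Cox (High vs Low): HR = {row['hr']:.2f} "
      f"({row['ci_low']:.2f}-{row['ci_high']:.2f}), p = {row['p']:.4f}")

adj = subtype_adjusted_analysis(cohort, "dichotomized", reference="Mesenchymal")
print("\nsubtype-adjusted Cox model (reference subtype: Mesenchymal):")
print(adj.table.round(4).to_string())
print("\nThe marker row is the subtype-independent prognostic effect; the "
      "overall row is the joint Wald test of the subtype block; the true "
      "generating HR for the marker is 1.57.")
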