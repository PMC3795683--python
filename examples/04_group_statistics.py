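"""Auxiliary group statistics: qPCR ddCT fold change, Welch t-test,
Kruskal-Wallis with Dunn's post-hoc, and Grubbs outlier exclusion."""
import numpy as np

from monomark import (
    QpcrRecord,
    ddct_fold_change,
    grubbs_filter,
    kruskal_dunn,
    welch_t,
)

# qPCR: treatment lowers the target's dCT by ~2 cycles -> ~4-fold induction
records = [
    QpcrRecord("c1", 26.1, 20.0, "control"),
    QpcrRecord("c2", 25.9, 20.1, "control"),
    QpcrRecord("c3", 26.0, 19.9, "control"),
    QpcrRecord("t1", 24.2, 20.0, "treatment"),
    QpcrRecord("t2", 23.9, 20.0, "treatment"),
    QpcrRecord("t3", 24.1, 19.9, "treatment"),
]
res = ddct_fold_change(records)
print(f"ddCT = {res.ddct:.3f} -> fold change = {res.fold_change:.2f} "
      "(2**-ddCT; >1 means induced in treatment)")

rng = np.random.default_rng(0)
x = rng.normal(0.0, 1.0, 6)
y = rng.normal(1.5, 1.0, 5)
w = welch_t(x, y)
print(f"\nWelch t: t = {w.t:.3f}, df = {w.df:.2f}, p = {w.p:.4f}")

groups = [rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(2.5, 1, 8)]
kd = kruskal_dunn(groups)
print(f"\nKruskal-Wallis: H = {kd.h:.3f}, p = {kd.p:.4g}")
print("Dunn pairwise (Bonferroni-adjusted):")
print(kd.pairwise.round(4).to_string(index=False))

values = [1.02, 0.98, 1.05, 0.97, 1.01, 6.4]
g = grubbs_filter(values)
print(f"\nGrubbs on {values}: excluded {g.excluded} in {g.n_passes} pass(es)")
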