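"""Auxiliary group statistics: ddCT fold change, Welch t, Kruskal-Wallis
with Dunn's post-hoc, and Grubbs outlier exclusion."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

@dataclass
class QpcrRecord:
    """One qPCR measurement: target and reference-gene CT for a sample under
    either the control or treatment condition."""

    sample: str
    target_ct: float
    reference_ct: float
    condition: str  # "control" | "treatment"


@dataclass
class DdctResult:
    fold_change: float
    ddct: float
    per_sample: pd.DataFrame  # sample, condition, dct


def ddct_fold_change(records) -> DdctResult:
    """Relative expression by the ddCT method.

    dCT = target_ct - reference_ct per sample; ddCT = mean dCT(treatment) -
    mean dCT(control); fold change = 2**(-ddCT).
    """
    if isinstance(records, pd.DataFrame):
        records = [
            QpcrRecord(r.sample, r.target_ct, r.reference_ct, r.condition)
            for r in records.itertuples(index=False)
        ]
    rows = []
    for r in records:
        if r.reference_ct is None or not np.isfinite(r.reference_ct):
            raise ValueError(f"missing reference CT for sample {r.sample!r}")
        if not np.isfinite(r.target_ct):
            raise ValueError(f"missing target CT for sample {r.sample!r}")
        if r.condition not in ("control", "treatment"):
            raise ValueError(f"unknown condition {r.condition!r}")
        for ct in (r.target_ct, r.reference_ct):
            if not 10 <= ct <= 40:
                warnings.warn(
                    f"CT {ct} outside the typical 10-40 cycle range", stacklevel=2
                )
        rows.append((r.sample, r.condition, r.target_ct - r.reference_ct))
    per_sample = pd.DataFrame(rows, columns=["sample", "condition", "dct"])
    by = per_sample.groupby("condition")["dct"].mean()
    for cond in ("control", "treatment"):
        if cond not in by.index:
            raise ValueError(f"need at least one {cond} record")
    ddct = float(by["treatment"] - by["control"])
    return DdctResult(float(2.0 ** (-ddct)), ddct, per_sample)


# ---------------------------------------------------------------------------
# two-group and multi-group tests
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(x, y) -> WelchResult:
    """Unequal-variance (Welch) two-sided t-test with Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if np.isclose(x.mean(), y.mean()):
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0)
        v1 = v2 = 1e-8  # variance floor keeps the statistic finite
    se2 = v1 / x.size + v2 / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (v1 / x.size) ** 2 / (x.size - 1) + (v2 / y.size) ** 2 / (y.size - 1)
    )
    p = float(2 * stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


@dataclass
class KruskalDunnResult:
    h: float
    p: float
    pairwise: pd.DataFrame  # group_1, group_2, z, p_unadjusted, p_adjusted
    alpha: float


def kruskal_dunn(groups, alpha: float = 0.05) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis H followed by Dunn's pairwise z tests on
    mean ranks (tie-corrected), Bonferroni-adjusted over the g(g-1)/2 pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError(
            "need at least 3 groups; for 2 groups use welch_t or a rank-sum test"
        )
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))
    ]
    # tie correction term for the rank-variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_un = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
            rows.append((i, j, float(z), p_un, min(1.0, p_un * n_pairs)))
    pairwise = pd.DataFrame(
        rows, columns=["group_1", "group_2", "z", "p_unadjusted", "p_adjusted"]
    )
    return KruskalDunnResult(float(h), float(p), pairwise, alpha)


# ---------------------------------------------------------------------------
# outlier exclusion
# ---------------------------------------------------------------------------

@dataclass
class GrubbsResult:
    retained: np.ndarray
    excluded: list = field(default_factory=list)
    n_passes: int = 0


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value at significance ``alpha``."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(x, alpha: float = 0.05) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier exclusion.

    Each pass removes at most the single most extreme value when
    G = max|x_i - mean| / sd exceeds the t-based critical value; passes
    repeat until no rejection (or fewer than 3 values remain). Zero-variance
    input excludes nothing.
    """
    vals = np.asarray(x, dtype=float)
    if vals.size < 3:
        raise ValueError("Grubbs' test needs at least 3 values")
    excluded: list = []
    passes = 0
    while vals.size >= 3:
        s = vals.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(vals - vals.mean())
        idx = int(np.argmax(dev))
        g = dev[idx] / s
        if g > grubbs_critical(vals.size, alpha):
            excluded.append(float(vals[idx]))
            vals = np.delete(vals, idx)
            passes += 1
        else:
            break
    return GrubbsResult(vals, excluded, passes)
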