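"""Four stand-in differential-expression channels.

Two complementary count-based tests and two complementary intensity-based
tests stand in for the two sequencing pipelines and the two array pipelines
of the original study design:

* **A** — Welch t on ``log2(normalized count + 0.5)``.
* **B** — exact permutation test on the difference of group means of
  ``log2(normalized count + 1)``, enumerating every label assignment
  (all C(n1+n2, n1) splits) and reporting a mid-p.
* **C** — pooled-variance t on log2 intensity with the per-gene pooled
  variance shrunk 50/50 toward the across-gene mean variance (moderated
  effective df = 4 x residual df, the Satterthwaite value for an equal-weight
  mix with an effectively infinite-df prior).
* **D** — Welch t on quantile-normalized log2 intensity.

Each channel emits, per tested gene, a log2 fold change (group1 over group2,
pseudocount 0.5 on count platforms), a two-sided p-value, a Benjamini-
Hochberg q-value over the channel's tested genes, and a within-direction
fold-change rank.

Degenerate-variance rule: when both group means are equal the p-value is set
to 1; otherwise variances are floored at 1e-8 before forming the t statistic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import COUNT, INTENSITY, ExpressionMatrix, two_group_split

logger = logging.getLogger(__name__)

CHANNELS = ("A", "B", "C", "D")
_COUNT_CHANNELS = ("A", "B")
_VAR_FLOOR = 1e-8
_MAX_EXACT_SPLITS = 200_000


@dataclass
class ChannelResult:
    """Per-gene output of one differential-expression channel.

    ``table`` is indexed by gene id with columns ``log2fc``, ``p``, ``q``,
    ``direction`` (the enriched group's label, or ``"none"`` for a zero fold
    change) and ``fc_rank`` (1..n within each direction, by descending
    \\|log2fc\\|, ties broken by ascending p then ascending gene id).
    """

    channel: str
    group1: str
    group2: str
    table: pd.DataFrame
    excluded_ids: list = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_counts(m: ExpressionMatrix, gene_lengths: dict | None = None) -> ExpressionMatrix:
    """Scale raw counts to CPM, or to FPKM when gene lengths (bp) are given.

    Per-sample CPM columns sum to 1e6 exactly (up to float round-off).
    """
    if m.platform != COUNT:
        raise ValueError("normalize_counts requires a count-platform matrix")
    lib = m.values.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    if gene_lengths is None:
        scaled = m.values.div(lib, axis=1) * 1e6
    else:
        lengths = pd.Series(
            [gene_lengths.get(g, np.nan) for g in m.gene_ids], index=m.gene_ids
        )
        if lengths.isna().any():
            missing = list(lengths.index[lengths.isna()])
            raise ValueError(f"missing gene length for: {missing[:10]}")
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        scaled = m.values.div(lib, axis=1).div(lengths, axis=0) * 1e9
    return ExpressionMatrix(scaled, COUNT, m.groups)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns: each sample's sorted values are replaced by
    the across-sample mean of sorted values (deterministic tie handling via
    stable argsort)."""
    X = values.to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[order[:, j], j] = mean_sorted
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values: q_(i) = min_{j>=i} p_(j) * n / j,
    capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# test statistics (vectorized over genes; rows = genes)
# ---------------------------------------------------------------------------

def _welch(a: np.ndarray, b: np.ndarray):
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(1), b.mean(1)
    v1 = np.maximum(a.var(1, ddof=1), _VAR_FLOOR)
    v2 = np.maximum(b.var(1, ddof=1), _VAR_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(np.abs(t), df)
    equal = np.isclose(m1, m2, rtol=0, atol=1e-12)
    p[equal] = 1.0
    return t, df, p


def _moderated_pooled_t(a: np.ndarray, b: np.ndarray):
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(1), b.mean(1)
    v1, v2 = a.var(1, ddof=1), b.var(1, ddof=1)
    resid_df = n1 + n2 - 2
    v_pool = ((n1 - 1) * v1 + (n2 - 1) * v2) / resid_df
    v_shrunk = np.maximum(0.5 * v_pool + 0.5 * v_pool.mean(), _VAR_FLOOR)
    t = (m1 - m2) / np.sqrt(v_shrunk * (1.0 / n1 + 1.0 / n2))
    df = 4 * resid_df
    p = 2 * stats.t.sf(np.abs(t), df)
    p[np.isclose(m1, m2, rtol=0, atol=1e-12)] = 1.0
    return t, p


def _exact_permutation_midp(a: np.ndarray, b: np.ndarray):
    """Mid-p for the observed difference of group means among all label splits.

    A zero observed difference returns mid-p 1 (the least extreme outcome),
    which covers the degenerate identical-groups case.
    """
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    from math import comb

    if comb(n, n1) > _MAX_EXACT_SPLITS:
        raise ValueError(
            f"exact permutation channel supports at most {_MAX_EXACT_SPLITS} "
            f"splits (got C({n},{n1})); it is intended for small replicate designs"
        )
    Y = np.hstack([a, b])
    masks = np.array(
        [np.isin(np.arange(n), c) for c in combinations(range(n), n1)]
    )
    s = Y @ masks.T / n1 - Y @ (~masks).T / n2  # genes x splits
    obs = a.mean(1) - b.mean(1)
    abs_s, abs_obs = np.abs(s), np.abs(obs)[:, None]
    tol = 1e-9 * np.maximum(1.0, abs_obs)
    greater = (abs_s > abs_obs + tol).sum(1)
    equal = (np.abs(abs_s - abs_obs) <= tol).sum(1)
    midp = (greater + 0.5 * equal) / masks.shape[0]
    midp[np.isclose(obs, 0.0, rtol=0, atol=1e-12)] = 1.0
    return obs, midp


# ---------------------------------------------------------------------------
# ranks
# ---------------------------------------------------------------------------

def assign_direction_ranks(table: pd.DataFrame) -> pd.Series:
    """Fold-change rank within each direction: 1..n by descending |log2fc|,
    ties broken by ascending p then ascending gene id. Genes with direction
    ``"none"`` get no rank."""
    rank = pd.Series(np.nan, index=table.index, dtype=float)
    for direction, sub in table.groupby("direction"):
        if direction == "none":
            continue
        order = np.lexsort(
            (np.asarray(sub.index), sub["p"].to_numpy(), -np.abs(sub["log2fc"].to_numpy()))
        )
        rank.loc[sub.index[order]] = np.arange(1, len(sub) + 1, dtype=float)
    return rank


# ---------------------------------------------------------------------------
# channel driver
# ---------------------------------------------------------------------------

def run_channel(
    m: ExpressionMatrix,
    channel: str,
    gene_lengths: dict | None = None,
    group_order=None,
) -> ChannelResult:
    """Run one of the four stand-in channels on a two-group matrix.

    Channels A and B require a count-platform matrix (normalized internally
    to CPM, or FPKM when ``gene_lengths`` is given); C and D require log2
    intensities. Each group must have at least two samples. All-zero genes on
    count platforms are excluded (and logged).
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if channel in _COUNT_CHANNELS:
        if m.platform != COUNT:
            raise ValueError(f"channel {channel} requires a count-platform matrix")
        all_zero = m.values.sum(axis=1) == 0
        excluded = list(m.gene_ids[all_zero])
        if excluded:
            logger.info(
                "channel %s: excluding %d all-zero genes", channel, len(excluded)
            )
            m = m.subset_genes(m.gene_ids[~all_zero])
        norm = normalize_counts(m, gene_lengths)
        g1, g2, x1, x2 = two_group_split(norm, group_order)
        mean1, mean2 = x1.mean(axis=1).to_numpy(), x2.mean(axis=1).to_numpy()
        log2fc = np.log2((mean1 + 0.5) / (mean2 + 0.5))
        if channel == "A":
            a = np.log2(x1.to_numpy() + 0.5)
            b = np.log2(x2.to_numpy() + 0.5)
            _, _, p = _welch(a, b)
        else:  # B
            a = np.log2(x1.to_numpy() + 1.0)
            b = np.log2(x2.to_numpy() + 1.0)
            _, p = _exact_permutation_midp(a, b)
    else:
        if m.platform != INTENSITY:
            raise ValueError(f"channel {channel} requires an intensity-platform matrix")
        excluded = []
        if channel == "D":
            m = ExpressionMatrix(quantile_normalize(m.values), INTENSITY, m.groups)
        g1, g2, x1, x2 = two_group_split(m, group_order)
        a, b = x1.to_numpy(dtype=float), x2.to_numpy(dtype=float)
        log2fc = a.mean(1) - b.mean(1)
        if channel == "C":
            _, p = _moderated_pooled_t(a, b)
        else:  # D
            _, _, p = _welch(a, b)

    q = bh_fdr(p)
    direction = np.where(log2fc > 0, g1, np.where(log2fc < 0, g2, "none"))
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "direction": direction},
        index=x1.index,
    )
    table.index.name = "entrez_id"
    table["fc_rank"] = assign_direction_ranks(table)
    return ChannelResult(channel, g1, g2, table, excluded)
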