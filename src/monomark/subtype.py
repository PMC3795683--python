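"""Molecular subtype assignment by signature matching and k-nearest neighbors.

Tumor samples are assigned to transcriptional subtypes (by default the four
GBM classes Classical / Mesenchymal / Neural / Proneural) by matching the
signature genes of a labeled reference expression set by integer gene id,
z-scoring each gene within each dataset (which makes the two platforms
comparable), and taking a majority vote among the k nearest reference
samples in Euclidean distance (k = 10 by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import ranksums

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SubtypeReference:
    """Labeled reference expression profiles over the signature genes.

    ``profiles``: genes x reference samples; ``labels``: reference sample ->
    subtype name (every reference sample must be labeled).
    """

    profiles: pd.DataFrame
    labels: dict

    def __post_init__(self) -> None:
        missing = [s for s in self.profiles.columns if s not in self.labels]
        if missing:
            raise ValueError(f"unlabeled reference samples: {missing}")

    @property
    def subtypes(self) -> list:
        return sorted(set(self.labels[s] for s in self.profiles.columns))


@dataclass
class MatchedPair:
    """Cohort and reference matrices restricted to the shared gene ids and
    z-scored per gene within each matrix."""

    cohort: pd.DataFrame
    reference: pd.DataFrame
    n_matched: int
    n_dropped_cohort: int
    n_dropped_reference: int


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1).replace(0.0, 1.0)
    return values.sub(mu, axis=0).div(sd, axis=0)


def match_signature_genes(
    cohort: ExpressionMatrix | pd.DataFrame, ref: SubtypeReference
) -> MatchedPair:
    """Restrict both matrices to the intersection of gene ids (identical row
    order) and z-score per gene within each matrix."""
    cvals = cohort.values if isinstance(cohort, ExpressionMatrix) else cohort
    common = cvals.index.intersection(ref.profiles.index).sort_values()
    if len(common) == 0:
        raise ValueError("no shared gene ids between cohort and reference")
    pair = MatchedPair(
        cohort=_zscore_rows(cvals.loc[common]),
        reference=_zscore_rows(ref.profiles.loc[common]),
        n_matched=len(common),
        n_dropped_cohort=len(cvals.index) - len(common),
        n_dropped_reference=len(ref.profiles.index) - len(common),
    )
    logger.info(
        "signature matching: %d genes matched, %d cohort-only, %d reference-only dropped",
        pair.n_matched, pair.n_dropped_cohort, pair.n_dropped_reference,
    )
    return pair


def knn_assign(
    cohort: pd.DataFrame, ref: SubtypeReference, k: int = 10,
    matched: MatchedPair | None = None,
) -> pd.DataFrame:
    """Assign each cohort sample the majority subtype among its k nearest
    reference samples (Euclidean distance over matched, z-scored genes).

    Vote ties are broken by the smallest summed distance to the tied label's
    neighbors, then lexicographically by label. Returns a DataFrame indexed
    by cohort sample with columns ``subtype`` and ``distance_margin`` (summed
    distance of the runner-up label minus the winner; +inf when only one
    label is represented among the neighbors).
    """
    if matched is None:
        matched = match_signature_genes(cohort, ref)
    n_ref = matched.reference.shape[1]
    if k < 1 or k > n_ref:
        raise ValueError(f"k={k} must be within 1..{n_ref} reference samples")
    C = matched.cohort.to_numpy(dtype=float).T      # cohort samples x genes
    R = matched.reference.to_numpy(dtype=float).T   # reference samples x genes
    for name, arr, ids in (
        ("cohort", C, matched.cohort.columns),
        ("reference", R, matched.reference.columns),
    ):
        bad = np.where(np.isnan(arr).any(axis=1))[0]
        if bad.size:
            raise ValueError(f"NaN in {name} profile of sample {ids[bad[0]]!r}")
    dist = cdist(C, R, metric="euclidean")
    ref_labels = np.array([ref.labels[s] for s in matched.reference.columns])
    rows = []
    for i, sample in enumerate(matched.cohort.columns):
        nn = np.argsort(dist[i], kind="stable")[:k]
        labels, counts = np.unique(ref_labels[nn], return_counts=True)
        summed = {
            lab: dist[i, nn[ref_labels[nn] == lab]].sum() for lab in labels
        }
        best_count = counts.max()
        tied = sorted(
            (lab for lab, c in zip(labels, counts) if c == best_count),
            key=lambda lab: (summed[lab], lab),
        )
        winner = tied[0]
        others = [summed[lab] for lab in labels if lab != winner]
        margin = (min(others) - summed[winner]) if others else np.inf
        rows.append((sample, winner, margin))
    out = pd.DataFrame(rows, columns=["sample", "subtype", "distance_margin"])
    return out.set_index("sample")


def subtype_expression_summary(
    cohort: ExpressionMatrix, assignments: pd.Series | pd.DataFrame, gene
):
    """Median and IQR of one gene's expression per subtype, plus pairwise
    two-sided Wilcoxon rank-sum tests between subtypes with >= 2 samples.

    Returns ``(summary, pairwise)`` DataFrames.
    """
    if isinstance(assignments, pd.DataFrame):
        assignments = assignments["subtype"]
    if gene not in cohort.gene_ids:
        raise KeyError(f"gene {gene!r} not in cohort matrix")
    expr = cohort.values.loc[gene]
    common = expr.index.intersection(assignments.index)
    expr, labels = expr.loc[common], assignments.loc[common]
    rows, groups = [], {}
    for subtype in sorted(labels.unique()):
        vals = expr[labels == subtype].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append((subtype, len(vals), med, q3 - q1))
        if len(vals) >= 2:
            groups[subtype] = vals
        else:
            logger.info(
                "subtype %s has <2 samples; excluded from pairwise tests", subtype
            )
    summary = pd.DataFrame(
        rows, columns=["subtype", "n", "median", "iqr"]
    ).set_index("subtype")
    pairs = []
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            stat, p = ranksums(groups[a], groups[b])
            pairs.append((a, b, stat, p))
    pairwise = pd.DataFrame(pairs, columns=["subtype_1", "subtype_2", "statistic", "p"])
    return summary, pairwise
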