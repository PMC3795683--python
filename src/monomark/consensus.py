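"""Cross-channel consensus: fold-change rank merging and the ≥3/4 FDR rule.

The merged catalog mirrors the study's high-confidence marker lists: every
gene in the intersection of the four channels' tested universes receives a
direction (majority vote over the per-channel fold-change signs), a
fold-change rank per channel within that direction, the arithmetic mean of
the four ranks, and a count of channels calling it significant (q < alpha).
A gene passes when at least ``min_methods`` channels call it significant.

Also houses the expression filter and the unsupervised clustering separation
check used as an upstream quality gate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix
from .diffexp import ChannelResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def expression_filter(
    m: ExpressionMatrix, threshold: float = 1.0, min_samples: int = 1
) -> pd.Index:
    """Genes with a (normalized) value strictly greater than ``threshold`` in
    at least ``min_samples`` samples — the "expressed in >= 1 of 6" gate."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > m.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {m.n_samples} available samples"
        )
    keep = (m.values > threshold).sum(axis=1) >= min_samples
    return m.gene_ids[keep]


# ---------------------------------------------------------------------------
# rank merging
# ---------------------------------------------------------------------------

@dataclass
class RankTables:
    """Per-channel within-direction fold-change ranks over the intersected
    gene universe."""

    genes: pd.Index
    direction: pd.Series          # gene -> group1 label / group2 label / "none"
    ranks: pd.DataFrame           # genes x channels, NaN for "none" genes
    fold_changes: pd.DataFrame    # genes x channels (log2)
    qvalues: pd.DataFrame         # genes x channels
    ambiguous_ids: list = field(default_factory=list)   # 2-2 sign splits
    n_dropped: int = 0            # ids outside the intersection


def fold_change_ranks(results: list[ChannelResult]) -> RankTables:
    """Intersect the channels' gene universes, assign each gene a direction by
    majority fold-change sign, and rank genes within each channel and
    direction by descending |log2fc| (ties: ascending p, then ascending id).

    Genes whose signs split 2-2 (no majority) are kept in the universe but
    carry direction ``"none"`` and no ranks; they are reported in
    ``ambiguous_ids``.
    """
    if len(results) < 1:
        raise ValueError("at least one channel result required")
    g1, g2 = results[0].group1, results[0].group2
    for r in results:
        if (r.group1, r.group2) != (g1, g2):
            raise ValueError("channels disagree on group labels/order")
    common = results[0].table.index
    universe = len(common)
    for r in results[1:]:
        common = common.intersection(r.table.index)
        universe = max(universe, len(r.table.index))
    if len(common) == 0:
        raise ValueError("empty gene-id intersection across channels")
    common = common.sort_values()
    n_dropped = sum(len(r.table.index.difference(common)) for r in results)
    if n_dropped:
        logger.info("rank merging: %d gene records dropped at intersection", n_dropped)

    fc = pd.DataFrame(
        {r.channel: r.table["log2fc"].reindex(common) for r in results}
    )
    qv = pd.DataFrame({r.channel: r.table["q"].reindex(common) for r in results})
    pv = pd.DataFrame({r.channel: r.table["p"].reindex(common) for r in results})

    sign_sum = np.sign(fc.to_numpy()).sum(axis=1)
    direction = pd.Series(
        np.where(sign_sum > 0, g1, np.where(sign_sum < 0, g2, "none")),
        index=common,
        name="direction",
    )
    ambiguous = list(common[direction == "none"])
    if ambiguous:
        logger.info(
            "rank merging: %d genes with tied fold-change signs excluded from "
            "directional lists", len(ambiguous)
        )

    ranks = pd.DataFrame(np.nan, index=common, columns=[r.channel for r in results])
    for r in results:
        for d in (g1, g2):
            ids = common[direction == d]
            if len(ids) == 0:
                continue
            absfc = np.abs(fc.loc[ids, r.channel].to_numpy())
            p = pv.loc[ids, r.channel].to_numpy()
            order = np.lexsort((np.asarray(ids), p, -absfc))
            ranks.loc[ids[order], r.channel] = np.arange(1, len(ids) + 1, dtype=float)
    return RankTables(common, direction, ranks, fc, qv, ambiguous, n_dropped)


@dataclass
class ConsensusTable:
    """Merged marker catalog (the high-confidence list analog).

    ``table`` is indexed by gene id with columns ``direction``,
    ``fc_<channel>``, ``q_<channel>``, ``rank_<channel>``, ``mean_fc_rank``,
    ``n_significant`` and ``pass``; sorted by ascending mean rank within each
    direction (directional genes first).
    """

    table: pd.DataFrame
    alpha: float
    min_methods: int
    channels: list

    def pass_ids(self) -> pd.Index:
        return self.table.index[self.table["pass"]]

    def direction_list(self, direction) -> pd.DataFrame:
        sub = self.table[self.table["direction"] == direction]
        return sub.sort_values("mean_fc_rank")


def mean_rank_aggregate(
    rank_tables: RankTables, alpha: float = 0.05, min_methods: int = 3
) -> ConsensusTable:
    """Average the per-channel ranks and apply the significance-count rule:
    ``pass`` iff at least ``min_methods`` channels report q < ``alpha``."""
    channels = list(rank_tables.ranks.columns)
    if len(channels) != 4:
        raise ValueError(f"expected four channels, got {channels}")
    if rank_tables.ranks.isna().to_numpy().any():
        bad = rank_tables.ranks.index[rank_tables.ranks.isna().any(axis=1)]
        directional = [g for g in bad if rank_tables.direction[g] != "none"]
        if directional:
            raise ValueError(
                f"genes missing a channel rank (intersection violated): {directional[:10]}"
            )
    mean_rank = rank_tables.ranks.mean(axis=1)
    n_sig = (rank_tables.qvalues < alpha).sum(axis=1)
    out = pd.DataFrame({"direction": rank_tables.direction})
    for c in channels:
        out[f"fc_{c}"] = rank_tables.fold_changes[c]
        out[f"q_{c}"] = rank_tables.qvalues[c]
        out[f"rank_{c}"] = rank_tables.ranks[c]
    out["mean_fc_rank"] = mean_rank
    out["n_significant"] = n_sig.astype(int)
    out["pass"] = n_sig >= min_methods
    directional = out["direction"] != "none"
    out = pd.concat(
        [
            out[directional].sort_values(["direction", "mean_fc_rank"]),
            out[~directional],
        ]
    )
    out.index.name = "entrez_id"
    return ConsensusTable(out, alpha, min_methods, channels)


def build_consensus(
    results: list[ChannelResult], alpha: float = 0.05, min_methods: int = 3
) -> ConsensusTable:
    """Convenience wrapper: rank merging followed by mean-rank aggregation."""
    return mean_rank_aggregate(fold_change_ranks(results), alpha, min_methods)


# ---------------------------------------------------------------------------
# clustering separation check
# ---------------------------------------------------------------------------

def _leaf_sets(root, labels):
    out = []

    def visit(node):
        if node.is_leaf():
            s = frozenset([labels[node.id]])
        else:
            s = visit(node.left) | visit(node.right)
        out.append(s)
        return s

    visit(root)
    return out


def cluster_separation(m: ExpressionMatrix, gene_ids=None):
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    Returns ``(linkage_matrix, separated)`` where ``separated`` is True iff
    every group's samples form one exclusive subtree of the dendrogram.
    """
    if gene_ids is not None:
        m = m.subset_genes(gene_ids)
    groups = {g: set(m.samples_in_group(g)) for g in m.group_names()}
    X = m.values.to_numpy(dtype=float)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = list(m.sample_ids[sds == 0])
        raise ValueError(
            f"constant expression profile for samples {bad}; correlation is "
            "undefined — widen the gene filter"
        )
    corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    leafsets = _leaf_sets(to_tree(Z), list(m.sample_ids))
    separated = all(frozenset(s) in leafsets for s in groups.values())
    return Z, separated
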