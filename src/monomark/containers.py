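"""Shared data containers.

The whole pipeline operates on gene-by-sample expression tables. A single
container, :class:`ExpressionMatrix`, carries the values together with a
platform tag (``"count"`` for sequencing-style nonnegative values such as raw
counts, CPM or FPKM; ``"intensity"`` for array-style log2 intensities) and an
optional mapping from sample id to group or subtype label.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNT = "count"
INTENSITY = "intensity"
PLATFORMS = (COUNT, INTENSITY)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id (Entrez-style integers in the synthetic
        pipeline; probe ids are tolerated for external data), columns are
        sample ids.
    platform
        ``"count"`` or ``"intensity"``.
    groups
        Optional mapping ``sample id -> group label`` covering every column.
    """

    values: pd.DataFrame
    platform: str
    groups: dict | None = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        idx = self.values.index
        if idx.duplicated().any():
            dupes = sorted(map(str, idx[idx.duplicated()].unique()))
            raise ValueError(f"duplicate gene ids: {', '.join(dupes[:10])}")
        vals = self.values.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.platform == COUNT and vals.size and np.nanmin(vals) < 0:
            raise ValueError("count-platform values must be nonnegative")
        if self.groups is not None:
            missing = [s for s in self.values.columns if s not in self.groups]
            if missing:
                raise ValueError(f"samples without a group label: {missing}")

    # -- convenience accessors ------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_names(self) -> list:
        """Distinct group labels, sorted for deterministic ordering."""
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        return sorted(set(self.groups[s] for s in self.values.columns))

    def samples_in_group(self, group) -> list:
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        return [s for s in self.values.columns if self.groups[s] == group]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], self.platform, self.groups
        )


def two_group_split(m: ExpressionMatrix, group_order=None):
    """Return ``(g1, g2, values1, values2)`` for a two-group matrix.

    ``group_order`` fixes which label is treated as group 1 (the numerator of
    fold changes); by default labels are taken in sorted order.
    """
    names = m.group_names()
    if len(names) != 2:
        raise ValueError(f"expected exactly two groups, found {names}")
    if group_order is not None:
        if sorted(group_order) != sorted(names):
            raise ValueError(f"group_order {group_order} does not match labels {names}")
        g1, g2 = group_order
    else:
        g1, g2 = names
    s1 = m.samples_in_group(g1)
    s2 = m.samples_in_group(g2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs at least 2 samples")
    return g1, g2, m.values[s1], m.values[s2]
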