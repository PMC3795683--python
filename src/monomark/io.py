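"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-delimited UTF-8 with '.' decimals and "NA" as the missing
value token. Expression matrices have the gene id in the first column and a
header row of sample ids. A minimal reader for the GEO series-matrix text
format is provided as a convenience for external cohorts.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .survival import SurvivalCohort

logger = logging.getLogger(__name__)


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                       keep_default_na=False)


def read_expression(path, platform, groups: dict | None = None) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV.

    Duplicate gene ids and non-numeric cells raise errors that name the
    offending id / row-column coordinates.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected a gene-id column plus sample columns")
    id_col = raw.columns[0]
    ids = raw[id_col]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    values = raw.drop(columns=[id_col])
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {values.iat[r, c]!r} at data row "
            f"{r + 1}, column {values.columns[c]!r}"
        )
    try:
        index = pd.Index(ids.astype(int), name=id_col)
    except ValueError:
        index = pd.Index(ids, name=id_col)
    numeric.index = index
    return ExpressionMatrix(numeric, platform, groups)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


def read_groups(path) -> dict:
    """Read a (sample, group) TSV into a mapping."""
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["sample", "group"] and df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns 'sample' and 'group'")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_clinical(path, event_map: dict | None = None) -> SurvivalCohort:
    """Read a clinical TSV (sample, time, event, optional subtype/marker).

    ``event_map`` converts string event labels (e.g. {"dead": 1, "alive": 0})
    before validation. Errors carry the offending line number (1-based,
    counting the header as line 1).
    """
    df = _read_tsv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("sample", "time", "event"):
        if needed not in cols:
            raise ValueError(f"{path}: missing required column {needed!r}")
    out = pd.DataFrame(index=pd.Index(df[cols["sample"]], name="sample"))
    times = pd.to_numeric(df[cols["time"]], errors="coerce")
    for i, t in enumerate(times):
        if pd.isna(t):
            raise ValueError(f"{path}: missing or non-numeric time at line {i + 2}")
        if t <= 0:
            raise ValueError(f"{path}: nonpositive time {t} at line {i + 2}")
    out["time"] = times.to_numpy(dtype=float)
    events_raw = df[cols["event"]]
    if event_map:
        events_raw = events_raw.map(lambda v: event_map.get(v, v))
    events = pd.to_numeric(events_raw, errors="coerce")
    for i, e in enumerate(events):
        if pd.isna(e) or e not in (0, 1):
            raise ValueError(
                f"{path}: event value {df[cols['event']].iloc[i]!r} not in "
                f"{{0,1}} at line {i + 2}"
            )
    out["event"] = events.to_numpy(dtype=int)
    for optional in ("subtype", "marker", "marker_group"):
        if optional in cols:
            col = df[cols[optional]]
            if optional == "marker":
                col = pd.to_numeric(col, errors="coerce")
            out[optional] = col.to_numpy()
    return SurvivalCohort(out)


def write_clinical(cohort: SurvivalCohort, path) -> None:
    cohort.data.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


def read_series_matrix(path, platform="intensity"):
    """Parse a GEO series-matrix text file.

    Returns ``(ExpressionMatrix, sample_metadata)`` where the metadata frame
    collects every ``!Sample_*`` annotation row (one row per annotation,
    columns = samples).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    meta_rows = []
    table_lines = []
    in_table = False
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!Sample_"):
                parts = [p.strip('"') for p in line.split("\t")]
                meta_rows.append(parts)
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix_table section found")
    header = [p.strip('"') for p in table_lines[0].split("\t")]
    records = [
        [p.strip('"') for p in line.split("\t")] for line in table_lines[1:]
    ]
    df = pd.DataFrame(records, columns=header).set_index(header[0])
    values = df.apply(pd.to_numeric, errors="coerce")
    metadata = pd.DataFrame(
        [r[1:] for r in meta_rows],
        index=[r[0].lstrip("!") for r in meta_rows],
    )
    sample_ids = None
    for key in ("Sample_geo_accession", "Sample_title"):
        if key in metadata.index:
            sample_ids = list(metadata.loc[key])
            break
    if sample_ids and len(sample_ids) == values.shape[1]:
        metadata.columns = sample_ids
    m = ExpressionMatrix(values, platform)
    return m, metadata


def write_channel_result(result, path) -> None:
    result.table.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


def read_channel_result(path, channel, group1, group2):
    from .diffexp import ChannelResult

    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    needed = {"log2fc", "p", "q", "direction", "fc_rank"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: not a channel result table")
    return ChannelResult(channel, group1, group2, df)


def write_consensus(consensus, path) -> None:
    consensus.table.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")
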