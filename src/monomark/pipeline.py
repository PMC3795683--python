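"""Pipeline orchestration: configuration, artifact management, stage driver.

``run_pipeline(cfg, command)`` executes one stage and leaves its artifacts
under ``cfg.outdir``; downstream stages read the upstream artifacts and fail
with an actionable error when one is missing. Given fixed seeds the whole
chain is deterministic (identical artifact bytes on rerun).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .consensus import build_consensus, cluster_separation, expression_filter
from .containers import COUNT, INTENSITY
from .diffexp import CHANNELS, normalize_counts, run_channel
from .groupstats import kruskal_dunn
from .simdata import CohortSimConfig, TwoPopSimConfig, write_fixtures
from .subtype import SubtypeReference, knn_assign, match_signature_genes, \
    subtype_expression_summary
from .survival import SurvivalCohort, logrank_test, marker_univariate, \
    median_dichotomize, subtype_adjusted_analysis

logger = logging.getLogger(__name__)

COMMANDS = ("simulate", "de", "consensus", "subtype", "survival", "stats", "report")


@dataclass
class PipelineConfig:
    """Stage parameters for the whole pipeline.

    Defaults reproduce the reference settings: FDR 0.05, significance in at
    least 3 of the 4 channels, k = 10 nearest neighbors, expression threshold
    1 in at least 1 sample, median dichotomization, Mesenchymal as the
    reference subtype.
    """

    outdir: Path = Path("monomark_out")
    seed: int = 0
    fdr: float = 0.05
    min_methods: int = 3
    knn_k: int = 10
    expr_threshold: float = 1.0
    expr_min_samples: int = 1
    reference_subtype: str = "Mesenchymal"
    marker_gene: int | None = None     # default: the simulated marker gene
    top_n: int = 20
    twopop: TwoPopSimConfig | None = None
    cohort: CohortSimConfig | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.twopop is None:
            self.twopop = TwoPopSimConfig(seed=self.seed)
        if self.cohort is None:
            self.cohort = CohortSimConfig(seed=self.seed + 1)
        if self.marker_gene is None:
            self.marker_gene = self.cohort.marker_gene_id


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name!r} ({path}); run the "
            f"{produced_by!r} command first"
        )
    return path


def _fixdir(cfg: PipelineConfig) -> Path:
    return cfg.outdir / "fixtures"


def run_pipeline(cfg: PipelineConfig, command: str) -> dict:
    """Run one pipeline stage; returns a dict of artifact paths plus counts."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; expected one of {COMMANDS}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    return _STAGES[command](cfg)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig) -> dict:
    paths = write_fixtures(_fixdir(cfg), cfg.twopop, cfg.cohort)
    logger.info("simulate: wrote %d fixture files to %s", len(paths), _fixdir(cfg))
    return {"artifacts": {k: str(p) for k, p in paths.items()}}


def _load_channel_matrix(cfg: PipelineConfig, name: str):
    fix = _fixdir(cfg)
    groups = mio.read_groups(_require(fix / "groups.tsv", "simulate"))
    platform = COUNT if name in ("A", "B") else INTENSITY
    return mio.read_expression(
        _require(fix / f"channel_{name}.tsv", "simulate"), platform, groups
    )


def _stage_de(cfg: PipelineConfig) -> dict:
    out = {}
    counts = {}
    for name in CHANNELS:
        m = _load_channel_matrix(cfg, name)
        res = run_channel(m, name)
        path = cfg.outdir / f"de_channel_{name}.tsv"
        mio.write_channel_result(res, path)
        out[name] = str(path)
        counts[name] = {
            "n_tested": int(len(res.table)),
            "n_excluded": res.n_excluded,
        }
        logger.info(
            "de channel %s: %d genes tested, %d excluded",
            name, len(res.table), res.n_excluded,
        )
    meta = {"groups": [res.group1, res.group2], "counts": counts}
    (cfg.outdir / "de_meta.json").write_text(json.dumps(meta, sort_keys=True))
    return {"artifacts": out, "counts": counts}


def _stage_consensus(cfg: PipelineConfig) -> dict:
    meta_path = _require(cfg.outdir / "de_meta.json", "de")
    meta = json.loads(meta_path.read_text())
    g1, g2 = meta["groups"]
    results = [
        mio.read_channel_result(
            _require(cfg.outdir / f"de_channel_{name}.tsv", "de"), name, g1, g2
        )
        for name in CHANNELS
    ]
    cons = build_consensus(results, alpha=cfg.fdr, min_methods=cfg.min_methods)
    path = cfg.outdir / "consensus.tsv"
    mio.write_consensus(cons, path)

    # expression filter + clustering separation check on the first count channel
    m = _load_channel_matrix(cfg, "A")
    cpm = normalize_counts(m)
    kept = expression_filter(cpm, cfg.expr_threshold, cfg.expr_min_samples)
    _, separated = cluster_separation(cpm, kept)
    summary = {
        "n_pass": int(cons.table["pass"].sum()),
        "n_ambiguous_direction": int((cons.table["direction"] == "none").sum()),
        "n_genes_after_expression_filter": int(len(kept)),
        "n_genes_dropped_by_filter": int(m.n_genes - len(kept)),
        "cluster_separation": bool(separated),
    }
    (cfg.outdir / "consensus_meta.json").write_text(
        json.dumps(summary, sort_keys=True)
    )
    logger.info("consensus: %s", summary)
    return {"artifacts": {"consensus": str(path)}, **summary}


def _stage_subtype(cfg: PipelineConfig) -> dict:
    fix = _fixdir(cfg)
    cohort_expr = mio.read_expression(
        _require(fix / "cohort_expression.tsv", "simulate"), INTENSITY
    )
    ref_profiles = mio.read_expression(
        _require(fix / "reference_expression.tsv", "simulate"), INTENSITY
    )
    ref_labels = pd.read_csv(
        _require(fix / "reference_labels.tsv", "simulate"), sep="\t"
    )
    ref = SubtypeReference(
        ref_profiles.values, dict(zip(ref_labels["sample"], ref_labels["subtype"]))
    )
    signature = cohort_expr.values.drop(index=cfg.marker_gene, errors="ignore")
    matched = match_signature_genes(signature, ref)
    assignments = knn_assign(signature, ref, k=cfg.knn_k, matched=matched)
    path = cfg.outdir / "assignments.tsv"
    assignments.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")
    counts = {
        "n_matched_genes": matched.n_matched,
        "n_dropped_cohort": matched.n_dropped_cohort,
        "n_dropped_reference": matched.n_dropped_reference,
        "n_assigned": int(len(assignments)),
    }
    logger.info("subtype: %s", counts)
    return {"artifacts": {"assignments": str(path)}, **counts}


def _assemble_cohort(cfg: PipelineConfig) -> SurvivalCohort:
    fix = _fixdir(cfg)
    cohort = mio.read_clinical(_require(fix / "clinical.tsv", "simulate"))
    expr = mio.read_expression(
        _require(fix / "cohort_expression.tsv", "simulate"), INTENSITY
    )
    assignments = pd.read_csv(
        _require(cfg.outdir / "assignments.tsv", "subtype"), sep="\t", index_col=0
    )
    df = cohort.data.copy()
    df["marker"] = expr.values.loc[cfg.marker_gene].reindex(df.index).to_numpy()
    df["subtype"] = assignments["subtype"].reindex(df.index).to_numpy()
    if df["marker"].isna().any():
        raise ValueError("marker expression missing for some cohort samples")
    return SurvivalCohort(df)


def _stage_survival(cfg: PipelineConfig) -> dict:
    cohort = _assemble_cohort(cfg)
    df = cohort.data
    df = df.assign(marker_group=median_dichotomize(df["marker"].to_numpy()))
    cohort = SurvivalCohort(df)
    lr = logrank_test(cohort, by="marker_group")
    report = {
        "n": cohort.n,
        "n_events": cohort.n_events,
        "logrank": {"statistic": lr.statistic, "p": lr.p},
        "univariate": {},
        "subtype_adjusted": {},
    }
    for mode in ("dichotomized", "continuous"):
        uni = marker_univariate(cohort, mode)
        row = uni.summary.iloc[0]
        report["univariate"][mode] = {
            "hr": row["hr"], "ci_low": row["ci_low"], "ci_high": row["ci_high"],
            "p": row["p"], "converged": uni.converged,
        }
        adj = subtype_adjusted_analysis(
            cohort, mode, reference=cfg.reference_subtype
        )
        report["subtype_adjusted"][mode] = {
            "table": {
                var: {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in row.items()
                }
                for var, row in adj.table.iterrows()
            },
            "converged": adj.fit.converged,
            "unstable_subtypes": adj.unstable_subtypes,
        }
    path = cfg.outdir / "survival_report.json"
    path.write_text(json.dumps(_round_floats(report), indent=2, sort_keys=True))
    adj_tsv = cfg.outdir / "survival_table.tsv"
    subtype_adjusted_analysis(
        cohort, "dichotomized", reference=cfg.reference_subtype
    ).table.to_csv(adj_tsv, sep="\t", float_format="%.6g", na_rep="NA")
    logger.info("survival: logrank p=%.4g", lr.p)
    return {"artifacts": {"survival_report": str(path), "survival_table": str(adj_tsv)}}


def _stage_stats(cfg: PipelineConfig) -> dict:
    cohort = _assemble_cohort(cfg)
    fix = _fixdir(cfg)
    expr = mio.read_expression(fix / "cohort_expression.tsv", INTENSITY)
    assignments = cohort.data["subtype"]
    summary, pairwise = subtype_expression_summary(
        expr, assignments, cfg.marker_gene
    )
    groups = [
        cohort.data.loc[assignments == s, "marker"].to_numpy()
        for s in sorted(assignments.unique())
        if (assignments == s).sum() >= 2
    ]
    out = {
        "per_subtype": {
            s: {"n": int(r["n"]), "median": r["median"], "iqr": r["iqr"]}
            for s, r in summary.iterrows()
        },
        "pairwise_ranksum": [
            {
                "subtype_1": r["subtype_1"], "subtype_2": r["subtype_2"],
                "p": r["p"],
            }
            for _, r in pairwise.iterrows()
        ],
    }
    if len(groups) >= 3:
        kd = kruskal_dunn(groups)
        out["kruskal"] = {"h": kd.h, "p": kd.p}
    path = cfg.outdir / "stats.json"
    path.write_text(json.dumps(_round_floats(out), indent=2, sort_keys=True))
    return {"artifacts": {"stats": str(path)}}


def _stage_report(cfg: PipelineConfig) -> dict:
    consensus_path = _require(cfg.outdir / "consensus.tsv", "consensus")
    survival_path = _require(cfg.outdir / "survival_report.json", "survival")
    consensus_meta = json.loads(
        _require(cfg.outdir / "consensus_meta.json", "consensus").read_text()
    )
    cons = pd.read_csv(consensus_path, sep="\t", index_col=0, na_values=["NA"])
    top = {}
    for direction, sub in cons[cons["pass"]].groupby("direction"):
        ordered = sub.sort_values("mean_fc_rank").head(cfg.top_n)
        top[str(direction)] = [
            {"entrez_id": int(g), "mean_fc_rank": float(r["mean_fc_rank"]),
             "n_significant": int(r["n_significant"])}
            for g, r in ordered.iterrows()
        ]
    report = {
        "parameters": {
            "fdr": cfg.fdr, "min_methods": cfg.min_methods, "knn_k": cfg.knn_k,
            "expr_threshold": cfg.expr_threshold,
            "expr_min_samples": cfg.expr_min_samples,
            "reference_subtype": cfg.reference_subtype, "seed": cfg.seed,
        },
        "consensus": {"summary": consensus_meta, "top": top},
        "survival": json.loads(Path(survival_path).read_text()),
    }
    path = cfg.outdir / "report.json"
    path.write_text(json.dumps(_round_floats(report), indent=2, sort_keys=True))
    logger.info("report: wrote %s", path)
    return {"artifacts": {"report": str(path)}}


def _round_floats(obj, digits: int = 10):
    """Round floats for stable, rerun-identical JSON artifacts."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


_STAGES = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "consensus": _stage_consensus,
    "subtype": _stage_subtype,
    "survival": _stage_survival,
    "stats": _stage_stats,
    "report": _stage_report,
}
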