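"""Seeded synthetic-data generators with known ground truth.

Two generators provide every input the pipeline needs:

* :func:`simulate_two_population_expression` emulates two FACS-purified cell
  populations (e.g. bone-marrow-derived monocytes vs brainstem microglia),
  three biological replicates each, measured on a sequencing platform
  (overdispersed counts; two independent count channels A/B) and an array
  platform (Gaussian log2 intensities; two independent intensity channels
  C/D). All four channels observe the same latent per-sample log2 expression
  and add channel-specific noise, so cross-channel rank agreement is
  informative rather than trivial. A configurable set of marker genes
  carries large population-specific fold changes (applied as a symmetric
  +/- log2FC/2 split so library composition stays balanced in expectation).

* :func:`simulate_survival_cohort` emulates a tumor cohort with subtype
  centroids over a signature gene set, one prognostic marker gene whose
  High/Low status (relative to the cohort median) multiplies the hazard,
  exponential event times under proportional hazards, and independent
  exponential censoring.

Every generator is deterministic given its config seed.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import COUNT, INTENSITY, ExpressionMatrix
from .subtype import SubtypeReference
from .survival import SurvivalCohort, median_dichotomize


class ConfigError(ValueError):
    """Invalid simulation configuration."""


DEFAULT_SUBTYPES = ("Classical", "Mesenchymal", "Neural", "Proneural")
# sample counts per subtype in the reference GBM cohort the pipeline emulates
_DEFAULT_PROPORTIONS = (33 / 159, 58 / 159, 19 / 159, 49 / 159)
_DEFAULT_SUBTYPE_LOG_HRS = {
    "Classical": math.log(0.89),
    "Mesenchymal": 0.0,
    "Neural": math.log(1.13),
    "Proneural": math.log(0.60),
}


def _check_interval(name, interval, positive_lower=False):
    lo, hi = interval
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
        raise ConfigError(f"degenerate {name} interval: {interval}")
    if positive_lower and lo <= 0:
        raise ConfigError(f"{name} lower bound must be positive, got {lo}")


@dataclass
class TwoPopSimConfig:
    """Study conditions for the two-population, two-platform experiment.

    Defaults mirror the catalog-discovery setting: 10,000 genes, 150 marker
    genes per direction with log2 fold changes between 2 and 12, three
    biological replicates per population, and lane yields of 15-22 million
    reads. Noise defaults describe FACS-purified populations pooled from many
    animals per replicate, which keeps between-replicate variation far below
    single-animal bulk tissue: count overdispersion 0.01, array noise 0.1
    log2 units, and 0.05 log2 units of shared biological replicate scatter
    (``sample_log2_sd``, the single between-replicate variance knob seen by
    all channels).
    """

    n_genes: int = 10_000
    n_marker_per_direction: int = 150
    log2fc_range: tuple = (2.0, 12.0)
    replicates_per_group: int = 3
    count_dispersion: float = 0.01
    intensity_sd: float = 0.1
    sample_log2_sd: float = 0.05
    library_size_range: tuple = (15e6, 22e6)
    group_names: tuple = ("pop1", "pop2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_marker_per_direction * 2 > self.n_genes:
            raise ConfigError("2 * n_marker_per_direction must not exceed n_genes")
        _check_interval("log2fc_range", self.log2fc_range, positive_lower=True)
        _check_interval("library_size_range", self.library_size_range,
                        positive_lower=True)
        if self.replicates_per_group < 2:
            raise ConfigError("replicates_per_group must be >= 2")
        if self.count_dispersion < 0 or self.intensity_sd < 0 or self.sample_log2_sd < 0:
            raise ConfigError("noise parameters must be nonnegative")
        if len(self.group_names) != 2 or len(set(self.group_names)) != 2:
            raise ConfigError("group_names must be two distinct labels")


@dataclass
class TwoPopSimResult:
    channels: dict            # "A"/"B" -> count ExpressionMatrix, "C"/"D" -> intensity
    truth: pd.DataFrame       # per gene: direction (pop1/pop2/null), true_log2fc
    config: TwoPopSimConfig


def simulate_two_population_expression(cfg: TwoPopSimConfig) -> TwoPopSimResult:
    """Generate the four channel matrices plus the ground-truth table.

    The latent log2 expression of gene g in sample s is
    ``mu_g + effect(g, group(s)) + N(0, sample_log2_sd)``; counts are drawn
    negative-binomially around library-scaled relative abundances (Poisson in
    the zero-dispersion limit) and intensities are the latent values plus
    Gaussian channel noise. ``true_log2fc`` is the group-1-over-group-2
    log2 fold change (positive for group-1-enriched markers).
    """
    rng = np.random.default_rng(cfg.seed)
    g1, g2 = cfg.group_names
    n, nm, reps = cfg.n_genes, cfg.n_marker_per_direction, cfg.replicates_per_group
    gene_ids = pd.Index(np.arange(10_001, 10_001 + n), name="entrez_id")
    mu = rng.normal(5.0, 2.0, n)
    fc = rng.uniform(cfg.log2fc_range[0], cfg.log2fc_range[1], 2 * nm)

    direction = np.array(["null"] * n, dtype=object)
    direction[:nm] = g1
    direction[nm:2 * nm] = g2
    true_log2fc = np.zeros(n)
    true_log2fc[:nm] = fc[:nm]
    true_log2fc[nm:2 * nm] = -fc[nm:]

    samples = [f"{g}_{i + 1}" for g in (g1, g2) for i in range(reps)]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    group_sign = np.array([1.0 if groups[s] == g1 else -1.0 for s in samples])
    # symmetric +/- fc/2 split keeps library composition balanced in expectation
    effect = 0.5 * np.outer(true_log2fc, group_sign)
    latent = (
        mu[:, None]
        + effect
        + rng.normal(0.0, cfg.sample_log2_sd, (n, len(samples)))
    )

    def draw_counts() -> pd.DataFrame:
        libs = rng.uniform(*cfg.library_size_range, len(samples))
        abundance = np.power(2.0, latent)
        mean = abundance / abundance.sum(axis=0) * libs
        if cfg.count_dispersion < 1e-12:
            counts = rng.poisson(mean)
        else:
            nb_n = 1.0 / cfg.count_dispersion
            nb_p = nb_n / (nb_n + mean)
            counts = rng.negative_binomial(nb_n, nb_p)
        return pd.DataFrame(counts, index=gene_ids, columns=samples)

    def draw_intensity() -> pd.DataFrame:
        vals = latent + rng.normal(0.0, cfg.intensity_sd, latent.shape)
        return pd.DataFrame(vals, index=gene_ids, columns=samples)

    channels = {
        "A": ExpressionMatrix(draw_counts(), COUNT, groups),
        "B": ExpressionMatrix(draw_counts(), COUNT, groups),
        "C": ExpressionMatrix(draw_intensity(), INTENSITY, groups),
        "D": ExpressionMatrix(draw_intensity(), INTENSITY, groups),
    }
    truth = pd.DataFrame(
        {"direction": direction, "true_log2fc": true_log2fc}, index=gene_ids
    )
    return TwoPopSimResult(channels, truth, cfg)


@dataclass
class CohortSimConfig:
    """Study conditions for the synthetic tumor cohort.

    Defaults mirror the survival setting the pipeline emulates: 159 samples
    split across the four GBM subtypes in the proportions 33/58/19/49, a
    dichotomized marker hazard ratio of 1.57, and subtype hazard ratios of
    0.89 / 1 / 1.13 / 0.60 against the Mesenchymal reference. Survival times
    are on an arbitrary common time scale. ``noise_sd`` defaults to
    0.25 x centroid_separation.
    """

    n_samples: int = 159
    subtype_labels: tuple = DEFAULT_SUBTYPES
    subtype_proportions: tuple = _DEFAULT_PROPORTIONS
    n_signature_genes: int = 40
    centroid_separation: float = 2.0
    noise_sd: float | None = None
    marker_log_hr: float = math.log(1.57)
    baseline_hazard: float = 0.2
    censoring_rate: float = 0.05
    subtype_log_hrs: dict = field(
        default_factory=lambda: dict(_DEFAULT_SUBTYPE_LOG_HRS)
    )
    marker_gene_id: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subtype_labels) != len(self.subtype_proportions):
            raise ConfigError("labels and proportions must align")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-12:
            raise ConfigError("subtype proportions must sum to 1")
        if min(self.subtype_proportions) < 0:
            raise ConfigError("subtype proportions must be nonnegative")
        if self.n_samples < 20:
            raise ConfigError("n_samples must be >= 20")
        if self.censoring_rate < 0:
            raise ConfigError("censoring_rate must be >= 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        unknown = set(self.subtype_log_hrs) - set(self.subtype_labels)
        if unknown:
            raise ConfigError(f"unknown subtype labels in subtype_log_hrs: {sorted(unknown)}")
        if self.n_signature_genes < len(self.subtype_labels):
            raise ConfigError("need at least one signature gene per subtype")
        if self.noise_sd is None:
            self.noise_sd = 0.25 * self.centroid_separation
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")

    def signature_gene_ids(self) -> pd.Index:
        return pd.Index(
            np.arange(40_001, 40_001 + self.n_signature_genes), name="entrez_id"
        )

    def centroids(self) -> pd.DataFrame:
        """Signature-gene centroid per subtype: a baseline of 6.0 log2 units
        with one block of genes elevated by ``centroid_separation`` per
        subtype."""
        ids = self.signature_gene_ids()
        k = len(self.subtype_labels)
        block = len(ids) // k
        cent = pd.DataFrame(6.0, index=ids, columns=list(self.subtype_labels))
        for i, label in enumerate(self.subtype_labels):
            lo = i * block
            hi = (i + 1) * block if i < k - 1 else len(ids)
            cent.iloc[lo:hi, i] += self.centroid_separation
        return cent


@dataclass
class CohortSimResult:
    expression: ExpressionMatrix   # signature genes + marker gene, log2 scale
    cohort: SurvivalCohort         # time, event, marker, subtype (true)
    truth: dict                    # generating parameters and latent states
    config: CohortSimConfig


def simulate_survival_cohort(cfg: CohortSimConfig) -> CohortSimResult:
    """Generate cohort expression, censored survival times and the truth
    record. The marker's High/Low status relative to the realized cohort
    median multiplies the hazard by exp(marker_log_hr)."""
    rng = np.random.default_rng(cfg.seed)
    labels = np.array(cfg.subtype_labels, dtype=object)
    subtype = rng.choice(labels, size=cfg.n_samples, p=cfg.subtype_proportions)
    samples = pd.Index([f"S{i + 1:04d}" for i in range(cfg.n_samples)], name="sample")

    cent = cfg.centroids()
    expr = (
        cent[subtype].to_numpy()
        + rng.normal(0.0, cfg.noise_sd, (len(cent), cfg.n_samples))
    )
    marker = rng.normal(6.0, 1.0, cfg.n_samples)
    values = pd.DataFrame(
        np.vstack([expr, marker]),
        index=cent.index.append(pd.Index([cfg.marker_gene_id])),
        columns=samples,
    )
    values.index.name = "entrez_id"

    high = median_dichotomize(marker) == "High"
    log_hr = np.array(
        [cfg.subtype_log_hrs.get(s, 0.0) for s in subtype], dtype=float
    ) + cfg.marker_log_hr * high
    rate = cfg.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censoring_rate, cfg.n_samples)
    else:
        t_cens = np.full(cfg.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    cohort = SurvivalCohort(
        pd.DataFrame(
            {"time": time, "event": event, "marker": marker, "subtype": subtype},
            index=samples,
        )
    )
    groups = dict(zip(samples, subtype))
    truth = {
        "marker_log_hr": cfg.marker_log_hr,
        "subtype_log_hrs": dict(cfg.subtype_log_hrs),
        "baseline_hazard": cfg.baseline_hazard,
        "censoring_rate": cfg.censoring_rate,
        "subtype": dict(zip(samples, subtype)),
        "marker_high": dict(zip(samples, map(bool, high))),
    }
    expression = ExpressionMatrix(values, INTENSITY, groups)
    return CohortSimResult(expression, cohort, truth, cfg)


def simulate_subtype_reference(
    cfg: CohortSimConfig, n_per_subtype: int = 10, seed: int | None = None
) -> SubtypeReference:
    """Labeled reference profiles drawn around the same subtype centroids
    (independent noise; default seed offset from the cohort's)."""
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    cent = cfg.centroids()
    cols, labels = [], {}
    blocks = []
    for label in cfg.subtype_labels:
        for i in range(n_per_subtype):
            name = f"REF_{label}_{i + 1}"
            cols.append(name)
            labels[name] = label
            blocks.append(
                cent[label].to_numpy()
                + rng.normal(0.0, cfg.noise_sd, len(cent))
            )
    profiles = pd.DataFrame(np.column_stack(blocks), index=cent.index, columns=cols)
    return SubtypeReference(profiles, labels)


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def _df_to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


def write_fixtures(
    outdir,
    twopop_cfg: TwoPopSimConfig | None = None,
    cohort_cfg: CohortSimConfig | None = None,
    n_reference_per_subtype: int = 10,
) -> dict:
    """Write every TSV/JSON input the pipeline consumes, with a manifest of
    seeds and ground truth. Returns a mapping of artifact name -> path."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as err:
        raise OSError(f"cannot write fixtures to {outdir}: {err}") from err

    twopop_cfg = twopop_cfg or TwoPopSimConfig()
    cohort_cfg = cohort_cfg or CohortSimConfig()

    paths = {}
    sim = simulate_two_population_expression(twopop_cfg)
    for name, m in sim.channels.items():
        p = outdir / f"channel_{name}.tsv"
        _df_to_tsv(m.values, p)
        paths[f"channel_{name}"] = p
    groups = pd.DataFrame(
        {"sample": list(sim.channels["A"].sample_ids),
         "group": [sim.channels["A"].groups[s] for s in sim.channels["A"].sample_ids]}
    )
    paths["groups"] = outdir / "groups.tsv"
    groups.to_csv(paths["groups"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    _df_to_tsv(sim.truth, paths["truth_genes"])

    cohort_sim = simulate_survival_cohort(cohort_cfg)
    paths["cohort_expression"] = outdir / "cohort_expression.tsv"
    _df_to_tsv(cohort_sim.expression.values, paths["cohort_expression"])
    clinical = cohort_sim.cohort.data.copy()
    paths["clinical"] = outdir / "clinical.tsv"
    _df_to_tsv(clinical, paths["clinical"])

    ref = simulate_subtype_reference(cohort_cfg, n_reference_per_subtype)
    paths["reference_expression"] = outdir / "reference_expression.tsv"
    _df_to_tsv(ref.profiles, paths["reference_expression"])
    ref_labels = pd.DataFrame(
        {"sample": list(ref.profiles.columns),
         "subtype": [ref.labels[s] for s in ref.profiles.columns]}
    )
    paths["reference_labels"] = outdir / "reference_labels.tsv"
    ref_labels.to_csv(paths["reference_labels"], sep="\t", index=False)

    manifest = {
        "twopop_config": _jsonable(asdict(twopop_cfg)),
        "cohort_config": _jsonable(asdict(cohort_cfg)),
        "n_reference_per_subtype": n_reference_per_subtype,
        "n_genes": twopop_cfg.n_genes,
        "n_marker_per_direction": twopop_cfg.n_marker_per_direction,
        "cohort_truth": {
            "marker_log_hr": cohort_cfg.marker_log_hr,
            "subtype_log_hrs": cohort_cfg.subtype_log_hrs,
        },
        "files": {k: p.name for k, p in paths.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
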