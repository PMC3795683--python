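"""Kaplan-Meier, log-rank and Cox proportional-hazards machinery.

A biomarker's prognostic value is evaluated the way the source study design
prescribes: the marker is dichotomized at the cohort median (values strictly
above the median are "High", ties go to "Low"), Kaplan-Meier curves and a
log-rank test compare the High/Low groups, and Cox models (univariate, and
multivariate with subtype dummy-coded against a declared reference level,
Mesenchymal by default) report hazard ratios with Wald 95% confidence
intervals. Tied event times use the Efron approximation. The joint effect of
a categorical block is summarized by a Wald chi-square on its dummy
coefficients (a likelihood-ratio variant is available).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import ConvergenceWarning
from scipy import stats

logger = logging.getLogger(__name__)

Z95 = 1.959964  # two-sided 95% normal quantile used for Wald intervals


@dataclass
class SurvivalCohort:
    """Per-sample survival records.

    ``data`` is indexed by sample id with columns ``time`` (positive),
    ``event`` (0/1) and optionally ``marker`` (continuous expression),
    ``subtype`` and ``marker_group`` (High/Low after dichotomization).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival cohort requires a {col!r} column")
        times = self.data["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("survival times must be finite and positive")
        ev = set(self.data["event"].unique())
        if not ev <= {0, 1}:
            raise ValueError(f"event indicator must be 0/1, found {sorted(ev)}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def with_marker_groups(self, marker_col: str = "marker") -> "SurvivalCohort":
        df = self.data.copy()
        df["marker_group"] = median_dichotomize(df[marker_col].to_numpy(dtype=float))
        return SurvivalCohort(df)


def median_dichotomize(values) -> np.ndarray:
    """Label values strictly above the median "High", the rest "Low"."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or not np.all(np.isfinite(values)):
        raise ValueError("need >= 2 finite values to dichotomize")
    med = np.median(values)
    if np.all(values == values[0]):
        raise ValueError("all values identical; no median split exists")
    return np.where(values > med, "High", "Low")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(cohort: SurvivalCohort, by: str | None = None) -> dict:
    """Product-limit survival estimate per group (one group named "all" when
    ``by`` is None). Each entry is a DataFrame with columns ``time``,
    ``survival`` and ``at_risk``."""
    df = cohort.data
    groups = {"all": df} if by is None else dict(tuple(df.groupby(by)))
    out = {}
    for name, sub in groups.items():
        if len(sub) == 0:
            raise ValueError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        table = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        out[name] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "at_risk": table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


@dataclass
class LogrankResult:
    statistic: float
    p: float
    groups: tuple


def logrank_test(cohort: SurvivalCohort, by: str = "marker_group") -> LogrankResult:
    """Two-group log-rank chi-square on the standard hypergeometric
    per-event-time contributions."""
    df = cohort.data
    labels = sorted(df[by].dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank comparison needs exactly two groups, got {labels}")
    a = df[df[by] == labels[0]]
    b = df[df[by] == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if df["event"].sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return LogrankResult(float(res.test_statistic), float(res.p_value), tuple(labels))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Cox model fit: per-covariate coefficients/HRs with Wald inference,
    joint Wald tests for categorical blocks, and fit metadata."""

    summary: pd.DataFrame              # coef, hr, se, ci_low, ci_high, p
    overall_p: dict                    # categorical block -> joint p
    log_partial_likelihood: float
    converged: bool
    n: int
    n_events: int
    diagnostics: list = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _build_design(df: pd.DataFrame, covariates, categorical):
    """Numeric covariates pass through; categorical ones are dummy-coded
    against their declared reference level, named ``col::level``."""
    categorical = categorical or {}
    X = pd.DataFrame(index=df.index)
    blocks = {}
    for cov in covariates:
        if cov in categorical:
            ref = categorical[cov]
            levels = sorted(df[cov].dropna().unique())
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {cov!r}")
            cols = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{cov}::{lev}"
                X[name] = (df[cov] == lev).astype(float)
                cols.append(name)
            blocks[cov] = cols
        else:
            X[cov] = pd.to_numeric(df[cov])
    return X, blocks


def cox_fit(
    cohort: SurvivalCohort,
    covariates,
    categorical: dict | None = None,
    overall_test: str = "wald",
) -> CoxFit:
    """Fit a Cox model with Efron handling of ties.

    ``covariates`` is a list of column names of ``cohort.data``;
    ``categorical`` maps a categorical column to its reference level. A
    monotone (perfectly separating) likelihood is reported as a
    non-converged fit with a diagnostic instead of raising; a rank-deficient
    design raises.
    """
    df = cohort.data
    if cohort.n_events < 1:
        raise ValueError("Cox model needs at least one event")
    X, blocks = _build_design(df, covariates, categorical)
    arr = X.to_numpy(dtype=float)
    if arr.shape[1] == 0:
        raise ValueError("no covariates in design")
    centered = arr - arr.mean(axis=0)
    if np.linalg.matrix_rank(centered) < arr.shape[1]:
        raise ValueError("collinear design matrix (rank-deficient after centering)")

    data = X.copy()
    data["time"] = df["time"].to_numpy(dtype=float)
    data["event"] = df["event"].to_numpy(dtype=float)
    cph = CoxPHFitter()
    diagnostics: list = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col="time", event_col="event")
        except ConvergenceError as err:
            return CoxFit(
                summary=pd.DataFrame(
                    np.nan,
                    index=X.columns,
                    columns=["coef", "hr", "se", "ci_low", "ci_high", "p"],
                ),
                overall_p={},
                log_partial_likelihood=np.nan,
                converged=False,
                n=cohort.n,
                n_events=cohort.n_events,
                diagnostics=[f"convergence failure: {err}"],
            )
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
            diagnostics.append(str(w.message))

    coef = cph.params_
    se = cph.standard_errors_
    z = coef / se
    summary = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "se": se,
            "ci_low": np.exp(coef - Z95 * se),
            "ci_high": np.exp(coef + Z95 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        }
    )
    summary.index.name = "covariate"

    overall = {}
    for block, cols in blocks.items():
        if not cols:
            continue
        b = coef[cols].to_numpy()
        V = cph.variance_matrix_.loc[cols, cols].to_numpy()
        if overall_test == "wald":
            chi2 = float(b @ np.linalg.solve(V, b))
        elif overall_test == "lr":
            reduced = [c for c in X.columns if c not in cols]
            if reduced:
                sub = data[reduced + ["time", "event"]]
                cph0 = CoxPHFitter().fit(sub, "time", "event")
                ll0 = cph0.log_likelihood_
            else:
                cph0 = CoxPHFitter().fit(data[["time", "event"]].assign(_null=0.0),
                                         "time", "event")
                ll0 = cph0.log_likelihood_
            chi2 = float(2 * (cph.log_likelihood_ - ll0))
        else:
            raise ValueError("overall_test must be 'wald' or 'lr'")
        overall[block] = float(stats.chi2.sf(chi2, df=len(cols)))

    return CoxFit(
        summary=summary,
        overall_p=overall,
        log_partial_likelihood=float(cph.log_likelihood_),
        converged=converged,
        n=cohort.n,
        n_events=cohort.n_events,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# marker analyses
# ---------------------------------------------------------------------------

def marker_univariate(
    cohort: SurvivalCohort, mode: str = "dichotomized", marker_col: str = "marker"
) -> CoxFit:
    """Univariate Cox fit of the marker, continuous or median-dichotomized
    (High coded 1 against Low)."""
    df = cohort.data.copy()
    if mode == "dichotomized":
        groups = median_dichotomize(df[marker_col].to_numpy(dtype=float))
        df["marker_high"] = (groups == "High").astype(float)
        cov = ["marker_high"]
    elif mode == "continuous":
        cov = [marker_col]
    else:
        raise ValueError("mode must be 'dichotomized' or 'continuous'")
    return cox_fit(SurvivalCohort(df), cov)


@dataclass
class SubtypeAdjustedReport:
    """Multivariate marker + subtype report shaped like the study's summary
    table: one marker row, one overall-subtype row, one contrast row per
    non-reference subtype."""

    mode: str
    reference: str
    fit: CoxFit
    table: pd.DataFrame
    unstable_subtypes: list = field(default_factory=list)


def subtype_adjusted_analysis(
    cohort: SurvivalCohort,
    mode: str = "dichotomized",
    reference: str = "Mesenchymal",
    marker_col: str = "marker",
    overall_test: str = "wald",
) -> SubtypeAdjustedReport:
    """Fit marker + subtype dummies (vs the reference subtype) and lay the
    result out as marker row / subtype-overall row / per-contrast rows."""
    df = cohort.data.copy()
    if "subtype" not in df.columns or df["subtype"].isna().any():
        raise ValueError("every sample needs an assigned subtype")
    if mode == "dichotomized":
        groups = median_dichotomize(df[marker_col].to_numpy(dtype=float))
        df["marker_high"] = (groups == "High").astype(float)
        marker_term, marker_label = "marker_high", "marker: High vs. Low"
    elif mode == "continuous":
        marker_term, marker_label = marker_col, "marker (continuous)"
    else:
        raise ValueError("mode must be 'dichotomized' or 'continuous'")

    events_per_subtype = df.groupby("subtype")["event"].sum()
    unstable = sorted(events_per_subtype.index[events_per_subtype == 0])
    if unstable:
        logger.warning("subtypes with zero events (unstable contrasts): %s", unstable)

    fit = cox_fit(
        SurvivalCohort(df),
        [marker_term, "subtype"],
        categorical={"subtype": reference},
        overall_test=overall_test,
    )
    rows = [
        {
            "variable": marker_label,
            "p": fit.summary.loc[marker_term, "p"],
            "hr": fit.summary.loc[marker_term, "hr"],
            "ci_low": fit.summary.loc[marker_term, "ci_low"],
            "ci_high": fit.summary.loc[marker_term, "ci_high"],
        },
        {
            "variable": "subtype (overall)",
            "p": fit.overall_p.get("subtype", np.nan),
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
        },
    ]
    for cov in fit.summary.index:
        if cov.startswith("subtype::"):
            level = cov.split("::", 1)[1]
            rows.append(
                {
                    "variable": f"{level} vs. {reference}",
                    "p": fit.summary.loc[cov, "p"],
                    "hr": fit.summary.loc[cov, "hr"],
                    "ci_low": fit.summary.loc[cov, "ci_low"],
                    "ci_high": fit.summary.loc[cov, "ci_high"],
                }
            )
    table = pd.DataFrame(rows).set_index("variable")
    return SubtypeAdjustedReport(mode, reference, fit, table, unstable)
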