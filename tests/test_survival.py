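"""Survival machinery: dichotomization, product-limit curves, log-rank, and
Cox fits checked against brute-force partial-likelihood oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from monomark import (
    CohortSimConfig,
    SurvivalCohort,
    cox_fit,
    km_curve,
    logrank_test,
    marker_univariate,
    median_dichotomize,
    simulate_survival_cohort,
    subtype_adjusted_analysis,
)
from oracles import cox_beta_grid, km_oracle, logrank_oracle


def _cohort(time, event, **cols):
    df = pd.DataFrame({"time": time, "event": event, **cols})
    return SurvivalCohort(df)


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------

def test_median_split_basic_and_tie_convention():
    assert median_dichotomize([1, 2, 3, 4]).tolist() == ["Low", "Low", "High", "High"]
    # ties at the median go Low
    assert median_dichotomize([1, 2, 2, 3]).tolist() == ["Low", "Low", "Low", "High"]
    with pytest.raises(ValueError, match="identical"):
        median_dichotomize([5.0, 5.0, 5.0])


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.floats(min_value=-1e6, max_value=1e6),
        min_size=3,
        max_size=31,
    ).filter(lambda v: len(set(v)) > 1)
)
def test_median_split_counting_property(values):
    labels = median_dichotomize(values)
    n = len(values)
    n_high = (labels == "High").sum()
    assert n_high <= n // 2  # never more High than Low
    if n % 2 == 1:
        # the sample sitting at the median is Low
        med_idx = int(np.argsort(values)[n // 2])
        assert labels[med_idx] == "Low"
        assert n_high <= (n - 1) // 2


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_steps_without_censoring():
    cohort = _cohort([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    curve = km_curve(cohort)["all"]
    at_events = curve[curve["time"] > 0]
    assert np.allclose(at_events["survival"], [0.75, 0.5, 0.25, 0.0])


def test_km_all_censored_is_flat_one():
    cohort = _cohort([1.0, 2.0, 3.0], [0, 0, 0])
    curve = km_curve(cohort)["all"]
    assert np.allclose(curve["survival"], 1.0)


def test_km_hand_value_with_censoring():
    # times 1, 2(censored), 3: S on [1,3) = 2/3, S after 3 = 0
    cohort = _cohort([1.0, 2.0, 3.0], [1, 0, 1])
    curve = km_curve(cohort)["all"].set_index("time")
    assert curve.loc[1.0, "survival"] == pytest.approx(2 / 3)
    assert curve.loc[3.0, "survival"] == pytest.approx(0.0)
    times, surv = km_oracle([1.0, 2.0, 3.0], [1, 0, 1])
    assert np.allclose(surv, [2 / 3, 0.0])


def test_km_matches_one_minus_ecdf_without_censoring():
    rng = np.random.default_rng(2)
    t = rng.exponential(1.0, 40)
    cohort = _cohort(t, np.ones(40, dtype=int))
    curve = km_curve(cohort)["all"]
    body = curve[curve["time"] > 0]
    ecdf = np.array([(t <= ti).mean() for ti in body["time"]])
    assert np.allclose(body["survival"], 1 - ecdf)
    s = curve["survival"].to_numpy()
    assert s[0] == 1.0 and np.all(np.diff(s) <= 1e-12) and np.all((s >= 0) & (s <= 1))


def test_km_rejects_nonpositive_times():
    with pytest.raises(ValueError, match="positive"):
        _cohort([0.0, 1.0], [1, 1])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    cohort = _cohort(t, [1] * 6, g=["A"] * 3 + ["B"] * 3)
    res = logrank_test(cohort, by="g")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_matches_hand_oracle_on_six_subjects():
    # alternating event times across groups; all events observed
    time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    group = ["A", "B", "A", "B", "A", "B"]
    cohort = _cohort(time, [1] * 6, g=group)
    res = logrank_test(cohort, by="g")
    expected = logrank_oracle(time, [1] * 6, np.array(group) == "A")
    # hand arithmetic: O_A=3, E_A=0.5+0.4+0.5+1/3+0.5, V=1.2122...
    assert expected == pytest.approx(
        (3 - (0.5 + 0.4 + 0.5 + 1 / 3 + 0.5)) ** 2
        / (0.25 + 0.24 + 0.25 + 2 / 9 + 0.25)
    )
    assert res.statistic == pytest.approx(expected, rel=1e-6)


def test_logrank_invariant_under_monotone_time_transform():
    rng = np.random.default_rng(3)
    t = rng.exponential(1.0, 30)
    g = ["A"] * 15 + ["B"] * 15
    e = rng.integers(0, 2, 30)
    e[0] = 1
    a = logrank_test(_cohort(t, e, g=g), by="g")
    b = logrank_test(_cohort(np.exp(t), e, g=g), by="g")
    assert a.statistic == pytest.approx(b.statistic, rel=1e-9)


def test_logrank_null_permutations_approximately_uniform():
    """Permuting group labels on null data yields approximately uniform
    p-values (KS test)."""
    from scipy.stats import kstest

    rng = np.random.default_rng(4)
    t = rng.exponential(1.0, 40)
    e = np.ones(40, dtype=int)
    pvals = []
    for _ in range(2000):
        g = rng.permutation(["A"] * 20 + ["B"] * 20)
        pvals.append(logrank_oracle(t, e, g == "A"))
    from scipy.stats import chi2

    pvals = chi2.sf(np.array(pvals), 1)
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_logrank_group_requirements():
    with pytest.raises(ValueError, match="two groups"):
        logrank_test(_cohort([1.0, 2.0], [1, 1], g=["A", "A"]), by="g")


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def test_cox_matches_grid_oracle_no_ties(six_subject_cox):
    fit = cox_fit(SurvivalCohort(six_subject_cox), ["x"])
    beta_grid = cox_beta_grid(
        six_subject_cox["time"], six_subject_cox["event"], six_subject_cox["x"]
    )
    assert fit.summary.loc["x", "coef"] == pytest.approx(beta_grid, abs=1e-3)
    assert fit.converged


def test_cox_matches_grid_oracle_with_ties(tied_censored_cox):
    fit = cox_fit(SurvivalCohort(tied_censored_cox), ["x"])
    beta_grid = cox_beta_grid(
        tied_censored_cox["time"], tied_censored_cox["event"], tied_censored_cox["x"]
    )
    assert fit.summary.loc["x", "coef"] == pytest.approx(beta_grid, abs=1e-3)


def test_cox_time_scale_invariance(six_subject_cox):
    a = cox_fit(SurvivalCohort(six_subject_cox), ["x"])
    doubled = six_subject_cox.assign(time=six_subject_cox["time"] * 2)
    b = cox_fit(SurvivalCohort(doubled), ["x"])
    assert a.summary.loc["x", "coef"] == pytest.approx(
        b.summary.loc["x", "coef"], rel=1e-9
    )
    assert a.summary.loc["x", "p"] == pytest.approx(b.summary.loc["x", "p"], rel=1e-9)


def test_cox_null_ci_coverage():
    """A covariate independent of survival: 95% Wald CI contains HR=1 in
    roughly 95% of repeated cohorts."""
    rng = np.random.default_rng(6)
    cover = 0
    n_seeds = 200
    for _ in range(n_seeds):
        n = 200
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0, n)
        cohort = _cohort(t, np.ones(n, dtype=int), x=x)
        fit = cox_fit(cohort, ["x"])
        cover += fit.summary.loc["x", "ci_low"] <= 1 <= fit.summary.loc["x", "ci_high"]
    assert 0.90 <= cover / n_seeds <= 0.99


def test_cox_ci_contains_hr_and_positive():
    sim = simulate_survival_cohort(CohortSimConfig(seed=13))
    fit = marker_univariate(sim.cohort, "dichotomized")
    row = fit.summary.loc["marker_high"]
    assert row["ci_low"] <= row["hr"] <= row["ci_high"]
    assert row["hr"] > 0


def test_cox_collinear_design_raises(six_subject_cox):
    df = six_subject_cox.assign(x2=six_subject_cox["x"] * 2.0)
    with pytest.raises(ValueError, match="collinear"):
        cox_fit(SurvivalCohort(df), ["x", "x2"])


def test_cox_perfect_separation_flagged():
    # covariate perfectly orders the event times -> monotone likelihood
    df = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
            "event": [1, 1, 1, 1, 1, 1],
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        }
    )
    fit = cox_fit(SurvivalCohort(df), ["x"])
    assert not fit.converged
    assert fit.diagnostics


def test_dichotomized_hr_direction_matches_km_ordering():
    """HR > 1 for High vs Low iff the High curve sits below the Low curve at
    the last event time (fixtures without curve crossings)."""
    for seed, log_hr in ((21, np.log(2.5)), (22, -np.log(2.5))):
        sim = simulate_survival_cohort(
            CohortSimConfig(seed=seed, marker_log_hr=log_hr, subtype_log_hrs={})
        )
        cohort = sim.cohort.with_marker_groups()
        fit = marker_univariate(cohort, "dichotomized")
        curves = km_curve(cohort, by="marker_group")
        t_last = min(c["time"].max() for c in curves.values())
        s_at = {
            g: c[c["time"] <= t_last]["survival"].iloc[-1]
            for g, c in curves.items()
        }
        assert (fit.hr("marker_high") > 1) == (s_at["High"] < s_at["Low"])


# ---------------------------------------------------------------------------
# subtype-adjusted report
# ---------------------------------------------------------------------------

def test_adjusted_report_structure_matches_summary_table_layout():
    sim = simulate_survival_cohort(CohortSimConfig(seed=15))
    report = subtype_adjusted_analysis(sim.cohort, "dichotomized")
    rows = list(report.table.index)
    assert rows[0] == "marker: High vs. Low"
    assert rows[1] == "subtype (overall)"
    contrasts = rows[2:]
    assert contrasts == [
        "Classical vs. Mesenchymal",
        "Neural vs. Mesenchymal",
        "Proneural vs. Mesenchymal",
    ]
    assert np.isnan(report.table.loc["subtype (overall)", "hr"])
    assert 0 <= report.table.loc["subtype (overall)", "p"] <= 1
    assert report.fit.overall_p["subtype"] == report.table.loc["subtype (overall)", "p"]


def test_adjusted_null_subtype_overall_p_is_uniformish():
    """With all subtype hazards equal, the overall subtype p-value should not
    concentrate below 0.05."""
    rng_hits = 0
    n_seeds = 60
    for seed in range(n_seeds):
        sim = simulate_survival_cohort(
            CohortSimConfig(seed=40_000 + seed, marker_log_hr=0.0, subtype_log_hrs={})
        )
        report = subtype_adjusted_analysis(sim.cohort, "dichotomized")
        rng_hits += report.table.loc["subtype (overall)", "p"] < 0.05
    assert rng_hits / n_seeds <= 0.15


def test_adjusted_recovery_of_marker_and_subtype_hrs():
    """n=600 cohorts with marker HR 1.6 and subtype HRs (0.6, 1.1, 0.9) vs the
    reference recover the marker HR within 5% on average."""
    subtype_hrs = {
        "Classical": np.log(0.6),
        "Neural": np.log(1.1),
        "Proneural": np.log(0.9),
        "Mesenchymal": 0.0,
    }
    hrs = []
    for seed in range(100):
        sim = simulate_survival_cohort(
            CohortSimConfig(
                n_samples=600,
                marker_log_hr=np.log(1.6),
                subtype_log_hrs=subtype_hrs,
                seed=50_000 + seed,
            )
        )
        report = subtype_adjusted_analysis(sim.cohort, "dichotomized")
        hrs.append(report.table.loc["marker: High vs. Low", "hr"])
    assert np.mean(hrs) == pytest.approx(1.6, rel=0.05)


def test_continuous_mode_reports_marker_row():
    sim = simulate_survival_cohort(CohortSimConfig(seed=16))
    report = subtype_adjusted_analysis(sim.cohort, "continuous")
    assert report.table.index[0] == "marker (continuous)"


def test_overall_test_lr_variant_close_to_wald():
    sim = simulate_survival_cohort(CohortSimConfig(seed=17))
    wald = subtype_adjusted_analysis(sim.cohort, "dichotomized", overall_test="wald")
    lr = subtype_adjusted_analysis(sim.cohort, "dichotomized", overall_test="lr")
    p_w = wald.table.loc["subtype (overall)", "p"]
    p_l = lr.table.loc["subtype (overall)", "p"]
    assert 0 <= p_l <= 1
    assert abs(np.log10(p_w + 1e-12) - np.log10(p_l + 1e-12)) < 1.0
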