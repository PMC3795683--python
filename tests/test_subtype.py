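"""Signature matching, k-nearest-neighbor subtype assignment, and
per-subtype expression summaries."""
import numpy as np
import pandas as pd
import pytest

from monomark import (
    INTENSITY,
    CohortSimConfig,
    ExpressionMatrix,
    SubtypeReference,
    knn_assign,
    match_signature_genes,
    simulate_subtype_reference,
    simulate_survival_cohort,
    subtype_expression_summary,
)


def _ref(profiles, labels):
    return SubtypeReference(pd.DataFrame(profiles), labels)


# ---------------------------------------------------------------------------
# gene matching
# ---------------------------------------------------------------------------

def test_match_identical_and_partial_and_disjoint():
    rng = np.random.default_rng(0)
    ref = SubtypeReference(
        pd.DataFrame(rng.normal(0, 1, (3, 4)), index=[1, 2, 3],
                     columns=["r0", "r1", "r2", "r3"]),
        {f"r{i}": "X" for i in range(4)},
    )
    cohort = pd.DataFrame(rng.normal(0, 1, (3, 2)), index=[1, 2, 3],
                          columns=["c0", "c1"])
    full = match_signature_genes(cohort, ref)
    assert full.n_matched == 3 and full.n_dropped_cohort == 0

    partial = match_signature_genes(cohort.set_axis([2, 3, 4]), ref)
    assert partial.n_matched == 2
    assert partial.n_dropped_cohort == 1
    assert partial.n_dropped_reference == 1
    assert list(partial.cohort.index) == [2, 3]
    assert list(partial.reference.index) == [2, 3]

    with pytest.raises(ValueError, match="shared"):
        match_signature_genes(cohort.set_axis([7, 8, 9]), ref)


def test_matching_zscores_each_gene():
    rng = np.random.default_rng(1)
    ref = SubtypeReference(
        pd.DataFrame(rng.normal(5, 2, (4, 5)), index=[1, 2, 3, 4],
                     columns=[f"r{i}" for i in range(5)]),
        {f"r{i}": "X" for i in range(5)},
    )
    cohort = pd.DataFrame(rng.normal(0, 1, (4, 6)), index=[1, 2, 3, 4],
                          columns=[f"c{i}" for i in range(6)])
    matched = match_signature_genes(cohort, ref)
    for df in (matched.cohort, matched.reference):
        assert np.allclose(df.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(df.std(axis=1, ddof=1), 1, atol=1e-12)


# ---------------------------------------------------------------------------
# kNN assignment
# ---------------------------------------------------------------------------

def test_k1_self_assignment_reproduces_reference_labels(cohort_sim):
    _, ref = cohort_sim
    assigned = knn_assign(ref.profiles, ref, k=1)
    expected = pd.Series(ref.labels)
    assert (assigned["subtype"] == expected.reindex(assigned.index)).all()


def test_vote_tie_broken_by_summed_distance_then_label():
    # two labels, two references each; k=4 makes the vote 2-2
    profiles = pd.DataFrame(
        {"x1": [1.0, 0.0], "x2": [3.0, 0.0], "y1": [-1.2, 0.0], "y2": [-2.9, 0.0]},
        index=[1, 2],
    )
    labels = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
    cohort = pd.DataFrame({"c": [0.0, 0.0], "pad": [10.0, 1.0]}, index=[1, 2])
    matched = match_signature_genes(cohort, SubtypeReference(profiles, labels))
    # bypass z-scoring effects by using raw profiles via a crafted reference:
    # sample c sits at 0; X refs at +1,+3 (sum 4) vs Y refs at -1.2,-2.9 (sum 4.1)
    assigned = knn_assign(cohort, SubtypeReference(profiles, labels), k=4)
    assert assigned.loc["c", "subtype"] in {"X", "Y"}
    # construct an exactly-tied-sum case: lexicographic tie-break
    sym = pd.DataFrame(
        {"x1": [1.0], "x2": [3.0], "y1": [-1.0], "y2": [-3.0]}, index=[1]
    )
    sym_ref = SubtypeReference(sym, labels)
    from monomark.subtype import MatchedPair

    matched = MatchedPair(pd.DataFrame({"c": [0.0]}, index=[1]), sym, 1, 0, 0)
    out = knn_assign(pd.DataFrame({"c": [0.0]}, index=[1]), sym_ref, k=4,
                     matched=matched)
    assert out.loc["c", "subtype"] == "X"  # equal sums -> lexicographic

    asym = pd.DataFrame(
        {"x1": [1.0], "x2": [3.5], "y1": [-1.0], "y2": [-3.0]}, index=[1]
    )
    matched = MatchedPair(pd.DataFrame({"c": [0.0]}, index=[1]), asym, 1, 0, 0)
    out = knn_assign(pd.DataFrame({"c": [0.0]}, index=[1]),
                     SubtypeReference(asym, labels), k=4, matched=matched)
    assert out.loc["c", "subtype"] == "Y"  # sum 4.0 beats sum 4.5


def test_nan_profile_names_offending_sample():
    profiles = pd.DataFrame({"r0": [1.0, 2.0], "r1": [0.0, 1.0]}, index=[1, 2])
    ref = SubtypeReference(profiles, {"r0": "X", "r1": "Y"})
    cohort = pd.DataFrame({"bad": [np.nan, 1.0], "ok": [1.0, 2.0]}, index=[1, 2])
    from monomark.subtype import MatchedPair

    matched = MatchedPair(cohort, profiles, 2, 0, 0)
    with pytest.raises(ValueError, match="bad"):
        knn_assign(cohort, ref, k=1, matched=matched)


def test_knn_recovery_on_centroid_cohort(cohort_sim):
    sim, ref = cohort_sim
    signature = sim.expression.values.drop(index=sim.config.marker_gene_id)
    assigned = knn_assign(signature, ref, k=10)
    truth = pd.Series(sim.truth["subtype"])
    accuracy = (assigned["subtype"] == truth.reindex(assigned.index)).mean()
    assert accuracy >= 0.95


def test_assignment_invariant_to_sample_order(cohort_sim):
    sim, ref = cohort_sim
    signature = sim.expression.values.drop(index=sim.config.marker_gene_id)
    rng = np.random.default_rng(5)
    shuffled_cohort = signature[rng.permutation(signature.columns)]
    shuffled_ref = SubtypeReference(
        ref.profiles[rng.permutation(ref.profiles.columns)], ref.labels
    )
    a = knn_assign(signature, ref, k=10)
    b = knn_assign(shuffled_cohort, shuffled_ref, k=10)
    assert (a["subtype"].sort_index() == b["subtype"].sort_index()).all()


def test_accuracy_degrades_monotonically_with_noise():
    accs = []
    for noise_frac in (0.1, 0.6, 1.5):
        cfg = CohortSimConfig(
            seed=31, noise_sd=noise_frac * 2.0, centroid_separation=2.0
        )
        sim = simulate_survival_cohort(cfg)
        ref = simulate_subtype_reference(cfg)
        signature = sim.expression.values.drop(index=cfg.marker_gene_id)
        assigned = knn_assign(signature, ref, k=10)
        truth = pd.Series(sim.truth["subtype"])
        accs.append((assigned["subtype"] == truth.reindex(assigned.index)).mean())
    assert accs[0] >= accs[1] >= accs[2]
    assert accs[0] > accs[2]


def test_k_bounds_enforced(cohort_sim):
    sim, ref = cohort_sim
    signature = sim.expression.values.drop(index=sim.config.marker_gene_id)
    with pytest.raises(ValueError, match="k="):
        knn_assign(signature, ref, k=0)
    with pytest.raises(ValueError, match="k="):
        knn_assign(signature, ref, k=ref.profiles.shape[1] + 1)


# ---------------------------------------------------------------------------
# per-subtype expression summary
# ---------------------------------------------------------------------------

def _summary_matrix(values_by_subtype, gene=99):
    cols, groups = {}, {}
    for subtype, values in values_by_subtype.items():
        for i, v in enumerate(values):
            name = f"{subtype}_{i}"
            cols[name] = [v]
            groups[name] = subtype
    m = ExpressionMatrix(pd.DataFrame(cols, index=[gene]), INTENSITY)
    return m, pd.Series(groups)


def test_identical_subtypes_rarely_significant():
    rng = np.random.default_rng(8)
    hits = 0
    for _ in range(40):
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        m, labels = _summary_matrix({"A": a, "B": b})
        _, pairwise = subtype_expression_summary(m, labels, 99)
        hits += pairwise["p"].iloc[0] < 0.05
    assert hits / 40 <= 0.10


def test_shifted_subtype_strongly_significant():
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, 20)
    b = rng.normal(5, 1, 20)  # 5 sd shift
    m, labels = _summary_matrix({"A": a, "B": b})
    summary, pairwise = subtype_expression_summary(m, labels, 99)
    assert pairwise["p"].iloc[0] < 1e-3
    assert summary.loc["B", "median"] > summary.loc["A", "median"]
    assert summary.loc["A", "iqr"] > 0


def test_single_subtype_yields_medians_only():
    m, labels = _summary_matrix({"A": [1.0, 2.0, 3.0]})
    summary, pairwise = subtype_expression_summary(m, labels, 99)
    assert len(summary) == 1
    assert pairwise.empty
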