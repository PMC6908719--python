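"""Laplace-corrected fold changes, proportion test, terminal terms,
and the run-comparison model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pepgo import (
    GoCountTable,
    GoEnrichment,
    InputError,
    IntegrityError,
    compare_runs,
    laplace_log2fc,
    proportion_test,
    terminal_terms,
)

from conftest import random_dag


def test_laplace_log2fc_closed_form():
    # ((1+1)/(19+1)) / ((3+1)/(9+1)) = 0.1/0.4 -> exactly -2
    assert laplace_log2fc(3, 9, 1, 19) == -2.0


@given(
    c=st.integers(0, 50), n=st.integers(1, 1000),
)
@settings(deadline=None, max_examples=50)
def test_laplace_identity_is_zero(c, n):
    n = max(n, c)
    assert laplace_log2fc(c, n, c, n) == 0.0


def test_laplace_zero_counts_comparable():
    assert laplace_log2fc(0, 10, 0, 10) == 0.0


@given(
    ca=st.integers(0, 100), na=st.integers(1, 5000),
    cb=st.integers(0, 100), nb=st.integers(1, 5000),
)
@settings(deadline=None, max_examples=100)
def test_laplace_antisymmetry(ca, na, cb, nb):
    na, nb = max(na, ca), max(nb, cb)
    assert laplace_log2fc(ca, na, cb, nb) == pytest.approx(
        -laplace_log2fc(cb, nb, ca, na)
    )


def test_laplace_count_above_total_rejected():
    with pytest.raises(InputError):
        laplace_log2fc(10, 5, 1, 10)


def test_proportion_test_equal_proportions():
    assert proportion_test(5, 100, 5, 100) == 1.0


def test_proportion_test_degenerate_pooled():
    assert proportion_test(0, 50, 0, 80) == 1.0
    assert proportion_test(50, 50, 80, 80) == 1.0


def test_proportion_test_z_squared_is_chisquare():
    """The pooled z-test without continuity correction is exactly the
    1-df chi-square test on the 2x2 table."""
    cases = [(10, 100, 0, 100), (3, 50, 9, 60), (40, 500, 75, 800)]
    for ca, na, cb, nb in cases:
        p = proportion_test(ca, na, cb, nb)
        z = stats.norm.isf(p / 2)
        table = np.array([[ca, na - ca], [cb, nb - cb]])
        chi2, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
        assert z**2 == pytest.approx(chi2, abs=1e-10)
        assert p == pytest.approx(p_chi, abs=1e-10)


@given(
    ca=st.integers(0, 200), na=st.integers(1, 5000),
    cb=st.integers(0, 200), nb=st.integers(1, 5000),
)
@settings(deadline=None, max_examples=100)
def test_proportion_test_swap_invariance(ca, na, cb, nb):
    na, nb = max(na, ca), max(nb, cb)
    assert proportion_test(ca, na, cb, nb) == pytest.approx(
        proportion_test(cb, nb, ca, na)
    )


# ---- terminal terms --------------------------------------------------------


def test_terminal_on_chain_and_siblings(toy_dag):
    chain = {"GO:0000001", "GO:0000002", "GO:0000003"}
    assert terminal_terms(toy_dag, chain) == {"GO:0000003"}
    siblings = {"GO:0000003", "GO:0000004"}
    assert terminal_terms(toy_dag, siblings) == siblings


def test_terminal_matches_brute_force_descendant_scan():
    rng = np.random.default_rng(17)
    for _ in range(20):
        dag = random_dag(rng, 40)
        ids = list(dag)
        observed = {str(t) for t in rng.choice(ids, size=15, replace=False)}
        expected = {
            t for t in observed
            if not any(
                t in dag.ancestors(o) for o in observed if o != t
            )
        }
        assert terminal_terms(dag, observed) == expected


# ---- compare_runs ----------------------------------------------------------


def _tables(toy_dag, counts_a, counts_b, total_a=1000, total_b=1000):
    return (
        GoCountTable("a", counts_a, total_a),
        GoCountTable("b", counts_b, total_b),
    )


def test_identical_tables_nothing_significant(toy_dag):
    counts = {"GO:0000001": 100, "GO:0000002": 50, "GO:0000003": 50}
    a, b = _tables(toy_dag, dict(counts), dict(counts))
    results = compare_runs(a, b, toy_dag)
    assert all(r.log2fc == 0.0 for r in results)
    assert not any(r.is_significant for r in results)


def test_single_term_bonferroni_is_identity(toy_dag):
    a, b = _tables(toy_dag, {"GO:0000001": 30}, {"GO:0000001": 60})
    (res,) = compare_runs(a, b, toy_dag)
    assert res.p_bonf == pytest.approx(res.p_raw)


def test_large_shift_on_leaf_is_significant(toy_dag):
    # leaf proportion 0.01 -> 0.20 at totals 5000: overwhelming evidence
    a, b = _tables(
        toy_dag,
        {"GO:0000001": 50, "GO:0000003": 50},
        {"GO:0000001": 1000, "GO:0000003": 1000},
        total_a=5000, total_b=5000,
    )
    results = {r.go_id: r for r in compare_runs(a, b, toy_dag, alpha=0.01)}
    assert results["GO:0000003"].is_significant
    # the ancestor changed too, but it is not terminal -> never flagged
    assert not results["GO:0000001"].is_significant
    assert results["GO:0000003"].log2fc == pytest.approx(
        np.log2((1001 / 5001) / (51 / 5001))
    )


def test_results_sorted_and_bonferroni_bounded(toy_dag):
    a, b = _tables(
        toy_dag,
        {"GO:0000001": 100, "GO:0000003": 40, "GO:0000004": 10},
        {"GO:0000001": 100, "GO:0000003": 80, "GO:0000004": 10},
    )
    results = compare_runs(a, b, toy_dag)
    ps = [r.p_bonf for r in results]
    assert ps == sorted(ps)
    assert all(0 <= r.p_bonf <= 1 for r in results)
    assert all(r.p_bonf >= r.p_raw for r in results)


def test_disjoint_ontology_rejected(toy_dag):
    a = GoCountTable("a", {"NOT:1": 5}, 10)
    b = GoCountTable("b", {"NOT:1": 5}, 10)
    with pytest.raises(IntegrityError):
        compare_runs(a, b, toy_dag)


def test_terminal_mode_ontology(toy_dag):
    # observed {B, C}: neither has an *observed* descendant, so both are
    # terminal relative to the observed set; but both have the unobserved
    # leaf D below them in the full ontology, so neither is an ontology leaf
    a, b = _tables(
        toy_dag, {"GO:0000003": 20, "GO:0000004": 20},
        {"GO:0000003": 25, "GO:0000004": 25},
    )
    obs = {r.go_id: r for r in compare_runs(a, b, toy_dag)}
    ont = {
        r.go_id: r
        for r in compare_runs(a, b, toy_dag, terminal_mode="ontology")
    }
    assert obs["GO:0000003"].is_terminal and obs["GO:0000004"].is_terminal
    assert not ont["GO:0000003"].is_terminal
    assert not ont["GO:0000004"].is_terminal


def test_model_results_object(toy_dag):
    a, b = _tables(
        toy_dag,
        {"GO:0000001": 50, "GO:0000003": 50},
        {"GO:0000001": 1000, "GO:0000003": 1000},
        total_a=5000, total_b=5000,
    )
    res = GoEnrichment(a, b, toy_dag).fit()
    assert res.n_tested == 2
    assert [r.go_id for r in res.significant] == ["GO:0000003"]
    frame = res.frame()
    assert set(frame.columns) >= {"go_id", "log2fc", "p_bonf", "significant"}
    assert "significant terminal terms: 1" in res.summary()
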