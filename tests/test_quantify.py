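"""Spectral-count propagation and taxon rollup."""

import numpy as np
import pytest

from pepgo import (
    GoIncidence,
    InputError,
    IntegrityError,
    PeptideAnnotation,
    PeptideObservation,
    class_abundance,
    go_spectral_counts,
    taxon_proportions,
)

from conftest import random_dag


def _ann(pep, go_ids, lca=None):
    return PeptideAnnotation(
        peptide=pep, protein_ids=frozenset({"p"}),
        go_ids=frozenset(go_ids), lca_taxon=lca, is_bacterial=True,
    )


def _obs(pep, count, run="r1"):
    return PeptideObservation(peptide=pep, run_id=run, spectral_count=count)


def test_single_peptide_propagates_to_all_terms():
    anns = {"PEP": _ann("PEP", {"B", "A", "root"})}
    table = go_spectral_counts(anns, [_obs("PEP", 5)], "r1")
    assert table.counts == {"B": 5, "A": 5, "root": 5}
    assert table.total_spectra == 5


def test_counts_are_additive_across_peptides():
    anns = {
        "P1": _ann("P1", {"A", "root"}),
        "P2": _ann("P2", {"A", "B", "root"}),
    }
    obs = [_obs("P1", 5), _obs("P2", 3)]
    table = go_spectral_counts(anns, obs, "r1")
    assert table.counts["A"] == 8
    assert table.counts["B"] == 3
    assert table.total_spectra == 8


def test_missing_annotation_is_integrity_error():
    with pytest.raises(IntegrityError):
        go_spectral_counts({}, [_obs("GHOST", 1)], "r1")


def _random_fixture(rng, n_peptides=50):
    """Random annotated peptides over a random DAG, plus per-run counts."""
    dag = random_dag(rng, 30)
    ids = list(dag)
    anns = {}
    obs = []
    for i in range(n_peptides):
        pep = f"PEP{i:03d}"
        k = int(rng.integers(1, 4))
        direct = {str(t) for t in rng.choice(ids, size=k, replace=False)}
        anns[pep] = _ann(pep, dag.closure(direct))
        obs.append(_obs(pep, int(rng.integers(1, 20))))
    return dag, anns, obs


def test_propagation_equals_per_spectrum_brute_force():
    """Expanding every spectrum individually and walking the DAG one
    spectrum at a time must give the same table."""
    rng = np.random.default_rng(21)
    dag, anns, obs = _random_fixture(rng)
    table = go_spectral_counts(anns, obs, "r1")
    brute = {}
    total = 0
    for o in obs:
        for _ in range(o.spectral_count):  # one spectrum at a time
            total += 1
            for t in anns[o.peptide].go_ids:
                brute[t] = brute.get(t, 0) + 1
    assert table.counts == brute
    assert table.total_spectra == total


def test_dag_monotonicity_of_counts():
    rng = np.random.default_rng(22)
    dag, anns, obs = _random_fixture(rng)
    table = go_spectral_counts(anns, obs, "r1")
    for tid, c in table.counts.items():
        for parent in dag[tid].parent_ids:
            assert table.counts.get(parent, 0) >= c


def test_removing_a_peptide_is_linear():
    rng = np.random.default_rng(23)
    dag, anns, obs = _random_fixture(rng)
    full = go_spectral_counts(anns, obs, "r1")
    reduced = go_spectral_counts(anns, obs[1:], "r1")
    removed = obs[0]
    for t in anns[removed.peptide].go_ids:
        assert full.counts[t] - reduced.counts.get(t, 0) == removed.spectral_count


def test_incidence_matrix_agrees_with_direct_counting():
    rng = np.random.default_rng(24)
    dag, anns, obs = _random_fixture(rng)
    order = [o.peptide for o in obs]
    inc = GoIncidence(anns, order)
    vec = np.array([o.spectral_count for o in obs])
    table = inc.count_table(vec, "r1")
    assert table.counts == go_spectral_counts(anns, obs, "r1").counts
    assert table.total_spectra == vec.sum()


# ---- taxon proportions and class abundance --------------------------------


def test_taxon_proportions_with_unclassified_sink(toy_tree):
    # 6 spectra resolve to class Flavobacteriia, 4 sit at phylum level
    anns = {
        "P1": _ann("P1", {"A"}, lca="30"),  # genus under Flavobacteriia
        "P2": _ann("P2", {"A"}, lca="10"),  # phylum: above class
    }
    obs = [_obs("P1", 6), _obs("P2", 4)]
    props = taxon_proportions(anns, obs, "r1", "A", toy_tree)
    assert props == {"Flavobacteriia": 0.6, "Unclassified": 0.4}
    assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)


def test_taxon_proportions_single_class(toy_tree):
    anns = {"P1": _ann("P1", {"A"}, lca="31")}
    props = taxon_proportions(anns, [_obs("P1", 7)], "r1", "A", toy_tree)
    assert props == {"Flavobacteriia": 1.0}


def test_taxon_proportions_zero_count_errors(toy_tree):
    anns = {"P1": _ann("P1", {"A"}, lca="30")}
    with pytest.raises(InputError):
        taxon_proportions(anns, [_obs("P1", 1)], "r1", "MISSING", toy_tree)


def test_class_abundance_arithmetic(toy_tree):
    anns = {
        "P1": _ann("P1", {"A"}, lca="30"),  # Flavobacteriia
        "P2": _ann("P2", {"A"}, lca="31"),  # Flavobacteriia
        "P3": _ann("P3", {"A"}, lca="32"),  # Gammaproteobacteria
    }
    obs = [_obs("P1", 2), _obs("P2", 3), _obs("P3", 5)]
    ab = class_abundance(anns, obs, "r1", toy_tree)
    assert ab == {"Flavobacteriia": 0.5, "Gammaproteobacteria": 0.5}


def test_class_abundance_empty_run_errors(toy_tree):
    with pytest.raises(InputError):
        class_abundance({}, [], "r1", toy_tree)


def test_class_abundance_equals_brute_force_tally(toy_tree):
    rng = np.random.default_rng(31)
    genera = ["30", "31", "32", "10", None]
    anns, obs = {}, []
    for i in range(40):
        pep = f"P{i}"
        anns[pep] = _ann(pep, {"A"}, lca=genera[int(rng.integers(5))])
        obs.append(_obs(pep, int(rng.integers(1, 10))))
    ab = class_abundance(anns, obs, "r1", toy_tree)
    brute = {}
    for o in obs:
        lca = anns[o.peptide].lca_taxon
        cls = None
        if lca is not None:
            node = toy_tree.rank_at(lca, "class")
            cls = toy_tree[node].name if node else None
        key = cls or "Unclassified"
        brute[key] = brute.get(key, 0) + o.spectral_count
    total = sum(brute.values())
    assert ab == {k: v / total for k, v in brute.items()}
    assert sum(ab.values()) == pytest.approx(1.0, abs=1e-9)
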