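"""Synthetic-data generator: determinism, construction guarantees, and
statistical faithfulness of the sampled tables."""

import numpy as np
import pytest

from pepgo import (
    GoEnrichment,
    InputError,
    SimConfig,
    annotate_peptides,
    class_abundance,
    filter_nonbacterial,
    generate_reference,
    generate_timecourse,
    go_spectral_counts,
    index_proteins,
    simulate,
    truth_eval,
    write_dataset,
)


SMALL = SimConfig(
    seed=7, n_proteins=120, n_peptides=600, total_spectra_per_run=5000,
    n_go_terms=40,
)


def _hash_dir(path):
    import hashlib

    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


def test_same_seed_byte_identical_outputs(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    write_dataset(simulate(SMALL), a)
    write_dataset(simulate(SimConfig(**{**SMALL.__dict__})), b)
    assert _hash_dir(a) == _hash_dir(b)


def test_generated_dag_and_tree_are_valid():
    ref = generate_reference(SMALL)
    # GoDag/TaxTree constructors validate acyclicity and rooting; check
    # the aspect roots and leaf bookkeeping on top
    assert len(ref.dag.roots) == 3
    assert all(ref.dag.is_leaf(t) for t in ref.leaf_terms)
    assert set(ref.marker_terms) <= set(ref.leaf_terms)
    assert ref.tree.find_by_name("Bacteria") == ref.bacteria_id


def test_single_class_config():
    ref = generate_reference(
        SimConfig(seed=1, n_classes=1, n_proteins=60, n_peptides=200,
                  lca_ambiguity_rate=0.0, n_go_terms=30)
    )
    classes = {
        c for c in ref.peptide_info["organism_class"] if c
    }
    assert classes == {"Flavobacteriia"}


def test_infeasible_config_rejected():
    with pytest.raises(InputError):
        generate_reference(SimConfig(seed=1, n_go_terms=7, n_spiked=6))
    with pytest.raises(InputError):
        SimConfig(seed=1, n_go_terms=2)
    with pytest.raises(InputError):
        SimConfig(seed=1, lca_ambiguity_rate=1.5)


def test_total_spectra_exact_multinomial():
    ds = simulate(SMALL)
    for run_id, obs in ds.psm_tables.items():
        assert sum(o.spectral_count for o in obs) == SMALL.total_spectra_per_run


def test_all_peptides_match_their_sources():
    ds = simulate(SMALL)
    matcher = index_proteins(ds.reference.proteins)
    misses = [p for p in ds.reference.peptides if not matcher.match(p)]
    assert misses == []


def test_zero_ambiguity_means_no_unclassified():
    config = SimConfig(
        seed=3, n_proteins=120, n_peptides=500, total_spectra_per_run=5000,
        lca_ambiguity_rate=0.0, nonbacterial_rate=0.0, n_go_terms=40,
    )
    ds = simulate(config)
    ref = ds.reference
    matcher = index_proteins(ref.proteins)
    anns = annotate_peptides(
        ref.dag, ref.tree, ref.proteins, matcher, ref.peptides
    )
    kept, removed = filter_nonbacterial(list(anns.values()))
    assert removed == 0
    kept_map = {a.peptide: a for a in kept}
    run = next(iter(ds.psm_tables))
    ab = class_abundance(kept_map, ds.psm_tables[run], run, ref.tree)
    assert "Unclassified" not in ab
    # every LCA resolves at genus rank
    assert all(
        ref.tree[a.lca_taxon].rank == "genus" for a in kept if a.lca_taxon
    )


def test_spike_realizes_configured_fold_change():
    """A +1.5 log2 spike over day 0 -> 1 moves the term's proportion by
    ~2^1.5, within multinomial sampling error."""
    ref = generate_reference(SMALL)
    term = ref.marker_terms[0]
    config = SimConfig(**{**SMALL.__dict__, "spiked_terms": ((term, 1.5),)})
    ds = generate_timecourse(config, ref)
    matcher = index_proteins(ref.proteins)
    anns = annotate_peptides(ref.dag, ref.tree, ref.proteins, matcher, ref.peptides)
    kept = {a.peptide: a for a in anns.values() if a.is_bacterial}

    def proportion(run):
        obs = [o for o in ds.psm_tables[run] if o.peptide in kept]
        t = go_spectral_counts(kept, obs, run)
        return t.counts.get(term, 0) / t.total_spectra, t.counts.get(term, 0)

    p0, c0 = proportion("om_d0")
    p1, c1 = proportion("om_d1")
    # compositional adjustment: an unbalanced spike inflates the total
    expected_ratio = 2**1.5 / (1 + p0 * (2**1.5 - 1))
    se = np.sqrt(1 / max(c0, 1) + 1 / max(c1, 1))  # log-scale sampling error
    assert np.log(p1 / p0) == pytest.approx(
        np.log(expected_ratio), abs=3 * se + 0.02
    )


def test_truth_eval_on_default_spikes():
    ds = simulate(SimConfig(seed=11))
    ref = ds.reference
    matcher = index_proteins(ref.proteins)
    anns = annotate_peptides(ref.dag, ref.tree, ref.proteins, matcher, ref.peptides)
    kept = {a.peptide: a for a in anns.values() if a.is_bacterial}

    def table(run):
        obs = [o for o in ds.psm_tables[run] if o.peptide in kept]
        return go_spectral_counts(kept, obs, run)

    res = GoEnrichment(table("om_d0"), table("om_d1"), ref.dag).fit()
    report = truth_eval(ds.truth, res.results)
    assert report["sensitivity"] == 1.0
    assert report["fp"] == 0


def test_class_trajectories_recovered_within_sampling_error():
    ds = simulate(SMALL)
    ref = ds.reference
    matcher = index_proteins(ref.proteins)
    anns = annotate_peptides(ref.dag, ref.tree, ref.proteins, matcher, ref.peptides)
    kept = {a.peptide: a for a in anns.values() if a.is_bacterial}
    n = SMALL.total_spectra_per_run
    for run in ("om_d0", "om_d1", "control_d6"):
        obs = [o for o in ds.psm_tables[run] if o.peptide in kept]
        ab = class_abundance(kept, obs, run, ref.tree)
        truth = ds.truth.class_trajectories[run]
        for cls, expected in truth.items():
            got = ab.get(cls, 0.0)
            sigma = np.sqrt(expected * (1 - expected) / n)
            assert abs(got - expected) <= 3 * sigma + 1e-3, (run, cls)


def test_null_config_has_no_spikes():
    ds = simulate(SimConfig(**{**SMALL.__dict__, "spiked_terms": ()}))
    assert ds.truth.spiked == {}
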