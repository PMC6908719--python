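"""Synthetic metaproteomics study generator.

Emulates the structure of a shipboard incubation time course: a
metagenome-predicted protein database with GO and top-hit taxon labels,
a small GO DAG (three aspects) and a rooted taxonomy (bacterial classes
under two phyla plus one eukaryotic branch), and per-run PSM tables at
days {0, 1, 6, 10} for two treatments ("om" = organic-matter amendment,
"control").

Spectral counts per run are multinomial draws over a fixed per-peptide
weight vector.  A configurable subset of terminal (leaf) GO terms is
*spiked*: the weights of peptides carrying a spiked term are multiplied
by ``2**(drift * min(day, spike_ramp_days))``, i.e. the log2 effect is
realized over the first interval and then held — matching bloom-type
responses where the largest changes happen within the first day and
persist.  Default spikes are sign-balanced: proportions are
compositional, and large one-sided spikes would drag every null term's
proportion down and contaminate specificity estimates.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .dynamics import RatioMatrix
from .errors import InputError
from .ontology import GoDag, GoTerm, write_obo
from .records import PeptideObservation, ProteinRecord
from .taxonomy import UNCLASSIFIED, TaxNode, TaxTree, write_taxonomy

AMINO_ACIDS = np.array(list("ACDEFGHIKMNPQRSTVWY"))  # L excluded: I/L folded

_CLASS_NAMES = (
    "Flavobacteriia",
    "Gammaproteobacteria",
    "Alphaproteobacteria",
    "Betaproteobacteria",
    "Actinobacteria",
    "Cytophagia",
    "Deltaproteobacteria",
    "Verrucomicrobiae",
    "Planctomycetia",
    "Sphingobacteriia",
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings (defaults are the study-like conditions).

    ``spiked_terms`` may list explicit ``(go_id, log2 drift per day)``
    pairs; when None, ``n_spiked`` leaf terms with modest spectral share
    are auto-selected with sign-balanced drifts spanning
    ``spike_log2_range``.
    """

    seed: int = 0
    n_classes: int = 6
    n_proteins: int = 300
    n_go_terms: int = 60
    days: tuple[float, ...] = (0, 1, 6, 10)
    n_peptides: int = 2000
    total_spectra_per_run: int = 20_000
    spiked_terms: tuple[tuple[str, float], ...] | None = None
    n_spiked: int = 6
    marker_proteins_per_term: int = 2
    spike_log2_range: tuple[float, float] = (2.2, 3.8)
    spike_ramp_days: float = 1.0
    spike_in_control: bool = False
    lca_ambiguity_rate: float = 0.15
    nonbacterial_rate: float = 0.02
    treatments: tuple[str, ...] = ("om", "control")
    otu_depth: int = 10_000

    def __post_init__(self):
        for name in (
            "n_classes", "n_proteins", "n_go_terms", "n_peptides",
            "total_spectra_per_run", "otu_depth",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.n_go_terms < 3:
            raise InputError("need at least the 3 aspect roots")
        for name in ("lca_ambiguity_rate", "nonbacterial_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise InputError(f"{name} must lie in [0, 1]")
        if len(self.days) < 2 or any(np.diff(self.days) <= 0):
            raise InputError("days must be >= 2 strictly increasing values")


@dataclass
class Reference:
    """Generated reference universe: ontology, taxonomy, proteins, and
    the fixed peptide set (sequences are substrings of their source
    proteins, so the matcher is guaranteed to find them)."""

    dag: GoDag
    tree: TaxTree
    proteins: list[ProteinRecord]
    peptides: list[str]
    leaf_terms: list[str]
    #: leaf terms reserved for spiking: each is the sole annotation of a
    #: few dedicated proteins, so drifting its carrier peptides induces
    #: no effect on any other terminal term
    marker_terms: tuple[str, ...]
    bacteria_id: str
    #: planned per-peptide labels (source class, ambiguity, bacterial flag)
    peptide_info: pd.DataFrame
    #: peptide index -> closed GO id set implied by the planned protein sets
    peptide_go: list[frozenset[str]]


@dataclass
class TruthTable:
    """Ground truth for recovery evaluation."""

    spiked: dict[str, float]
    #: run_id -> {class or Unclassified -> expected fraction of retained
    #: bacterial spectra}
    class_trajectories: dict[str, dict[str, float]]
    #: run_id -> {class -> expected organism-level (16S-like) fraction}
    otu_trajectories: dict[str, dict[str, float]]


@dataclass
class SimulatedDataset:
    config: SimConfig
    reference: Reference
    truth: TruthTable
    #: run_id -> (treatment, day)
    run_meta: dict[str, tuple[str, float]]
    #: run_id -> list of PeptideObservation (count >= 1)
    psm_tables: dict[str, list[PeptideObservation]]
    #: run_id -> {class -> fraction} sampled 16S-like tables
    otu_tables: dict[str, dict[str, float]]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _build_dag(rng: np.random.Generator, n_terms: int) -> tuple[GoDag, list[str]]:
    aspects = (
        "biological_process",
        "molecular_function",
        "cellular_component",
    )
    terms: dict[str, GoTerm] = {}
    per_aspect: dict[str, list[str]] = {a: [] for a in aspects}
    for i in range(n_terms):
        tid = f"GO:{i + 1:07d}"
        aspect = aspects[i % 3]
        if i < 3:
            terms[tid] = GoTerm(id=tid, name=aspect, aspect=aspect)
        else:
            pool = per_aspect[aspect]
            k = 1 if len(pool) < 2 else int(rng.integers(1, 3))
            parents = frozenset(
                rng.choice(pool, size=min(k, len(pool)), replace=False)
            )
            terms[tid] = GoTerm(
                id=tid, name=f"synthetic term {i + 1}", aspect=aspect,
                parent_ids=parents,
            )
        per_aspect[aspect].append(tid)
    dag = GoDag(terms)
    used_as_parent = set().union(*(t.parent_ids for t in terms.values()))
    leaves = sorted(set(terms) - used_as_parent - set(dag.roots))
    return dag, leaves


def _build_tree(n_classes: int) -> tuple[TaxTree, dict[str, list[str]], str, str]:
    """Taxonomy: root -> {Bacteria -> 2 phyla -> classes -> 2 genera each,
    Eukaryota -> 1 phylum -> 1 class -> 1 genus}."""
    nodes: dict[str, TaxNode] = {
        "1": TaxNode("1", "cellular root", "root", None),
        "B": TaxNode("B", "Bacteria", "superkingdom", "1"),
        "E": TaxNode("E", "Eukaryota", "superkingdom", "1"),
        "P1": TaxNode("P1", "Bacteroidetes", "phylum", "B"),
        "P2": TaxNode("P2", "Proteobacteria", "phylum", "B"),
        "PE": TaxNode("PE", "Ochrophyta", "phylum", "E"),
        "CE": TaxNode("CE", "Bacillariophyceae", "class", "PE"),
        "GE": TaxNode("GE", "Thalassiosira", "genus", "CE"),
    }
    class_genera: dict[str, list[str]] = {}
    for i in range(n_classes):
        name = (
            _CLASS_NAMES[i]
            if i < len(_CLASS_NAMES)
            else f"SyntheticClass{i + 1:02d}"
        )
        cid = f"C{i + 1}"
        nodes[cid] = TaxNode(cid, name, "class", "P1" if i % 2 == 0 else "P2")
        genera = []
        for j in range(2):
            gid = f"{cid}g{j + 1}"
            nodes[gid] = TaxNode(gid, f"{name}_genus{j + 1}", "genus", cid)
            genera.append(gid)
        class_genera[name] = genera
    return TaxTree(nodes), class_genera, "B", "GE"


def generate_reference(config: SimConfig) -> Reference:
    """Build the deterministic reference universe for ``config``.

    Proteins get 1-4 leaf GO annotations and a genus-level top-hit
    taxon; a ``nonbacterial_rate`` sliver of proteins (at least two)
    belongs to the eukaryotic branch.  Peptides are substrings (8-15 aa)
    of their source proteins; an ``lca_ambiguity_rate`` fraction of
    bacterial peptides is additionally planted verbatim into a protein
    of a *different* class, forcing their LCA above class rank.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    dag, leaves = _build_dag(rng, config.n_go_terms)
    if not leaves:
        raise InputError("generated ontology has no leaf terms")
    tree, class_genera, bacteria_id, euk_genus = _build_tree(config.n_classes)
    class_names = list(class_genera)

    n_euk = max(2, round(config.nonbacterial_rate * config.n_proteins))
    n_bact = config.n_proteins - n_euk
    if n_bact < config.n_classes:
        raise InputError("n_proteins too small for the requested classes")

    # Reserve marker leaves for spiking (only when spikes are auto-chosen).
    n_markers = config.n_spiked if config.spiked_terms is None else 0
    n_marker_prot = n_markers * config.marker_proteins_per_term
    if n_markers and (len(leaves) <= n_markers + 2 or n_bact <= n_marker_prot):
        raise InputError(
            "not enough leaf terms or proteins to reserve spike markers; "
            "increase n_go_terms/n_proteins or reduce n_spiked"
        )
    markers = (
        tuple(sorted(map(str, rng.choice(leaves, size=n_markers, replace=False))))
        if n_markers
        else ()
    )
    general_leaves = [t for t in leaves if t not in set(markers)]

    # Uneven but fixed class composition (Dirichlet over classes).
    class_weights = rng.dirichlet(np.full(config.n_classes, 5.0))
    protein_class_idx = rng.choice(
        config.n_classes, size=n_bact, p=class_weights
    )

    # Dedicate proteins to marker terms.  Consecutive markers (an
    # up/down spike pair downstream) share a class, so balanced spiking
    # leaves the class composition unchanged: the study conditions are
    # fast functional change against a slowly moving taxonomy.
    marker_prot_idx: set[int] = set()
    marker_assignment: dict[int, str] = {}
    if n_marker_prot:
        pool_by_class = {
            c: list(map(int, np.where(protein_class_idx == c)[0]))
            for c in range(config.n_classes)
        }
        order = sorted(
            range(config.n_classes), key=lambda c: -len(pool_by_class[c])
        )
        for k, term in enumerate(markers):
            cls = order[(k // 2) % len(order)]
            pool = pool_by_class[cls]
            if len(pool) < config.marker_proteins_per_term:
                raise InputError(
                    "not enough proteins in a class to host spike markers; "
                    "increase n_proteins or reduce n_spiked"
                )
            take = rng.choice(
                len(pool), size=config.marker_proteins_per_term, replace=False
            )
            for j in sorted(map(int, take), reverse=True):
                idx = pool.pop(j)
                marker_prot_idx.add(idx)
                marker_assignment[idx] = term

    sequences: list[str] = []
    annotations: list[frozenset[str]] = []
    taxa: list[str] = []
    prot_class: list[str | None] = []
    for i in range(n_bact):
        cls = class_names[protein_class_idx[i]]
        genus = class_genera[cls][int(rng.integers(0, 2))]
        sequences.append(_random_sequence(rng, int(rng.integers(150, 301))))
        if i in marker_assignment:
            annotations.append(frozenset({marker_assignment[i]}))
        else:
            n_go = int(rng.integers(1, 5))
            annotations.append(
                frozenset(
                    rng.choice(
                        general_leaves,
                        size=min(n_go, len(general_leaves)),
                        replace=False,
                    )
                )
            )
        taxa.append(genus)
        prot_class.append(cls)
    for _ in range(n_euk):
        sequences.append(_random_sequence(rng, int(rng.integers(150, 301))))
        annotations.append(
            frozenset(rng.choice(general_leaves, size=1, replace=False))
        )
        taxa.append(euk_genus)
        prot_class.append(None)

    # --- peptides ---------------------------------------------------------
    n_nonbact_pep = round(config.nonbacterial_rate * config.n_peptides)
    n_bact_pep = config.n_peptides - n_nonbact_pep
    n_ambiguous = round(config.lca_ambiguity_rate * n_bact_pep)

    # shared: intervals (on hosts and on extraction sources) that exist in
    # more than one protein; unambiguous draws must not fall inside them
    shared: dict[int, list[tuple[int, int]]] = {}
    peptide_seqs: list[str] = []
    pep_sources: list[tuple[int, ...]] = []
    pep_ambiguous: list[bool] = []
    pep_bacterial: list[bool] = []
    seen: set[str] = set()

    def draw_peptide(
        prot_idx: int, avoid_shared: bool
    ) -> tuple[str, int] | None:
        seq = sequences[prot_idx]
        for _ in range(50):
            length = int(rng.integers(8, 16))
            if len(seq) <= length:
                continue
            start = int(rng.integers(0, len(seq) - length))
            if avoid_shared:
                bad = any(
                    start >= s and start + length <= e
                    for s, e in shared.get(prot_idx, [])
                )
                if bad:
                    continue
            pep = seq[start : start + length]
            if pep not in seen:
                return pep, start
        return None

    # Ambiguous peptides first: planting mutates host sequences.  Marker
    # proteins are excluded so spiked-term carriers stay single-source.
    hosts_of_class = {
        c: [
            i for i in range(n_bact)
            if prot_class[i] == c and i not in marker_prot_idx
        ]
        for c in class_names
    }
    nonmarker_bact = [i for i in range(n_bact) if i not in marker_prot_idx]
    made = 0
    attempts = 0
    while made < n_ambiguous and attempts < n_ambiguous * 20:
        attempts += 1
        src = int(rng.choice(nonmarker_bact))
        drawn = draw_peptide(src, avoid_shared=False)
        if drawn is None:
            continue
        pep, src_start = drawn
        other_classes = [c for c in class_names if c != prot_class[src]]
        host_pool = hosts_of_class[rng.choice(other_classes)]
        if not host_pool:
            continue
        host = int(rng.choice(host_pool))
        hseq = sequences[host]
        if len(hseq) <= len(pep) + 2:
            continue
        pos = int(rng.integers(0, len(hseq) - len(pep)))
        # never overwrite a region that carries another peptide's copy
        if any(
            pos < e and pos + len(pep) > s for s, e in shared.get(host, [])
        ):
            continue
        sequences[host] = hseq[:pos] + pep + hseq[pos + len(pep):]
        shared.setdefault(host, []).append((pos, pos + len(pep)))
        shared.setdefault(src, []).append((src_start, src_start + len(pep)))
        seen.add(pep)
        peptide_seqs.append(pep)
        pep_sources.append((src, host))
        pep_ambiguous.append(True)
        pep_bacterial.append(True)
        made += 1

    def fill(n: int, pool_start: int, pool_end: int, bacterial: bool) -> None:
        made = 0
        attempts = 0
        while made < n and attempts < n * 20 + 100:
            attempts += 1
            idx = int(rng.integers(pool_start, pool_end))
            drawn = draw_peptide(idx, avoid_shared=True)
            if drawn is None:
                continue
            pep, _ = drawn
            seen.add(pep)
            peptide_seqs.append(pep)
            pep_sources.append((idx,))
            pep_ambiguous.append(False)
            pep_bacterial.append(bacterial)
            made += 1
        if made < n:
            raise InputError(
                "could not draw enough unique peptides; "
                "increase n_proteins or reduce n_peptides"
            )

    fill(n_bact_pep - made, 0, n_bact, bacterial=True)
    if n_nonbact_pep:
        fill(n_nonbact_pep, n_bact, config.n_proteins, bacterial=False)

    proteins = [
        ProteinRecord(
            id=f"prot_{i:05d}",
            sequence=sequences[i],
            go_ids=annotations[i],
            top_hit_taxon=taxa[i],
        )
        for i in range(config.n_proteins)
    ]

    peptide_go = [
        frozenset().union(
            *(dag.closure(annotations[s]) for s in srcs)
        )
        for srcs in pep_sources
    ]
    info = pd.DataFrame(
        {
            "peptide": peptide_seqs,
            "source_class": [
                UNCLASSIFIED
                if amb
                else (prot_class[srcs[0]] or "")
                for srcs, amb in zip(pep_sources, pep_ambiguous)
            ],
            "organism_class": [
                prot_class[srcs[0]] or "" for srcs in pep_sources
            ],
            "ambiguous": pep_ambiguous,
            "bacterial": pep_bacterial,
        }
    )
    return Reference(
        dag=dag,
        tree=tree,
        proteins=proteins,
        peptides=peptide_seqs,
        leaf_terms=leaves,
        marker_terms=markers,
        bacteria_id=bacteria_id,
        peptide_info=info,
        peptide_go=peptide_go,
    )


def choose_spiked_terms(
    config: SimConfig, reference: Reference
) -> tuple[tuple[str, float], ...]:
    """Assign sign-balanced drifts spanning ``spike_log2_range`` to the
    reference's reserved marker terms (alternating up/down)."""
    chosen = list(reference.marker_terms)
    if not chosen:
        return ()
    lo, hi = config.spike_log2_range
    mags = np.linspace(lo, hi, num=len(chosen))
    return tuple(
        (t, float(m) * (1 if i % 2 == 0 else -1))
        for i, (t, m) in enumerate(zip(chosen, mags))
    )


def generate_timecourse(
    config: SimConfig, reference: Reference
) -> SimulatedDataset:
    """Sample the per-run PSM tables and 16S-like OTU tables.

    Per run, counts are one multinomial draw of
    ``total_spectra_per_run`` spectra over the per-peptide weights for
    that (treatment, day); weights of peptides carrying spiked terms are
    scaled by ``2**(drift * min(day, ramp))`` in the "om" treatment (and
    in the control too when ``spike_in_control`` is set).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(reference.peptides)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)

    spiked = config.spiked_terms
    if spiked is None:
        spiked = choose_spiked_terms(config, reference)
    for term, _ in spiked:
        if term not in reference.dag:
            raise InputError(f"spiked term {term} absent from reference")
        if not any(term in gos for gos in reference.peptide_go):
            raise InputError(f"spiked term {term} has no carrier peptides")

    carriers = {
        term: np.array(
            [i for i, gos in enumerate(reference.peptide_go) if term in gos]
        )
        for term, _ in spiked
    }

    # Balance the spiked set so its net weight change is zero: scale the
    # base weights of down-spiked carriers until the weight the up-spikes
    # add equals the weight the down-spikes remove.  Then the total weight
    # is the same at every day and null-term proportions stay constant —
    # spiking is not allowed to masquerade as a compositional shift in
    # every other term.  Auto-chosen spikes are balanced pairwise (each
    # up/down pair shares a class, keeping class shares constant too);
    # explicit spike lists are balanced globally.
    ramp = config.spike_ramp_days

    def _balance(ups, downs):
        added = sum(
            base[carriers[t]].sum() * (2.0 ** (d * ramp) - 1.0) for t, d in ups
        )
        removed = sum(
            base[carriers[t]].sum() * (1.0 - 2.0 ** (d * ramp))
            for t, d in downs
        )
        if added > 0 and removed > 0:
            gamma = added / removed
            for t, _ in downs:
                base[carriers[t]] *= gamma

    if config.spiked_terms is None:
        for pair in zip(spiked[0::2], spiked[1::2]):
            ups = [(t, d) for t, d in pair if d > 0]
            downs = [(t, d) for t, d in pair if d < 0]
            _balance(ups, downs)
    else:
        _balance(
            [(t, d) for t, d in spiked if d > 0],
            [(t, d) for t, d in spiked if d < 0],
        )
    bacterial = reference.peptide_info["bacterial"].to_numpy()
    src_class = reference.peptide_info["source_class"].to_numpy()
    org_class = reference.peptide_info["organism_class"].to_numpy()

    run_meta: dict[str, tuple[str, float]] = {}
    psm_tables: dict[str, list[PeptideObservation]] = {}
    otu_tables: dict[str, dict[str, float]] = {}
    class_truth: dict[str, dict[str, float]] = {}
    otu_truth: dict[str, dict[str, float]] = {}

    for treatment in config.treatments:
        for day in config.days:
            run_id = f"{treatment}_d{int(day) if float(day).is_integer() else day}"
            run_meta[run_id] = (treatment, float(day))
            w = base.copy()
            if treatment == "om" or config.spike_in_control:
                effect_days = min(day, config.spike_ramp_days)
                for term, drift in spiked:
                    w[carriers[term]] *= 2.0 ** (drift * effect_days)
            p = w / w.sum()
            counts = rng.multinomial(config.total_spectra_per_run, p)
            psm_tables[run_id] = [
                PeptideObservation(
                    peptide=reference.peptides[i],
                    run_id=run_id,
                    spectral_count=int(c),
                )
                for i, c in enumerate(counts)
                if c > 0
            ]
            # expected class composition among retained bacterial weight
            wb = p[bacterial]
            cls = src_class[bacterial]
            traj: dict[str, float] = {}
            for c in np.unique(cls):
                traj[str(c)] = float(wb[cls == c].sum() / wb.sum())
            class_truth[run_id] = traj
            # organism-level composition (16S sees through ambiguity)
            ocls = org_class[bacterial]
            otraj: dict[str, float] = {}
            for c in np.unique(ocls):
                otraj[str(c)] = float(wb[ocls == c].sum() / wb.sum())
            otu_truth[run_id] = otraj
            labels = sorted(otraj)
            probs = np.array([otraj[c] for c in labels])
            otu_counts = rng.multinomial(config.otu_depth, probs / probs.sum())
            otu_tables[run_id] = {
                c: int(k) / config.otu_depth
                for c, k in zip(labels, otu_counts)
                if k > 0
            }

    truth = TruthTable(
        spiked=dict(spiked),
        class_trajectories=class_truth,
        otu_trajectories=otu_truth,
    )
    return SimulatedDataset(
        config=config,
        reference=reference,
        truth=truth,
        run_meta=run_meta,
        psm_tables=psm_tables,
        otu_tables=otu_tables,
    )


def simulate(config: SimConfig) -> SimulatedDataset:
    """Convenience wrapper: reference + timecourse in one call."""
    return generate_timecourse(config, generate_reference(config))


def truth_eval(
    truth: TruthTable,
    enrichment_results,
) -> dict[str, float]:
    """Sensitivity/specificity of significant-term calls against the
    spiked-term truth, computed over tested *terminal* terms."""
    spiked = set(truth.spiked)
    tp = fp = fn = tn = 0
    for r in enrichment_results:
        if not r.is_terminal:
            continue
        if r.go_id in spiked:
            if r.is_significant:
                tp += 1
            else:
                fn += 1
        else:
            if r.is_significant:
                fp += 1
            else:
                tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sens, "specificity": spec,
    }


def simulate_ratio_matrices(
    n_func: int = 71,
    n_tax: int = 24,
    days: Sequence[float] = (0, 1, 6),
    func_step: float = 0.05,
    tax_step: float = 0.005,
    seed: int = 0,
) -> tuple[RatioMatrix, RatioMatrix]:
    """Directly simulate functional and taxonomic ratio matrices.

    Rows start at a uniform baseline and take Gaussian per-day steps of
    group-specific scale; cells are clipped to [0, 1].  With equal
    scales the two groups are exchangeable (a true null for the
    permutation test).
    """
    rng = np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)
    gaps = np.diff(days)

    def make(n_rows: int, scale: float, prefix: str) -> RatioMatrix:
        v0 = rng.uniform(0.02, 0.3, size=n_rows)
        steps = rng.normal(0.0, scale, size=(n_rows, len(gaps))) * gaps
        values = np.concatenate(
            [v0[:, None], v0[:, None] + np.cumsum(steps, axis=1)], axis=1
        )
        return RatioMatrix(
            row_ids=[f"{prefix}{i}" for i in range(n_rows)],
            days=days,
            values=np.clip(values, 0.0, 1.0),
        )

    return make(n_func, func_step, "fn"), make(n_tax, tax_step, "tax")


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write the dataset in the pipeline's on-disk formats.

    Emits proteins.fasta, annotations.tsv, taxonomy.tsv, ontology.obo,
    psm_<run>.tsv, otu_<run>.tsv, truth.tsv, and a ready-to-run
    manifest.yaml.
    """
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref = dataset.reference
    pio.write_protein_fasta(ref.proteins, out / "proteins.fasta")
    pio.write_annotation_table(ref.proteins, out / "annotations.tsv")
    write_taxonomy(ref.tree, out / "taxonomy.tsv")
    write_obo(ref.dag, out / "ontology.obo")
    for run_id, obs in sorted(dataset.psm_tables.items()):
        pio.write_psm_table(obs, out / f"psm_{run_id}.tsv")
    for run_id, table in sorted(dataset.otu_tables.items()):
        rows = [(run_id, c, f) for c, f in sorted(table.items())]
        pd.DataFrame(rows, columns=["run_id", "class", "fraction"]).to_csv(
            out / f"otu_{run_id}.tsv", sep="\t", index=False
        )
    pd.DataFrame(
        sorted(dataset.truth.spiked.items()),
        columns=["go_id", "log2_drift_per_day"],
    ).to_csv(out / "truth.tsv", sep="\t", index=False)

    manifest = {
        "reference": {
            "fasta": "proteins.fasta",
            "annotations": "annotations.tsv",
            "taxonomy": "taxonomy.tsv",
            "obo": "ontology.obo",
        },
        "experiments": [
            {
                "experiment": f"synthetic_{treatment}",
                "site": "synthetic",
                "treatment": "OM_input" if treatment == "om" else "control",
                "runs": [
                    {
                        "run_id": run_id,
                        "day": day,
                        "psm": f"psm_{run_id}.tsv",
                        "otu": f"otu_{run_id}.tsv",
                    }
                    for run_id, (tr, day) in sorted(
                        dataset.run_meta.items(), key=lambda kv: kv[1][1]
                    )
                    if tr == treatment
                ],
            }
            for treatment in dataset.config.treatments
        ],
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
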