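"""Spectral-count quantification over the GO DAG and the taxonomy.

Counting is peptide-centric: a peptide's spectral count is credited
once to every GO term in its ancestor-closed annotation set, no matter
how many matched proteins carry the term — this sidesteps the protein
inference problem entirely.  Taxon accounting rolls each peptide's LCA
up to class rank; spectra that cannot be resolved at class rank fall
into the reserved ``Unclassified`` bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .errors import InputError, IntegrityError
from .ontology import GoDag
from .records import PeptideAnnotation, PeptideObservation
from .taxonomy import UNCLASSIFIED, TaxTree


@dataclass
class GoCountTable:
    """Per-run propagated GO spectral counts.

    ``total_spectra`` is the post-filter bacterial total for the run —
    the denominator of every proportion downstream.
    """

    run_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_spectra: int = 0


def _run_observations(
    observations: Iterable[PeptideObservation], run_id: str
) -> list[PeptideObservation]:
    return [o for o in observations if o.run_id == run_id]


def go_spectral_counts(
    annotations: Mapping[str, PeptideAnnotation],
    observations: Iterable[PeptideObservation],
    run_id: str,
) -> GoCountTable:
    """Propagated GO counts for one run.

    Every observation's peptide must be present in ``annotations``
    (i.e., the observations have already been restricted to retained,
    matched, bacterial peptides); a missing annotation is an integrity
    error.  ``total_spectra`` includes peptides whose proteins carry no
    GO annotation.
    """
    counts: dict[str, int] = {}
    total = 0
    for obs in _run_observations(observations, run_id):
        ann = annotations.get(obs.peptide)
        if ann is None:
            raise IntegrityError(
                f"observation without annotation: {obs.peptide} in {run_id}"
            )
        total += obs.spectral_count
        for gid in ann.go_ids:  # already ancestor-closed, each term once
            counts[gid] = counts.get(gid, 0) + obs.spectral_count
    return GoCountTable(run_id=run_id, counts=counts, total_spectra=total)


def _class_of(
    ann: PeptideAnnotation, tree: TaxTree, rank: str
) -> str:
    """Reporting bucket for a peptide: the *name* of its LCA rolled up
    to ``rank``, or ``Unclassified`` when the rollup is impossible."""
    if ann.lca_taxon is None:
        return UNCLASSIFIED
    node = tree.rank_at(ann.lca_taxon, rank)
    return tree[node].name if node is not None else UNCLASSIFIED


def taxon_proportions(
    annotations: Mapping[str, PeptideAnnotation],
    observations: Iterable[PeptideObservation],
    run_id: str,
    go_id: str,
    tree: TaxTree,
    rank: str = "class",
    counts: GoCountTable | None = None,
) -> dict[str, float]:
    """Per-taxon share of one GO term's spectra in one run.

    Each peptide contributing to ``go_id`` adds its spectral count to
    the bucket of its class-rank rollup (or ``Unclassified``); buckets
    are divided by the term's propagated count, so they sum to 1.
    """
    if counts is None:
        counts = go_spectral_counts(annotations, observations, run_id)
    term_total = counts.counts.get(go_id, 0)
    if term_total == 0:
        raise InputError(
            f"GO term {go_id} has zero spectra in run {run_id}: "
            "proportions undefined"
        )
    buckets: dict[str, int] = {}
    for obs in _run_observations(observations, run_id):
        ann = annotations[obs.peptide]
        if go_id not in ann.go_ids:
            continue
        key = _class_of(ann, tree, rank)
        buckets[key] = buckets.get(key, 0) + obs.spectral_count
    return {k: v / term_total for k, v in buckets.items()}


def class_abundance(
    annotations: Mapping[str, PeptideAnnotation],
    observations: Iterable[PeptideObservation],
    run_id: str,
    tree: TaxTree,
    rank: str = "class",
) -> dict[str, float]:
    """Run-level relative abundance per taxonomic class.

    Spectral counts bucketed by each peptide's class rollup (with the
    ``Unclassified`` sink) and normalized by the run total; fractions
    sum to 1.
    """
    buckets: dict[str, int] = {}
    total = 0
    for obs in _run_observations(observations, run_id):
        ann = annotations.get(obs.peptide)
        if ann is None:
            raise IntegrityError(
                f"observation without annotation: {obs.peptide} in {run_id}"
            )
        key = _class_of(ann, tree, rank)
        buckets[key] = buckets.get(key, 0) + obs.spectral_count
        total += obs.spectral_count
    if total == 0:
        raise InputError(f"run {run_id} has no retained spectra")
    return {k: v / total for k, v in buckets.items()}


class GoIncidence:
    """Sparse peptide x GO-term incidence for fast repeated counting.

    Rows follow a fixed peptide order; columns a fixed term order.
    Multiplying a per-peptide count vector through the matrix yields the
    same propagated counts as :func:`go_spectral_counts` — used by the
    simulation-heavy calibration paths where thousands of count tables
    are needed.
    """

    def __init__(
        self,
        annotations: Mapping[str, PeptideAnnotation],
        peptide_order: Sequence[str],
    ):
        self.peptides = list(peptide_order)
        term_set: set[str] = set()
        for pep in self.peptides:
            term_set |= annotations[pep].go_ids
        self.terms = sorted(term_set)
        t_index = {t: i for i, t in enumerate(self.terms)}
        rows, cols = [], []
        for i, pep in enumerate(self.peptides):
            for gid in annotations[pep].go_ids:
                rows.append(i)
                cols.append(t_index[gid])
        data = np.ones(len(rows), dtype=np.int64)
        self.matrix = sparse.csr_matrix(
            (data, (rows, cols)),
            shape=(len(self.peptides), len(self.terms)),
        )

    def counts(self, peptide_counts: np.ndarray) -> np.ndarray:
        """Propagated term counts for a per-peptide count vector."""
        return np.asarray(
            self.matrix.T @ np.asarray(peptide_counts, dtype=np.int64)
        )

    def count_table(self, peptide_counts: np.ndarray, run_id: str) -> GoCountTable:
        vec = self.counts(peptide_counts)
        counts = {
            t: int(c) for t, c in zip(self.terms, vec) if c > 0
        }
        return GoCountTable(
            run_id=run_id,
            counts=counts,
            total_spectra=int(np.sum(peptide_counts)),
        )
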