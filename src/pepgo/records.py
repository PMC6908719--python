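"""Shared plain-data record types."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ProteinRecord:
    """One metagenome-predicted protein with its functional and
    taxonomic labels.

    ``top_hit_taxon`` is the precomputed taxon of the protein's top
    homology hit (one per protein); the package never re-ranks hits.
    """

    id: str
    sequence: str
    go_ids: frozenset[str] = field(default_factory=frozenset)
    top_hit_taxon: str | None = None


@dataclass(frozen=True)
class PeptideObservation:
    """One (peptide, run) row of a PSM table; ``spectral_count`` is the
    number of spectra matched to the peptide in that run."""

    peptide: str
    run_id: str
    spectral_count: int


@dataclass(frozen=True)
class PeptideAnnotation:
    """A peptide joined to the database: matched proteins, the
    ancestor-closed union of their GO annotations, the LCA of their
    top-hit taxa, and the bacterial filter flag."""

    peptide: str
    protein_ids: frozenset[str]
    go_ids: frozenset[str]
    lca_taxon: str | None
    is_bacterial: bool
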