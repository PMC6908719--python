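"""Peptide annotation: GO closure, LCA taxon, bacterial filter."""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .errors import InputError
from .matching import PeptideMatcher
from .ontology import GoDag
from .records import PeptideAnnotation, ProteinRecord
from .taxonomy import TaxTree

logger = logging.getLogger(__name__)


def _proteins_by_id(proteins) -> Mapping[str, ProteinRecord]:
    if isinstance(proteins, Mapping):
        return proteins
    return {p.id: p for p in proteins}


def _resolve_bacteria(tree: TaxTree, bacteria_id: str | None) -> str:
    if bacteria_id is not None:
        if bacteria_id not in tree:
            raise KeyError(f"unknown taxon: {bacteria_id!r}")
        return bacteria_id
    found = tree.find_by_name("Bacteria")
    if found is None:
        raise InputError(
            "taxonomy has no node named 'Bacteria'; pass bacteria_id explicitly"
        )
    return found


def annotate_peptide(
    dag: GoDag,
    tree: TaxTree,
    proteins,
    matcher: PeptideMatcher,
    peptide: str,
    bacteria_id: str | None = None,
    keep_untaxed: bool = False,
) -> PeptideAnnotation:
    """Join one peptide to the protein database.

    go_ids is the union over matched proteins of their GO annotations
    plus all ancestors (a fixed point of ancestor closure).  lca_taxon
    is the LCA of the matched proteins' non-missing top-hit taxa, or
    None when no matched protein carries a taxon.  is_bacterial is true
    when the LCA lies on or under the Bacteria node; peptides with no
    taxon are nonbacterial by default (conservative removal) unless
    ``keep_untaxed`` is set.

    An unmatched peptide is not an error: it yields an annotation with
    empty protein and GO sets.
    """
    by_id = _proteins_by_id(proteins)
    bacteria = _resolve_bacteria(tree, bacteria_id)
    hits = matcher.match(peptide)
    go_ids: set[str] = set()
    taxa: set[str] = set()
    for pid in hits:
        prot = by_id[pid]
        for gid in prot.go_ids:
            if gid not in dag:
                logger.warning(
                    "protein %s: GO id %s not in ontology, dropped", pid, gid
                )
                continue
            go_ids.add(gid)
            go_ids |= dag.ancestors(gid)
        if prot.top_hit_taxon is not None:
            taxa.add(prot.top_hit_taxon)
    lca_taxon = tree.lca(taxa) if taxa else None
    if lca_taxon is None:
        is_bacterial = bool(keep_untaxed and hits)
    else:
        is_bacterial = tree.is_under(lca_taxon, bacteria)
    return PeptideAnnotation(
        peptide=peptide,
        protein_ids=frozenset(hits),
        go_ids=frozenset(go_ids),
        lca_taxon=lca_taxon,
        is_bacterial=is_bacterial,
    )


def annotate_peptides(
    dag: GoDag,
    tree: TaxTree,
    proteins,
    matcher: PeptideMatcher,
    peptides: Iterable[str],
    bacteria_id: str | None = None,
    keep_untaxed: bool = False,
) -> dict[str, PeptideAnnotation]:
    """Annotate a collection of unique peptides; returns peptide -> annotation."""
    by_id = _proteins_by_id(proteins)
    bacteria = _resolve_bacteria(tree, bacteria_id)
    out: dict[str, PeptideAnnotation] = {}
    n_unmatched = 0
    for pep in peptides:
        if pep in out:
            continue
        ann = annotate_peptide(
            dag, tree, by_id, matcher, pep,
            bacteria_id=bacteria, keep_untaxed=keep_untaxed,
        )
        if not ann.protein_ids:
            n_unmatched += 1
        out[pep] = ann
    if n_unmatched:
        logger.warning(
            "%d of %d peptides matched no protein and carry no annotation",
            n_unmatched, len(out),
        )
    return out


def filter_nonbacterial(
    annotations: Sequence[PeptideAnnotation],
) -> tuple[list[PeptideAnnotation], int]:
    """Split annotations on the bacterial flag.

    Returns ``(kept, removed_count)`` where kept preserves input order
    and ``len(kept) + removed_count == len(annotations)``.
    """
    kept = [a for a in annotations if a.is_bacterial]
    return kept, len(annotations) - len(kept)
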