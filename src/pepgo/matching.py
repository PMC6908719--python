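"""Exact peptide-to-protein substring matching under I/L equivalence.

Isoleucine and leucine are isobaric and indistinguishable by the mass
spectrometer, so by default both query and database are normalized
(L -> I) before matching.  The index concatenates all normalized
protein sequences into one text with a sentinel separator; a query is
answered by repeated ``str.find`` over the text, mapping hit offsets
back to protein records.  The sentinel never occurs in a peptide, so a
hit cannot straddle two proteins.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Sequence

from .errors import InputError, IntegrityError
from .records import ProteinRecord

_SENTINEL = "#"


def normalize_il(seq: str) -> str:
    """Collapse I/L ambiguity (L -> I)."""
    return seq.replace("L", "I")


def _check_peptide(peptide: str) -> None:
    if not peptide:
        raise InputError("empty peptide")
    if not peptide.isalpha() or not peptide.isupper():
        raise InputError(f"peptide is not an amino-acid string: {peptide!r}")


class PeptideMatcher:
    """Substring index over a protein database.

    Parameters
    ----------
    proteins:
        Nonempty sequence of :class:`ProteinRecord` with unique ids.
    il_equivalence:
        Treat I and L as identical (default, standard metaproteomics
        practice for MS data).
    """

    def __init__(
        self, proteins: Sequence[ProteinRecord], il_equivalence: bool = True
    ):
        proteins = list(proteins)
        if not proteins:
            raise InputError("cannot index an empty protein list")
        ids = [p.id for p in proteins]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise IntegrityError(f"duplicate protein id: {dup}")
        self.il_equivalence = il_equivalence
        self._ids = ids
        parts = []
        starts = []  # start offset of each protein in the text
        pos = 0
        for p in proteins:
            if not p.sequence:
                raise InputError(f"protein {p.id} has an empty sequence")
            seq = normalize_il(p.sequence) if il_equivalence else p.sequence
            parts.append(seq)
            starts.append(pos)
            pos += len(seq) + 1
        self._text = _SENTINEL.join(parts)
        self._starts = starts

    def match(self, peptide: str) -> set[str]:
        """Ids of all proteins containing ``peptide`` as a contiguous
        substring (under the configured I/L equivalence)."""
        _check_peptide(peptide)
        query = normalize_il(peptide) if self.il_equivalence else peptide
        hits: set[str] = set()
        pos = self._text.find(query)
        while pos != -1:
            idx = bisect_right(self._starts, pos) - 1
            hits.add(self._ids[idx])
            pos = self._text.find(query, pos + 1)
        return hits


def index_proteins(
    proteins: Iterable[ProteinRecord], il_equivalence: bool = True
) -> PeptideMatcher:
    """Build a :class:`PeptideMatcher` over the protein database."""
    return PeptideMatcher(list(proteins), il_equivalence=il_equivalence)


def match_peptide(matcher: PeptideMatcher, peptide: str) -> set[str]:
    """Module-level alias for :meth:`PeptideMatcher.match`."""
    return matcher.match(peptide)
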