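"""Rooted reference taxonomy: parsing, LCA, and rank rollup.

The native format is a 4-column TSV (``id<TAB>parent_id<TAB>rank<TAB>
name``, header required, one root row with empty parent).  Ranks
outside the canonical 8-rank set are collapsed to ``no rank`` and
skipped by :meth:`TaxTree.rank_at`, so e.g. suborders never block a
class-level rollup.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputError, IntegrityError

CANONICAL_RANKS = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
NO_RANK = "no rank"
_RANK_INDEX = {r: i for i, r in enumerate(CANONICAL_RANKS)}

#: Reserved bucket name for spectra that cannot be resolved to the
#: reporting rank (LCA missing, above the rank, or off the rank path).
UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class TaxNode:
    id: str
    name: str
    rank: str  # canonical rank or "no rank"
    parent_id: str | None  # None for the root


class TaxTree:
    """Single-rooted taxonomy with validated parent chains."""

    def __init__(self, nodes: Mapping[str, TaxNode]):
        self._nodes: dict[str, TaxNode] = dict(nodes)
        self._path_cache: dict[str, tuple[str, ...]] = {}
        roots = [n.id for n in self._nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise IntegrityError(
                f"taxonomy must have exactly one root, found {len(roots)}"
            )
        self._root_id = roots[0]
        for node in self._nodes.values():
            if node.parent_id is not None and node.parent_id not in self._nodes:
                raise IntegrityError(
                    f"node {node.id} references missing parent {node.parent_id}"
                )
        # Walk every parent chain once: detects cycles and rank inversions.
        for nid in self._nodes:
            path = self.path_to_root(nid)
            prev = None  # rank index, finest seen so far walking rootward
            for pid in reversed(path):  # root -> node
                r = self._nodes[pid].rank
                if r == NO_RANK:
                    continue
                idx = _RANK_INDEX[r]
                if prev is not None and idx < prev:
                    raise IntegrityError(
                        f"rank inversion on path to {nid}: {r} below finer rank"
                    )
                prev = idx

    def __contains__(self, nid: str) -> bool:
        return nid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __getitem__(self, nid: str) -> TaxNode:
        try:
            return self._nodes[nid]
        except KeyError:
            raise KeyError(f"unknown taxon: {nid!r}") from None

    @property
    def root_id(self) -> str:
        return self._root_id

    @property
    def nodes(self) -> Mapping[str, TaxNode]:
        return self._nodes

    def path_to_root(self, nid: str) -> tuple[str, ...]:
        """Node ids from ``nid`` (inclusive) up to the root (inclusive)."""
        if nid not in self._nodes:
            raise KeyError(f"unknown taxon: {nid!r}")
        cached = self._path_cache.get(nid)
        if cached is not None:
            return cached
        path = [nid]
        seen = {nid}
        cur = self._nodes[nid]
        while cur.parent_id is not None:
            if cur.parent_id in seen:
                raise IntegrityError(f"cycle in taxonomy at {cur.parent_id}")
            path.append(cur.parent_id)
            seen.add(cur.parent_id)
            cur = self._nodes[cur.parent_id]
        result = tuple(path)
        self._path_cache[nid] = result
        return result

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest (deepest) common ancestor of a nonempty taxon set.

        ``lca({x}) == x``; the result is an ancestor-or-self of every
        member and no strict descendant of it is."""
        taxa = list(taxa)
        if not taxa:
            raise InputError("lca() requires a nonempty taxon set")
        others = [set(self.path_to_root(t)) for t in taxa[1:]]
        for candidate in self.path_to_root(taxa[0]):
            if all(candidate in s for s in others):
                return candidate
        raise IntegrityError("disconnected taxonomy (no common ancestor)")

    def rank_at(self, nid: str, rank: str) -> str | None:
        """The unique ancestor-or-self of ``nid`` at ``rank``, or None
        when the node sits above (or off) that rank."""
        if rank not in _RANK_INDEX:
            raise InputError(f"unknown rank: {rank!r}")
        for pid in self.path_to_root(nid):
            if self._nodes[pid].rank == rank:
                return pid
        return None

    def is_under(self, nid: str, ancestor_id: str) -> bool:
        """True when ``ancestor_id`` is an ancestor-or-self of ``nid``."""
        if ancestor_id not in self._nodes:
            raise KeyError(f"unknown taxon: {ancestor_id!r}")
        return ancestor_id in self.path_to_root(nid)

    def find_by_name(self, name: str) -> str | None:
        """Id of the first node whose name matches (case-insensitive)."""
        low = name.lower()
        for nid, node in self._nodes.items():
            if node.name.lower() == low:
                return nid
        return None


def lca(tree: TaxTree, taxa: Iterable[str]) -> str:
    return tree.lca(taxa)


def rank_at(tree: TaxTree, nid: str, rank: str) -> str | None:
    return tree.rank_at(nid, rank)


def parse_taxonomy(source) -> TaxTree:
    """Parse the 4-column taxonomy TSV into a :class:`TaxTree`.

    Expects a header row with columns ``id, parent_id, rank, name``.
    Non-canonical ranks are normalized to ``no rank``.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise InputError(f"malformed taxonomy TSV: {exc}") from exc
    required = {"id", "parent_id", "rank", "name"}
    if not required.issubset(df.columns):
        raise InputError(
            f"taxonomy TSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise IntegrityError(f"duplicate taxon id: {dup}")
    nodes = {}
    for row in df.itertuples(index=False):
        rank = row.rank if row.rank in _RANK_INDEX else NO_RANK
        parent = row.parent_id if row.parent_id not in ("", "-") else None
        nodes[row.id] = TaxNode(
            id=row.id, name=row.name, rank=rank, parent_id=parent
        )
    return TaxTree(nodes)


def write_taxonomy(tree: TaxTree, path) -> None:
    rows = [
        (n.id, n.parent_id or "", n.rank, n.name)
        for n in sorted(tree.nodes.values(), key=lambda n: n.id)
    ]
    pd.DataFrame(rows, columns=["id", "parent_id", "rank", "name"]).to_csv(
        path, sep="\t", index=False
    )
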