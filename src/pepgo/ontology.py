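"""Gene Ontology DAG: parsing, ancestor closure, terminal terms.

The ontology is held as a plain parent-pointer DAG (term -> set of
parent term ids over ``is_a`` and, optionally, ``part_of`` edges).
Ancestor closure is the workhorse of peptide-centric quantification:
every spectral count credited to a term is also credited to all of its
ancestors, so closures are memoized per term.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import obonet

from .errors import InputError, IntegrityError

#: GO aspect (namespace) names; each aspect has a single root term.
ASPECTS = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class GoTerm:
    """One ontology term.

    ``parent_ids`` holds the direct parents over the configured edge
    relations; aspect roots have an empty parent set.  ``aspect`` may be
    ``None`` for toy ontologies that omit namespace lines.
    """

    id: str
    name: str
    aspect: str | None
    parent_ids: frozenset[str] = field(default_factory=frozenset)


class GoDag:
    """Validated directed acyclic graph of :class:`GoTerm`.

    Construction checks that every referenced parent exists, that the
    edge relation is acyclic, and that every term reaches exactly one
    root (terms with no parents).
    """

    def __init__(self, terms: Mapping[str, GoTerm]):
        self._terms: dict[str, GoTerm] = dict(terms)
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._children: dict[str, set[str]] | None = None
        self._validate()

    # -- container protocol -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __getitem__(self, term_id: str) -> GoTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise KeyError(f"unknown GO term: {term_id!r}") from None

    def __iter__(self):
        return iter(self._terms)

    @property
    def terms(self) -> Mapping[str, GoTerm]:
        return self._terms

    @property
    def roots(self) -> frozenset[str]:
        return self._roots

    # -- validation ----------------------------------------------------------

    def _validate(self) -> None:
        for t in self._terms.values():
            for p in t.parent_ids:
                if p not in self._terms:
                    raise IntegrityError(
                        f"term {t.id} references unknown parent {p}"
                    )
        # Kahn topological sort to detect cycles.
        indeg = {tid: 0 for tid in self._terms}
        for t in self._terms.values():
            for p in t.parent_ids:
                indeg[p] += 1
        queue = [tid for tid, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            tid = queue.pop()
            seen += 1
            for p in self._terms[tid].parent_ids:
                indeg[p] -= 1
                if indeg[p] == 0:
                    queue.append(p)
        if seen != len(self._terms):
            raise IntegrityError("ontology contains a cycle")
        self._roots = frozenset(
            tid for tid, t in self._terms.items() if not t.parent_ids
        )
        if self._terms and not self._roots:
            raise IntegrityError("ontology has no root term")
        for tid in self._terms:
            anc = self.ancestors(tid)
            n_roots = len((anc | {tid}) & self._roots)
            if n_roots != 1:
                raise IntegrityError(
                    f"term {tid} reaches {n_roots} roots (expected exactly 1)"
                )

    # -- queries -------------------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` by parent edges,
        excluding ``term_id`` itself.  Each ancestor appears once no
        matter how many paths lead to it."""
        if term_id not in self._terms:
            raise KeyError(f"unknown GO term: {term_id!r}")
        cached = self._anc_cache.get(term_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self._terms[term_id].parent_ids)
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            hit = self._anc_cache.get(cur)
            if hit is not None:
                out.add(cur)
                out |= hit
                continue
            out.add(cur)
            stack.extend(self._terms[cur].parent_ids)
        result = frozenset(out)
        self._anc_cache[term_id] = result
        return result

    def closure(self, term_ids: Iterable[str]) -> frozenset[str]:
        """Union of the given terms and all their ancestors."""
        out: set[str] = set()
        for tid in term_ids:
            out.add(tid)
            out |= self.ancestors(tid)
        return frozenset(out)

    def children(self, term_id: str) -> frozenset[str]:
        """Direct children of a term (inverted parent relation)."""
        if self._children is None:
            ch: dict[str, set[str]] = {tid: set() for tid in self._terms}
            for t in self._terms.values():
                for p in t.parent_ids:
                    ch[p].add(t.id)
            self._children = ch
        if term_id not in self._terms:
            raise KeyError(f"unknown GO term: {term_id!r}")
        return frozenset(self._children[term_id])

    def is_leaf(self, term_id: str) -> bool:
        return not self.children(term_id)

    def aspect_of(self, term_id: str) -> str | None:
        """Aspect of a term, falling back to the aspect of its root."""
        t = self[term_id]
        if t.aspect is not None:
            return t.aspect
        for r in (self.ancestors(term_id) | {term_id}) & self._roots:
            root = self._terms[r]
            return root.aspect if root.aspect is not None else root.name
        return None


def ancestors(dag: GoDag, term_id: str) -> frozenset[str]:
    """Module-level alias for :meth:`GoDag.ancestors`."""
    return dag.ancestors(term_id)


def parse_obo(source, include_part_of: bool = True) -> GoDag:
    """Parse an OBO 1.2/1.4 stream or path into a :class:`GoDag`.

    Obsolete terms are dropped (obonet default).  Parent edges are taken
    from ``is_a`` and, when ``include_part_of`` is true (the default),
    ``relationship: part_of`` clauses; all other relations are ignored.
    Edges to terms absent from the file (e.g. in ontology slims) are
    dropped rather than invented.

    Raises :class:`InputError` on malformed OBO and
    :class:`IntegrityError` on cyclic edge sets.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        graph = obonet.read_obo(source, ignore_obsolete=True)
    except IntegrityError:
        raise
    except Exception as exc:  # obonet raises assorted ValueErrors
        raise InputError(f"malformed OBO input: {exc}") from exc

    relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    node_ids = set(graph.nodes)
    terms: dict[str, GoTerm] = {}
    for node, data in graph.nodes(data=True):
        parents = frozenset(
            v
            for _, v, key in graph.out_edges(node, keys=True)
            if key in relations and v in node_ids
        )
        terms[node] = GoTerm(
            id=node,
            name=data.get("name", node),
            aspect=data.get("namespace"),
            parent_ids=parents,
        )
    return GoDag(terms)


def write_obo(dag: GoDag, path) -> None:
    """Serialize a :class:`GoDag` to minimal OBO 1.2 text (round-trips
    through :func:`parse_obo`).  Only is_a edges are emitted; the
    package's generated ontologies use no other relation."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for tid in sorted(dag.terms):
            t = dag[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {t.id}\n")
            fh.write(f"name: {t.name}\n")
            if t.aspect:
                fh.write(f"namespace: {t.aspect}\n")
            for p in sorted(t.parent_ids):
                fh.write(f"is_a: {p} ! {dag[p].name}\n")
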