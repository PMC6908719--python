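"""Shared fixtures: toy ontology/taxonomy and a small simulated study."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from pepgo import (
    GoDag,
    GoTerm,
    SimConfig,
    TaxNode,
    TaxTree,
    parse_obo,
    simulate,
)

TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: biological_process
namespace: biological_process

[Term]
id: GO:0000002
name: process A
namespace: biological_process
is_a: GO:0000001 ! biological_process

[Term]
id: GO:0000003
name: process B
namespace: biological_process
is_a: GO:0000002 ! process A

[Term]
id: GO:0000004
name: process C
namespace: biological_process
is_a: GO:0000002 ! process A

[Term]
id: GO:0000005
name: diamond bottom
namespace: biological_process
is_a: GO:0000003 ! process B
is_a: GO:0000004 ! process C
"""


@pytest.fixture(scope="session")
def toy_dag() -> GoDag:
    """Chain root <- A <- {B, C} <- D (diamond)."""
    return parse_obo(TOY_OBO)


TOY_TAXONOMY = """\
id\tparent_id\trank\tname
1\t\troot\tcellular root
2\t1\tsuperkingdom\tBacteria
3\t1\tsuperkingdom\tEukaryota
10\t2\tphylum\tBacteroidetes
11\t2\tphylum\tProteobacteria
20\t10\tclass\tFlavobacteriia
21\t11\tclass\tGammaproteobacteria
30\t20\tgenus\tPolaribacter
31\t20\tgenus\tTenacibaculum
32\t21\tgenus\tColwellia
40\t3\tgenus\tThalassiosira
"""


@pytest.fixture(scope="session")
def toy_tree() -> TaxTree:
    from pepgo import parse_taxonomy

    return parse_taxonomy(TOY_TAXONOMY)


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated study at the default (study-like) settings."""
    return simulate(SimConfig(seed=42))


def random_dag(rng: np.random.Generator, n_terms: int) -> GoDag:
    """Random single-root DAG for oracle-equivalence tests."""
    terms = {"T000": GoTerm(id="T000", name="root", aspect=None)}
    ids = ["T000"]
    for i in range(1, n_terms):
        tid = f"T{i:03d}"
        k = int(rng.integers(1, min(3, len(ids)) + 1))
        parents = frozenset(
            str(p) for p in rng.choice(ids, size=k, replace=False)
        )
        terms[tid] = GoTerm(id=tid, name=tid, aspect=None, parent_ids=parents)
        ids.append(tid)
    return GoDag(terms)


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxTree:
    """Random rooted taxonomy (ranks all 'no rank' except the root)."""
    nodes = {"n0": TaxNode("n0", "root", "root", None)}
    for i in range(1, n_nodes):
        parent = f"n{rng.integers(0, i)}"
        nodes[f"n{i}"] = TaxNode(f"n{i}", f"taxon {i}", "no rank", parent)
    return TaxTree(nodes)


def brute_force_ancestors(dag: GoDag, term_id: str) -> set:
    """Transitive closure by repeated expansion (independent oracle)."""
    out = set()
    frontier = set(dag[term_id].parent_ids)
    while frontier:
        out |= frontier
        frontier = {
            p for t in frontier for p in dag[t].parent_ids
        } - out
    return out


def brute_force_lca(tree: TaxTree, taxa) -> str:
    """Intersection-of-root-paths oracle: deepest node present on every
    member's path to the root."""
    paths = [tree.path_to_root(t) for t in taxa]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # deepest = maximal distance from root
    return max(common, key=lambda n: len(tree.path_to_root(n)))
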