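"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's algorithms: parsimony scores are
minimized by explicit enumeration over every assignment of internal nodes
(and '?' leaves), and MPR state sets are collected from the argmin
assignments.  They are exponential and only usable on tiny trees — which is
the point.
"""

from __future__ import annotations

import itertools

import pytest

from chromoclad import karyomap
from chromoclad.charcoding import CharacterMatrix
from chromoclad.fixtures import load_all_fixtures, load_karyotype
from chromoclad.karyomap import HomologyMap, PaintSignal
from chromoclad.mptree import PhyloTree

OUTGROUP = ["DEC", "DRO", "DYO"]

#: the published study topology: Tonatia basal in the ingroup, PHA+PDI sisters
STUDY_NEWICK = "(((PHA,PDI),LSI),TSA,(DEC,(DRO,DYO)));"


@pytest.fixture(scope="session")
def fixture_maps() -> dict[str, HomologyMap]:
    return load_all_fixtures()


@pytest.fixture(scope="session")
def pha_karyotype():
    return load_karyotype("PHA")


@pytest.fixture(scope="session")
def identity_pha_map(pha_karyotype) -> HomologyMap:
    """PHA 'painted' with its own probes: each probe on its own chromosome."""
    chroms = pha_karyotype.autosome_pairs + (pha_karyotype.sex_system[0],)
    return HomologyMap(
        "PHA", "PHA", tuple(PaintSignal(probe=c.label, target=c.label) for c in chroms)
    )


@pytest.fixture(scope="session")
def study_tree() -> PhyloTree:
    return PhyloTree.from_newick(STUDY_NEWICK)


@pytest.fixture()
def outgroup() -> list[str]:
    return list(OUTGROUP)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def tree_edges(tree: PhyloTree) -> list[tuple[int, int]]:
    out = []
    for u, nbrs in tree.adj.items():
        for v in nbrs:
            if u < v:
                out.append((u, v))
    return out


def brute_force_char_steps(tree: PhyloTree, matrix: CharacterMatrix, j: int) -> int:
    """Minimum changes for character j by enumerating every labeling."""
    edges = tree_edges(tree)
    row = {t: i for i, t in enumerate(matrix.taxa)}
    fixed: dict[int, str] = {}
    free: list[int] = []
    for node in tree.adj:
        if node < tree.n_leaves:
            s = matrix.states[row[tree.labels[node]], j]
            if s == "?":
                free.append(node)
            else:
                fixed[node] = s
        else:
            free.append(node)
    best = None
    for combo in itertools.product("01", repeat=len(free)):
        lab = dict(fixed)
        lab.update(zip(free, combo))
        changes = sum(1 for u, v in edges if lab[u] != lab[v])
        if best is None or changes < best:
            best = changes
    return best


def brute_force_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    return sum(brute_force_char_steps(tree, matrix, j) for j in range(matrix.n_characters))


def brute_force_mpr(tree: PhyloTree, matrix: CharacterMatrix, j: int) -> dict[int, set[str]]:
    """States each node takes in at least one minimum-change labeling."""
    edges = tree_edges(tree)
    row = {t: i for i, t in enumerate(matrix.taxa)}
    fixed: dict[int, str] = {}
    free: list[int] = []
    for node in tree.adj:
        if node < tree.n_leaves and matrix.states[row[tree.labels[node]], j] != "?":
            fixed[node] = matrix.states[row[tree.labels[node]], j]
        else:
            free.append(node)
    scored: list[tuple[int, dict[int, str]]] = []
    for combo in itertools.product("01", repeat=len(free)):
        lab = dict(fixed)
        lab.update(zip(free, combo))
        scored.append((sum(1 for u, v in edges if lab[u] != lab[v]), lab))
    best = min(s for s, _ in scored)
    out: dict[int, set[str]] = {n: set() for n in tree.adj}
    for s, lab in scored:
        if s == best:
            for n, st in lab.items():
                out[n].add(st)
    return out
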