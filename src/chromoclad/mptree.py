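"""Unrooted binary topologies, Fitch parsimony, and exhaustive MP search.

The number of distinct unrooted binary topologies on *n* labelled leaves is
(2n−5)!!, i.e. 3, 15, 105, 945, 10395 ... for n = 4, 5, 6, 7, 8.  At the
scale of chromosome-painting datasets (here 7 taxa, 945 topologies) the tree
space can be enumerated outright, so the maximum-parsimony tree set, the
consistency index, bootstrap proportions and Bremer decay indices are all
exact — no heuristic search is involved.

Fitch's algorithm computes, for one binary character, the minimum number of
state changes on a tree: a postorder pass assigns each internal node the
intersection of its children's state sets when non-empty (else the union,
counting one step).  Missing data '?' enters as the full state set {0,1} and
can never add a step.  The pass is vectorized over characters, and the result
is independent of the rooting used for the traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
import numpy as np

from .charcoding import CharacterMatrix

__all__ = [
    "PhyloTree",
    "TreeSearchResult",
    "n_unrooted_topologies",
    "canonical_bipartition",
    "enumerate_topologies",
    "fitch_steps",
    "fitch_length",
    "fitch_steps_matrix",
    "exhaustive_search",
    "consistency_index",
    "MAX_EXHAUSTIVE_TAXA",
]

#: hard cap for exhaustive enumeration: (2·12−5)!! ≈ 13.7 million topologies
MAX_EXHAUSTIVE_TAXA = 12

_CODE = {"0": 1, "1": 2, "?": 3}


class PhyloTree:
    """A binary tree topology over labelled leaves.

    Leaves are nodes ``0..n-1`` carrying ``labels``; internal nodes have
    degree 3 (unrooted) except for an optional degree-2 root.  ``support``
    maps bipartitions (frozensets of leaf labels, see :meth:`bipartitions`)
    to annotation strings written as internal-node labels in newick output.
    """

    def __init__(
        self,
        labels: Sequence[str],
        adj: dict[int, tuple[int, ...]],
        root: int | None = None,
        support: dict[frozenset[str], str] | None = None,
    ) -> None:
        self.labels = list(labels)
        self.adj = {k: tuple(v) for k, v in adj.items()}
        self.root = root
        self.support = dict(support or {})
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate leaf labels")
        for node, nbrs in self.adj.items():
            deg = len(nbrs)
            if node < len(self.labels):
                if deg != 1:
                    raise ValueError(f"leaf {node} has degree {deg}")
            elif node == root:
                if deg < 2:
                    raise ValueError(f"root {node} must have degree >= 2, has {deg}")
            elif deg < 3:
                # search trees are strictly binary (degree 3); consensus
                # summaries may carry polytomies (degree > 3) but never
                # degree-2 internal nodes
                raise ValueError(f"internal node {node} has degree {deg} < 3")

    # -- basic structure ---------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def is_rooted(self) -> bool:
        return self.root is not None

    def _ref_label(self) -> str:
        return min(self.labels)

    def _side(self, child: int, parent: int) -> frozenset[str]:
        """Leaf labels on the ``child`` side of edge (parent, child)."""
        out: list[str] = []
        stack = [(child, parent)]
        while stack:
            node, par = stack.pop()
            if node < self.n_leaves:
                out.append(self.labels[node])
            for nbr in self.adj[node]:
                if nbr != par:
                    stack.append((nbr, node))
        return frozenset(out)

    def bipartitions(self, include_trivial: bool = False) -> frozenset[frozenset[str]]:
        """Canonical bipartitions: each edge's leaf side *not* containing the
        lexicographically smallest label.  Internal edges only by default."""
        ref = self._ref_label()
        all_labels = frozenset(self.labels)
        out: set[frozenset[str]] = set()
        seen: set[tuple[int, int]] = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                if self.root is not None and self.root in (u, v):
                    # the two root edges describe the same bipartition as the
                    # suppressed root edge; handled once via the non-root side
                    pass
                side = self._side(v, u)
                if ref in side:
                    side = all_labels - side
                if not include_trivial and not (2 <= len(side) <= self.n_leaves - 2):
                    continue
                if not side or side == all_labels:
                    continue
                out.add(side)
        return frozenset(out)

    def clade_leafsets(self) -> frozenset[frozenset[str]]:
        """For a rooted tree: the leaf set below every internal node (excluding
        the root's full set and trivial single leaves)."""
        if self.root is None:
            raise ValueError("clades require a rooted tree")
        out: set[frozenset[str]] = set()

        def walk(node: int, parent: int) -> frozenset[str]:
            if node < self.n_leaves:
                return frozenset([self.labels[node]])
            below: set[str] = set()
            for nbr in self.adj[node]:
                if nbr != parent:
                    below |= walk(nbr, node)
            fs = frozenset(below)
            if node != self.root and len(fs) >= 2:
                out.add(fs)
            return fs

        walk(self.root, -1)
        return frozenset(out)

    # -- construction ------------------------------------------------------
    def copy(self, support: dict[frozenset[str], str] | None = None) -> "PhyloTree":
        return PhyloTree(self.labels, self.adj, self.root, support if support is not None else self.support)

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = False) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = [lf for lf in dtree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
        ids: dict[int, int] = {id(lf): i for i, lf in enumerate(leaves)}
        nxt = len(labels)
        adj: dict[int, list[int]] = {}

        def get_id(node) -> int:
            nonlocal nxt
            if id(node) not in ids:
                ids[id(node)] = nxt
                nxt += 1
            return ids[id(node)]

        for node in dtree.preorder_node_iter():
            get_id(node)
        for node in dtree.preorder_node_iter():
            for child in node.child_nodes():
                adj.setdefault(get_id(node), []).append(get_id(child))
                adj.setdefault(get_id(child), []).append(get_id(node))
        seed = get_id(dtree.seed_node)
        root: int | None = None
        if rooted:
            if len(adj[seed]) != 2:
                raise ValueError("rooted newick must have a bifurcating root")
            root = seed
        elif len(adj.get(seed, ())) == 2:  # suppress degree-2 root
            a, b = adj[seed]
            adj[a] = [x for x in adj[a] if x != seed] + [b]
            adj[b] = [x for x in adj[b] if x != seed] + [a]
            del adj[seed]
        return cls(labels, {k: tuple(v) for k, v in adj.items()}, root=root)

    def unrooted(self) -> "PhyloTree":
        """Suppress the root (if any) and return the unrooted topology."""
        if self.root is None:
            return self.copy()
        adj = {k: list(v) for k, v in self.adj.items()}
        a, b = adj[self.root]
        adj[a] = [x for x in adj[a] if x != self.root] + [b]
        adj[b] = [x for x in adj[b] if x != self.root] + [a]
        del adj[self.root]
        return PhyloTree(self.labels, {k: tuple(v) for k, v in adj.items()}, root=None, support=self.support)

    # -- serialization -----------------------------------------------------
    def _newick_below(self, node: int, parent: int, annotate: bool) -> str:
        if node < self.n_leaves:
            return self.labels[node]
        parts = sorted(self._newick_below(c, node, annotate) for c in self.adj[node] if c != parent)
        label = ""
        if annotate and self.support:
            side = self._side(node, parent)
            ref = self._ref_label()
            if ref in side:
                side = frozenset(self.labels) - side
            if side in self.support:
                label = str(self.support[side])
        return "(" + ",".join(parts) + ")" + label

    def to_newick(self, annotate: bool = False) -> str:
        """Newick string; rooted trees keep their root, unrooted trees are
        written rooted at the smallest-label leaf's pendant edge (canonical)."""
        if self.root is not None:
            return self._newick_below(self.root, -1, annotate).rstrip() + ";"
        ref_leaf = self.labels.index(self._ref_label())
        (nbr,) = self.adj[ref_leaf]
        return f"({self.labels[ref_leaf]},{self._newick_below(nbr, ref_leaf, annotate)});"

    def canonical_newick(self) -> str:
        """Deterministic topology identity string (unrooted form)."""
        return self.unrooted().to_newick()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        if set(self.labels) != set(other.labels):
            return False
        if (self.root is None) != (other.root is None):
            return False
        if self.root is not None:
            return self.clade_leafsets() == other.clade_leafsets()
        return self.bipartitions() == other.bipartitions()

    def __hash__(self) -> int:
        return hash((frozenset(self.labels), self.bipartitions()))

    def __repr__(self) -> str:
        return f"<PhyloTree {self.to_newick()}>"


def canonical_bipartition(all_labels: Sequence[str], side: Sequence[str]) -> frozenset[str]:
    """Canonical form of a bipartition: the side not containing the smallest
    label.  Use this to look up clades in support dictionaries."""
    side = frozenset(side)
    full = frozenset(all_labels)
    if not side < full:
        raise ValueError("side must be a proper subset of the labels")
    return full - side if min(full) in side else side


def n_unrooted_topologies(n_taxa: int) -> int:
    """(2n−5)!! — the count of distinct unrooted binary topologies."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    out = 1
    for k in range(3, 2 * n_taxa - 4, 2):
        out *= k
    return out


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[PhyloTree]:
    """Yield every distinct unrooted binary topology on ``taxa`` exactly once.

    Stepwise leaf addition: each topology on k leaves spawns one child
    topology per edge (2k−3 edges), which generates each n-leaf topology via
    a unique insertion history.
    """
    taxa = list(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa to enumerate topologies")

    def edges_of(adj: dict[int, tuple[int, ...]]) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in adj.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return out

    def grow(adj: dict[int, tuple[int, ...]], next_leaf: int, next_internal: int) -> Iterator[dict]:
        if next_leaf == n:
            yield adj
            return
        for u, v in edges_of(adj):
            new = dict(adj)
            m = next_internal
            new[u] = tuple(x if x != v else m for x in new[u])
            new[v] = tuple(x if x != u else m for x in new[v])
            new[m] = (u, v, next_leaf)
            new[next_leaf] = (m,)
            yield from grow(new, next_leaf + 1, next_internal + 1)

    base = {0: (n,), 1: (n,), 2: (n,), n: (0, 1, 2)}
    if n == 3:
        yield PhyloTree(taxa, base)
        return
    for adj in grow(base, 3, n + 1):
        yield PhyloTree(taxa, adj)


def _encode(matrix: CharacterMatrix) -> np.ndarray:
    enc = np.zeros(matrix.states.shape, dtype=np.uint8)
    for sym, code in _CODE.items():
        enc[matrix.states == sym] = code
    return enc


def fitch_steps(tree: PhyloTree, matrix: CharacterMatrix) -> np.ndarray:
    """Per-character minimum state changes on ``tree`` (vectorized Fitch pass)."""
    if set(tree.labels) != set(matrix.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    enc = _encode(matrix)
    row = {t: i for i, t in enumerate(matrix.taxa)}
    n_chars = matrix.n_characters
    steps = np.zeros(n_chars, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}

    start = tree.root if tree.root is not None else 0
    order: list[tuple[int, tuple[int, ...]]] = []
    stack: list[tuple[int, int]] = [(start, -1)]
    post: list[tuple[int, int]] = []
    while stack:
        node, parent = stack.pop()
        post.append((node, parent))
        for nbr in tree.adj[node]:
            if nbr != parent:
                stack.append((nbr, node))
    for node, parent in reversed(post):
        children = tuple(x for x in tree.adj[node] if x != parent)
        if node < tree.n_leaves:
            sets[node] = enc[row[tree.labels[node]]]
            # unrooted traversal starts at leaf 0: fold its child subtree in below
        if children:
            order.append((node, children))
            s = sets[children[0]] if node >= tree.n_leaves else None
            if node >= tree.n_leaves:
                for c in children[1:]:
                    inter = s & sets[c]
                    empty = inter == 0
                    steps += empty
                    s = np.where(empty, s | sets[c], inter)
                sets[node] = s
            else:  # start leaf of an unrooted traversal
                inter = sets[node] & sets[children[0]]
                steps += inter == 0
    return steps


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Tree score: total Fitch steps summed over characters."""
    return int(fitch_steps(tree, matrix).sum())


def fitch_steps_matrix(trees: Sequence[PhyloTree], matrix: CharacterMatrix) -> np.ndarray:
    """Stacked per-character step counts, one row per topology."""
    return np.vstack([fitch_steps(t, matrix) for t in trees])


def consistency_index(matrix: CharacterMatrix, length: int, digits: int = 4) -> float:
    """CI = Σ per-character minimum steps / tree length, rounded to ``digits``.

    CI is 1 exactly when the tree is homoplasy-free (every character changes
    the theoretical minimum number of times).
    """
    msum = int(matrix.min_steps().sum())
    if length == 0:
        if msum:
            raise ValueError("length 0 with nonzero minimum steps")
        return 1.0
    if length < msum:
        raise ValueError(f"length {length} below theoretical minimum {msum}")
    return round(msum / length, digits)


@dataclass
class TreeSearchResult:
    """Outcome of an exhaustive maximum-parsimony search."""

    mp_trees: list[PhyloTree]
    length: int
    ci: float
    n_topologies_examined: int
    matrix: CharacterMatrix = field(repr=False, default=None)

    def strict_consensus_bipartitions(self) -> frozenset[frozenset[str]]:
        out = self.mp_trees[0].bipartitions()
        for t in self.mp_trees[1:]:
            out &= t.bipartitions()
        return out


def exhaustive_search(matrix: CharacterMatrix) -> TreeSearchResult:
    """Enumerate every topology and return all attaining the minimum length.

    Refuses more than ``MAX_EXHAUSTIVE_TAXA`` taxa (tree space grows as
    (2n−5)!!; beyond 12 taxa a branch-and-bound strategy would be required).
    MP trees are returned in canonical newick order.
    """
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("exhaustive search needs at least 3 taxa")
    if n > MAX_EXHAUSTIVE_TAXA:
        raise ValueError(
            f"{n} taxa exceeds the exhaustive cap of {MAX_EXHAUSTIVE_TAXA}; "
            "use a branch-and-bound search for larger problems"
        )
    best: list[PhyloTree] = []
    best_len: int | None = None
    examined = 0
    for tree in enumerate_topologies(matrix.taxa):
        examined += 1
        length = fitch_length(tree, matrix)
        if best_len is None or length < best_len:
            best, best_len = [tree], length
        elif length == best_len:
            best.append(tree)
    best.sort(key=lambda t: t.canonical_newick())
    return TreeSearchResult(
        mp_trees=best,
        length=int(best_len),
        ci=consistency_index(matrix, int(best_len)),
        n_topologies_examined=examined,
        matrix=matrix,
    )
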