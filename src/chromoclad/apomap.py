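"""A-posteriori character mapping on the rooted MP tree.

After the unrooted MP tree is rooted on the outgroup (outgroup-method
polarization: no polarity is assumed during coding), every character's most
parsimonious reconstructions are computed and the character is assigned
exactly one category:

* **homoplasy** — the character needs more steps on the tree than its
  theoretical minimum (convergence or reversal);
* **plesiomorphy** — the derived condition (state 1) is already present at
  the ingroup's most recent common ancestor, i.e. shared with the outgroup
  or fixed below the ingroup root;
* **autapomorphy** — a single change on a terminal branch (derived state
  unique to one taxon);
* **synapomorphy** — a single change on an internal branch (shared derived
  state uniting a clade);
* **constant** — no variation at all (minimum steps 0).

The precedence homoplasy > plesiomorphy > autapomorphy > synapomorphy
partitions the characters; it is configurable because the boundary cases
(e.g. a homoplastic character whose derived state is also ancestral for the
ingroup) admit other conventions.

Where the most parsimonious reconstruction is ambiguous, change placement
follows DELTRAN by default (transformations delayed toward the tips), with
ACCTRAN selectable; both are computed and a disagreement flag is raised when
the category depends on the choice.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .charcoding import CharacterMatrix
from .mptree import PhyloTree, fitch_steps

__all__ = [
    "CharacterMapping",
    "root_on_outgroup",
    "ancestral_states",
    "resolve_states",
    "classify_characters",
    "root_state_report",
    "CATEGORIES",
]

CATEGORIES = ("autapomorphy", "synapomorphy", "plesiomorphy", "homoplasy", "constant")
Optimization = Literal["deltran", "acctran"]


@dataclass
class CharacterMapping:
    """Per-character summary of its fit on the rooted MP tree."""

    character_id: str
    steps: int
    min_steps: int
    change_branches: list[str]
    category: str
    optimization_dependent: bool = False  # category differs under ACCTRAN vs DELTRAN

    def __post_init__(self) -> None:
        if self.steps < self.min_steps:
            raise ValueError("steps below theoretical minimum")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def root_on_outgroup(tree: PhyloTree, outgroup: Sequence[str]) -> PhyloTree:
    """Place the root on the branch separating ``outgroup`` from the ingroup.

    Requires the outgroup to be monophyletic (or a single taxon) in the
    unrooted topology; an outgroup interdigitated with the ingroup cannot be
    separated by one edge and is an error.
    """
    tree = tree.unrooted()
    og = frozenset(outgroup)
    missing = og - set(tree.labels)
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    if not og or og == set(tree.labels):
        raise ValueError("outgroup must be a non-empty proper subset of the taxa")
    target = None
    seen: set[tuple[int, int]] = set()
    for u, nbrs in tree.adj.items():
        for v in nbrs:
            if (v, u) in seen:
                continue
            seen.add((u, v))
            side = tree._side(v, u)
            if side == og:
                target = (u, v)
            elif side == frozenset(tree.labels) - og:
                target = (v, u)
    if target is None:
        raise ValueError(
            f"outgroup {sorted(og)} is not separable from the ingroup by a single edge"
        )
    u, v = target  # v = outgroup-side endpoint
    adj = {k: list(nbrs) for k, nbrs in tree.adj.items()}
    root = max(adj) + 1
    adj[u] = [x if x != v else root for x in adj[u]]
    adj[v] = [x if x != u else root for x in adj[v]]
    adj[root] = [v, u]  # outgroup side first, ingroup side second
    return PhyloTree(tree.labels, {k: tuple(x) for k, x in adj.items()}, root=root, support=tree.support)


def _children(tree: PhyloTree, node: int, parent: int) -> tuple[int, ...]:
    return tuple(x for x in tree.adj[node] if x != parent)


def _orders(tree: PhyloTree) -> tuple[list[tuple[int, int]], dict[int, int]]:
    """(preorder list of (node, parent), depth per node) from the root."""
    if tree.root is None:
        raise ValueError("rooted tree required")
    pre: list[tuple[int, int]] = []
    depth = {tree.root: 0}
    stack = [(tree.root, -1)]
    while stack:
        node, parent = stack.pop()
        pre.append((node, parent))
        for c in _children(tree, node, parent):
            depth[c] = depth[node] + 1
            stack.append((c, node))
    return pre, depth


_INF = 10**9


def ancestral_states(
    tree: PhyloTree, matrix: CharacterMatrix
) -> list[dict[int, frozenset[str]]]:
    """Most-parsimonious-reconstruction state sets per node, per character.

    Exact unit-cost dynamic programming: an upward pass computes, per node
    and state, the minimum changes in the subtree below; a downward pass the
    minimum in the rest of the tree.  A state belongs to a node's MPR set iff
    the two costs sum to the character's minimum.  (The classic Fitch second
    pass can overstate MPR sets when leaves carry '?'; the cost decomposition
    has no such blind spot.)  Leaves scored '?' carry the full set {0, 1}.
    """
    if tree.root is None:
        raise ValueError("rooted tree required")
    if set(tree.labels) != set(matrix.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    pre, _ = _orders(tree)
    row = {t: i for i, t in enumerate(matrix.taxa)}
    states = ("0", "1")
    out: list[dict[int, frozenset[str]]] = []
    for j in range(matrix.n_characters):
        obs = {
            i: ({"0", "1"} if matrix.states[row[tree.labels[i]], j] == "?" else {matrix.states[row[tree.labels[i]], j]})
            for i in range(tree.n_leaves)
        }
        up: dict[int, dict[str, int]] = {}
        for node, parent in reversed(pre):
            if node < tree.n_leaves:
                up[node] = {s: (0 if s in obs[node] else _INF) for s in states}
                continue
            up[node] = {
                s: sum(
                    min(up[c][t] + (s != t) for t in states)
                    for c in _children(tree, node, parent)
                )
                for s in states
            }
        down: dict[int, dict[str, int]] = {tree.root: {s: 0 for s in states}}
        for node, parent in pre:
            for child in _children(tree, node, parent):
                siblings = [c for c in _children(tree, node, parent) if c != child]
                down[child] = {
                    s: min(
                        (s != t)
                        + down[node][t]
                        + sum(min(up[w][r] + (t != r) for r in states) for w in siblings)
                        for t in states
                    )
                    for s in states
                }
        total = min(up[tree.root].values())
        mpr = {
            node: frozenset(s for s in states if up[node][s] + down[node][s] == total)
            for node in up
        }
        out.append(mpr)
    return out


def resolve_states(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    mode: Optimization = "deltran",
) -> list[dict[int, str]]:
    """One concrete most parsimonious labeling per character.

    Among all MP labelings (enumerated exactly over the ambiguous nodes),
    DELTRAN picks the one pushing changes closest to the tips (maximum summed
    depth of change edges), ACCTRAN the one pulling them toward the root
    (minimum summed depth); remaining ties break on the lexicographically
    smallest state vector, so the output is deterministic.
    """
    if mode not in ("deltran", "acctran"):
        raise ValueError(f"unknown optimization mode {mode!r}")
    mprs = ancestral_states(tree, matrix)
    steps_per_char = fitch_steps(tree, matrix)
    pre, depth = _orders(tree)
    nodes = [n for n, _ in pre]
    parent_of = {n: p for n, p in pre}
    out: list[dict[int, str]] = []
    for j, mpr in enumerate(mprs):
        ambiguous = [n for n in nodes if len(mpr[n]) > 1]
        fixed = {n: next(iter(mpr[n])) for n in nodes if len(mpr[n]) == 1}
        best_key: tuple | None = None
        best: dict[int, str] | None = None
        for combo in itertools.product("01", repeat=len(ambiguous)):
            lab = dict(fixed)
            lab.update(zip(ambiguous, combo))
            changes = [n for n in nodes if parent_of[n] != -1 and lab[n] != lab[parent_of[n]]]
            if len(changes) != int(steps_per_char[j]):
                continue
            chdepth = sum(depth[n] for n in changes)
            # DELTRAN: maximize change depth; ACCTRAN: minimize it
            primary = -chdepth if mode == "deltran" else chdepth
            key = (primary, tuple(lab[n] for n in nodes))
            if best_key is None or key < best_key:
                best_key, best = key, lab
        assert best is not None, "no labeling matched the Fitch step count"
        out.append(best)
    return out


def _branch_name(tree: PhyloTree, child: int) -> str:
    """A branch is named by what hangs below it: the leaf, or the clade members."""
    if child < tree.n_leaves:
        return tree.labels[child]
    return "+".join(_leaves_below(tree, child))


def _leaves_below(tree: PhyloTree, node: int) -> list[str]:
    pre, _ = _orders(tree)
    parent_of = {n: p for n, p in pre}
    out: list[str] = []
    stack = [node]
    while stack:
        x = stack.pop()
        if x < tree.n_leaves:
            out.append(tree.labels[x])
        else:
            stack.extend(_children(tree, x, parent_of[x]))
    return sorted(out)


def _ingroup_root(tree: PhyloTree, outgroup: Sequence[str]) -> int:
    og = frozenset(outgroup)
    a, b = _children(tree, tree.root, -1)
    below_a = frozenset(_leaves_below(tree, a))
    if below_a == og:
        return b
    if frozenset(_leaves_below(tree, b)) == og:
        return a
    raise ValueError("root does not separate the given outgroup from the ingroup")


def classify_characters(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    outgroup: Sequence[str],
    mode: Optimization = "deltran",
    precedence: Sequence[str] = ("homoplasy", "plesiomorphy", "autapomorphy", "synapomorphy"),
    plesiomorphy_at: Literal["root", "ingroup_mrca"] = "root",
) -> tuple[list[CharacterMapping], Counter]:
    """Assign every character one apomorphy category on the rooted tree.

    Rules, applied in ``precedence`` order after the unconditional *constant*
    (min steps 0) test: homoplasy — steps exceed the minimum; plesiomorphy —
    derived state 1 resolved at the root, i.e. already present in the common
    ancestor shared with the outgroup (``plesiomorphy_at='ingroup_mrca'``
    moves the test to the ingroup's MRCA, which additionally absorbs changes
    on the ingroup stem); autapomorphy — single change on a terminal branch;
    synapomorphy — single change on an internal branch.  Returns the mappings
    plus category counts (which sum to the number of characters).
    """
    if set(precedence) != set(CATEGORIES) - {"constant"}:
        raise ValueError("precedence must order the four non-constant categories")
    steps = fitch_steps(tree, matrix)
    min_steps = matrix.min_steps()
    pre, _ = _orders(tree)
    parent_of = {n: p for n, p in pre}
    ig_root = _ingroup_root(tree, outgroup) if plesiomorphy_at == "ingroup_mrca" else tree.root

    def categorize(lab: dict[int, str], j: int) -> tuple[str, list[str]]:
        changes = [n for n, p in parent_of.items() if p != -1 and lab[n] != lab[p]]
        branches = [_branch_name(tree, n) for n in sorted(changes)]
        for cat in precedence:
            if cat == "homoplasy" and steps[j] > min_steps[j]:
                return "homoplasy", branches
            if cat == "plesiomorphy" and lab[ig_root] == "1":
                return "plesiomorphy", branches
            if cat == "autapomorphy" and len(changes) == 1 and changes[0] < tree.n_leaves:
                return "autapomorphy", branches
            if cat == "synapomorphy" and len(changes) >= 1:
                return "synapomorphy", branches
        # no change below the root at all (e.g. state fixed by '?' leaves)
        return "plesiomorphy" if lab[ig_root] == "1" else "synapomorphy", branches

    primary = resolve_states(tree, matrix, mode=mode)
    alternate = resolve_states(tree, matrix, mode="acctran" if mode == "deltran" else "deltran")
    mappings: list[CharacterMapping] = []
    counts: Counter = Counter()
    for j, cdef in enumerate(matrix.characters):
        if min_steps[j] == 0:
            cat, branches, flag = "constant", [], False
        else:
            cat, branches = categorize(primary[j], j)
            alt_cat, _ = categorize(alternate[j], j)
            flag = alt_cat != cat
        mappings.append(
            CharacterMapping(
                character_id=cdef.id,
                steps=int(steps[j]),
                min_steps=int(min_steps[j]),
                change_branches=branches,
                category=cat,
                optimization_dependent=flag,
            )
        )
        counts[cat] += 1
    return mappings, counts


def root_state_report(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    outgroup: Sequence[str],
    mode: Optimization = "deltran",
) -> dict:
    """Characters inferred in the derived state at the ingroup root, and the
    reference units conserved in toto there.

    The root set is the artifact's counterpart of an ancestral-karyotype
    statement: every synteny character with state 1 at the ingroup's MRCA is
    a rearrangement already present in the ancestor; reference units touched
    by none of them are ancestrally conserved in toto.
    """
    resolved = resolve_states(tree, matrix, mode=mode)
    ig_root = _ingroup_root(tree, outgroup)
    root_chars = [
        matrix.characters[j].id for j in range(matrix.n_characters) if resolved[j][ig_root] == "1"
    ]
    all_units: set[str] = set()
    derived_units: set[str] = set()
    for j, cdef in enumerate(matrix.characters):
        all_units |= cdef.reference_units
        if resolved[j][ig_root] == "1":
            derived_units |= cdef.reference_units
    return {
        "root_state_1_characters": sorted(root_chars),
        "conserved_units": sorted(all_units - derived_units),
        "rearranged_units": sorted(derived_units),
    }
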