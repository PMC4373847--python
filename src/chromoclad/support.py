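"""Clade support: nonparametric bootstrap and Bremer decay indices.

Bootstrap: characters are resampled with replacement to the original count;
each replicate is solved by *exact* exhaustive search and every MP tree of the
replicate contributes its bipartitions, fractionally (1/ties) when several
trees tie.  Because a replicate differs from the original matrix only in its
column multiplicities, replicate tree lengths are obtained as a dot product
between the precomputed per-topology × per-character Fitch step matrix and
the resample weights — algebraically identical to re-running the search on
the resampled matrix, at a fraction of the cost.

Bremer (decay) index of a clade: the extra steps demanded by the best tree
that does *not* contain the clade.  With the full topology set enumerated it
is computed exactly, with no reverse-constraint heuristics.  Bremer values
are deterministic given the matrix; only the bootstrap consumes the seed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charcoding import CharacterMatrix
from .mptree import (
    PhyloTree,
    TreeSearchResult,
    enumerate_topologies,
    fitch_steps_matrix,
)

__all__ = [
    "CladeSupport",
    "bootstrap_support",
    "bipartition_frequencies",
    "majority_rule_consensus",
    "bremer_support",
    "support_table",
]

DEFAULT_BOOTSTRAP_REPS = 2000  #: replicate count used throughout


@dataclass(frozen=True)
class CladeSupport:
    clade: frozenset[str]
    bootstrap_pct: float | None = None
    bremer: int | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_pct is not None and not (0.0 <= self.bootstrap_pct <= 100.0):
            raise ValueError("bootstrap percentage outside [0, 100]")
        if self.bremer is not None and self.bremer < 0:
            raise ValueError("Bremer support cannot be negative")


def bootstrap_support(
    matrix: CharacterMatrix,
    n_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Bootstrap percentage per clade (bipartition), over ``n_reps`` replicates.

    Reproducible for a given seed.  Clades never seen in any replicate's MP
    trees are absent from the result (support 0).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if matrix.n_taxa < 4:
        raise ValueError("bootstrap needs at least 4 taxa")
    topologies = list(enumerate_topologies(matrix.taxa))
    steps = fitch_steps_matrix(topologies, matrix)  # (n_topologies, n_characters)
    biparts = [t.bipartitions() for t in topologies]
    rng = np.random.default_rng(seed)
    n_chars = matrix.n_characters
    tally: dict[frozenset[str], float] = defaultdict(float)
    for _ in range(n_reps):
        weights = np.bincount(rng.integers(0, n_chars, size=n_chars), minlength=n_chars)
        lengths = steps @ weights
        winners = np.flatnonzero(lengths == lengths.min())
        frac = 1.0 / len(winners)
        for ti in winners:
            for bp in biparts[ti]:
                tally[bp] += frac
    return {bp: 100.0 * v / n_reps for bp, v in tally.items()}


def bipartition_frequencies(trees: list[PhyloTree]) -> dict[frozenset[str], float]:
    """Fraction of ``trees`` containing each internal bipartition."""
    if not trees:
        raise ValueError("no trees")
    leafset = set(trees[0].labels)
    for t in trees[1:]:
        if set(t.labels) != leafset:
            raise ValueError("trees have mismatched leaf sets")
    counts: Counter[frozenset[str]] = Counter()
    for t in trees:
        counts.update(t.bipartitions())
    return {bp: c / len(trees) for bp, c in counts.items()}


def majority_rule_consensus(trees: list[PhyloTree], threshold: float = 0.5) -> PhyloTree:
    """Consensus tree of all bipartitions with frequency > ``threshold``.

    For threshold ≥ 0.5 the retained set is guaranteed compatible.  Retained
    bipartitions are annotated with their percentage frequency; unresolved
    regions appear as polytomies (a star tree in the extreme).
    """
    if threshold < 0.5:
        raise ValueError("threshold below 0.5 does not guarantee a compatible set")
    freqs = bipartition_frequencies(trees)
    kept = {bp: f for bp, f in freqs.items() if f > threshold}
    labels = list(trees[0].labels)
    ref = min(labels)
    n = len(labels)
    leaf_id = {lab: i for i, lab in enumerate(labels)}

    # nest clusters (all exclude ref, so they form a laminar family)
    clusters = sorted(kept, key=len)
    parent_of: dict[int, int | frozenset[str]] = {}
    cluster_parent: dict[frozenset[str], frozenset[str] | None] = {}
    for i, c in enumerate(clusters):
        cluster_parent[c] = next((d for d in clusters[i + 1 :] if c < d), None)
    for lab in labels:
        if lab == ref:
            continue
        owner = next((c for c in clusters if lab in c), None)
        parent_of[leaf_id[lab]] = owner if owner is not None else None

    adj: dict[int, list[int]] = defaultdict(list)
    next_id = n
    cluster_id: dict[frozenset[str], int] = {}
    for c in clusters:
        cluster_id[c] = next_id
        next_id += 1
    root = next_id
    adj[root].append(leaf_id[ref])
    adj[leaf_id[ref]].append(root)
    for lab in labels:
        if lab == ref:
            continue
        owner = parent_of[leaf_id[lab]]
        up = cluster_id[owner] if owner is not None else root
        adj[up].append(leaf_id[lab])
        adj[leaf_id[lab]].append(up)
    for c in clusters:
        par = cluster_parent[c]
        up = cluster_id[par] if par is not None else root
        adj[up].append(cluster_id[c])
        adj[cluster_id[c]].append(up)
    # suppress a degree-2 root (fully resolved top level)
    if len(adj[root]) == 2:
        a, b = adj[root]
        adj[a] = [x for x in adj[a] if x != root] + [b]
        adj[b] = [x for x in adj[b] if x != root] + [a]
        del adj[root]
    support = {bp: f"{100.0 * f:.1f}" for bp, f in kept.items()}
    return PhyloTree(labels, {k: tuple(v) for k, v in adj.items()}, root=None, support=support)


def bremer_support(matrix: CharacterMatrix, result: TreeSearchResult) -> dict[frozenset[str], int]:
    """Decay index for every clade of the strict consensus of the MP trees.

    bremer(clade) = min length over enumerated topologies lacking the clade,
    minus the MP length.  A clade absent from some MP tree would decay at no
    cost; only strict-consensus clades (present in all MP trees) are scored.
    """
    topologies = list(enumerate_topologies(matrix.taxa))
    lengths = fitch_steps_matrix(topologies, matrix).sum(axis=1)
    clades = result.strict_consensus_bipartitions()
    out: dict[frozenset[str], int] = {}
    for clade in clades:
        without = [
            int(lengths[i]) for i, t in enumerate(topologies) if clade not in t.bipartitions()
        ]
        if not without:
            raise ValueError(f"every topology contains clade {sorted(clade)}")
        out[clade] = min(without) - result.length
    return out


def support_table(
    bootstrap: dict[frozenset[str], float] | None = None,
    bremer: dict[frozenset[str], int] | None = None,
    clades: list[frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Tabulate support values (one row per clade, members comma-joined)."""
    if clades is None:
        clades = sorted(
            set(bootstrap or {}) | set(bremer or {}), key=lambda c: (-len(c), sorted(c))
        )
    rows = []
    for clade in clades:
        rows.append(
            {
                "clade": ",".join(sorted(clade)),
                "bootstrap_pct": None if bootstrap is None else round(bootstrap.get(clade, 0.0), 2),
                "bremer": None if bremer is None else bremer.get(clade),
            }
        )
    return pd.DataFrame(rows, columns=["clade", "bootstrap_pct", "bremer"])
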