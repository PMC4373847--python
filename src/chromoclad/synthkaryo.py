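"""Karyotype-evolution simulator: rearrangements along a known tree.

An ancestral complement of conserved units (one chromosome per unit, playing
the role of the reference species' complement) evolves along a rooted tree
with branch lengths.  Per branch, event counts are drawn per type from a
Poisson distribution with mean rate × branch length; events are:

* **fusion** — two chromosomes joined end to end (creates syntenic
  associations between their units);
* **fission** — a chromosome split at a boundary between units (creates a
  syntenic disruption); with ``allow_unit_internal_fission`` a break may fall
  inside a unit, splitting it into two fragments (which can later end up as
  discontiguous blocks on one chromosome — the pattern painting reports as
  n_blocks > 1);
* **reciprocal_translocation** — terminal blocks exchanged between two
  chromosomes;
* **inversion** — painting-invisible; recorded as a structural binary
  character scored 1 for every tip descending from the branch.

Genomic content is conserved: no gain or loss events, so every unit's
material is present exactly once in every tip complement.  Tips are then
"painted" with probes for the ancestral units, yielding exactly the
homology-map tables the pipeline consumes, and the true binary matrix is
produced by running the character coder on those maps — the generator and
the coder cannot drift apart.  The event log, replayed deterministically,
reproduces every tip complement bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import karyomap
from .charcoding import (
    CharacterMatrix,
    derive_association_characters,
    derive_disruption_characters,
    merge_structural_characters,
)
from .karyomap import Chromosome, HomologyMap, Karyotype, Morphology, PaintSignal
from .mptree import PhyloTree

__all__ = [
    "SimConfig",
    "Event",
    "EventLog",
    "SimResult",
    "DEFAULT_RATES",
    "phyllostomini_like_tree",
    "ancestral_karyotype",
    "simulate",
    "replay",
    "true_tree_is_mp",
    "internal_edges_covered",
]

#: Expected events per unit branch length.  With unit-length branches this
#: gives ≈ 4–5 events per branch, i.e. ≈ 55 changes over a 7-taxon tree —
#: the rearrangement density observed in heavily rearranged bat karyotypes.
DEFAULT_RATES: dict[str, float] = {
    "fusion": 2.0,
    "fission": 1.5,
    "reciprocal_translocation": 0.5,
    "inversion": 0.5,
}

EVENT_TYPES = tuple(DEFAULT_RATES)

#: A 7-taxon study-shaped tree: a 4-taxon ingroup with one early-branching
#: genus and two sister species, plus a 3-taxon outgroup clade.
def phyllostomini_like_tree(taxa: Sequence[str] = ("PHA", "PDI", "LSI", "TSA", "DEC", "DRO", "DYO")) -> str:
    a, b, c, d, e, f, g = taxa
    return f"(((({a}:1,{b}:1):1,{c}:1):1,{d}:1):1,({e}:1,({f}:1,{g}:1):1):1);"


@dataclass(frozen=True)
class SimConfig:
    tree: str  #: rooted newick with branch lengths
    ancestral_units: int = 16
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    seed: int = 0
    allow_unit_internal_fission: bool = False
    species_prefix: str = "ANC"  #: probe-label prefix for the ancestral units

    def __post_init__(self) -> None:
        if self.ancestral_units < 2:
            raise ValueError("need at least 2 ancestral units")
        bad = set(self.rates) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types: {sorted(bad)}")
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class Event:
    branch: str  #: label of the child node below the branch
    etype: str
    operands: tuple[int, ...]


@dataclass
class EventLog:
    tree: str  #: the rooted newick the events hang on
    ancestral_units: int
    events: list[Event]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"branch": e.branch, "event": e.etype, "operands": ",".join(map(str, e.operands))}
                for e in self.events
            ],
            columns=["branch", "event", "operands"],
        )


Complement = tuple[tuple[tuple[int, int], ...], ...]  # chromosomes -> parts -> (unit, fragment)


@dataclass
class SimResult:
    config: SimConfig
    maps: dict[str, HomologyMap]
    annotations: pd.DataFrame
    matrix: CharacterMatrix
    log: EventLog
    true_tree: PhyloTree  #: rooted true topology
    tip_complements: dict[str, Complement]
    reference: Karyotype

    def write(self, outdir: str | Path) -> None:
        """Emit the same TSV/NEXUS formats the pipeline consumes, plus truth files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tip, hmap in self.maps.items():
            karyomap.write_homology_map(hmap, outdir / f"{tip.lower()}_{self.config.species_prefix.lower()}.tsv")
        self.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        self.matrix.to_tsv(outdir / "matrix.tsv")
        self.matrix.to_nexus(outdir / "matrix.nex")
        (outdir / "true_tree.nwk").write_text(self.true_tree.to_newick() + "\n", encoding="utf-8")
        self.log.to_frame().to_csv(outdir / "events.tsv", sep="\t", index=False)


def ancestral_karyotype(n_units: int, prefix: str = "ANC") -> Karyotype:
    """Reference complement used to 'paint' simulated tips: one bi-armed
    chromosome per conserved unit plus a sex pair."""
    karyomap.register_species(prefix)
    autosomes = tuple(
        Chromosome(label=f"{prefix}-{u}", morphology=Morphology.BI_ARMED) for u in range(1, n_units + 1)
    )
    sex = (
        Chromosome(f"{prefix}-X", Morphology.BI_ARMED, is_sex=True),
        Chromosome(f"{prefix}-Y", Morphology.ACROCENTRIC, is_sex=True),
    )
    return Karyotype(
        species_code=prefix,
        diploid_number=2 * n_units + 2,
        fundamental_number=4 * n_units,
        autosome_pairs=autosomes,
        sex_system=sex,
    )


# ---------------------------------------------------------------------------
# event mechanics (shared by simulate and replay)
# ---------------------------------------------------------------------------


def _apply_event(complement: list[list[tuple[int, int]]], event: Event, frag_counter: dict[int, int]) -> None:
    """Apply one event in place.  Operands fully determine the outcome, so a
    replayed log reproduces complements exactly."""
    et, ops = event.etype, event.operands
    if et == "fusion":
        i, j = ops
        merged = complement[i] + complement[j]
        for k in sorted((i, j), reverse=True):
            del complement[k]
        complement.append(merged)
    elif et == "fission":
        i, cut = ops
        chrom = complement[i]
        left, right = chrom[:cut], chrom[cut:]
        if not left or not right:
            raise ValueError(f"invalid fission cut {cut} on chromosome of {len(chrom)} parts")
        del complement[i]
        complement.extend([left, right])
    elif et == "unit_internal_fission":
        i, pi = ops
        chrom = complement[i]
        unit, _ = chrom[pi]
        f1 = frag_counter[unit] = frag_counter.get(unit, 0) + 1
        f2 = frag_counter[unit] = frag_counter[unit] + 1
        left = chrom[:pi] + [(unit, f1)]
        right = [(unit, f2)] + chrom[pi + 1 :]
        del complement[i]
        complement.extend([left, right])
    elif et == "reciprocal_translocation":
        i, j, ci, cj = ops
        a, b = complement[i], complement[j]
        na, nb = a[:ci] + b[cj:], b[:cj] + a[ci:]
        if not na or not nb:
            raise ValueError("translocation would create an empty chromosome")
        complement[i], complement[j] = na, nb
    elif et == "inversion":
        (i,) = ops
        complement[i] = complement[i]  # content unchanged: painting-invisible
    else:
        raise ValueError(f"malformed event type {et!r}")


def _sample_event(
    etype: str,
    complement: list[list[tuple[int, int]]],
    rng: np.random.Generator,
    allow_internal: bool,
) -> tuple[str, tuple[int, ...]] | None:
    """Draw valid operands for an event; None when no valid target exists
    (e.g. fission requested on a complement of single-part chromosomes, with
    unit-internal breaks disabled)."""
    n = len(complement)
    if etype == "fusion":
        if n < 2:
            return None
        i, j = map(int, rng.choice(n, size=2, replace=False))
        return etype, (i, j)
    if etype == "inversion":
        return etype, (int(rng.integers(n)),)
    if etype == "fission":
        boundary = [k for k, c in enumerate(complement) if len(c) >= 2]
        use_internal = allow_internal and (not boundary or rng.random() < 0.5)
        if use_internal:
            i = int(rng.integers(n))
            pi = int(rng.integers(len(complement[i])))
            return "unit_internal_fission", (i, pi)
        if not boundary:
            return None
        i = int(boundary[int(rng.integers(len(boundary)))])
        cut = int(rng.integers(1, len(complement[i])))
        return etype, (i, cut)
    if etype == "reciprocal_translocation":
        if n < 2:
            return None
        for _ in range(64):  # resample until the exchange moves material both ways
            i, j = map(int, rng.choice(n, size=2, replace=False))
            ci = int(rng.integers(0, len(complement[i]) + 1))
            cj = int(rng.integers(0, len(complement[j]) + 1))
            a, b = complement[i], complement[j]
            na, nb = a[:ci] + b[cj:], b[:cj] + a[ci:]
            if na and nb and (na, nb) != (a, b) and not (ci == 0 and cj == 0):
                return etype, (i, j, ci, cj)
        return None
    raise ValueError(f"unknown event type {etype!r}")


def _paint(tip: str, complement: Complement, prefix: str) -> HomologyMap:
    """Emit the painting table a probe panel for the ancestral units would
    produce on this complement (one signal per unit per chromosome, counting
    maximal runs of the unit as discontiguous blocks)."""
    karyomap.register_species(tip)
    karyomap.register_species(prefix)
    signals: list[PaintSignal] = []
    for k, chrom in enumerate(complement, start=1):
        target = f"{tip}-{k}"
        runs: dict[int, int] = {}
        prev_unit = None
        for unit, _frag in chrom:
            if unit != prev_unit:
                runs[unit] = runs.get(unit, 0) + 1
            prev_unit = unit
        for unit in sorted(runs):
            signals.append(PaintSignal(probe=f"{prefix}-{unit}", target=target, n_blocks=runs[unit]))
    return HomologyMap(target_species=tip, probe_species=prefix, signals=tuple(signals))


def _node_name(node, counter: list[int]) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    counter[0] += 1
    node.label = f"N{counter[0]}"
    return node.label


def simulate(config: SimConfig) -> SimResult:
    """Run the simulation; deterministic for a given config (seed included)."""
    rng = np.random.default_rng(config.seed)
    dtree = dendropy.Tree.get(data=config.tree, schema="newick")
    counter = [0]
    for node in dtree.preorder_node_iter():
        _node_name(node, counter)

    ancestral: list[list[tuple[int, int]]] = [[(u, 0)] for u in range(1, config.ancestral_units + 1)]
    complements: dict[str, list[list[tuple[int, int]]]] = {}
    frag_counter: dict[int, int] = {}
    events: list[Event] = []
    inversion_chars: list[tuple[str, str]] = []  # (character_id, branch)

    for node in dtree.preorder_node_iter():
        name = _node_name(node, counter)
        if node.parent_node is None:
            complements[name] = [list(c) for c in ancestral]
            continue
        parent = _node_name(node.parent_node, counter)
        comp = [list(c) for c in complements[parent]]
        blen = node.edge.length if node.edge.length is not None else 1.0
        drawn: list[str] = []
        for etype in EVENT_TYPES:
            rate = config.rates.get(etype, 0.0)
            drawn.extend([etype] * int(rng.poisson(rate * blen)))
        order = rng.permutation(len(drawn))
        inv_k = 0
        for idx in order:
            sampled = _sample_event(drawn[int(idx)], comp, rng, config.allow_unit_internal_fission)
            if sampled is None:
                continue
            etype, ops = sampled
            ev = Event(branch=name, etype=etype, operands=tuple(ops))
            _apply_event(comp, ev, frag_counter)
            events.append(ev)
            if ev.etype == "inversion":
                inv_k += 1
                inversion_chars.append((f"inv:{name}:{inv_k}", name))
        complements[name] = comp

    tips = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    tip_complements: dict[str, Complement] = {
        t: tuple(tuple(tuple(p) for p in c) for c in complements[t]) for t in tips
    }
    maps = {t: _paint(t, tip_complements[t], config.species_prefix) for t in tips}

    # structural annotations: each inversion marks every tip below its branch
    below: dict[str, set[str]] = {}
    for node in dtree.preorder_node_iter():
        below[_node_name(node, counter)] = {lf.taxon.label for lf in node.leaf_iter()}
    ann_rows = []
    for cid, branch in inversion_chars:
        for t in tips:
            ann_rows.append(
                {"taxon": t, "character_id": cid, "state": "1" if t in below[branch] else "0", "note": ""}
            )
    annotations = pd.DataFrame(ann_rows, columns=["taxon", "character_id", "state", "note"])

    reference = ancestral_karyotype(config.ancestral_units, config.species_prefix)
    states = [karyomap.synteny_partition(maps[t]) for t in tips]
    assoc = derive_association_characters(states, reference)
    disr = derive_disruption_characters(states, list(maps.values()), reference)
    matrix = merge_structural_characters(annotations if len(annotations) else None, [assoc, disr], taxa=tips)

    true_tree = PhyloTree.from_newick(config.tree, rooted=True)
    log = EventLog(tree=config.tree, ancestral_units=config.ancestral_units, events=events)
    return SimResult(
        config=config,
        maps=maps,
        annotations=annotations,
        matrix=matrix,
        log=log,
        true_tree=true_tree,
        tip_complements=tip_complements,
        reference=reference,
    )


def replay(log: EventLog, ancestral_units: int | None = None) -> dict[str, Complement]:
    """Re-derive every tip complement from the event log alone (round-trip
    oracle for the simulator).  Events are applied in recorded order."""
    n_units = ancestral_units if ancestral_units is not None else log.ancestral_units
    dtree = dendropy.Tree.get(data=log.tree, schema="newick")
    counter = [0]
    for node in dtree.preorder_node_iter():
        _node_name(node, counter)
    by_branch: dict[str, list[Event]] = {}
    for ev in log.events:
        by_branch.setdefault(ev.branch, []).append(ev)
    ancestral = [[(u, 0)] for u in range(1, n_units + 1)]
    complements: dict[str, list[list[tuple[int, int]]]] = {}
    frag_counter: dict[int, int] = {}
    for node in dtree.preorder_node_iter():
        name = _node_name(node, counter)
        if node.parent_node is None:
            complements[name] = [list(c) for c in ancestral]
            continue
        comp = [list(c) for c in complements[_node_name(node.parent_node, counter)]]
        for ev in by_branch.get(name, []):
            _apply_event(comp, ev, frag_counter)
        complements[name] = comp
    tips = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    return {t: tuple(tuple(tuple(p) for p in c) for c in complements[t]) for t in tips}


# ---------------------------------------------------------------------------
# truth-comparison helpers
# ---------------------------------------------------------------------------


def true_tree_is_mp(result: SimResult) -> bool:
    """Whether the simulated matrix is homoplasy-free on the generating tree
    (the tree attains the per-character theoretical minimum)."""
    from .mptree import fitch_length

    return fitch_length(result.true_tree.unrooted(), result.matrix) == int(
        result.matrix.min_steps().sum()
    )


def internal_edges_covered(result: SimResult) -> bool:
    """Whether every internal edge of the true topology is supported by at
    least one clean character (its taxa scored 1 are exactly one side)."""
    matrix = result.matrix
    taxa = matrix.taxa
    full = frozenset(taxa)
    char_sides = set()
    for j in range(matrix.n_characters):
        ones = frozenset(t for i, t in enumerate(taxa) if matrix.states[i, j] == "1")
        char_sides.add(ones)
        char_sides.add(full - ones)
    return all(
        bp in char_sides or (full - bp) in char_sides
        for bp in result.true_tree.unrooted().bipartitions()
    )
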