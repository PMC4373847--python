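"""Model front-end: a character matrix in, a fitted parsimony estimate out.

``ChromosomeParsimony`` is the one-stop entry point: construct it from a
binary character matrix (or directly from homology maps plus structural
annotations), call :meth:`~ChromosomeParsimony.fit`, and read the estimates
off the returned :class:`ParsimonyResults` — the MP tree set and length, the
consistency index, bootstrap percentages and Bremer decay indices per clade,
and the a-posteriori apomorphy classification of every character.
"""

from __future__ import annotations

import textwrap
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import apomap, charcoding, karyomap, mptree, support
from .charcoding import CharacterMatrix, count_informative
from .karyomap import HomologyMap, Karyotype
from .mptree import PhyloTree, TreeSearchResult

__all__ = ["ChromosomeParsimony", "ParsimonyResults"]


class ChromosomeParsimony:
    """Maximum-parsimony phylogeny estimator for binary chromosomal characters.

    Parameters
    ----------
    matrix
        Taxa × binary characters over {0, 1, ?}.
    outgroup
        Taxa used to root the tree and polarize characters a posteriori.
        Must be separable from the ingroup by one edge of the MP tree.

    Examples
    --------
    >>> model = ChromosomeParsimony.from_maps(maps, reference, outgroup=["DEC", "DRO", "DYO"])
    >>> res = model.fit(bootstrap_reps=2000, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, matrix: CharacterMatrix, outgroup: Sequence[str] = ()) -> None:
        self.matrix = matrix
        self.outgroup = tuple(outgroup)
        missing = set(self.outgroup) - set(matrix.taxa)
        if missing:
            raise ValueError(f"outgroup taxa not in matrix: {sorted(missing)}")

    @classmethod
    def from_maps(
        cls,
        maps: Sequence[HomologyMap],
        reference: Karyotype,
        annotations: pd.DataFrame | None = None,
        outgroup: Sequence[str] = (),
        taxa: Sequence[str] | None = None,
    ) -> "ChromosomeParsimony":
        """Code characters from painting homology maps and build the model."""
        states = [karyomap.synteny_partition(m) for m in maps]
        assoc = charcoding.derive_association_characters(states, reference)
        disr = charcoding.derive_disruption_characters(states, list(maps), reference)
        matrix = charcoding.merge_structural_characters(annotations, [assoc, disr], taxa=taxa)
        return cls(matrix, outgroup=outgroup)

    @classmethod
    def from_nexus(cls, path: str | Path, outgroup: Sequence[str] = ()) -> "ChromosomeParsimony":
        return cls(CharacterMatrix.from_nexus(Path(path)), outgroup=outgroup)

    @classmethod
    def from_tsv(cls, path: str | Path, outgroup: Sequence[str] = ()) -> "ChromosomeParsimony":
        return cls(CharacterMatrix.from_tsv(Path(path)), outgroup=outgroup)

    def fit(
        self,
        bootstrap_reps: int = support.DEFAULT_BOOTSTRAP_REPS,
        seed: int = 0,
        optimization: str = "deltran",
        consensus_threshold: float = 0.5,
    ) -> "ParsimonyResults":
        """Exhaustive MP search, support estimation and character mapping.

        ``seed`` drives only the bootstrap resampling; search, Bremer and the
        classification are deterministic given the matrix.
        """
        search = mptree.exhaustive_search(self.matrix)
        boot = (
            support.bootstrap_support(self.matrix, n_reps=bootstrap_reps, seed=seed)
            if bootstrap_reps and self.matrix.n_taxa >= 4
            else {}
        )
        bremer = support.bremer_support(self.matrix, search)
        rooted = classification = counts = root_report = None
        if self.outgroup:
            rooted = apomap.root_on_outgroup(search.mp_trees[0], self.outgroup)
            classification, counts = apomap.classify_characters(
                rooted, self.matrix, self.outgroup, mode=optimization
            )
            root_report = apomap.root_state_report(rooted, self.matrix, self.outgroup, mode=optimization)
        return ParsimonyResults(
            model=self,
            search=search,
            bootstrap=boot,
            bremer=bremer,
            bootstrap_reps=bootstrap_reps,
            seed=seed,
            optimization=optimization,
            consensus_threshold=consensus_threshold,
            rooted_tree=rooted,
            classification=classification,
            category_counts=counts,
            root_report=root_report,
        )


@dataclass
class ParsimonyResults:
    """Fitted parsimony estimate with support, diagnostics and mapping."""

    model: ChromosomeParsimony
    search: TreeSearchResult
    bootstrap: dict[frozenset[str], float]
    bremer: dict[frozenset[str], int]
    bootstrap_reps: int
    seed: int
    optimization: str
    consensus_threshold: float
    rooted_tree: PhyloTree | None = None
    classification: list[apomap.CharacterMapping] | None = None
    category_counts: Counter | None = None
    root_report: dict | None = None

    # -- scalar estimates --------------------------------------------------
    @property
    def length(self) -> int:
        return self.search.length

    @property
    def ci(self) -> float:
        return self.search.ci

    @property
    def mp_trees(self) -> list[PhyloTree]:
        return self.search.mp_trees

    @property
    def n_informative(self) -> int:
        return count_informative(self.model.matrix)

    def consensus(self) -> PhyloTree:
        """Majority-rule consensus of the MP trees (strict when unique)."""
        return support.majority_rule_consensus(self.mp_trees, self.consensus_threshold)

    def support_table(self) -> pd.DataFrame:
        return support.support_table(self.bootstrap, self.bremer)

    def mapping_table(self) -> pd.DataFrame:
        if self.classification is None:
            raise ValueError("no outgroup given: characters were not classified")
        return pd.DataFrame(
            [
                {
                    "character": m.character_id,
                    "steps": m.steps,
                    "min_steps": m.min_steps,
                    "branches": ";".join(m.change_branches),
                    "category": m.category,
                    "optimization_dependent": m.optimization_dependent,
                }
                for m in self.classification
            ]
        )

    def annotated_tree(self) -> PhyloTree:
        """Best tree annotated as 'bremer/bootstrap' per internal clade."""
        tree = self.mp_trees[0]
        ann: dict[frozenset[str], str] = {}
        for clade in tree.bipartitions():
            parts = []
            if clade in self.bremer:
                parts.append(str(self.bremer[clade]))
            if self.bootstrap:
                parts.append(f"{self.bootstrap.get(clade, 0.0):.0f}")
            if parts:
                ann[clade] = "/".join(parts)
        return tree.copy(support=ann)

    def summary(self) -> str:
        m = self.model.matrix
        lines = [
            "Chromosome-character maximum parsimony",
            "=" * 54,
            f"Taxa:                  {m.n_taxa} ({', '.join(m.taxa)})",
            f"Characters:            {m.n_characters} "
            f"(informative: {self.n_informative})",
            f"Topologies examined:   {self.search.n_topologies_examined}",
            f"MP trees:              {len(self.mp_trees)}",
            f"Tree length (steps):   {self.length}",
            f"Consistency index:     {self.ci:.4f}",
            f"Bootstrap replicates:  {self.bootstrap_reps} (seed {self.seed})",
            f"Optimization:          {self.optimization.upper()}",
        ]
        if self.model.outgroup:
            lines.append(f"Outgroup:              {', '.join(self.model.outgroup)}")
        lines.append("Best tree:             " + self.annotated_tree().to_newick(annotate=True))
        if self.bremer:
            lines.append("")
            lines.append("Clade support (bootstrap % / Bremer):")
            for clade in sorted(self.bremer, key=lambda c: (-len(c), sorted(c))):
                boot = self.bootstrap.get(clade, 0.0)
                lines.append(
                    f"  {{{','.join(sorted(clade))}}}: {boot:.1f} / {self.bremer[clade]}"
                )
        if self.category_counts is not None:
            lines.append("")
            order = ("autapomorphy", "synapomorphy", "plesiomorphy", "homoplasy", "constant")
            counted = ", ".join(
                f"{self.category_counts.get(k, 0)} {k}"
                for k in order
                if self.category_counts.get(k, 0) or k != "constant"
            )
            lines.append(f"Character mapping:     {counted}")
        return "\n".join(lines)
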