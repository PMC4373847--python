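# Methods

## Data model

A painting experiment is reduced to `PaintSignal(probe, target, n_blocks,
region)` records.  `n_blocks` counts discontiguous hybridization blocks of
one probe on one target chromosome: two blocks of the same probe separated by
non-homologous material contribute two segments to the panel total while
remaining a single record, preserving both the per-chromosome synteny fact
and the segment arithmetic.  Region qualifiers (arm, proximal/distal) are
free text and never parsed into coordinates — painting has no base-pair
resolution, so no coordinate convention arises.

Karyotype validation uses the conventional arithmetic: 2n = 2·(autosome
pairs) + 2, and FN counts autosomal arms only (2 per bi-armed, 1 per
one-armed chromosome, both homologs; sex chromosomes excluded).  This is the
only convention that reproduces all three shipped (2n, FN) pairs, e.g. 2n=34
with 28 bi-armed + 4 one-armed autosomes giving FN=60.

## Character coding

Characters are binary, equally weighted (rearrangements are treated as
equally likely a priori), and polarity-free at coding time: 1 is the
rearranged condition relative to the reference complement, direction is
established only by outgroup rooting.  A taxon lacking painting evidence for
a unit scores `?`, never 0 — absence of evidence in ZOO-FISH is not evidence
of conservation.  Associations are pairwise: a chromosome carrying units
{i, j, k} yields the three pairwise characters, which keeps the coding
binary and mechanical at the cost of some redundancy among nested fusions
(documented so users can compare totals against manually coded matrices).
Heterochromatin-only differences are structural annotations, never synteny
characters, because painting probes carry no constitutive-heterochromatin
information.

## Parsimony

Tree space is enumerated exactly by stepwise leaf insertion — each unrooted
binary topology on n leaves arises from a unique insertion history, giving
(2n−5)!! distinct topologies with no deduplication needed (checked against
the closed form for n = 3..8).  A hard cap of 12 taxa keeps full enumeration
affordable (≈13.7 M topologies); beyond that the search refuses and points
to branch-and-bound as the appropriate tool, which is out of scope.

Fitch scoring is vectorized across characters with state sets packed in two
bits; `?` enters as the full set {0,1} and can never add a step.  The
traversal roots arbitrarily (at the first leaf's pendant edge); the score is
rooting-invariant, which the tests check by re-rooting and permuting leaves.
Equally parsimonious trees are all retained, in canonical newick order
(subtrees sorted lexicographically from the smallest-label leaf), and
downstream consumers receive the full set plus a consensus.

CI = Σ min_steps / length with min_steps(c) = (distinct observed non-`?`
states) − 1, reported to 4 decimals.  CI = 1 exactly on homoplasy-free
matrices.

## Support

Bootstrap resamples characters with replacement to the original count; every
replicate is solved exactly.  Because a replicate differs from the original
matrix only in column multiplicities, the per-topology × per-character Fitch
step matrix is computed once and each replicate's tree lengths are a single
matrix–vector product with the resample weights — algebraically identical to
re-running the exhaustive search per replicate.  All MP trees of a replicate
contribute bipartitions fractionally (1/ties) to avoid bias toward arbitrary
tie order.  The default is 2,000 replicates; one seeded generator drives all
resampling and is echoed in machine-readable output.

Bremer indices are computed from the same enumerated tree space: for each
clade of the strict consensus of MP trees, the decay is the best length
among topologies lacking the clade minus the MP length — exact, with no
reverse-constraint heuristics, and deterministic (seed-free).

## Ancestral states and apomorphy categories

MPR state sets come from an exact unit-cost dynamic program: an upward pass
gives the minimum changes below each node per state, a downward pass the
minimum in the remainder, and a state is in the MPR set iff the two costs
sum to the character's minimum.  The classic Fitch second pass was tried
first and overstates MPR sets when leaves carry `?`; the cost decomposition
has no such blind spot and is verified against brute-force enumeration of
all labelings on small trees.

Ambiguous change placement follows DELTRAN by default (changes pushed toward
the tips, selected exactly as the MP labeling maximizing the summed depth of
change edges; ACCTRAN minimizes it; remaining ties break on the
lexicographically smallest state vector).  Classification is recomputed
under both optimizations and flagged when the category depends on the
choice.

Categories partition the characters with precedence homoplasy >
plesiomorphy > autapomorphy > synapomorphy (configurable), after an
unconditional *constant* test (min_steps = 0):

- **homoplasy** — steps exceed the theoretical minimum;
- **plesiomorphy** — derived state 1 resolved at the *root* of the rooted
  tree, i.e. already present in the ancestor shared with the outgroup.
  Testing at the ingroup MRCA instead (selectable via
  `plesiomorphy_at="ingroup_mrca"`) would also absorb changes on the ingroup
  stem — precisely the tribe-level synapomorphies — so the root criterion is
  the default;
- **autapomorphy** — single change on a terminal branch;
- **synapomorphy** — single change on an internal branch.

The root-state report lists characters resolved derived at the ingroup MRCA
(the ancestral-karyotype statement) and the reference units untouched by any
of them (conserved in toto ancestrally).

## Simulator

The generator evolves an ancestral complement of conserved units (default
16, matching a painting panel of ~16 probes) along a rooted tree with branch
lengths.  Event counts per branch and type are Poisson with mean
rate × branch length; defaults are fusion 2.0, fission 1.5, reciprocal
translocation 0.5, inversion 0.5 per unit branch length, which on the
default unit-branch 7-taxon tree gives ≈4–5 events per branch and ≈55
changes over the tree — the rearrangement density of heavily rearranged bat
karyotypes.  Genomic content is conserved (no gain/loss events): every
unit's fragments occur exactly once in every tip, which the tests assert.
Breakpoints fall uniformly on unit boundaries; an optional flag allows
unit-internal fission, the mechanism behind discontiguous same-probe blocks
on one chromosome.  A fission requested on a complement with no valid
breakpoint is dropped after resampling.  Inversions are painting-invisible
and surface only as structural characters scored 1 for the tips below the
event's branch.

Tips are "painted" with probes for the ancestral units (one signal per unit
per chromosome, maximal runs counted as blocks), and the emitted matrix is
produced by running the character coder on those painted tables, so the
generator and the coder cannot drift apart.  The event log addresses
chromosomes positionally and is replayed through the same event-application
code, reproducing every tip complement bit-exactly — the round-trip oracle.

What the simulator does *not* emulate: breakpoint hotspots and reuse,
heterochromatin dynamics, chromosome-number drift by aneuploidy, arm-level
morphology bookkeeping beyond inversion marks, and probe-detection failure
(simulated tips have no missing data).  Passing tests on simulated data
therefore demonstrate the correctness of coding, search, support and
classification under clean detection — not robustness to the partial
hybridization and judgment calls of real painting experiments.

Interacting events generate genuine homoplasy (e.g. a fission splitting a
previously fused junction reads as a reversal), so under default rates only
a minority of runs (≈30%) are homoplasy-free.  On every homoplasy-free run
the generating topology is provably among the MP trees; it is the *unique*
MP tree exactly when every internal edge of the true tree received at least
one clean supporting character, and the test suite asserts both facts
separately rather than conflating them into a single recovery rate.

## Numerical and degenerate-input choices

- Bipartitions are canonicalized as the side not containing the smallest
  leaf label (`canonical_bipartition` helps users build lookup keys).
- Consensus trees may contain polytomies (a star tree under total
  disagreement); search trees are strictly binary.
- `consistency_index` refuses lengths below the theoretical minimum and a
  zero length with variable characters; an all-constant matrix at length 0
  returns CI 1.0 by convention.
- Empty homology maps are legal (header-only TSV); species codes of an empty
  map come from the filename stem.
- The character matrix rejects columns scored `?` in every taxon, duplicate
  taxa and duplicate character ids; bootstrap column resampling suffixes
  duplicated ids to keep them unique.

## Problem sizes used in tests

The suite verifies Fitch scores against the brute-force labeling oracle on
1,000 random instances of up to 6 taxa × 10 characters across all topologies,
recovery on 100 simulation seeds, and bootstrap behavior at 200–2,000
replicates; the full suite and the acceptance script each complete in well
under a minute on one core, since exhaustive search at 7 taxa costs only 945
vectorized Fitch passes.
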