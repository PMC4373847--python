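"""Outgroup rooting, ancestral reconstructions and apomorphy categories."""

import numpy as np
import pytest

from chromoclad.apomap import (
    ancestral_states,
    classify_characters,
    root_on_outgroup,
    root_state_report,
)
from chromoclad.charcoding import CharacterDef, CharacterMatrix
from chromoclad.mptree import PhyloTree, enumerate_topologies, fitch_steps

from conftest import brute_force_mpr

TAXA = ["TSA", "LSI", "PHA", "PDI", "DEC", "DRO", "DYO"]


def matrix_from_one_sets(one_sets, taxa=TAXA, missing=()):
    cols = []
    for k, ones in enumerate(one_sets):
        q = missing[k] if k < len(missing) else set()
        cols.append(["?" if t in q else ("1" if t in ones else "0") for t in taxa])
    chars = [CharacterDef(f"c{j}", "structural") for j in range(len(cols))]
    return CharacterMatrix(taxa, chars, np.array(cols).T)


@pytest.fixture()
def rooted_study(study_tree, outgroup):
    return root_on_outgroup(study_tree, outgroup)


def test_rooting_on_study_outgroup(study_tree, outgroup, rooted_study):
    """Rooting on the outgroup yields the ingroup ladder
    (TSA,(LSI,(PHA,PDI))) with Tonatia basal."""
    clades = rooted_study.clade_leafsets()
    assert frozenset({"TSA", "LSI", "PHA", "PDI"}) in clades
    assert frozenset({"LSI", "PHA", "PDI"}) in clades
    assert frozenset({"PHA", "PDI"}) in clades
    assert frozenset(outgroup) in clades
    # the unrooted topology is unchanged by rooting
    assert rooted_study.unrooted().bipartitions() == study_tree.bipartitions()


def test_rooting_single_taxon_outgroup():
    t = PhyloTree.from_newick("(A,((B,C),D));")
    rooted = root_on_outgroup(t, ["A"])
    assert rooted.clade_leafsets() >= {frozenset({"B", "C"})}


def test_rooting_rejects_interdigitated_outgroup(study_tree):
    with pytest.raises(ValueError, match="not separable"):
        root_on_outgroup(study_tree, ["DEC", "TSA"])
    with pytest.raises(ValueError, match="not in tree"):
        root_on_outgroup(study_tree, ["XXX"])


def test_ancestral_states_trivial_cases(rooted_study):
    m = matrix_from_one_sets([{"TSA"}, set(), set(TAXA)])
    mprs = ancestral_states(rooted_study, m)
    internal = [n for n in rooted_study.adj if n >= rooted_study.n_leaves]
    assert all(mprs[0][n] == frozenset({"0"}) for n in internal)  # autapomorphy
    assert all(mprs[1][n] == frozenset({"0"}) for n in internal)  # constant 0
    assert all(mprs[2][n] == frozenset({"1"}) for n in internal)  # constant 1


def test_ancestral_states_match_brute_force_enumeration():
    """The cost-decomposition MPR sets equal explicit enumeration of all
    most parsimonious labelings, '?' leaves included."""
    rng = np.random.default_rng(31)
    for _ in range(25):
        n = int(rng.integers(4, 7))
        taxa = [f"T{i}" for i in range(n)]
        topos = list(enumerate_topologies(taxa))
        tree = topos[int(rng.integers(len(topos)))]
        rooted = root_on_outgroup(tree, [taxa[0]])
        states = rng.choice(["0", "1", "?"], size=(n, 3), p=[0.45, 0.45, 0.1])
        for j in range(3):
            if (states[:, j] == "?").all():
                states[0, j] = "1"
        m = CharacterMatrix(taxa, [CharacterDef(f"c{j}", "structural") for j in range(3)], states)
        mprs = ancestral_states(rooted, m)
        for j in range(3):
            expected = brute_force_mpr(rooted, m, j)
            assert {n: set(s) for n, s in mprs[j].items()} == expected


def test_homoplastic_character_is_ambiguous_where_expected(rooted_study):
    """A state shared by LSI and PHA only conflicts with the topology:
    two steps, with reconstruction ambiguity around the LSI/PHA region."""
    m = matrix_from_one_sets([{"LSI", "PHA"}])
    assert int(fitch_steps(rooted_study, m)[0]) == 2
    mpr = ancestral_states(rooted_study, m)[0]
    assert any(len(mpr[n]) == 2 for n in mpr if n >= rooted_study.n_leaves)


def test_classification_of_canonical_cases(rooted_study, outgroup):
    m = matrix_from_one_sets(
        [
            {"PDI"},                                  # unique to one terminal
            {"PHA", "PDI"},                           # clean internal change
            {"LSI", "PHA"},                           # conflicts: extra step
            {"TSA", "LSI", "PHA", "PDI", "DEC"},      # ancestral, lost in DRO+DYO
            {"TSA", "LSI", "PHA", "PDI"},             # ingroup-stem change
            set(),                                    # constant
        ]
    )
    cls, counts = classify_characters(rooted_study, m, outgroup)
    by_id = {c.character_id: c for c in cls}
    assert by_id["c0"].category == "autapomorphy" and by_id["c0"].change_branches == ["PDI"]
    assert by_id["c1"].category == "synapomorphy" and by_id["c1"].change_branches == ["PDI+PHA"]
    assert by_id["c2"].category == "homoplasy" and by_id["c2"].steps == 2
    assert by_id["c3"].category == "plesiomorphy"
    assert by_id["c4"].category == "synapomorphy"  # tribe-level shared derived state
    assert by_id["c5"].category == "constant"
    assert sum(counts.values()) == m.n_characters
    # deterministic
    cls2, _ = classify_characters(rooted_study, m, outgroup)
    assert [c.category for c in cls2] == [c.category for c in cls]


def test_acctran_deltran_divergence_is_flagged(rooted_study, outgroup):
    """State present in PHA and unknown in PDI: DELTRAN places the gain on
    the PHA terminal (autapomorphy), ACCTRAN on the PHA+PDI stem
    (synapomorphy); both runs flag the dependence."""
    m = matrix_from_one_sets([{"PHA"}], missing=[{"PDI"}])
    delt, _ = classify_characters(rooted_study, m, outgroup, mode="deltran")
    acct, _ = classify_characters(rooted_study, m, outgroup, mode="acctran")
    assert delt[0].category == "autapomorphy" and delt[0].change_branches == ["PHA"]
    assert acct[0].category == "synapomorphy" and acct[0].change_branches == ["PDI+PHA"]
    assert delt[0].optimization_dependent and acct[0].optimization_dependent


def test_precedence_is_configurable(rooted_study, outgroup):
    m = matrix_from_one_sets([{"TSA", "LSI", "PHA", "PDI", "DEC"}])
    default, _ = classify_characters(rooted_study, m, outgroup)
    assert default[0].category == "plesiomorphy"
    flipped, _ = classify_characters(
        rooted_study,
        m,
        outgroup,
        precedence=("homoplasy", "autapomorphy", "synapomorphy", "plesiomorphy"),
    )
    assert flipped[0].category == "synapomorphy"  # loss on the DRO+DYO stem
    with pytest.raises(ValueError):
        classify_characters(rooted_study, m, outgroup, precedence=("homoplasy",))


def test_root_state_report_lists_plesiomorphies(rooted_study, outgroup):
    m = matrix_from_one_sets(
        [
            {"TSA", "LSI", "PHA", "PDI", "DEC"},  # plesiomorphy -> in root set
            {"PHA", "PDI"},                        # nested synapomorphy -> not
            {"PDI"},                               # autapomorphy -> not
        ]
    )
    report = root_state_report(rooted_study, m, outgroup)
    cls, counts = classify_characters(rooted_study, m, outgroup)
    plesio = {c.character_id for c in cls if c.category == "plesiomorphy"}
    assert plesio <= set(report["root_state_1_characters"])
    assert report["root_state_1_characters"] == ["c0"]

    none = matrix_from_one_sets([{"PDI"}, {"TSA"}])
    assert root_state_report(rooted_study, none, outgroup)["root_state_1_characters"] == []


def test_steps_in_mapping_agree_with_fitch(rooted_study, outgroup):
    rng = np.random.default_rng(3)
    states = rng.choice(["0", "1"], size=(7, 9))
    m = CharacterMatrix(TAXA, [CharacterDef(f"c{j}", "structural") for j in range(9)], states)
    cls, counts = classify_characters(rooted_study, m, outgroup)
    per_char = fitch_steps(rooted_study, m)
    assert [c.steps for c in cls] == [int(s) for s in per_char]
    assert sum(counts.values()) == 9
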