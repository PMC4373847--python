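"""Character derivation, matrix assembly and matrix I/O round-trips."""

import numpy as np
import pandas as pd
import pytest

from chromoclad import count_informative, synteny_partition
from chromoclad.charcoding import (
    CharacterDef,
    CharacterMatrix,
    derive_association_characters,
    derive_disruption_characters,
    merge_structural_characters,
)


@pytest.fixture()
def ingroup_data(fixture_maps, identity_pha_map):
    maps = [fixture_maps["TSA_PHA"], fixture_maps["LSI_PHA"], identity_pha_map]
    return maps, [synteny_partition(m) for m in maps]


def test_character_def_cardinality_rules():
    with pytest.raises(ValueError):
        CharacterDef("x", "association", reference_units=frozenset({"PHA-1"}))
    with pytest.raises(ValueError):
        CharacterDef("x", "disruption", reference_units=frozenset({"PHA-1", "PHA-2"}))
    with pytest.raises(ValueError):
        CharacterDef("x", "banding")


def test_association_pha3_pha4_scored_in_tonatia(ingroup_data, pha_karyotype):
    """PHA-3 and PHA-4 are joined on TSA-1 (and TSA-4): the association
    character scores 1 in TSA and 0 in the unrearranged reference."""
    _, states = ingroup_data
    derived = {c.id: s for c, s in derive_association_characters(states, pha_karyotype)}
    assert "assoc:PHA-3+PHA-4" in derived
    assert derived["assoc:PHA-3+PHA-4"]["TSA"] == "1"
    assert derived["assoc:PHA-3+PHA-4"]["PHA"] == "0"
    assert derived["assoc:PHA-3+PHA-4"]["LSI"] == "0"  # detected but never joined


def test_all_singleton_partition_scores_zero_everywhere(ingroup_data, pha_karyotype):
    _, states = ingroup_data
    for cdef, scores in derive_association_characters(states, pha_karyotype):
        assert scores["PHA"] == "0"  # the reference complement carries no association
        assert scores["LSI"] in "0?"  # LSI is unfused relative to PHA


def test_association_derivation_is_deterministic_and_taxon_order_free(ingroup_data, pha_karyotype):
    maps, states = ingroup_data
    a = derive_association_characters(states, pha_karyotype)
    b = derive_association_characters(list(reversed(states)), pha_karyotype)
    assert [c.id for c, _ in a] == [c.id for c, _ in b]
    assert [s for _, s in a] == [s for _, s in b]


def test_disruption_pha13_split_in_tsa_and_lsi(ingroup_data, pha_karyotype):
    """PHA-13 is fissioned in both TSA and LSI but intact in PHA itself."""
    maps, states = ingroup_data
    derived = {c.id: s for c, s in derive_disruption_characters(states, maps, pha_karyotype)}
    assert derived["fission:PHA-13"] == {"TSA": "1", "LSI": "1", "PHA": "0"}
    # PHA-14 is conserved in toto everywhere: no disruption character emitted
    assert "fission:PHA-14" not in derived
    # PHA-5 is on a single TSA chromosome but in two discontiguous blocks
    assert derived["fission:PHA-5"]["TSA"] == "1"


def test_mixed_probe_panels_are_rejected(fixture_maps, pha_karyotype):
    states = [synteny_partition(fixture_maps["TSA_PHA"]), synteny_partition(fixture_maps["TSA_CBR"])]
    with pytest.raises(ValueError):
        derive_association_characters(states, pha_karyotype)


def test_merge_appends_structural_after_synteny(ingroup_data, pha_karyotype):
    maps, states = ingroup_data
    assoc = derive_association_characters(states, pha_karyotype)
    disr = derive_disruption_characters(states, maps, pha_karyotype)
    ann = pd.DataFrame(
        [
            {"taxon": "PDI", "character_id": "inv:pair15-biarmed", "state": "1", "note": "pericentric inversion"},
            {"taxon": "PHA", "character_id": "inv:pair15-biarmed", "state": "0", "note": ""},
            {"taxon": "LSI", "character_id": "inv:pair15-biarmed", "state": "0", "note": ""},
        ]
    )
    m = merge_structural_characters(ann, [assoc, disr], taxa=["TSA", "LSI", "PHA", "PDI"])
    kinds = [c.kind for c in m.characters]
    assert kinds == sorted(kinds, key=("association", "disruption", "structural").index)
    assert m.n_characters == len(assoc) + len(disr) + 1
    assert m.state("PDI", "inv:pair15-biarmed") == "1"
    assert m.state("PHA", "inv:pair15-biarmed") == "0"
    assert m.state("PDI", "assoc:PHA-3+PHA-4") == "?"  # PDI has no panel-wide painting data

    empty = merge_structural_characters(None, [assoc, disr])
    assert empty.n_characters == len(assoc) + len(disr)


def test_merge_rejects_bad_annotations(ingroup_data, pha_karyotype):
    maps, states = ingroup_data
    assoc = derive_association_characters(states, pha_karyotype)
    dup = pd.DataFrame(
        [
            {"taxon": "PHA", "character_id": "x", "state": "1"},
            {"taxon": "PHA", "character_id": "x", "state": "0"},
        ]
    )
    with pytest.raises(ValueError, match="duplicate"):
        merge_structural_characters(dup, [assoc])
    bad_state = pd.DataFrame([{"taxon": "PHA", "character_id": "x", "state": "2"}])
    with pytest.raises(ValueError, match="state"):
        merge_structural_characters(bad_state, [assoc])
    stranger = pd.DataFrame([{"taxon": "AAA", "character_id": "x", "state": "1"}])
    with pytest.raises(ValueError, match="taxon"):
        merge_structural_characters(stranger, [assoc], taxa=["TSA", "LSI", "PHA"])


def test_count_informative_definition():
    taxa = ["A", "B", "C", "D"]
    m = CharacterMatrix(
        taxa,
        [CharacterDef(f"c{j}", "structural") for j in range(3)],
        [["1", "1", "1"], ["1", "0", "?"], ["0", "0", "?"], ["0", "0", "1"]],
    )
    # c0: 2×1 + 2×0 -> informative; c1: single 1; c2: 2×1 but no two 0s
    assert count_informative(m) == 1
    auto = CharacterMatrix(
        taxa,
        [CharacterDef(f"a{j}", "structural") for j in range(4)],
        np.where(np.eye(4, dtype=bool), "1", "0"),
    )
    assert count_informative(auto) == 0


def test_matrix_invariants():
    with pytest.raises(ValueError, match="does not match"):
        CharacterMatrix(["A"], [CharacterDef("c", "structural")], [["0", "1"]])
    with pytest.raises(ValueError, match="outside"):
        CharacterMatrix(["A"], [CharacterDef("c", "structural")], [["2"]])
    with pytest.raises(ValueError, match=r"\?"):
        CharacterMatrix(["A", "B"], [CharacterDef("c", "structural")], [["?"], ["?"]])


@pytest.mark.parametrize("fmt", ["tsv", "nexus"])
def test_matrix_roundtrips_bit_exact(fmt, ingroup_data, pha_karyotype):
    maps, states = ingroup_data
    assoc = derive_association_characters(states, pha_karyotype)
    disr = derive_disruption_characters(states, maps, pha_karyotype)
    m = merge_structural_characters(None, [assoc, disr])
    if fmt == "tsv":
        text = m.to_tsv()
        back = CharacterMatrix.from_tsv(text)
        assert back == m
        assert [c.kind for c in back.characters] == [c.kind for c in m.characters]
        assert back.to_tsv() == text
    else:
        text = m.to_nexus()
        back = CharacterMatrix.from_nexus(text)
        assert back.taxa == m.taxa
        assert (back.states == m.states).all()
        assert back.to_nexus() == text
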