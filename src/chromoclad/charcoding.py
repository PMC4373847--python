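"""Binary cladistic coding of chromosomal rearrangements.

Characters are derived from painting homology maps against a reference
complement of minimal conserved units (the *P. hastatus* chromosomes in the
shipped data):

* **association** — two reference units found joined on one target chromosome
  (the signature of a fusion or translocation); one character per unordered
  pair of units observed together in at least one taxon;
* **disruption** — a reference unit split over several target chromosomes, or
  present as more than one discontiguous block on a single chromosome (the
  signature of a fission);
* **structural** — painting-invisible rearrangements scored from banding
  (pericentric inversions, NOR position, heterochromatin states), supplied as
  a per-taxon annotation table.

All characters are binary with 1 the rearranged condition relative to the
reference, 0 the conserved condition, and '?' missing data (a taxon without
painting evidence for a unit is unknown, not conserved).  No polarity is
assumed at coding time; direction is established a posteriori by outgroup
rooting.  All characters carry equal weight, on the premise that chromosome
rearrangements are equally likely to occur.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .karyomap import HomologyMap, Karyotype, SyntenyState

__all__ = [
    "CharacterDef",
    "CharacterMatrix",
    "derive_association_characters",
    "derive_disruption_characters",
    "merge_structural_characters",
    "count_informative",
    "read_annotations",
]

STATES = ("0", "1", "?")


@dataclass(frozen=True)
class CharacterDef:
    id: str
    kind: str  # association | disruption | structural
    description: str = ""
    reference_units: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("association", "disruption", "structural"):
            raise ValueError(f"unknown character kind {self.kind!r}")
        if self.kind == "association" and len(self.reference_units) != 2:
            raise ValueError(f"association character {self.id!r} must reference exactly 2 units")
        if self.kind == "disruption" and len(self.reference_units) != 1:
            raise ValueError(f"disruption character {self.id!r} must reference exactly 1 unit")


class CharacterMatrix:
    """Taxa × binary characters grid over {0, 1, ?} with character metadata."""

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[CharacterDef],
        states: np.ndarray | Sequence[Sequence[str]],
    ) -> None:
        self.taxa: list[str] = list(taxa)
        self.characters: list[CharacterDef] = list(characters)
        arr = np.asarray(states, dtype="<U1")
        if arr.shape != (len(self.taxa), len(self.characters)):
            raise ValueError(
                f"state grid {arr.shape} does not match {len(self.taxa)} taxa × "
                f"{len(self.characters)} characters"
            )
        bad = set(arr.ravel()) - set(STATES)
        if bad:
            raise ValueError(f"states outside {{0,1,?}}: {sorted(bad)}")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        ids = [c.id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate character ids")
        for j, cid in enumerate(ids):
            if arr.shape[0] and (arr[:, j] == "?").all():
                raise ValueError(f"character {cid!r} is scored '?' in every taxon")
        self.states = arr

    # -- container sugar ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def state(self, taxon: str, char_id: str) -> str:
        return self.states[self.taxa.index(taxon), [c.id for c in self.characters].index(char_id)]

    def column(self, j: int) -> np.ndarray:
        return self.states[:, j]

    def min_steps(self) -> np.ndarray:
        """Per character: (number of distinct observed non-'?' states) − 1."""
        out = np.zeros(self.n_characters, dtype=int)
        for j in range(self.n_characters):
            out[j] = max(len({s for s in self.states[:, j] if s != "?"}) - 1, 0)
        return out

    def subset_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        """Column subset/resample (duplicates allowed, ids suffixed to stay unique)."""
        chars = []
        seen: dict[str, int] = {}
        for j in indices:
            c = self.characters[j]
            n = seen.get(c.id, 0)
            seen[c.id] = n + 1
            cid = c.id if n == 0 else f"{c.id}#{n}"
            chars.append(CharacterDef(cid, c.kind, c.description, c.reference_units))
        return CharacterMatrix(self.taxa, chars, self.states[:, list(indices)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.taxa, columns=[c.id for c in self.characters])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and [c.id for c in self.characters] == [c.id for c in other.characters]
            and bool((self.states == other.states).all())
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa × {self.n_characters} characters>"

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path | None = None) -> str | None:
        """TSV: header row of character ids (with kind suffix comment rows)."""
        lines = ["# kind:\t" + "\t".join(c.kind for c in self.characters)]
        lines.append("taxon\t" + "\t".join(c.id for c in self.characters))
        for i, t in enumerate(self.taxa):
            lines.append(t + "\t" + "\t".join(self.states[i]))
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        Path(path).write_text(text, encoding="utf-8")
        return None

    @classmethod
    def from_tsv(cls, source: str | Path) -> "CharacterMatrix":
        text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) or "\n" not in str(source) else str(source)
        kinds: list[str] | None = None
        header: list[str] | None = None
        taxa: list[str] = []
        rows: list[list[str]] = []
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.lower().startswith("# kind:"):
                    kinds = line.split("\t")[1:]
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            taxa.append(fields[0])
            rows.append(fields[1:])
        if header is None:
            raise ValueError("matrix TSV has no header")
        if kinds is None:
            kinds = [_kind_from_id(cid) for cid in header]
        chars = [
            CharacterDef(cid, kind, reference_units=_units_from_id(cid, kind))
            for cid, kind in zip(header, kinds)
        ]
        return cls(taxa, chars, rows)

    def to_nexus(self, path: str | Path | None = None) -> str | None:
        """NEXUS DATA block (DATATYPE=STANDARD SYMBOLS="01" MISSING=?)."""
        taxon_namespace = dendropy.TaxonNamespace(self.taxa)
        cm = dendropy.StandardCharacterMatrix(taxon_namespace=taxon_namespace)
        alphabet = cm.default_state_alphabet
        for i, t in enumerate(self.taxa):
            taxon = taxon_namespace.get_taxon(t)
            cm[taxon] = alphabet.get_states_for_symbols("".join(self.states[i]))
        text = cm.as_string(schema="nexus")
        if path is None:
            return text
        Path(path).write_text(text, encoding="utf-8")
        return None

    @classmethod
    def from_nexus(cls, source: str | Path, characters: Sequence[CharacterDef] | None = None) -> "CharacterMatrix":
        """Read a NEXUS standard matrix.  Character metadata is not stored in
        the DATA block; generic defs (``c1..cN``, kind structural) are created
        unless ``characters`` supplies them."""
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
            cm = dendropy.StandardCharacterMatrix.get(path=str(source), schema="nexus")
        else:
            cm = dendropy.StandardCharacterMatrix.get(data=source, schema="nexus")
        taxa = [t.label for t in cm.taxon_namespace]
        rows = []
        for t in cm.taxon_namespace:
            rows.append([s.symbol for s in cm[t]])
        n_chars = len(rows[0]) if rows else 0
        if characters is None:
            characters = [CharacterDef(f"c{j + 1}", "structural") for j in range(n_chars)]
        return cls(taxa, characters, rows)


def _kind_from_id(cid: str) -> str:
    if cid.startswith("assoc:"):
        return "association"
    if cid.startswith("fission:"):
        return "disruption"
    return "structural"


def _units_from_id(cid: str, kind: str) -> frozenset[str]:
    if kind == "association":
        return frozenset(cid.split(":", 1)[1].split("+"))
    if kind == "disruption":
        return frozenset([cid.split(":", 1)[1]])
    return frozenset()


def _check_reference(states: Iterable[SyntenyState], reference: Karyotype) -> None:
    ref = reference.species_code
    for st in states:
        for group in st.partition.values():
            for unit in group:
                if not unit.startswith(ref + "-"):
                    raise ValueError(
                        f"synteny state for {st.taxon} references unit {unit!r} "
                        f"outside the reference complement {ref}"
                    )


def _unit_sort_key(label: str) -> tuple:
    code, _, name = label.partition("-")
    return (code, 0, int(name)) if name.isdigit() else (code, 1, name)


def derive_association_characters(
    states: Sequence[SyntenyState], reference: Karyotype
) -> list[tuple[CharacterDef, dict[str, str]]]:
    """One character per unordered pair of reference units syntenic in ≥1 taxon.

    A taxon scores 1 if the two units share a target chromosome, 0 if both are
    detected but never share one, '?' if either unit is undetected there.
    """
    _check_reference(states, reference)
    pairs: set[frozenset[str]] = set()
    for st in states:
        for group in st.partition.values():
            units = sorted(group)
            for a_i in range(len(units)):
                for b_i in range(a_i + 1, len(units)):
                    pairs.add(frozenset((units[a_i], units[b_i])))
    out: list[tuple[CharacterDef, dict[str, str]]] = []
    for pair in sorted(pairs, key=lambda p: tuple(_unit_sort_key(u) for u in sorted(p, key=_unit_sort_key))):
        a, b = sorted(pair, key=_unit_sort_key)
        cdef = CharacterDef(
            id=f"assoc:{a}+{b}",
            kind="association",
            description=f"{a} and {b} syntenic on one chromosome",
            reference_units=frozenset(pair),
        )
        scores: dict[str, str] = {}
        for st in states:
            detected = st.detected_units()
            if a not in detected or b not in detected:
                scores[st.taxon] = "?"
            elif any(a in g and b in g for g in st.partition.values()):
                scores[st.taxon] = "1"
            else:
                scores[st.taxon] = "0"
        out.append((cdef, scores))
    return out


def derive_disruption_characters(
    states: Sequence[SyntenyState], maps: Sequence[HomologyMap], reference: Karyotype
) -> list[tuple[CharacterDef, dict[str, str]]]:
    """One character per reference unit disrupted in ≥1 taxon.

    Disrupted means painted on >1 target chromosome, or present as >1
    discontiguous block on a single chromosome.  1 = disrupted, 0 = conserved
    in toto, '?' = undetected.
    """
    _check_reference(states, reference)
    by_taxon = {m.target_species: m for m in maps}
    if len(by_taxon) != len(maps):
        raise ValueError("multiple maps for one target species")
    probe_species = {m.probe_species for m in maps}
    if len(probe_species) > 1:
        raise ValueError(f"mixed probe species: {sorted(probe_species)}")
    if maps and probe_species != {reference.species_code}:
        raise ValueError("maps' probe species differs from the reference complement")

    def disrupted(taxon: str, unit: str) -> str:
        st = next(s for s in states if s.taxon == taxon)
        if unit not in st.detected_units():
            return "?"
        n_targets = sum(1 for g in st.partition.values() if unit in g)
        multi_block = any(
            s.n_blocks > 1 for s in by_taxon[taxon].signals if s.probe == unit
        ) if taxon in by_taxon else False
        return "1" if n_targets > 1 or multi_block else "0"

    units: set[str] = set()
    for st in states:
        units |= st.detected_units()
    out: list[tuple[CharacterDef, dict[str, str]]] = []
    for unit in sorted(units, key=_unit_sort_key):
        scores = {st.taxon: disrupted(st.taxon, unit) for st in states}
        if "1" not in scores.values():
            continue  # conserved everywhere observed: no disruption character
        cdef = CharacterDef(
            id=f"fission:{unit}",
            kind="disruption",
            description=f"{unit} split into ≥2 chromosomes or blocks",
            reference_units=frozenset([unit]),
        )
        out.append((cdef, scores))
    return out


def read_annotations(source: str | Path) -> pd.DataFrame:
    """Read a structural-annotation TSV (columns taxon, character_id, state, note)."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    required = {"taxon", "character_id", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def merge_structural_characters(
    annotations: pd.DataFrame | None,
    derived: Sequence[Sequence[tuple[CharacterDef, dict[str, str]]]],
    taxa: Sequence[str] | None = None,
) -> CharacterMatrix:
    """Assemble the full matrix: associations, then disruptions, then structural.

    ``derived`` is the list of per-kind lists produced by the derive_*
    functions; ``annotations`` holds structural rows keyed by (taxon,
    character_id) with states in {0,1,?}.  Column order is deterministic:
    association, disruption, structural blocks, each sorted by id.
    """
    columns: list[tuple[CharacterDef, dict[str, str]]] = []
    for block in derived:
        columns.extend(sorted(block, key=lambda c: c[0].id))

    struct_cols: dict[str, dict[str, str]] = {}
    struct_notes: dict[str, str] = {}
    if annotations is not None and len(annotations):
        seen: set[tuple[str, str]] = set()
        for _, row in annotations.iterrows():
            taxon, cid, state = str(row["taxon"]), str(row["character_id"]), str(row["state"])
            if state not in STATES:
                raise ValueError(f"annotation state {state!r} for ({taxon}, {cid}) not in {{0,1,?}}")
            if (taxon, cid) in seen:
                raise ValueError(f"duplicate annotation row for ({taxon}, {cid})")
            seen.add((taxon, cid))
            struct_cols.setdefault(cid, {})[taxon] = state
            if "note" in row and str(row.get("note", "")):
                struct_notes[cid] = str(row["note"])
    for cid in sorted(struct_cols):
        columns.append(
            (CharacterDef(id=cid, kind="structural", description=struct_notes.get(cid, "")), struct_cols[cid])
        )

    if taxa is None:
        ordered: list[str] = []
        for _, scores in columns:
            for t in scores:
                if t not in ordered:
                    ordered.append(t)
        taxa = ordered
    else:
        taxa = list(taxa)
        for _, scores in columns:
            for t in scores:
                if t not in taxa:
                    raise ValueError(f"taxon {t!r} not in taxa list")

    grid = np.full((len(taxa), len(columns)), "?", dtype="<U1")
    for j, (_, scores) in enumerate(columns):
        for t, s in scores.items():
            grid[taxa.index(t), j] = s
    return CharacterMatrix(taxa, [c for c, _ in columns], grid)


def count_informative(matrix: CharacterMatrix) -> int:
    """Parsimony-informative characters: ≥2 taxa scored 1 and ≥2 scored 0."""
    n = 0
    for j in range(matrix.n_characters):
        col = matrix.column(j)
        if (col == "1").sum() >= 2 and (col == "0").sum() >= 2:
            n += 1
    return n
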