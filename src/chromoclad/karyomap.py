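"""Karyotypes and cross-species chromosome-painting homology maps.

Cross-species painting (ZOO-FISH) hybridizes whole-chromosome probes of a
reference species onto the metaphases of a target species.  Each probe lights
up the chromosomal material homologous to one reference chromosome; the set of
signals for a probe panel is a *homology map*.  Two derived quantities drive
the downstream cladistics:

* the **segment count** — the total number of discontiguous hybridization
  blocks, a classic summary of how rearranged the target genome is relative to
  the reference;
* the **synteny partition** — which reference chromosomes (conserved units)
  co-occur on which target chromosomes, from which syntenic *associations*
  and *disruptions* are coded as binary characters.

Karyotype descriptions (diploid number 2n, fundamental number FN, chromosome
morphologies) are validated with the standard arithmetic: 2n counts all
chromosomes, FN counts autosomal arms (2 per bi-armed chromosome, 1 per
one-armed chromosome, over both homologs; sex chromosomes excluded).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Morphology",
    "Chromosome",
    "Karyotype",
    "PaintSignal",
    "HomologyMap",
    "SyntenyState",
    "KNOWN_SPECIES",
    "register_species",
    "species_of_label",
    "read_homology_map",
    "write_homology_map",
    "read_karyotype",
    "count_segments",
    "validate_karyotype",
    "synteny_partition",
]

#: Species codes of the eight taxa analysed by painting (ingroup Phyllostomini
#: plus the Desmodontinae outgroup and the two probe-source species).  Codes
#: outside this registry must be registered before use.
KNOWN_SPECIES: set[str] = {"TSA", "LSI", "PDI", "PHA", "CBR", "DEC", "DRO", "DYO"}


def register_species(code: str) -> None:
    """Register an additional species code (e.g. for simulated taxa)."""
    if not code or not code.isalnum():
        raise ValueError(f"invalid species code: {code!r}")
    KNOWN_SPECIES.add(code.upper())


def species_of_label(label: str) -> str:
    """Species code encoded in a chromosome label such as ``'PHA-13'``."""
    code, sep, rest = label.partition("-")
    if not sep or not rest:
        raise ValueError(f"chromosome label {label!r} is not of the form CODE-NAME")
    return code.upper()


class Morphology(enum.Enum):
    """Gross chromosome morphology as seen in conventional staining."""

    METACENTRIC = "metacentric"
    SUBMETACENTRIC = "submetacentric"
    ACROCENTRIC = "acrocentric"
    ONE_ARMED = "one_armed"
    BI_ARMED = "bi_armed"
    UNKNOWN = "unknown"

    @property
    def arms(self) -> int | None:
        """Arm count contributed to FN: 2 (bi-armed), 1 (one-armed), None (unknown)."""
        if self in (Morphology.METACENTRIC, Morphology.SUBMETACENTRIC, Morphology.BI_ARMED):
            return 2
        if self in (Morphology.ACROCENTRIC, Morphology.ONE_ARMED):
            return 1
        return None


@dataclass(frozen=True)
class Chromosome:
    label: str
    morphology: Morphology = Morphology.UNKNOWN
    is_sex: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.morphology, str):  # accept plain strings from config files
            object.__setattr__(self, "morphology", Morphology(self.morphology))


@dataclass(frozen=True)
class Karyotype:
    """A species' chromosomal complement: 2n, FN and per-chromosome morphology."""

    species_code: str
    diploid_number: int
    fundamental_number: int
    autosome_pairs: tuple[Chromosome, ...]
    sex_system: tuple[Chromosome, ...] = ()

    @property
    def chromosomes(self) -> tuple[Chromosome, ...]:
        return self.autosome_pairs + self.sex_system

    def labels(self) -> set[str]:
        return {c.label for c in self.chromosomes}


def validate_karyotype(k: Karyotype) -> list[str]:
    """Check the 2n / FN arithmetic; return one message per violated invariant.

    An empty report means the karyotype is internally consistent.  Violations
    are reported, never raised: a partially described karyotype (unknown
    morphologies) simply yields an FN report entry if the arithmetic cannot
    close.
    """
    report: list[str] = []
    labels = [c.label for c in k.chromosomes]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        report.append(f"duplicate chromosome labels: {sorted(dupes)}")
    expected_2n = 2 * len(k.autosome_pairs) + 2
    if k.diploid_number != expected_2n:
        report.append(
            f"2n mismatch: declared 2n={k.diploid_number} but "
            f"{len(k.autosome_pairs)} autosome pairs imply 2n={expected_2n}"
        )
    arms = [c.morphology.arms for c in k.autosome_pairs]
    if any(a is None for a in arms):
        report.append("FN not checkable: some autosome morphologies are unknown")
    else:
        fn = 2 * sum(arms)  # both homologs of every autosome pair
        if fn != k.fundamental_number:
            report.append(
                f"FN mismatch: declared FN={k.fundamental_number} but autosome "
                f"morphologies imply FN={fn}"
            )
    for c in k.chromosomes:
        if c.morphology in (Morphology.METACENTRIC, Morphology.SUBMETACENTRIC) and c.morphology.arms != 2:
            report.append(f"{c.label}: metacentric/submetacentric must be bi-armed")
    return report


@dataclass(frozen=True)
class PaintSignal:
    """One probe's hybridization on one target chromosome.

    ``n_blocks`` counts discontiguous blocks of the same probe on that
    chromosome (two blocks separated by non-homologous material count as two
    segments, e.g. PHA-5 on TSA-6).
    """

    probe: str
    target: str
    n_blocks: int = 1
    region: str | None = None

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks} for {self.probe}/{self.target}")


@dataclass(frozen=True)
class HomologyMap:
    """All painting signals of one probe panel on one target species."""

    target_species: str
    probe_species: str
    signals: tuple[PaintSignal, ...]
    note: str | None = None  #: free-text caveat carried from the source (e.g. a count discrepancy)

    def __post_init__(self) -> None:
        for sp, kind in ((self.target_species, "target"), (self.probe_species, "probe")):
            if sp not in KNOWN_SPECIES:
                raise ValueError(f"unknown {kind} species code: {sp!r}")
        seen: set[tuple[str, str]] = set()
        for s in self.signals:
            if species_of_label(s.probe) != self.probe_species:
                raise ValueError(f"probe {s.probe!r} does not belong to {self.probe_species}")
            if species_of_label(s.target) != self.target_species:
                raise ValueError(f"target {s.target!r} does not belong to {self.target_species}")
            key = (s.probe, s.target)
            if key in seen:
                raise ValueError(f"duplicate (probe, target) pair: {key}")
            seen.add(key)

    @property
    def probes(self) -> list[str]:
        """Distinct probe labels, in first-appearance order."""
        out: list[str] = []
        for s in self.signals:
            if s.probe not in out:
                out.append(s.probe)
        return out


@dataclass(frozen=True)
class SyntenyState:
    """Grouping of reference units by target chromosome for one taxon.

    ``partition`` maps each target chromosome (with at least one signal) to
    the set of reference chromosome labels detected on it.  Groups are
    disjoint in target labels but one probe may appear in several groups
    (a syntenic disruption).
    """

    taxon: str
    partition: Mapping[str, frozenset[str]]

    def detected_units(self) -> frozenset[str]:
        out: set[str] = set()
        for group in self.partition.values():
            out |= group
        return frozenset(out)


def count_segments(homology_map: HomologyMap) -> int:
    """Total number of homologous segments revealed by the probe panel."""
    return sum(s.n_blocks for s in homology_map.signals)


def synteny_partition(homology_map: HomologyMap) -> SyntenyState:
    """Group reference units by the target chromosome carrying them."""
    groups: dict[str, set[str]] = {}
    for s in homology_map.signals:
        groups.setdefault(s.target, set()).add(s.probe)
    return SyntenyState(
        taxon=homology_map.target_species,
        partition={t: frozenset(g) for t, g in groups.items()},
    )


# ---------------------------------------------------------------------------
# I/O: homology-map TSV and karyotype config
# ---------------------------------------------------------------------------

_COLUMNS = ("probe", "target", "n_blocks", "region")


def read_homology_map(path: str | Path) -> HomologyMap:
    """Read a homology map from TSV (columns probe, target, n_blocks, region).

    Lines starting with ``#`` are comments; a leading comment of the form
    ``# note: ...`` is preserved on the returned map.  Species codes are taken
    from the label prefixes and must be consistent across rows.
    """
    path = Path(path)
    note_parts: list[str] = []
    rows: list[tuple[int, PaintSignal]] = []
    header: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                text = line.lstrip().lstrip("#").strip()
                if text.lower().startswith("note:"):
                    note_parts.append(text[5:].strip())
                continue
            fields = [f.strip() for f in line.split("\t")]
            if header is None:
                header = [f.lower() for f in fields]
                if header[: 2] != ["probe", "target"]:
                    raise ValueError(f"{path}:{lineno}: expected header starting 'probe\\ttarget', got {line!r}")
                continue
            row = dict(zip(header, fields))
            try:
                n_blocks = int(row.get("n_blocks") or 1)
                sig = PaintSignal(
                    probe=row["probe"],
                    target=row["target"],
                    n_blocks=n_blocks,
                    region=(row.get("region") or None),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            rows.append((lineno, sig))
    if header is None:
        raise ValueError(f"{path}: empty file (no header)")
    signals = tuple(sig for _, sig in rows)
    if signals:
        probe_species = species_of_label(signals[0].probe)
        target_species = species_of_label(signals[0].target)
    else:
        # species of an empty map are taken from the filename stem TARGET_PROBE
        parts = path.stem.upper().split("_")
        target_species, probe_species = (parts + ["", ""])[:2]
    try:
        return HomologyMap(
            target_species=target_species,
            probe_species=probe_species,
            signals=signals,
            note=" ".join(note_parts) or None,
        )
    except ValueError as exc:
        # attribute duplicate/validation failures to the offending row
        for lineno, sig in rows:
            try:
                HomologyMap(target_species, probe_species, tuple(s for _, s in rows[: rows.index((lineno, sig)) + 1]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
        raise


def write_homology_map(homology_map: HomologyMap, path: str | Path) -> None:
    """Write a homology map as TSV; inverse of :func:`read_homology_map`."""
    path = Path(path)
    lines: list[str] = []
    if homology_map.note:
        lines.append(f"# note: {homology_map.note}")
    lines.append("\t".join(_COLUMNS))
    for s in homology_map.signals:
        lines.append("\t".join([s.probe, s.target, str(s.n_blocks), s.region or ""]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_karyotype(path: str | Path, species: str | None = None) -> Karyotype | dict[str, Karyotype]:
    """Read karyotype definitions from a YAML config.

    The file maps species codes to ``{2n, fn, autosomes: [[label, morphology],
    ...], sex: [[label, morphology], ...]}``.  Returns a single karyotype when
    ``species`` is given, else a dict of all of them.
    """
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    out: dict[str, Karyotype] = {}
    for code, spec in data.items():
        autosomes = tuple(
            Chromosome(label=lab, morphology=Morphology(m)) for lab, m in spec.get("autosomes", [])
        )
        sex = tuple(
            Chromosome(label=lab, morphology=Morphology(m), is_sex=True) for lab, m in spec.get("sex", [])
        )
        out[code] = Karyotype(
            species_code=code,
            diploid_number=int(spec["2n"]),
            fundamental_number=int(spec["fn"]),
            autosome_pairs=autosomes,
            sex_system=sex,
        )
    if species is not None:
        return out[species]
    return out
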