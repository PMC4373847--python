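"""Loaders for the shipped painting fixtures.

The package ships the published cross-species painting tables for the tribe
Phyllostomini — *Tonatia saurophila* (TSA), *Lophostoma silvicola* (LSI) and
*Phyllostomus discolor* (PDI) painted with *Phyllostomus hastatus* (PHA) and
*Carollia brevicauda* (CBR) probe panels — plus the karyotype descriptions of
the painted species.

The LSI×CBR table is shipped with a documented discrepancy: the enumerated
signals sum to 25 segments while the source text states 26; the loader
surfaces this through the map's ``note`` field.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .karyomap import HomologyMap, Karyotype, read_homology_map, read_karyotype

__all__ = ["FIXTURE_NAMES", "fixture_path", "load_fixture", "load_all_fixtures", "load_karyotype"]

#: name -> packaged data file
FIXTURE_NAMES: dict[str, str] = {
    "TSA_PHA": "tsa_pha.tsv",
    "TSA_CBR": "tsa_cbr.tsv",
    "LSI_PHA": "lsi_pha.tsv",
    "LSI_CBR": "lsi_cbr.tsv",
    "PDI_PHA": "pdi_pha.tsv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a shipped fixture TSV (name like ``'TSA_PHA'``)."""
    try:
        fname = FIXTURE_NAMES[name.upper()]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choices: {sorted(FIXTURE_NAMES)}") from None
    return Path(str(resources.files("chromoclad.data").joinpath(fname)))


def load_fixture(name: str) -> HomologyMap:
    """Load one shipped homology map by ``TARGET_PROBE`` name."""
    return read_homology_map(fixture_path(name))


def load_all_fixtures() -> dict[str, HomologyMap]:
    return {name: load_fixture(name) for name in FIXTURE_NAMES}


def load_karyotype(species: str) -> Karyotype:
    """Load a shipped karyotype description (TSA, LSI, PDI or PHA)."""
    path = Path(str(resources.files("chromoclad.data").joinpath("karyotypes.yaml")))
    k = read_karyotype(path, species=species.upper())
    assert isinstance(k, Karyotype)
    return k
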