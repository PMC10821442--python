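"""Marker panel and categorical domain definitions.

The default panel mirrors a California-style newborn-screening (NBS) marker
set: 41 metabolites measured by MS/MS from dried blood spots (amino acids,
acylcarnitines, succinylacetone) plus five non-MS/MS markers (TRA, TSH, OHP,
IRT, TREC), 46 markers in total.  Three RUSP disorders are screened by
elevated levels of a single marker each: malonic acidemia (MAL, marker C3DC),
carnitine palmitoyltransferase II deficiency (CPT-II, marker C16), and
3-methylcrotonyl-CoA carboxylase deficiency (3MCC, marker C5OH).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ConfigError, ParseError

MARKER_CLASSES = ("acylcarnitine", "amino_acid", "other")


@dataclass(frozen=True)
class MarkerDef:
    """One marker of an NBS panel."""

    name: str
    marker_class: str  # one of MARKER_CLASSES
    disease: Optional[str] = None  # disease screened via this marker, if any
    rusp_flag: bool = False

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise ConfigError(
                f"marker {self.name!r}: unknown class {self.marker_class!r}"
            )


_AMINO_ACIDS = [
    "ALA", "ARG", "ASA", "CIT", "GLY", "LEU", "MET",
    "ORN", "PHE", "PRO", "TYR", "VAL",
]

_ACYLCARNITINES = [
    "C0", "C2", "C3", "C3DC", "C4", "C4DC", "C4OH", "C5", "C5:1", "C5DC",
    "C5OH", "C6", "C6DC", "C8", "C8:1", "C10", "C10:1", "C12", "C12:1",
    "C14", "C14:1", "C14OH", "C16", "C16:1", "C16OH", "C18", "C18:1", "C18:2",
]

_OTHER_MSMS = ["SA"]  # succinylacetone

_NON_MSMS = ["TRA", "TSH", "OHP", "IRT", "TREC"]

_DISEASE_MARKERS = {"C3DC": "MAL", "C16": "CPT-II", "C5OH": "3MCC"}

#: disease code -> marker name for the default panel
DISEASES = {v: k for k, v in _DISEASE_MARKERS.items()}

#: fixed priority used when one record exceeds several screening cutoffs
DISEASE_ORDER = ("MAL", "CPT-II", "3MCC")


def default_panel() -> list[MarkerDef]:
    """The 46-marker default panel (41 MS/MS metabolites + 5 other markers)."""
    panel = []
    for name in _AMINO_ACIDS:
        panel.append(MarkerDef(name, "amino_acid"))
    for name in _ACYLCARNITINES:
        panel.append(
            MarkerDef(
                name,
                "acylcarnitine",
                disease=_DISEASE_MARKERS.get(name),
                rusp_flag=name in _DISEASE_MARKERS,
            )
        )
    for name in _OTHER_MSMS + _NON_MSMS:
        panel.append(MarkerDef(name, "other"))
    return panel


def marker_names(panel: Iterable[MarkerDef]) -> list[str]:
    return [m.name for m in panel]


def validate_panel(panel: Sequence[MarkerDef]) -> None:
    """Check panel invariants: unique names, one marker per disease code."""
    names = marker_names(panel)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"duplicate marker names in panel: {dupes}")
    seen: dict[str, str] = {}
    for m in panel:
        if m.disease is not None:
            if m.disease in seen:
                raise ConfigError(
                    f"disease {m.disease!r} mapped to both "
                    f"{seen[m.disease]!r} and {m.name!r}"
                )
            seen[m.disease] = m.name


def disease_marker(panel: Sequence[MarkerDef], disease: str) -> MarkerDef:
    for m in panel:
        if m.disease == disease:
            return m
    raise ConfigError(f"no marker in panel screens disease {disease!r}")


# --- parent-reported ethnicity ------------------------------------------------

#: the 17 detailed parent-reported ethnicity categories
ETHNICITY_CODES = (
    "Asian East Indian", "Black", "Cambodian", "Chinese", "Filipino",
    "Guamanian", "Hawaiian", "Hispanic", "Japanese", "Korean", "Laos",
    "Middle Eastern", "Native American", "Other Southeast Asian", "Samoan",
    "Vietnamese", "White",
)

#: detailed code -> one of the four major groups used in stratified analyses;
#: Pacific Islander and Native American categories have no major group and are
#: excluded from major-group analyses (configurable at call sites).
MAJOR_GROUP_MAP = {
    "Asian East Indian": "Asian",
    "Cambodian": "Asian",
    "Chinese": "Asian",
    "Filipino": "Asian",
    "Japanese": "Asian",
    "Korean": "Asian",
    "Laos": "Asian",
    "Other Southeast Asian": "Asian",
    "Vietnamese": "Asian",
    "Black": "Black",
    "Hispanic": "Hispanic",
    "White": "White",
    "Middle Eastern": "White",
    # Guamanian, Hawaiian, Samoan, Native American: no major group
}

MAJOR_GROUPS = ("Asian", "Black", "Hispanic", "White")


def major_group(code: str) -> Optional[str]:
    """Major ethnicity group for a detailed code, or None if unmapped."""
    return MAJOR_GROUP_MAP.get(code)


# --- panel IO -----------------------------------------------------------------

_PANEL_COLUMNS = ["name", "marker_class", "disease", "rusp_flag"]


def write_panel(panel: Sequence[MarkerDef], path) -> None:
    df = pd.DataFrame(
        {
            "name": [m.name for m in panel],
            "marker_class": [m.marker_class for m in panel],
            "disease": [m.disease if m.disease else "NA" for m in panel],
            "rusp_flag": [str(m.rusp_flag).lower() for m in panel],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> list[MarkerDef]:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"panel file missing columns: {missing}")
    panel = []
    for i, row in df.iterrows():
        try:
            panel.append(
                MarkerDef(
                    name=row["name"],
                    marker_class=row["marker_class"],
                    disease=None if row["disease"] in ("", "NA") else row["disease"],
                    rusp_flag=row["rusp_flag"].strip().lower() in ("true", "1", "yes"),
                )
            )
        except ConfigError as exc:
            raise ParseError(f"panel row {i + 2}: {exc}") from exc
    validate_panel(panel)
    return panel
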