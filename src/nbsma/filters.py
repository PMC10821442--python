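"""Cohort exclusion filters and derived classifications.

Core exclusion rules (applied in order; a removed record is attributed to
the lowest-numbered failing rule):

R1  birth weight < 1000 g or > 5000 g
R2  gestational age unknown, < 28 or > 42 weeks
R3  age at blood collection unknown, < 12 h or > 168 h
R4  TPN status unknown or positive
R5  transfusion status unknown or positive
R6  maternal age < 15 or > 44 years

Boundary values are retained (the rule text is read strictly, e.g. BW in
[1000, 5000] g survives R1).  The ethnicity filter (E1 multiple codes, E2
unknown) and the false-positive-analysis restriction (FP1: BW 2500-4000 g
and GA 37-42 weeks, layered on the core filters) follow the same reporting
convention.  Membership of the retained set never depends on rule order;
only the attribution of removals does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .simulate import n_ethnicities


@dataclass
class FilterReport:
    n_input: int
    n_output: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_output + sum(self.removed_by_rule.values()) == self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "removed_by_rule": dict(self.removed_by_rule),
        }


def _violates_r1(df: pd.DataFrame) -> np.ndarray:
    bw = df["bw_grams"].to_numpy()
    return (bw < 1000) | (bw > 5000)


def _violates_r2(df: pd.DataFrame) -> np.ndarray:
    ga = df["ga_weeks"].to_numpy(dtype=float)
    return np.isnan(ga) | (ga < 28) | (ga > 42)


def _violates_r3(df: pd.DataFrame) -> np.ndarray:
    aabc = df["aabc_hours"].to_numpy(dtype=float)
    return np.isnan(aabc) | (aabc < 12) | (aabc > 168)


def _violates_r4(df: pd.DataFrame) -> np.ndarray:
    return (df["tpn"] != "negative").to_numpy()


def _violates_r5(df: pd.DataFrame) -> np.ndarray:
    return (df["transfusion"] != "negative").to_numpy()


def _violates_r6(df: pd.DataFrame) -> np.ndarray:
    ma = df["ma_years"].to_numpy()
    return (ma < 15) | (ma > 44)


CORE_RULES: list[tuple[str, Callable[[pd.DataFrame], np.ndarray]]] = [
    ("R1", _violates_r1),
    ("R2", _violates_r2),
    ("R3", _violates_r3),
    ("R4", _violates_r4),
    ("R5", _violates_r5),
    ("R6", _violates_r6),
]


def _apply_rules(records: pd.DataFrame,
                 rules: Sequence[tuple[str, Callable]]) -> tuple[pd.DataFrame, FilterReport]:
    removed_by_rule: dict[str, int] = {}
    unattributed = np.ones(len(records), dtype=bool)
    for rule_id, violates in rules:
        hit = violates(records) & unattributed
        removed_by_rule[rule_id] = int(hit.sum())
        unattributed &= ~hit
    retained = records.loc[unattributed].reset_index(drop=True)
    return retained, FilterReport(len(records), len(retained), removed_by_rule)


def apply_core_filters(records: pd.DataFrame,
                       skip_rules: Sequence[str] = ()) -> tuple[pd.DataFrame, FilterReport]:
    """Apply exclusion rules R1-R6 (optionally skipping some, e.g. R5 for
    false-positive case records whose transfusion status is unavailable)."""
    rules = [(rid, fn) for rid, fn in CORE_RULES if rid not in skip_rules]
    return _apply_rules(records, rules)


def classify_term(ga_weeks):
    """``"preterm"`` iff GA <= 36 weeks, ``"term"`` iff GA >= 37 weeks.

    Accepts a scalar or an array/Series; GA must be known and within 28-42
    weeks (call after the core filters).
    """
    ga = np.asarray(ga_weeks, dtype=float)
    if np.isnan(ga).any() or (ga < 28).any() or (ga > 42).any():
        raise DegenerateInputError("classify_term requires known GA in 28-42 weeks")
    out = np.where(ga <= 36, "preterm", "term")
    return out.item() if np.isscalar(ga_weeks) else out


def apply_ethnicity_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Retain records with exactly one detailed ethnicity code.

    E1 removes multiple-ethnicity records, E2 removes unknown-ethnicity ones.
    """
    n_codes = n_ethnicities(records).to_numpy()
    return _apply_rules(records, [
        ("E1", lambda df: n_codes > 1),
        ("E2", lambda df: n_codes == 0),
    ])


def _violates_fp1(df: pd.DataFrame) -> np.ndarray:
    bw = df["bw_grams"].to_numpy()
    ga = df["ga_weeks"].to_numpy(dtype=float)
    return (bw < 2500) | (bw > 4000) | np.isnan(ga) | (ga < 37) | (ga > 42)


def apply_fp_analysis_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Restrict to normal birth weight (2500-4000 g) term (37-42 w) infants.

    Layered on the core filters (rule FP1); for false-positive case records
    the caller should have run :func:`apply_core_filters` with R5 skipped,
    since transfusion status is unavailable for them.
    """
    return _apply_rules(records, [("FP1", _violates_fp1)])
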