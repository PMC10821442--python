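"""False-positive enrichment analysis in the advanced maternal-age group.

For each disorder, the number of false-positive (FP) cases with maternal age
>= 35 years is compared with the count expected if FP cases were distributed
like screen-negative infants: expected = n_fp_total x p_advanced, where
p_advanced is the screen-negative proportion in the advanced group.  The
comparison uses a Pearson chi-squared test (no continuity correction) on the
2 x 2 table of (FP / screen-negative) x (advanced / not advanced).  A
sensitivity variant excludes FP cases sampled before 24 h of age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .effects import DEFAULT_SCHEME, MAGroupScheme
from .errors import DegenerateInputError
from .simulate import fp_label


@dataclass
class FPAnalysisResult:
    disease: str
    marker: str
    n_fp_total: int
    n_fp_advanced: int
    p_advanced: float
    expected_float: float
    expected_rounded: int
    chi2: Optional[float] = None
    p_value: Optional[float] = None
    aabc_restricted: bool = False
    low_expected_cell: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "disease", "marker", "n_fp_total", "n_fp_advanced", "p_advanced",
            "expected_float", "expected_rounded", "chi2", "p_value",
            "aabc_restricted", "low_expected_cell",
        )}


def round_half_away(x: float) -> int:
    """Round halves away from zero (34.5 -> 35, -34.5 -> -35)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def advanced_proportion(screen_negatives: pd.DataFrame,
                        scheme: MAGroupScheme = DEFAULT_SCHEME) -> float:
    """Fraction of screen-negative records with MA >= the advanced threshold."""
    if len(screen_negatives) == 0:
        raise DegenerateInputError("no screen-negative records")
    ma = screen_negatives["ma_years"].to_numpy()
    return float((ma >= scheme.advanced_min).mean())


def expected_vs_observed(fp_records: pd.DataFrame, disease: str,
                         p_advanced: float, marker: str = "",
                         scheme: MAGroupScheme = DEFAULT_SCHEME,
                         ) -> FPAnalysisResult:
    """Observed and expected advanced-MA counts among FP cases of one disease."""
    label = fp_label(disease)
    cases = fp_records[fp_records["screen_label"] == label]
    n_total = len(cases)
    if n_total == 0:
        raise DegenerateInputError(f"no false-positive records for {disease}")
    n_advanced = int((cases["ma_years"].to_numpy() >= scheme.advanced_min).sum())
    expected = n_total * p_advanced
    return FPAnalysisResult(
        disease=disease, marker=marker, n_fp_total=n_total,
        n_fp_advanced=n_advanced, p_advanced=p_advanced,
        expected_float=expected, expected_rounded=round_half_away(expected),
    )


def chi2_2x2(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared (two-sided) on a 2 x 2 contingency table."""
    chi2, p, _, expected = stats.chi2_contingency(np.asarray(table),
                                                  correction=correction)
    return float(chi2), float(p)


def fp_enrichment_test(result: FPAnalysisResult, n_sn_advanced: int,
                       n_sn_total: int,
                       correction: bool = False) -> FPAnalysisResult:
    """Complete an FP result with the 2 x 2 chi-squared test.

    Table rows are (FP, screen-negative), columns (advanced, not advanced).
    An expected cell below 5 attaches a warning flag; the test still runs.
    """
    if min(result.n_fp_total, n_sn_total) <= 0:
        raise DegenerateInputError("both FP and screen-negative counts must be positive")
    table = np.array([
        [result.n_fp_advanced, result.n_fp_total - result.n_fp_advanced],
        [n_sn_advanced, n_sn_total - n_sn_advanced],
    ], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    low = bool((expected < 5).any())
    if low:
        warnings.warn(f"{result.disease}: an expected cell is below 5")
    chi2, p = chi2_2x2(table, correction=correction)
    return replace(result, chi2=chi2, p_value=p, low_expected_cell=low)


def fp_analysis(fp_records: pd.DataFrame, screen_negatives: pd.DataFrame,
                disease: str, marker: str = "",
                scheme: MAGroupScheme = DEFAULT_SCHEME,
                correction: bool = False) -> FPAnalysisResult:
    """Expected-vs-observed counts plus chi-squared test for one disease."""
    p_adv = advanced_proportion(screen_negatives, scheme)
    result = expected_vs_observed(fp_records, disease, p_adv, marker=marker,
                                  scheme=scheme)
    ma = screen_negatives["ma_years"].to_numpy()
    n_sn_advanced = int((ma >= scheme.advanced_min).sum())
    return fp_enrichment_test(result, n_sn_advanced, len(screen_negatives),
                              correction=correction)


def aabc_sensitivity(fp_records: pd.DataFrame, screen_negatives: pd.DataFrame,
                     disease: str, marker: str = "",
                     min_hours: float = 24.0,
                     scheme: MAGroupScheme = DEFAULT_SCHEME,
                     restrict_denominator: bool = True,
                     correction: bool = False) -> FPAnalysisResult:
    """Re-run the FP analysis excluding FP cases with AaBC < ``min_hours``.

    By default the screen-negative denominator is restricted to the same
    AaBC range for symmetry; ``restrict_denominator=False`` keeps the full
    screen-negative proportion.
    """
    aabc = fp_records["aabc_hours"].to_numpy(dtype=float)
    kept = fp_records.loc[~np.isnan(aabc) & (aabc >= min_hours)]
    sn = screen_negatives
    if restrict_denominator:
        sn_aabc = sn["aabc_hours"].to_numpy(dtype=float)
        sn = sn.loc[~np.isnan(sn_aabc) & (sn_aabc >= min_hours)]
    result = fp_analysis(kept, sn, disease, marker=marker, scheme=scheme,
                         correction=correction)
    return replace(result, aabc_restricted=True)
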