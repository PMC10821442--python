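"""Association tests between maternal age and other covariates, and smoothed
marker-level trend curves over maternal age.

Tests: Welch two-sample t-test of mean MA by infant sex; one-way ANOVA of MA
across ethnicity groups (major or detailed); Pearson chi-squared homogeneity
test (no continuity correction) of the preterm proportion across the six MA
groups.  Trend curves are regression-spline fits (OLS on a cubic B-spline
basis) of marker level on MA per stratum, with a pointwise 95% confidence
band for the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .effects import DEFAULT_SCHEME, MAGroupScheme, assign_ma_group
from .errors import DegenerateInputError
from .filters import classify_term
from .panel import MAJOR_GROUP_MAP
from .simulate import n_ethnicities


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test: str
    df: Optional[float] = None

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic,
                "p_value": self.p_value, "df": self.df}


def ma_by_sex_test(records: pd.DataFrame) -> TestResult:
    """Welch t-test of mean maternal age between male and female infants."""
    ma = records["ma_years"].to_numpy(dtype=float)
    male = ma[(records["sex"] == "male").to_numpy()]
    female = ma[(records["sex"] == "female").to_numpy()]
    if len(male) < 2 or len(female) < 2:
        raise DegenerateInputError("both sexes must be present with n >= 2")
    t, p = stats.ttest_ind(male, female, equal_var=False)
    return TestResult(float(t), float(p), "welch_t")


def _ethnicity_groups(records: pd.DataFrame, grouping: str) -> pd.Series:
    single = n_ethnicities(records) == 1
    eth = records.loc[single, "ethnicity"]
    if grouping == "detailed":
        return eth
    if grouping == "major":
        mapped = eth.map(MAJOR_GROUP_MAP)
        return mapped.dropna()
    raise DegenerateInputError(f"unknown grouping {grouping!r}")


def ma_by_ethnicity_anova(records: pd.DataFrame,
                          grouping: str = "major") -> TestResult:
    """One-way ANOVA of maternal age across ethnicity groups.

    Groups with fewer than 2 records are dropped with a warning; single-
    ethnicity records only (multiple/unknown are excluded upstream).
    """
    groups = _ethnicity_groups(records, grouping)
    ma = records.loc[groups.index, "ma_years"].to_numpy(dtype=float)
    samples = []
    for g in sorted(groups.unique()):
        vals = ma[(groups == g).to_numpy()]
        if len(vals) < 2:
            warnings.warn(f"dropping ethnicity group {g!r} with n={len(vals)}")
            continue
        samples.append(vals)
    if len(samples) < 2:
        raise DegenerateInputError("ANOVA needs >= 2 groups with n >= 2")
    f, p = stats.f_oneway(*samples)
    return TestResult(float(f), float(p), "anova")


def group_mean_ma(records: pd.DataFrame, grouping: str = "detailed") -> pd.Series:
    """Mean maternal age per ethnicity group (single-ethnicity records)."""
    groups = _ethnicity_groups(records, grouping)
    ma = records.loc[groups.index, "ma_years"]
    return ma.groupby(groups.to_numpy()).mean()


def preterm_proportion_test(records: pd.DataFrame,
                            scheme: MAGroupScheme = DEFAULT_SCHEME,
                            ) -> tuple[TestResult, np.ndarray]:
    """Homogeneity of the preterm proportion across the six MA groups.

    Pearson chi-squared on the 2 x k (preterm/term x MA group) table without
    continuity correction; also returns the per-group preterm proportions.
    """
    idx = assign_ma_group(records["ma_years"].to_numpy(), scheme)
    term = classify_term(records["ga_weeks"].to_numpy(dtype=float))
    k = len(scheme.bands)
    table = np.zeros((2, k), dtype=int)
    for g in range(k):
        in_g = idx == g
        if not in_g.any():
            raise DegenerateInputError(
                f"MA group {scheme.band_label(g)} has no records"
            )
        table[0, g] = int((term[in_g] == "preterm").sum())
        table[1, g] = int((term[in_g] == "term").sum())
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    proportions = table[0] / table.sum(axis=0)
    return TestResult(float(chi2), float(p), "chi2_homogeneity", df=float(dof)), proportions


@dataclass
class TrendCurve:
    marker: str
    stratum: str
    ma_grid: np.ndarray
    mean_curve: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.marker, "stratum": self.stratum,
            "ma_years": self.ma_grid, "mean": self.mean_curve,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def _strata(records: pd.DataFrame, stratify_by: Optional[str]) -> dict[str, np.ndarray]:
    n = len(records)
    if stratify_by is None:
        return {"all": np.ones(n, dtype=bool)}
    if stratify_by == "sex":
        return {s: (records["sex"] == s).to_numpy() for s in ("male", "female")}
    if stratify_by == "term":
        term = classify_term(records["ga_weeks"].to_numpy(dtype=float))
        return {s: term == s for s in ("term", "preterm")}
    if stratify_by == "ethnicity":
        single = (n_ethnicities(records) == 1).to_numpy()
        major = records["ethnicity"].map(lambda e: MAJOR_GROUP_MAP.get(e, ""))
        return {
            g: single & (major == g).to_numpy()
            for g in ("Asian", "Black", "Hispanic", "White")
        }
    raise DegenerateInputError(f"unknown stratification {stratify_by!r}")


MIN_STRATUM_SIZE = 30


def trend_curve(records: pd.DataFrame, marker: str,
                stratify_by: Optional[str] = None, spline_df: int = 6,
                grid: Optional[np.ndarray] = None) -> list[TrendCurve]:
    """Smoothed mean marker level versus maternal age, per stratum.

    Fits an OLS regression on a cubic B-spline basis in MA (``spline_df``
    degrees of freedom) and evaluates the mean and its pointwise 95%
    confidence band on an integer MA grid.  Strata below
    :data:`MIN_STRATUM_SIZE` records are skipped with a warning.
    """
    import statsmodels.formula.api as smf

    curves = []
    for label, mask in _strata(records, stratify_by).items():
        sub = records.loc[mask, ["ma_years", marker]].rename(
            columns={marker: "level"}
        )
        if len(sub) < MIN_STRATUM_SIZE:
            warnings.warn(f"stratum {label!r} below {MIN_STRATUM_SIZE} records; skipped")
            continue
        lo, hi = int(sub["ma_years"].min()), int(sub["ma_years"].max())
        g = np.arange(lo, hi + 1) if grid is None else np.asarray(grid)
        # cap spline df so the design stays well-posed on narrow age ranges
        df_eff = min(spline_df, max(3, len(sub["ma_years"].unique()) - 1))
        model = smf.ols(f"level ~ bs(ma_years, df={df_eff})", data=sub).fit()
        pred = model.get_prediction(pd.DataFrame({"ma_years": g}))
        frame = pred.summary_frame(alpha=0.05)
        curves.append(TrendCurve(
            marker=marker, stratum=label, ma_grid=g,
            mean_curve=frame["mean"].to_numpy(),
            ci_low=frame["mean_ci_lower"].to_numpy(),
            ci_high=frame["mean_ci_upper"].to_numpy(),
        ))
    return curves
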