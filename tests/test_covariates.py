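import math

import numpy as np
import pytest

import nbsma
from nbsma import DegenerateInputError
from nbsma.covariates import (
    group_mean_ma,
    ma_by_ethnicity_anova,
    ma_by_sex_test,
    preterm_proportion_test,
    trend_curve,
)
from nbsma.simulate import SimConfig

from conftest import make_records, one_marker_config, tiny_panel


def welch_oracle(a, b):
    ma_, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    return (ma_ - mb) / math.sqrt(va / len(a) + vb / len(b))


def anova_oracle(*groups):
    grand = np.mean(np.concatenate(groups))
    k = len(groups)
    n = sum(len(g) for g in groups)
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def chi2_oracle(table):
    table = np.asarray(table, dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return ((table - expected) ** 2 / expected).sum()


def test_welch_t_matches_hand_computation():
    male_ma = [25, 31, 29, 35, 22]
    female_ma = [30, 28, 33, 26, 27]
    records = make_records(10, ma_years=male_ma + female_ma,
                           sex=["male"] * 5 + ["female"] * 5)
    result = ma_by_sex_test(records)
    assert result.statistic == pytest.approx(welch_oracle(male_ma, female_ma),
                                             abs=1e-10)


def test_sex_shift_detected():
    """A planted 2-year mean MA difference at n = 10,000 per sex is
    overwhelmingly significant."""
    rng = np.random.default_rng(31)
    n = 10_000
    ma = np.concatenate([
        np.round(rng.normal(31, 6, n)), np.round(rng.normal(29, 6, n)),
    ]).astype(int)
    records = make_records(2 * n, ma_years=ma,
                           sex=["male"] * n + ["female"] * n)
    assert ma_by_sex_test(records).p_value < 1e-3


def test_sex_null_is_calibrated():
    rng = np.random.default_rng(5)
    n = 50_000
    records = make_records(
        n,
        ma_years=np.round(rng.normal(29, 6, n)).astype(int),
        sex=list(rng.choice(["male", "female"], size=n)),
    )
    assert abs(ma_by_sex_test(records).statistic) < 3


def test_anova_matches_hand_computation():
    groups = {"Hispanic": [25, 27, 29], "White": [31, 30, 35], "Black": [22, 26, 24]}
    ma, eth = [], []
    for code, vals in groups.items():
        ma += vals
        eth += [code] * len(vals)
    records = make_records(9, ma_years=ma, ethnicity=eth)
    result = ma_by_ethnicity_anova(records, grouping="detailed")
    assert result.statistic == pytest.approx(anova_oracle(*groups.values()),
                                             abs=1e-10)


def test_anova_drops_tiny_groups():
    records = make_records(7, ma_years=[25, 26, 30, 31, 29, 33, 40],
                           ethnicity=["Hispanic"] * 3 + ["White"] * 3 + ["Black"])
    with pytest.warns(UserWarning, match="Black"):
        result = ma_by_ethnicity_anova(records, grouping="detailed")
    assert np.isfinite(result.statistic)


def test_ethnicity_mean_ma_recovery():
    """Planted Korean/Japanese maternal-age offsets are recovered to 0.2 y."""
    cfg = SimConfig(
        seed=41, n_total=30_000, panel=tiny_panel("C16"),
        effect_curves={}, covariate_effects={},
        distribution_family="normal",
        ethnicity_weights={"Korean": 0.3, "Japanese": 0.3, "Hispanic": 0.4},
        frac_multi_ethnicity=0.0, frac_unknown_ethnicity=0.0,
    )
    cohort = nbsma.generate_cohort(cfg)
    means = group_mean_ma(cohort, grouping="detailed")
    assert means["Korean"] == pytest.approx(33.9, abs=0.2)
    assert means["Japanese"] == pytest.approx(35.1, abs=0.2)
    result = ma_by_ethnicity_anova(cohort, grouping="detailed")
    assert result.p_value < 1e-3


def test_preterm_chi2_matches_hand_computation():
    ma = [17, 17, 17, 22, 22, 27, 27, 32, 32, 37, 37, 42, 42]
    ga = [34.0, 39.0, 39.0, 39.0, 39.0, 34.0, 39.0, 39.0, 39.0,
          34.0, 39.0, 39.0, 34.0]
    records = make_records(13, ma_years=ma, ga_weeks=ga)
    result, proportions = preterm_proportion_test(records)
    table = np.zeros((2, 6))
    for m, g in zip(ma, ga):
        col = (m - 15) // 5
        table[0 if g <= 36 else 1, col] += 1
    assert result.statistic == pytest.approx(chi2_oracle(table), abs=1e-10)
    assert proportions[0] == pytest.approx(1 / 3)


def test_preterm_u_shape_minimum_recovered():
    """With planted U-shaped preterm probabilities (minimum at 20-24 years),
    the estimated proportion vector finds the minimum there."""
    probs = [0.09, 0.05, 0.06, 0.07, 0.08, 0.10]
    hits = 0
    for seed in range(20):
        cfg = one_marker_config(
            seed=seed, n_total=100_000,
            preterm_prob_by_ma_group={"default": probs},
        )
        cohort = nbsma.generate_cohort(cfg)
        kept, _ = nbsma.apply_core_filters(cohort)
        _, proportions = preterm_proportion_test(kept)
        hits += int(np.argmin(proportions)) == 1
    assert hits >= 19


def test_empty_group_raises():
    records = make_records(3, ma_years=[17, 22, 27])
    with pytest.raises(DegenerateInputError):
        preterm_proportion_test(records)


@pytest.mark.parametrize("test_fn, build", [
    ("sex", None), ("anova", None), ("preterm", None),
])
def test_type_I_error_calibration(test_fn, build):
    """Under the null each test rejects at the 5% level for 5% +/- 2% of
    replicates (1,000 replicates of small synthetic strata)."""
    rng = np.random.default_rng(99)
    n_reps = 1_000
    rejections = 0
    for _ in range(n_reps):
        if test_fn == "sex":
            n = 120
            records = make_records(
                n, ma_years=rng.normal(29, 6, n).round().astype(int),
                sex=list(rng.choice(["male", "female"], size=n)),
            )
            p = ma_by_sex_test(records).p_value
        elif test_fn == "anova":
            n = 120
            records = make_records(
                n, ma_years=rng.normal(29, 6, n).round().astype(int),
                ethnicity=list(rng.choice(["Hispanic", "White", "Black", "Chinese"],
                                          size=n)),
            )
            p = ma_by_ethnicity_anova(records, grouping="detailed").p_value
        else:
            n = 600
            ma = np.repeat([17, 22, 27, 32, 37, 42], n // 6)
            ga = np.where(rng.random(n) < 0.3, 34.0, 39.0)
            records = make_records(n, ma_years=ma, ga_weeks=list(ga))
            p = preterm_proportion_test(records)[0].p_value
        rejections += p < 0.05
    assert 0.03 <= rejections / n_reps <= 0.07


def trend_records(mean_fn, n_per_age=40, sd=1.0, seed=0, marker="C16"):
    rng = np.random.default_rng(seed)
    ages = np.repeat(np.arange(15, 45), n_per_age)
    levels = mean_fn(ages) + rng.normal(0, sd, len(ages))
    return make_records(len(ages), panel=tiny_panel(marker),
                        ma_years=ages, **{marker: levels})


def test_trend_flat_signal_stays_flat():
    records = trend_records(lambda a: np.full(len(a), 5.0), seed=1)
    [curve] = trend_curve(records, "C16")
    se = 1.0 / np.sqrt(40)
    assert curve.mean_curve.max() - curve.mean_curve.min() < 3 * se
    assert (curve.ci_low <= curve.mean_curve).all()
    assert (curve.mean_curve <= curve.ci_high).all()


def test_trend_linear_truth_within_band():
    """For a linear mean the fitted curve covers the truth at >= 90% of
    grid points (regression-spline estimator contract)."""
    records = trend_records(lambda a: 0.1 * a, seed=2)
    [curve] = trend_curve(records, "C16")
    truth = 0.1 * curve.ma_grid
    covered = (curve.ci_low <= truth) & (truth <= curve.ci_high)
    assert covered.mean() >= 0.9


def test_trend_monotone_then_plateau():
    def mean_fn(a):
        return np.minimum(a, 35.0) * 0.2

    records = trend_records(mean_fn, seed=3, sd=0.5)
    [curve] = trend_curve(records, "C16")
    rising = curve.mean_curve[curve.ma_grid <= 33]
    assert (np.diff(rising) > 0).mean() > 0.8
    plateau = curve.mean_curve[curve.ma_grid >= 36]
    assert plateau.max() - plateau.min() < 0.5


def test_trend_monotone_decreasing():
    records = trend_records(lambda a: -0.15 * a, seed=4, sd=0.5,
                            marker="C5OH")
    [curve] = trend_curve(records, "C5OH")
    assert (np.diff(curve.mean_curve) < 0).mean() > 0.9


def test_trend_affine_equivariance():
    records = trend_records(lambda a: 0.1 * a, seed=6)
    [base] = trend_curve(records, "C16")
    scaled = records.copy()
    scaled["C16"] = 3.0 * scaled["C16"] + 7.0
    [other] = trend_curve(scaled, "C16")
    np.testing.assert_allclose(other.mean_curve, 3.0 * base.mean_curve + 7.0,
                               rtol=1e-8)


def test_trend_small_stratum_skipped():
    records = trend_records(lambda a: 0.1 * a, n_per_age=2, seed=7)
    records = records.iloc[:20]
    with pytest.warns(UserWarning, match="skipped"):
        curves = trend_curve(records, "C16", stratify_by="sex")
    assert curves == [] or all(c.stratum in ("male", "female") for c in curves)
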