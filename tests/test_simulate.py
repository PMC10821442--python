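import numpy as np
import pandas as pd
import pytest

import nbsma
from nbsma import ConfigError, ParseError, SimConfig
from nbsma.simulate import (
    SCREEN_NEGATIVE,
    fp_label,
    generate_fp_labels,
    n_ethnicities,
    read_cohort,
    write_cohort,
)

from conftest import make_records, one_marker_config, tiny_panel


def test_determinism_bit_identical(tmp_path):
    """Identical seed and config give byte-identical cohort tables."""
    cfg = one_marker_config(seed=42, n_total=2_000)
    a = nbsma.generate_cohort(cfg)
    b = nbsma.generate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(a, pa)
    write_cohort(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_no_planted_effect_groups_agree():
    """Without planted shifts, advanced and baseline marker means agree."""
    cfg = one_marker_config(seed=5)
    cohort = nbsma.generate_two_group_cohort(cfg, 5_000, 5_000)
    adv = cohort[cohort["ma_years"] >= 35]["C16"]
    base = cohort[cohort["ma_years"] <= 19]["C16"]
    se = np.sqrt(adv.var() / len(adv) + base.var() / len(base))
    assert abs(adv.mean() - base.mean()) < 4 * se


@pytest.mark.parametrize("delta", [-0.5, -0.2, 0.0, 0.2, 0.5])
def test_planted_shift_recovery(delta):
    """Planted standardized shifts are recovered as Cohen's d, unbiased.

    50 seeds at 10,000 records per group: the per-seed d stays within
    3 standard errors of the planted value for all but stray seeds, and the
    seed-averaged d is within the correspondingly tighter bound.
    """
    n = 10_000
    cfg = one_marker_config(
        effect_curves={"C16": [0, 0, 0, 0, delta, delta]},
    )
    se = np.sqrt(1 / n + 1 / n)
    ds = []
    for seed in range(50):
        cohort = nbsma.generate_two_group_cohort(cfg, n, n, seed=seed)
        result = nbsma.advanced_vs_baseline(cohort, cfg.panel)
        ds.append(result.values.loc["C16", "advanced"])
    ds = np.asarray(ds)
    assert (np.abs(ds - delta) < 3 * se).sum() >= 48
    assert abs(ds.mean() - delta) < 3 * se / np.sqrt(50)


def test_ethnicity_marginals_within_binomial_bounds():
    """Realized multiple/unknown-ethnicity fractions match the config."""
    n = 20_000
    cfg = SimConfig(seed=11, n_total=n, panel=tiny_panel("C16"),
                    effect_curves={}, covariate_effects={},
                    distribution_family="normal")
    cohort = nbsma.generate_cohort(cfg)
    counts = n_ethnicities(cohort)
    for frac, observed in [
        (cfg.frac_multi_ethnicity, (counts > 1).sum()),
        (cfg.frac_unknown_ethnicity, (counts == 0).sum()),
    ]:
        bound = 2.576 * np.sqrt(n * frac * (1 - frac))
        assert abs(observed - n * frac) < bound


def test_unreachable_cutoff_yields_no_fp():
    cfg = one_marker_config(seed=1, n_total=1_000)
    cohort = nbsma.generate_cohort(cfg)
    labelled = generate_fp_labels(cohort, cfg.panel, {"CPT-II": np.inf})
    assert (labelled["screen_label"] == SCREEN_NEGATIVE).all()


def test_fp_count_matches_direct_scan():
    """FP labelling equals a brute-force strict-threshold scan (ties negative)."""
    cfg = one_marker_config(seed=2, n_total=10_000)
    cohort = nbsma.generate_cohort(cfg)
    cutoff = float(np.quantile(cohort["C16"], 0.99))
    labelled = generate_fp_labels(cohort, cfg.panel, {"CPT-II": cutoff})
    expected = int((cohort["C16"].to_numpy() > cutoff).sum())
    assert (labelled["screen_label"] == fp_label("CPT-II")).sum() == expected


def test_multi_cutoff_priority_order():
    panel = tiny_panel("C3DC", "C16")
    records = make_records(1, panel=panel, C3DC=10.0, C16=10.0)
    labelled = generate_fp_labels(records, panel, {"CPT-II": 1.0, "MAL": 1.0})
    # MAL precedes CPT-II in the documented disease order
    assert labelled["screen_label"].iloc[0] == fp_label("MAL")


def test_planted_shift_enriches_fp_in_advanced_group():
    """A positive advanced-group shift makes the disease marker's FP cases
    over-represent advanced maternal ages (majority direction over seeds)."""
    cfg = one_marker_config("C3DC",
                            effect_curves={"C3DC": [0, 0, 0, 0, 0.22, 0.22]})
    wins = 0
    for seed in range(20):
        cohort = nbsma.generate_two_group_cohort(cfg, 5_000, 5_000, seed=seed)
        baseline = cohort[cohort["ma_years"] <= 19]["C3DC"]
        cutoff = float(np.quantile(baseline, 0.995))
        labelled = generate_fp_labels(cohort, cfg.panel, {"MAL": cutoff})
        is_fp = labelled["screen_label"] == fp_label("MAL")
        if is_fp.sum() == 0:
            continue
        advanced = labelled["ma_years"] >= 35
        fp_share = advanced[is_fp].mean()
        sn_share = advanced[~is_fp].mean()
        wins += fp_share > sn_share
    assert wins > 10


def test_round_trip_identity(tmp_path):
    cfg = SimConfig(seed=3, n_total=1_000, panel=tiny_panel("C16", "C5OH"),
                    effect_curves={}, covariate_effects={})
    cohort = nbsma.generate_cohort(cfg)
    path = tmp_path / "cohort.csv"
    write_cohort(cohort, path)
    back = read_cohort(path, cfg.panel)
    pd.testing.assert_frame_equal(back, cohort.reset_index(drop=True))


def test_handcrafted_table_parses(tmp_path):
    panel = tiny_panel("C16")
    text = (
        "id,ma_years,ga_weeks,bw_grams,aabc_hours,sex,ethnicity,tpn,"
        "transfusion,screen_label,C16\n"
        "a,30,39,3200,24.5,male,Hispanic,negative,negative,screen_negative,1.5\n"
        "b,17,NA,2900,NA,female,Chinese;White,U,negative,screen_negative,0.8\n"
        "c,41,36,2100,100.0,female,,negative,U,fp_MAL,9.9\n"
    )
    path = tmp_path / "t.csv"
    path.write_text(text)
    records = read_cohort(path, panel)
    assert list(records["ma_years"]) == [30, 17, 41]
    assert np.isnan(records["ga_weeks"].iloc[1])
    assert np.isnan(records["aabc_hours"].iloc[1])  # the NA sentinel
    assert records["tpn"].iloc[1] == "unknown"
    assert records["transfusion"].iloc[2] == "unknown"
    assert list(n_ethnicities(records)) == [1, 2, 0]
    assert records["screen_label"].iloc[2] == "fp_MAL"


@pytest.mark.parametrize("mutation, message", [
    ("drop_marker", "missing columns"),
    ("bad_level", "non-numeric"),
    ("bad_sex", "unknown code"),
    ("bad_ethnicity", "unknown ethnicity"),
])
def test_parse_errors_name_the_row(tmp_path, mutation, message):
    panel = tiny_panel("C16")
    header = ("id,ma_years,ga_weeks,bw_grams,aabc_hours,sex,ethnicity,tpn,"
              "transfusion,screen_label,C16")
    row = "a,30,39,3200,24.5,male,Hispanic,negative,negative,screen_negative,1.5"
    if mutation == "drop_marker":
        header = header[: -len(",C16")]
        row = row[: -len(",1.5")]
    elif mutation == "bad_level":
        row = row.replace(",1.5", ",abc")
    elif mutation == "bad_sex":
        row = row.replace("male", "m")
    else:
        row = row.replace("Hispanic", "Martian")
    path = tmp_path / "bad.csv"
    path.write_text(header + "\n" + row + "\n")
    with pytest.raises(ParseError, match=message):
        read_cohort(path, panel)


def test_unknown_marker_in_effect_curves_rejected():
    cfg = one_marker_config(effect_curves={"NOPE": [0, 0, 0, 0, 0.2, 0.2]})
    with pytest.raises(ConfigError, match="NOPE"):
        nbsma.generate_cohort(cfg)


def test_nonzero_baseline_entry_rejected():
    cfg = one_marker_config(effect_curves={"C16": [0.1, 0, 0, 0, 0, 0]})
    with pytest.raises(ConfigError, match="baseline"):
        nbsma.generate_cohort(cfg)


def test_cutoff_without_marker_rejected():
    cfg = one_marker_config(seed=1, n_total=10)
    cohort = nbsma.generate_cohort(cfg)
    with pytest.raises(ConfigError, match="MAL"):
        generate_fp_labels(cohort, cfg.panel, {"MAL": 1.0})


def test_levels_finite_and_nonnegative():
    cfg = nbsma.paper_analogue_config(seed=9, n_total=3_000)
    cohort = nbsma.generate_cohort(cfg)
    for m in cfg.panel:
        levels = cohort[m.name].to_numpy()
        assert np.isfinite(levels).all()
        assert (levels >= 0).all()
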