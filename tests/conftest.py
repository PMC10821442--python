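"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nbsma import MarkerDef, SimConfig, default_panel
from nbsma.simulate import COVARIATE_COLUMNS, SCREEN_NEGATIVE


def tiny_panel(*names: str, marker_class: str = "acylcarnitine") -> list[MarkerDef]:
    """A small panel; disease markers keep their standard disease codes."""
    diseases = {"C3DC": "MAL", "C16": "CPT-II", "C5OH": "3MCC"}
    return [
        MarkerDef(n, marker_class, disease=diseases.get(n),
                  rusp_flag=n in diseases)
        for n in names
    ]


def make_records(n: int = 1, panel=None, **overrides) -> pd.DataFrame:
    """Handcrafted cohort rows; every unspecified field is filter-clean."""
    panel = panel if panel is not None else tiny_panel("C16")
    defaults = {
        "id": [f"T{i}" for i in range(n)],
        "ma_years": 30,
        "ga_weeks": 39.0,
        "bw_grams": 3200,
        "aabc_hours": 24.0,
        "sex": "male",
        "ethnicity": "Hispanic",
        "tpn": "negative",
        "transfusion": "negative",
        "screen_label": SCREEN_NEGATIVE,
    }
    data = {}
    for col in COVARIATE_COLUMNS:
        val = overrides.get(col, defaults[col])
        data[col] = val if isinstance(val, (list, np.ndarray, pd.Series)) else [val] * n
    for m in panel:
        val = overrides.get(m.name, 1.0)
        data[m.name] = val if isinstance(val, (list, np.ndarray, pd.Series)) else [val] * n
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def full_panel():
    return default_panel()


def one_marker_config(name: str = "C16", **kwargs) -> SimConfig:
    """Normal-family single-marker scenario without planted structure."""
    defaults = dict(
        panel=tiny_panel(name),
        effect_curves={},
        covariate_effects={},
        ma_offset_by_ethnicity={},
        distribution_family="normal",
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_run():
    """One moderate-size paper-analogue cohort shared across tests.

    Returns (config, core-filtered screen-negative cohort, effect-profile
    matrix).
    """
    import nbsma

    cfg = nbsma.paper_analogue_config(seed=7, n_total=150_000)
    cohort = nbsma.generate_cohort(cfg)
    core, _ = nbsma.apply_core_filters(cohort)
    profile = nbsma.effect_profile(core, cfg.panel)
    return cfg, core, profile
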