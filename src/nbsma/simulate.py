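"""Seeded synthetic newborn-screening cohort generator.

Generates tabular cohorts with the statistical structure the downstream
maternal-age (MA) analysis assumes: per-marker continuous level
distributions, standardized mean shifts planted per 5-year MA group
relative to the 15-19-year baseline, covariate influences (infant sex,
term/preterm status, major ethnicity group, age at blood collection),
an MA-prematurity association that is U-shaped over MA groups, and
cutoff-driven false-positive screening labels for three disorders
(MAL via C3DC, CPT-II via C16, 3MCC via C5OH).

Cohorts are plain pandas DataFrames, one row per infant, with the covariate
columns of :data:`COVARIATE_COLUMNS` followed by one column per marker.
Unknown values are NaN (numeric) or ``"unknown"`` / empty ethnicity
(categorical) in memory; the file dialect uses ``NA`` and ``U`` sentinels.

Standardized shifts are additive on the scale on which effect sizes are
later computed: raw levels for the ``normal`` family (so a planted shift of
0.29 yields Cohen's d = 0.29 up to sampling noise), log levels for the
``lognormal`` family (approximately equal to the raw-level d for small
shifts).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import panel as panel_mod
from .errors import ConfigError, ParseError
from .panel import (
    DISEASE_ORDER,
    ETHNICITY_CODES,
    MAJOR_GROUP_MAP,
    MarkerDef,
    _ACYLCARNITINES,
    _AMINO_ACIDS,
    _NON_MSMS,
    _OTHER_MSMS,
    default_panel,
    marker_names,
    validate_panel,
)

# ---------------------------------------------------------------------------
# cohort schema

COVARIATE_COLUMNS = [
    "id", "ma_years", "ga_weeks", "bw_grams", "aabc_hours", "sex",
    "ethnicity", "tpn", "transfusion", "screen_label",
]

SEXES = ("male", "female")
STATUS_VALUES = ("negative", "positive", "unknown")
SCREEN_NEGATIVE = "screen_negative"

#: age range the generator draws maternal ages from; deliberately wider than
#: the 15-44 analysis range so the MA filter has work to do
MA_AGE_RANGE = (12, 50)

#: age-at-blood-collection bands (hours) used for planted AaBC effects
AABC_BANDS = (24.0, 48.0)  # <24, 24-48, >=48

_MA_BANDS = [(15, 19), (20, 24), (25, 29), (30, 34), (35, 39), (40, 44)]
N_MA_GROUPS = len(_MA_BANDS)


def fp_label(disease: str) -> str:
    return f"fp_{disease}"


# ---------------------------------------------------------------------------
# default scenario parameters

def _default_ma_weights() -> dict[int, float]:
    """Discretized normal MA distribution, mean 29.5 y, SD 6 y, on 12-50."""
    ages = np.arange(MA_AGE_RANGE[0], MA_AGE_RANGE[1] + 1)
    w = np.exp(-0.5 * ((ages - 29.5) / 6.0) ** 2)
    w /= w.sum()
    return {int(a): float(p) for a, p in zip(ages, w)}


def _ma_weights_mean(weights: Mapping[int, float]) -> float:
    return float(sum(a * p for a, p in weights.items()))


#: planted standardized shifts for the signature markers, per MA group
#: (baseline first, always 0): monotone rise-then-plateau for the six markers
#: elevated at advanced MA, monotone decrease for C5OH, a non-monotone hump
#: for C3 (above threshold in mid groups but not in the pooled advanced
#: group), a shallow U for C0 and a small drift for ARG (below threshold).
_SIGNATURE_CURVES: dict[str, tuple[float, ...]] = {
    "C16":   (0.0, 0.10, 0.18, 0.25, 0.29, 0.29),
    "C3DC":  (0.0, 0.08, 0.14, 0.19, 0.22, 0.22),
    "C5OH":  (0.0, -0.12, -0.22, -0.32, -0.43, -0.43),
    "C14":   (0.0, 0.10, 0.18, 0.24, 0.30, 0.30),
    "C18":   (0.0, 0.09, 0.16, 0.22, 0.27, 0.27),
    "C18:1": (0.0, 0.11, 0.19, 0.26, 0.32, 0.32),
    "C3":    (0.0, 0.12, 0.25, 0.22, 0.15, 0.10),
    "C0":    (0.0, -0.10, -0.15, -0.12, -0.05, 0.05),
    "ARG":   (0.0, -0.02, -0.04, -0.05, -0.06, -0.06),
}

_DRIFT_SHAPE = np.array([0.0, 0.35, 0.6, 0.8, 0.95, 1.0])


def _default_effect_curves() -> dict[str, tuple[float, ...]]:
    """Signature curves plus small class-wide drifts.

    The remaining acylcarnitines get small positive rise-then-plateau curves
    and the amino acids small negative ones (both capped well below the 0.2
    flagging threshold), reproducing the global structure of the effect
    heatmap: an increasing cluster enriched in acylcarnitines at the top and
    a decreasing cluster at the bottom.  Non-metabolite markers get tiny
    alternating drifts and interleave in the middle.
    """
    curves = {k: tuple(v) for k, v in _SIGNATURE_CURVES.items()}
    for i, name in enumerate(_ACYLCARNITINES):
        if name not in curves:
            amp = 0.04 + 0.08 * (i / (len(_ACYLCARNITINES) - 1))
            curves[name] = tuple(amp * _DRIFT_SHAPE)
    for i, name in enumerate(_AMINO_ACIDS):
        if name not in curves:
            amp = -(0.03 + 0.07 * (i / (len(_AMINO_ACIDS) - 1)))
            curves[name] = tuple(amp * _DRIFT_SHAPE)
    for i, name in enumerate(_OTHER_MSMS + _NON_MSMS):
        amp = 0.02 * (1 if i % 2 == 0 else -1)
        curves[name] = tuple(amp * _DRIFT_SHAPE)
    return curves


DEFAULT_EFFECT_CURVES: dict[str, tuple[float, ...]] = _default_effect_curves()

#: covariate influences (standardized shifts) for the three signature markers;
#: term and male infants have the highest levels for all three
DEFAULT_COVARIATE_EFFECTS: dict[str, dict] = {
    "C16": {
        "male": 0.10, "preterm": -0.10,
        "ethnicity": {"White": 0.10, "Asian": -0.05},
        "aabc": (-0.05, 0.0, 0.05),
    },
    "C3DC": {
        "male": 0.08, "preterm": -0.08,
        "ethnicity": {"Black": 0.10, "White": 0.08},
        "aabc": (-0.05, 0.0, 0.05),
    },
    "C5OH": {
        "male": 0.10, "preterm": -0.12,
        "ethnicity": {"Black": 0.12},
        "aabc": (0.08, 0.0, -0.04),
    },
}

#: preterm probability per MA group, U-shaped; minimum at 20-24 years for
#: Black and Hispanic infants and at 25-29 years for Asian and White infants
DEFAULT_PRETERM_PROBS: dict[str, tuple[float, ...]] = {
    "Black":    (0.085, 0.055, 0.062, 0.070, 0.082, 0.098),
    "Hispanic": (0.080, 0.055, 0.060, 0.068, 0.080, 0.095),
    "Asian":    (0.075, 0.062, 0.054, 0.060, 0.072, 0.090),
    "White":    (0.072, 0.060, 0.052, 0.058, 0.070, 0.088),
    "default":  (0.080, 0.058, 0.058, 0.065, 0.078, 0.092),
}

#: single-ethnicity composition (normalized at use); roughly Californian
DEFAULT_ETHNICITY_WEIGHTS: dict[str, float] = {
    "Hispanic": 0.46, "White": 0.28, "Black": 0.06, "Chinese": 0.03,
    "Filipino": 0.03, "Middle Eastern": 0.03, "Vietnamese": 0.025,
    "Asian East Indian": 0.025, "Korean": 0.012, "Other Southeast Asian": 0.012,
    "Japanese": 0.008, "Cambodian": 0.008, "Laos": 0.007,
    "Native American": 0.006, "Samoan": 0.005, "Guamanian": 0.004,
    "Hawaiian": 0.004,
}


def _default_ma_offsets() -> dict[str, float]:
    """Per-ethnicity shifts (years) added to the base MA draw.

    Calibrated so the Korean and Japanese subgroups have the highest mean MA
    (33.9 and 35.1 years) while Asian and White groups sit above Hispanic and
    Black groups.
    """
    base = _ma_weights_mean(_default_ma_weights())
    return {
        "Korean": 33.9 - base,
        "Japanese": 35.1 - base,
        "Chinese": 2.0,
        "Asian East Indian": 1.5,
        "White": 1.3,
        "Middle Eastern": 1.0,
        "Hispanic": -1.2,
        "Black": -0.8,
    }


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort scenario.

    ``base_params`` maps marker name to a ``(loc, scale)`` pair: mean and SD
    of raw levels for the ``normal`` family, mean and SD of log levels for
    the ``lognormal`` family.  ``distribution_family`` may be a single family
    name applied to every marker or a per-marker mapping.
    """

    seed: int = 0
    n_total: int = 500_000
    panel: Sequence[MarkerDef] = field(default_factory=default_panel)
    ma_distribution: dict[int, float] = field(default_factory=_default_ma_weights)
    effect_curves: dict[str, Sequence[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_EFFECT_CURVES.items()}
    )
    covariate_effects: dict[str, dict] = field(
        default_factory=lambda: {
            k: {**v, "ethnicity": dict(v["ethnicity"]), "aabc": list(v["aabc"])}
            for k, v in DEFAULT_COVARIATE_EFFECTS.items()
        }
    )
    preterm_prob_by_ma_group: dict[str, Sequence[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PRETERM_PROBS.items()}
    )
    ma_offset_by_ethnicity: dict[str, float] = field(default_factory=_default_ma_offsets)
    ethnicity_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_WEIGHTS)
    )
    frac_multi_ethnicity: float = 0.179
    frac_unknown_ethnicity: float = 0.020
    base_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    distribution_family: str | dict[str, str] = "lognormal"
    frac_male: float = 0.519
    frac_tpn_positive: float = 0.010
    frac_tpn_unknown: float = 0.004
    frac_transfusion_positive: float = 0.008
    frac_transfusion_unknown: float = 0.004
    frac_aabc_unknown: float = 0.004
    frac_aabc_late: float = 0.002
    frac_ga_unknown: float = 0.002
    frac_ga_out_of_range: float = 0.008

    def family(self, marker: str) -> str:
        if isinstance(self.distribution_family, str):
            return self.distribution_family
        return self.distribution_family.get(marker, "lognormal")

    def params(self, marker: str) -> tuple[float, float]:
        if marker in self.base_params:
            return self.base_params[marker]
        # defaults: right-skewed levels with median 1 for lognormal; a level
        # scale comfortably away from the truncation at 0 for normal
        return (0.0, 0.5) if self.family(marker) == "lognormal" else (10.0, 1.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel"] = [dataclasses.asdict(m) for m in self.panel]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "panel" in d:
            d["panel"] = [MarkerDef(**m) for m in d["panel"]]
        if "ma_distribution" in d:
            d["ma_distribution"] = {int(k): float(v) for k, v in d["ma_distribution"].items()}
        return cls(**d)


def paper_analogue_config(seed: int = 0, n_total: int = 500_000) -> SimConfig:
    """The default analysis scenario with calibration-grade marker levels.

    Uses the normal family with unit scale for every marker so that planted
    standardized shifts equal the Cohen's d values computed downstream (up to
    sampling noise), with the signature-marker shifts 0.29 (C16), 0.22
    (C3DC) and -0.43 (C5OH) in the advanced-MA groups.
    """
    return SimConfig(seed=seed, n_total=n_total, distribution_family="normal")


def validate_config(config: SimConfig) -> None:
    validate_panel(config.panel)
    names = set(marker_names(config.panel))
    for marker in config.effect_curves:
        if marker not in names:
            raise ConfigError(f"effect_curves refers to unknown marker {marker!r}")
    for marker, curve in config.effect_curves.items():
        if len(curve) != N_MA_GROUPS:
            raise ConfigError(
                f"effect curve for {marker!r} has {len(curve)} entries, "
                f"expected {N_MA_GROUPS}"
            )
        if curve[0] != 0:
            raise ConfigError(f"effect curve for {marker!r}: baseline entry must be 0")
    for marker in config.covariate_effects:
        if marker not in names:
            raise ConfigError(f"covariate_effects refers to unknown marker {marker!r}")
    fracs = {
        "frac_multi_ethnicity": config.frac_multi_ethnicity,
        "frac_unknown_ethnicity": config.frac_unknown_ethnicity,
        "frac_male": config.frac_male,
    }
    for name, v in fracs.items():
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name} = {v} outside [0, 1]")
    if config.frac_multi_ethnicity + config.frac_unknown_ethnicity > 1:
        raise ConfigError("ethnicity fractions sum to more than 1")
    w = np.array(list(config.ma_distribution.values()), dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ConfigError("ma_distribution weights must be nonnegative and sum > 0")
    for group, probs in config.preterm_prob_by_ma_group.items():
        p = np.asarray(probs, dtype=float)
        if len(p) != N_MA_GROUPS or (p < 0).any() or (p > 1).any():
            raise ConfigError(f"preterm probabilities for {group!r} invalid")


# ---------------------------------------------------------------------------
# generation internals


def _sample_ethnicity(config: SimConfig, rng: np.random.Generator, n: int,
                      clean: bool) -> tuple[np.ndarray, np.ndarray]:
    """Return (semicolon-joined ethnicity strings, first detailed code)."""
    codes = np.array(list(config.ethnicity_weights.keys()))
    unknown_codes = set(codes) - set(ETHNICITY_CODES)
    if unknown_codes:
        raise ConfigError(f"unknown ethnicity codes in weights: {sorted(unknown_codes)}")
    w = np.array(list(config.ethnicity_weights.values()), dtype=float)
    w = w / w.sum()
    first = rng.choice(codes, size=n, p=w)
    if clean:
        return first.copy(), first
    u = rng.random(n)
    multi = u < config.frac_multi_ethnicity
    unknown = (u >= config.frac_multi_ethnicity) & (
        u < config.frac_multi_ethnicity + config.frac_unknown_ethnicity
    )
    second = rng.choice(codes, size=n, p=w)
    # re-draw second codes that collide with the first (multi = distinct codes)
    while True:
        clash = multi & (second == first)
        if not clash.any():
            break
        second[clash] = rng.choice(codes, size=int(clash.sum()), p=w)
    joined = first.astype(object).copy()
    joined[multi] = [f"{a};{b}" for a, b in zip(first[multi], second[multi])]
    joined[unknown] = ""
    firsts = first.astype(object)
    firsts[unknown] = ""
    return joined, firsts


def _sample_ma(config: SimConfig, rng: np.random.Generator,
               first_code: np.ndarray, clean: bool) -> np.ndarray:
    n = len(first_code)
    ages = np.array(list(config.ma_distribution.keys()))
    w = np.array(list(config.ma_distribution.values()), dtype=float)
    w = w / w.sum()
    ma = rng.choice(ages, size=n, p=w).astype(float)
    if not clean and config.ma_offset_by_ethnicity:
        offset = np.zeros(n)
        for code, off in config.ma_offset_by_ethnicity.items():
            offset[first_code == code] = off
        # stochastic rounding keeps MA integral while preserving the mean
        lo = np.floor(offset)
        ma += lo + (rng.random(n) < (offset - lo))
    return np.clip(ma, MA_AGE_RANGE[0], MA_AGE_RANGE[1]).astype(int)


def _ma_group_index(ma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clipped 5-year band index and an in-analysis-range mask."""
    in_range = (ma >= 15) & (ma <= 44)
    idx = np.clip((ma - 15) // 5, 0, N_MA_GROUPS - 1)
    return idx.astype(int), in_range


_PRETERM_GA_WEEKS = np.arange(28, 37)
_PRETERM_GA_W = np.array([1, 1, 2, 3, 4, 6, 9, 12, 15], dtype=float)
_TERM_GA_WEEKS = np.arange(37, 43)
_TERM_GA_W = np.array([8, 22, 30, 22, 12, 6], dtype=float)


def _sample_ga(config: SimConfig, rng: np.random.Generator, preterm: np.ndarray,
               clean: bool) -> np.ndarray:
    n = len(preterm)
    ga = rng.choice(_TERM_GA_WEEKS, size=n, p=_TERM_GA_W / _TERM_GA_W.sum()).astype(float)
    npre = int(preterm.sum())
    if npre:
        ga[preterm] = rng.choice(
            _PRETERM_GA_WEEKS, size=npre, p=_PRETERM_GA_W / _PRETERM_GA_W.sum()
        )
    if not clean:
        u = rng.random(n)
        out = u < config.frac_ga_out_of_range
        ga[out] = rng.choice(np.array([25.0, 26.0, 27.0, 43.0, 44.0]), size=int(out.sum()))
        ga[(u >= config.frac_ga_out_of_range)
           & (u < config.frac_ga_out_of_range + config.frac_ga_unknown)] = np.nan
    return ga


def _sample_bw(rng: np.random.Generator, ga: np.ndarray, clean: bool) -> np.ndarray:
    ga_eff = np.where(np.isnan(ga), 40.0, ga)
    bw = rng.normal(3480.0 - 195.0 * (40.0 - ga_eff), 440.0)
    if clean:
        bw = np.clip(bw, 2520.0, 3980.0)
    return np.maximum(np.round(bw), 400).astype(int)


def _sample_aabc(config: SimConfig, rng: np.random.Generator, n: int,
                 clean: bool) -> np.ndarray:
    aabc = np.exp(rng.normal(np.log(36.0), 0.45, size=n))
    aabc = np.round(aabc, 1)
    if clean:
        return np.clip(aabc, 12.0, 168.0)
    u = rng.random(n)
    aabc[u < config.frac_aabc_late] = np.round(
        rng.uniform(169.0, 336.0, size=int((u < config.frac_aabc_late).sum())), 1
    )
    unk = (u >= config.frac_aabc_late) & (
        u < config.frac_aabc_late + config.frac_aabc_unknown
    )
    aabc[unk] = np.nan
    return aabc


def _sample_status(rng: np.random.Generator, n: int, frac_pos: float,
                   frac_unk: float, clean: bool) -> np.ndarray:
    status = np.full(n, "negative", dtype=object)
    if clean:
        return status
    u = rng.random(n)
    status[u < frac_pos] = "positive"
    status[(u >= frac_pos) & (u < frac_pos + frac_unk)] = "unknown"
    return status


def _standardized_shift(config: SimConfig, marker: str, group_idx: np.ndarray,
                        in_range: np.ndarray, male: np.ndarray,
                        preterm: np.ndarray, major: np.ndarray,
                        aabc: np.ndarray) -> np.ndarray:
    n = len(group_idx)
    z = np.zeros(n)
    curve = config.effect_curves.get(marker)
    if curve is not None:
        z += np.asarray(curve, dtype=float)[group_idx] * in_range
    cov = config.covariate_effects.get(marker)
    if cov:
        z += cov.get("male", 0.0) * male
        z += cov.get("preterm", 0.0) * preterm
        for group, shift in cov.get("ethnicity", {}).items():
            z += shift * (major == group)
        aabc_shifts = cov.get("aabc")
        if aabc_shifts is not None:
            band = np.digitize(np.where(np.isnan(aabc), AABC_BANDS[0], aabc), AABC_BANDS)
            z += np.asarray(aabc_shifts, dtype=float)[band] * ~np.isnan(aabc)
    return z


def _generate(config: SimConfig, rng: np.random.Generator, n: int,
              ma: Optional[np.ndarray] = None, clean: bool = False,
              id_prefix: str = "NB") -> pd.DataFrame:
    joined_eth, first_code = _sample_ethnicity(config, rng, n, clean)
    if ma is None:
        ma = _sample_ma(config, rng, first_code, clean)
    group_idx, in_range = _ma_group_index(ma)

    major = np.array([MAJOR_GROUP_MAP.get(c, "") for c in first_code], dtype=object)
    if clean:
        preterm = np.zeros(n, dtype=bool)
    else:
        probs = np.empty(n)
        default_probs = np.asarray(
            config.preterm_prob_by_ma_group.get(
                "default", DEFAULT_PRETERM_PROBS["default"]
            ),
            dtype=float,
        )
        probs[:] = default_probs[group_idx]
        for group, p in config.preterm_prob_by_ma_group.items():
            if group == "default":
                continue
            mask = major == group
            if mask.any():
                probs[mask] = np.asarray(p, dtype=float)[group_idx[mask]]
        preterm = rng.random(n) < probs

    ga = _sample_ga(config, rng, preterm, clean)
    bw = _sample_bw(rng, ga, clean)
    aabc = _sample_aabc(config, rng, n, clean)
    male = rng.random(n) < config.frac_male
    tpn = _sample_status(rng, n, config.frac_tpn_positive,
                         config.frac_tpn_unknown, clean)
    transfusion = _sample_status(rng, n, config.frac_transfusion_positive,
                                 config.frac_transfusion_unknown, clean)

    data: dict[str, np.ndarray | list] = {
        "id": [f"{id_prefix}{i:07d}" for i in range(n)],
        "ma_years": ma.astype(int),
        "ga_weeks": ga,
        "bw_grams": bw,
        "aabc_hours": aabc,
        "sex": np.where(male, "male", "female"),
        "ethnicity": joined_eth,
        "tpn": tpn,
        "transfusion": transfusion,
        "screen_label": np.full(n, SCREEN_NEGATIVE, dtype=object),
    }
    for m in config.panel:
        z = _standardized_shift(config, m.name, group_idx, in_range,
                                male, preterm, major, aabc)
        eps = rng.standard_normal(n)
        loc, scale = config.params(m.name)
        if config.family(m.name) == "normal":
            levels = np.maximum(loc + scale * (z + eps), 0.0)
        else:
            levels = np.exp(loc + scale * (z + eps))
        data[m.name] = levels
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# public generators


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate ``config.n_total`` records; deterministic in (seed, config)."""
    validate_config(config)
    rng = np.random.default_rng(config.seed)
    return _generate(config, rng, config.n_total)


def generate_grouped_cohort(config: SimConfig,
                            group_sizes: Mapping[int, int],
                            seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a clean cohort with exact per-MA-group sizes.

    Keys of ``group_sizes`` are 5-year band indices (0 = 15-19 baseline).
    Records are generated in-range for every exclusion filter (term GA,
    normal BW, known AaBC, TPN/transfusion negative, single ethnicity) so
    effect-size calibration is not confounded by filtering.
    """
    validate_config(config)
    for g in group_sizes:
        if not 0 <= g < N_MA_GROUPS:
            raise ConfigError(f"unknown MA group index {g}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    parts = []
    for g in sorted(group_sizes):
        ma = _sample_ma_in_band(config, rng, group_sizes[g], _MA_BANDS[g])
        parts.append(_generate(config, rng, group_sizes[g], ma=ma, clean=True,
                               id_prefix=f"G{g}_"))
    return pd.concat(parts, ignore_index=True)


def generate_two_group_cohort(config: SimConfig, n_baseline: int,
                              n_advanced: int,
                              seed: Optional[int] = None) -> pd.DataFrame:
    """Clean cohort with exact baseline (15-19) and advanced (>= 35) sizes.

    Advanced maternal ages are drawn from the configured MA distribution
    conditioned on 35-44 years, so the pooled advanced shift reflects the
    scenario's group-4/5 mixture.
    """
    validate_config(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ma_b = _sample_ma_in_band(config, rng, n_baseline, (15, 19))
    ma_a = _sample_ma_in_band(config, rng, n_advanced, (35, 44))
    base = _generate(config, rng, n_baseline, ma=ma_b, clean=True, id_prefix="B")
    adv = _generate(config, rng, n_advanced, ma=ma_a, clean=True, id_prefix="A")
    return pd.concat([base, adv], ignore_index=True)


def _sample_ma_in_band(config: SimConfig, rng: np.random.Generator, n: int,
                       band: tuple[int, int]) -> np.ndarray:
    ages = np.array([a for a in config.ma_distribution if band[0] <= a <= band[1]])
    if len(ages) == 0:
        raise ConfigError(f"ma_distribution has no weight in band {band}")
    w = np.array([config.ma_distribution[int(a)] for a in ages], dtype=float)
    if w.sum() <= 0:
        raise ConfigError(f"ma_distribution has zero weight in band {band}")
    return rng.choice(ages, size=n, p=w / w.sum()).astype(int)


# ---------------------------------------------------------------------------
# screening labels


def generate_fp_labels(records: pd.DataFrame, panel: Sequence[MarkerDef],
                       cutoffs: Mapping[str, float]) -> pd.DataFrame:
    """Set ``screen_label`` from per-disease level cutoffs.

    A record is labelled ``fp_<disease>`` exactly when its level of that
    disease's marker strictly exceeds the cutoff (ties remain negative).
    Records exceeding several cutoffs get the first matching disease in
    :data:`nbsma.panel.DISEASE_ORDER` (then alphabetical for any others).
    """
    markers = {}
    for disease in cutoffs:
        markers[disease] = panel_mod.disease_marker(panel, disease).name
    out = records.copy()
    out["screen_label"] = SCREEN_NEGATIVE
    order = [d for d in DISEASE_ORDER if d in cutoffs]
    order += sorted(set(cutoffs) - set(order))
    unlabelled = np.ones(len(out), dtype=bool)
    for disease in order:
        hit = (out[markers[disease]].to_numpy() > cutoffs[disease]) & unlabelled
        out.loc[hit, "screen_label"] = fp_label(disease)
        unlabelled &= ~hit
    return out


def cutoffs_from_quantiles(records: pd.DataFrame, panel: Sequence[MarkerDef],
                           quantiles: Mapping[str, float]) -> dict[str, float]:
    """Screening cutoffs set at per-disease marker-level quantiles."""
    cutoffs = {}
    for disease, q in quantiles.items():
        name = panel_mod.disease_marker(panel, disease).name
        cutoffs[disease] = float(np.quantile(records[name].to_numpy(), q))
    return cutoffs


# ---------------------------------------------------------------------------
# cohort file IO (UTF-8 delimited text; NA/U sentinels)


def write_cohort(records: pd.DataFrame, path, sep: str = ",") -> None:
    out = records.copy()
    for col in ("tpn", "transfusion"):
        out[col] = out[col].replace("unknown", "U")
    ga = out["ga_weeks"]
    out["ga_weeks"] = ga.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out["aabc_hours"] = out["aabc_hours"].map(
        lambda v: "NA" if pd.isna(v) else repr(float(v))
    )
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cohort(path, panel: Sequence[MarkerDef]) -> pd.DataFrame:
    """Parse a cohort table; errors name the offending row (1-based, with header)."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=[], encoding="utf-8")
    names = marker_names(panel)
    missing = [c for c in COVARIATE_COLUMNS + names if c not in df.columns]
    if missing:
        raise ParseError(f"cohort file missing columns: {missing}")

    def numeric(col: str, integer: bool = False) -> pd.Series:
        raw = df[col].replace("NA", np.nan)
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna() & (raw != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"row {row}: non-numeric value {raw[bad].iloc[0]!r} "
                             f"in column {col!r}")
        return vals.round().astype("float").astype(int) if integer else vals

    out = pd.DataFrame({"id": df["id"]})
    out["ma_years"] = numeric("ma_years", integer=True)
    out["ga_weeks"] = numeric("ga_weeks")
    out["bw_grams"] = numeric("bw_grams", integer=True)
    out["aabc_hours"] = numeric("aabc_hours")

    def categorical(col: str, allowed: Sequence[str],
                    mapping: Optional[Mapping[str, str]] = None) -> pd.Series:
        vals = df[col]
        if mapping:
            vals = vals.replace(mapping)
        bad = ~vals.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"row {row}: unknown code {df[col][bad].iloc[0]!r} "
                             f"in column {col!r}")
        return vals

    out["sex"] = categorical("sex", SEXES)
    out["ethnicity"] = df["ethnicity"]
    for i, joined in enumerate(out["ethnicity"]):
        for code in str(joined).split(";"):
            if code and code not in ETHNICITY_CODES:
                raise ParseError(f"row {i + 2}: unknown ethnicity code {code!r}")
    out["tpn"] = categorical("tpn", STATUS_VALUES, {"U": "unknown"})
    out["transfusion"] = categorical("transfusion", STATUS_VALUES, {"U": "unknown"})
    labels = [SCREEN_NEGATIVE] + [fp_label(d) for d in DISEASE_ORDER]
    out["screen_label"] = categorical("screen_label", labels)
    for name in names:
        vals = numeric(name)
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
            raise ParseError(f"row {row}: missing level for marker {name!r}")
        if (vals < 0).any() or not np.isfinite(vals).all():
            row = int(np.flatnonzero(((vals < 0) | ~np.isfinite(vals)).to_numpy())[0]) + 2
            raise ParseError(f"row {row}: invalid level for marker {name!r}")
        out[name] = vals
    return out


def n_ethnicities(records: pd.DataFrame) -> pd.Series:
    """Number of reported detailed ethnicity codes per record (0 = unknown)."""
    eth = records["ethnicity"].fillna("")
    return eth.map(lambda s: 0 if not s else len(str(s).split(";")))
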