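"""Baseline-anchored Cohen's d effect-size profiles across maternal-age groups.

For every marker, levels in each 5-year maternal-age (MA) group are compared
with the 15-19-year baseline group using Cohen's d with the pooled standard
deviation,

    d = (m_c - m_b) / s_p,
    s_p = sqrt(((n_c - 1) s_c^2 + (n_b - 1) s_b^2) / (n_c + n_b - 2)),

with sample variances on n-1 denominators.  No small-sample (Hedges)
correction is applied; at cohort scale it is negligible.  Markers whose
absolute d exceeds a threshold (default 0.2) in at least one comparison are
flagged.  A second analysis pools the 35-39 and 40-44 bands into one
"advanced" group and compares it with the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError, UndefinedEffectError
from .panel import MarkerDef, marker_names

DEFAULT_THRESHOLD = 0.2


@dataclass(frozen=True)
class MAGroupScheme:
    """Inclusive 5-year maternal-age bands covering 15-44 years."""

    bands: tuple[tuple[int, int], ...] = (
        (15, 19), (20, 24), (25, 29), (30, 34), (35, 39), (40, 44),
    )
    baseline_index: int = 0
    advanced_min: int = 35

    def band_label(self, index: int) -> str:
        lo, hi = self.bands[index]
        return f"{lo}-{hi}"

    @property
    def comparison_indices(self) -> list[int]:
        return [i for i in range(len(self.bands)) if i != self.baseline_index]


DEFAULT_SCHEME = MAGroupScheme()


def assign_ma_group(ma_years, scheme: MAGroupScheme = DEFAULT_SCHEME):
    """Band index containing each maternal age (scalar or array).

    Ages must fall inside the scheme's bands (run the filters first).
    """
    ma = np.asarray(ma_years)
    idx = np.full(ma.shape, -1, dtype=int)
    for i, (lo, hi) in enumerate(scheme.bands):
        idx[(ma >= lo) & (ma <= hi)] = i
    if (idx < 0).any():
        bad = np.asarray(ma)[idx < 0].ravel()[0]
        raise DegenerateInputError(f"maternal age {bad} outside all MA bands")
    return int(idx) if ma.ndim == 0 else idx


@dataclass(frozen=True)
class EffectSizeResult:
    marker: str
    comparison_group: str
    d: float
    n_baseline: int
    n_comparison: int
    mean_baseline: float
    mean_comparison: float
    sd_baseline: float
    sd_comparison: float
    sd_pooled: float


def cohens_d(levels_comparison, levels_baseline, marker: str = "",
             comparison_group: str = "") -> EffectSizeResult:
    """Pooled-SD Cohen's d of a comparison sample versus a baseline sample."""
    c = np.asarray(levels_comparison, dtype=float)
    b = np.asarray(levels_baseline, dtype=float)
    n_c, n_b = len(c), len(b)
    if n_c < 2 or n_b < 2:
        raise InsufficientDataError(
            f"cohens_d needs >= 2 values per group (got {n_c} and {n_b})"
        )
    m_c, m_b = float(c.mean()), float(b.mean())
    v_c, v_b = float(c.var(ddof=1)), float(b.var(ddof=1))
    s_p = math.sqrt(((n_c - 1) * v_c + (n_b - 1) * v_b) / (n_c + n_b - 2))
    if s_p == 0.0:
        raise UndefinedEffectError(
            f"zero pooled SD for marker {marker!r}: effect size undefined"
        )
    return EffectSizeResult(
        marker=marker,
        comparison_group=comparison_group,
        d=(m_c - m_b) / s_p,
        n_baseline=n_b,
        n_comparison=n_c,
        mean_baseline=m_b,
        mean_comparison=m_c,
        sd_baseline=math.sqrt(v_b),
        sd_comparison=math.sqrt(v_c),
        sd_pooled=s_p,
    )


@dataclass
class EffectProfileMatrix:
    """Markers x comparison-groups matrix of Cohen's d values."""

    values: pd.DataFrame  # index: marker names; columns: group labels
    threshold: float = DEFAULT_THRESHOLD
    results: dict[tuple[str, str], EffectSizeResult] = field(default_factory=dict)

    @property
    def markers(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> list[str]:
        return list(self.values.columns)

    @property
    def flagged(self) -> set[str]:
        """Markers whose max |d| over comparison groups exceeds the threshold."""
        mask = self.values.abs().max(axis=1) > self.threshold
        return set(self.values.index[mask])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per marker x group) for TSV output."""
        rows = []
        for (marker, group), r in self.results.items():
            rows.append({
                "marker": marker, "group": group, "d": r.d,
                "n_baseline": r.n_baseline, "n_comparison": r.n_comparison,
                "mean_baseline": r.mean_baseline,
                "mean_comparison": r.mean_comparison,
                "sd_baseline": r.sd_baseline, "sd_comparison": r.sd_comparison,
                "sd_pooled": r.sd_pooled,
                "flagged": marker in self.flagged,
            })
        return pd.DataFrame(rows)


def _profile(records: pd.DataFrame, panel: Sequence[MarkerDef],
             comparisons: dict[str, np.ndarray], baseline_mask: np.ndarray,
             threshold: float, log_levels: bool) -> EffectProfileMatrix:
    if int(baseline_mask.sum()) < 2:
        raise InsufficientDataError("baseline MA group has fewer than 2 records")
    names = marker_names(panel)
    values = pd.DataFrame(index=pd.Index(names, name="marker"),
                          columns=list(comparisons), dtype=float)
    results: dict[tuple[str, str], EffectSizeResult] = {}
    for name in names:
        levels = records[name].to_numpy(dtype=float)
        if log_levels:
            levels = np.log(levels + 1e-12)
        base = levels[baseline_mask]
        for label, mask in comparisons.items():
            if int(mask.sum()) < 2:
                continue  # too few records: d stays NaN for this cell
            r = cohens_d(levels[mask], base, marker=name, comparison_group=label)
            values.loc[name, label] = r.d
            results[(name, label)] = r
    return EffectProfileMatrix(values=values, threshold=threshold, results=results)


def effect_profile(records: pd.DataFrame, panel: Sequence[MarkerDef],
                   scheme: MAGroupScheme = DEFAULT_SCHEME,
                   threshold: float = DEFAULT_THRESHOLD,
                   log_levels: bool = False) -> EffectProfileMatrix:
    """Cohen's d of every marker in every non-baseline MA group vs baseline."""
    idx = assign_ma_group(records["ma_years"].to_numpy(), scheme)
    comparisons = {
        scheme.band_label(i): idx == i for i in scheme.comparison_indices
    }
    return _profile(records, panel, comparisons, idx == scheme.baseline_index,
                    threshold, log_levels)


def advanced_vs_baseline(records: pd.DataFrame, panel: Sequence[MarkerDef],
                         scheme: MAGroupScheme = DEFAULT_SCHEME,
                         threshold: float = DEFAULT_THRESHOLD,
                         log_levels: bool = False) -> EffectProfileMatrix:
    """Single-column profile pooling all MA >= ``scheme.advanced_min`` years."""
    ma = records["ma_years"].to_numpy()
    idx = assign_ma_group(ma, scheme)
    comparisons = {"advanced": ma >= scheme.advanced_min}
    return _profile(records, panel, comparisons, idx == scheme.baseline_index,
                    threshold, log_levels)
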