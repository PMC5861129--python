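"""Normalization and fermentation metrics.

Implements the study's min–max feature scaling of log10-transformed
abundances (used for protein / monoterpene / sugar heatmaps), the derived
sugar-consumption scores, the residual-sugar (attenuation) fraction, and the
sliding-window maximum specific growth rate from OD600 time series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import SugarProfile

__all__ = [
    "DegenerateRangeError",
    "InsufficientDataError",
    "ScaledSeries",
    "DEFAULT_TITER_FLOOR",
    "DEFAULT_SUGAR_FLOOR",
    "minmax_log_scale",
    "sugar_consumption_score",
    "residual_sugar_fraction",
    "max_growth_rate",
]

#: Default floors applied before log10, below the GC-MS / HPLC standard-curve
#: ranges (0.2 mg/L and 0.2 g/L respectively), so a stored zero never reaches
#: the logarithm.
DEFAULT_TITER_FLOOR = 0.01  # mg/L
DEFAULT_SUGAR_FLOOR = 0.01  # g/L

FERMENTABLE_SUGARS = ("maltotriose", "maltose", "glucose")


class DegenerateRangeError(ValueError):
    """All values identical after log transform; min–max scaling is undefined."""


class InsufficientDataError(ValueError):
    """Not enough data points to carry out the estimate."""


@dataclass(frozen=True)
class ScaledSeries:
    """Min–max scaled values in [0, 1] plus the log10-space range used."""

    values: np.ndarray
    source_min: float  # min of log10-transformed inputs
    source_max: float  # max of log10-transformed inputs

    def rescale(self, new_values: Sequence[float], floor: float) -> np.ndarray:
        """Scale further values with this series' frozen min/max."""
        s = np.log10(np.maximum(np.asarray(new_values, dtype=float), floor))
        return (s - self.source_min) / (self.source_max - self.source_min)


def minmax_log_scale(values: Sequence[float], floor: float = DEFAULT_TITER_FLOOR) -> ScaledSeries:
    """Min–max scale log10-transformed measurements onto [0, 1].

    Each value is clipped below at ``floor``, log10-transformed to s_i, then
    normalized as s'_i = (s_i - min(S)) / (max(S) - min(S)).  The minimum of
    the series maps to exactly 0 and the maximum to exactly 1.

    Raises
    ------
    DegenerateRangeError
        If all values coincide after the transform (max == min).  Callers
        that need a fallback (e.g. a heatmap column) must substitute
        explicitly.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("minmax_log_scale needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("minmax_log_scale: values must be finite")
    if floor <= 0:
        raise ValueError("minmax_log_scale: floor must be > 0")
    s = np.log10(np.maximum(arr, floor))
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        raise DegenerateRangeError("all values identical after log10 transform")
    return ScaledSeries(values=(s - lo) / (hi - lo), source_min=lo, source_max=hi)


def sugar_consumption_score(
    profiles: Sequence[SugarProfile],
    wort: SugarProfile,
    floor: float = DEFAULT_SUGAR_FLOOR,
) -> dict[str, dict[str, float]]:
    """Per-strain, per-sugar consumption scores in [0, 1].

    For each fermentable sugar (maltotriose, maltose, glucose) the min–max
    log scaling is computed over all strains together with the unfermented
    wort, and the scaled value is subtracted from 1 so that higher means
    closer to the desired (fully consumed) profile: a strain at wort level
    scores 0, the strain with the least residual sugar scores 1.  Ethanol is
    scaled the same way but not inverted.

    Returns ``{sugar: {strain_id: score}}``; a degenerate range for any sugar
    propagates as :class:`DegenerateRangeError`.
    """
    out: dict[str, dict[str, float]] = {}
    ids = [p.strain_id for p in profiles]
    for sugar in (*FERMENTABLE_SUGARS, "ethanol"):
        pool = [getattr(p, sugar) for p in profiles] + [getattr(wort, sugar)]
        scaled = minmax_log_scale(pool, floor=floor).values[: len(profiles)]
        if sugar in FERMENTABLE_SUGARS:
            scaled = 1.0 - scaled
        out[sugar] = dict(zip(ids, (float(v) for v in scaled)))
    return out


def residual_sugar_fraction(profile: SugarProfile, wort: SugarProfile) -> float:
    """Fraction of the wort's total fermentable sugar remaining, clipped to [0, 1]."""
    denom = wort.total_fermentable
    if denom <= 0:
        raise ZeroDivisionError("wort total fermentable sugar must be > 0")
    return float(np.clip(profile.total_fermentable / denom, 0.0, 1.0))


def max_growth_rate(
    times: Sequence[float],
    od: Sequence[float],
    window: float = 5.0,
    od_floor: float = 1e-6,
) -> float:
    """Maximum specific growth rate (per hour) from an OD600 time series.

    Over every contiguous sliding window spanning at least ``window`` hours
    (advancing one sample at a time), ln(OD) is regressed on time by least
    squares; the estimate is the maximum slope over windows.  The estimate is
    invariant to multiplying OD by a positive constant and to prepending a
    lag phase before the exponential segment.

    Raises
    ------
    InsufficientDataError
        If the series does not span one full window with >= 2 points.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and od must be 1-D and the same length")
    if t.size < 2:
        raise InsufficientDataError("need at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[-1] - t[0] < window:
        raise InsufficientDataError(
            f"series spans {t[-1] - t[0]:.3g} h; need at least one {window:.3g} h window"
        )
    ln_od = np.log(np.maximum(y, od_floor))

    best = -np.inf
    n = t.size
    j = 0
    for i in range(n):
        # smallest j with t[j] - t[i] >= window
        j = max(j, i + 1)
        while j < n and t[j] - t[i] < window:
            j += 1
        if j >= n:
            break
        tw = t[i : j + 1]
        yw = ln_od[i : j + 1]
        slope = np.polyfit(tw, yw, 1)[0]
        best = max(best, float(slope))
    if not np.isfinite(best):  # pragma: no cover - guarded by span check above
        raise InsufficientDataError("no complete window found")
    return max(best, 0.0)
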