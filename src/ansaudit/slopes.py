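"""Ratio-effect-slope diagnostics over Weber-fraction ranges.

In a number-comparison task the *ratio effect* is the performance
difference between an easy (large-ratio) and a hard (small-ratio)
condition.  Under the Gaussian ANS model it is computed here as the
overlap at the small ratio minus the overlap at the large ratio — a
standardized index in ``[0, 1]``.  Because the overlap is a nonlinear
(L-shaped) function of the ratio, the ratio effect is a non-monotonic
function of the Weber fraction ``w``, which is exactly what makes the
ratio effect slope a potentially invalid proxy for ANS sensitivity.

This module quantifies that validity: the effect curve over a ``w``
grid, the expected range of the effect over a ``w`` interval (a
standardized variability index), and a classification of the
effect–``w`` relation as mostly negative, mostly positive, or mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import overlap

__all__ = [
    "RatioPair",
    "SlopeCurve",
    "SlopeRange",
    "DirectionClass",
    "PAPER_RATIO_PAIRS",
    "ratio_effect",
    "linear_slope",
    "slope_curve",
    "expected_range",
    "classify_direction",
    "range_table",
    "direction_table",
]

#: the six ratio pairs used throughout the reference simulations,
#: spanning small-value, large-value, and mixed ratio ranges
PAPER_RATIO_PAIRS: tuple[tuple[float, float], ...] = (
    (1.125, 1.4),
    (1.125, 2.0),
    (1.125, 4.0),
    (1.5, 5.0),
    (2.0, 5.0),
    (4.0, 9.0),
)

#: default Weber-fraction step for curves, ranges and classification
DEFAULT_GRID_STEP = 1e-3

#: finite-difference steps with |step| below this count as neither sign
_STEP_SIGN_TOL = 1e-6


@dataclass(frozen=True)
class RatioPair:
    """Two comparison-task ratios, small < large, both >= 1."""

    r_small: float
    r_large: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.r_small < self.r_large):
            raise ValueError(
                f"need 1 <= r_small < r_large, got ({self.r_small}, {self.r_large})"
            )

    @property
    def label(self) -> str:
        return f"{self.r_small:g}-{self.r_large:g}"


def _as_pair(pair) -> RatioPair:
    return pair if isinstance(pair, RatioPair) else RatioPair(*pair)


@dataclass(frozen=True)
class SlopeCurve:
    """Ratio effect evaluated on a strictly increasing Weber-fraction grid."""

    pair: RatioPair
    w_grid: np.ndarray
    effects: np.ndarray

    def __post_init__(self) -> None:
        if len(self.w_grid) != len(self.effects):
            raise ValueError("w_grid and effects must have equal length")
        if len(self.w_grid) > 1 and not np.all(np.diff(self.w_grid) > 0):
            raise ValueError("w_grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"w": self.w_grid, "ratio_effect": self.effects})


@dataclass(frozen=True)
class SlopeRange:
    """Min, max and range of the ratio effect over a Weber-fraction interval.

    ``range`` is a standardized variability index in ``[0, 1]``: large
    values mean the design can separate observers within the interval.
    """

    min_effect: float
    max_effect: float

    @property
    def range(self) -> float:
        return self.max_effect - self.min_effect


@dataclass(frozen=True)
class DirectionClass:
    """Direction of the ratio-effect / Weber-fraction relation.

    ``label`` is ``"negative"`` when at least ``neg_threshold`` of the
    signed grid steps of the effect curve are decreasing, ``"positive"``
    when at most ``pos_threshold`` are, and ``"mixed"`` otherwise.
    A mixed relation means the slope is uninterpretable as a sensitivity
    index over that interval.
    """

    label: str
    fraction_negative_steps: float

    def __post_init__(self) -> None:
        if self.label not in {"negative", "positive", "mixed"}:
            raise ValueError(f"unknown direction label {self.label!r}")


def ratio_effect(pair, w):
    """Overlap at the small ratio minus overlap at the large ratio.

    Non-negative because the overlap is non-increasing in the ratio;
    tiny negative rounding residue is clamped to 0.  Vectorizes over
    ``w``.
    """
    p = _as_pair(pair)
    eff = overlap(p.r_small, w) - overlap(p.r_large, w)
    return np.maximum(eff, 0.0) if isinstance(eff, np.ndarray) else max(eff, 0.0)


def linear_slope(ratios, w: float) -> float:
    """OLS slope of representational overlap against ratio.

    Generalizes the two-ratio effect to designs with many ratios: the
    performance index is regressed on the ratio and the fitted slope is
    returned with its natural (typically negative) sign.  For exactly
    two ratios this equals ``-ratio_effect / (r_large - r_small)``.
    """
    rs = np.unique(np.asarray(ratios, dtype=float))
    if rs.size < 2:
        raise ValueError(f"need at least 2 distinct ratios, got {ratios}")
    ov = overlap(rs, np.full_like(rs, float(w)))
    slope, _ = np.polyfit(rs, ov, 1)
    return float(slope)


def slope_curve(pair, w_grid) -> SlopeCurve:
    """Ratio effect along a Weber-fraction grid (the effect-vs-w curve)."""
    p = _as_pair(pair)
    grid = np.asarray(w_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("w_grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("w_grid values must be positive")
    return SlopeCurve(pair=p, w_grid=grid, effects=np.asarray(ratio_effect(p, grid)))


def _interval_grid(w_interval, grid_step: float) -> np.ndarray:
    w_lo, w_hi = float(w_interval[0]), float(w_interval[1])
    if not (0 < w_lo <= w_hi):
        raise ValueError(f"need 0 < w_lo <= w_hi, got [{w_lo}, {w_hi}]")
    if grid_step <= 0:
        raise ValueError(f"grid_step must be positive, got {grid_step}")
    n = max(int(round((w_hi - w_lo) / grid_step)) + 1, 1)
    return np.linspace(w_lo, w_hi, n)


def expected_range(pair, w_interval, grid_step: float = DEFAULT_GRID_STEP) -> SlopeRange:
    """Expected variability of the ratio effect over a Weber interval.

    Evaluates the effect on a dense grid over ``[w_lo, w_hi]`` and
    returns the minimum, maximum, and their difference.  A degenerate
    interval ``[w, w]`` yields range 0.
    """
    p = _as_pair(pair)
    grid = _interval_grid(w_interval, grid_step)
    eff = np.asarray(ratio_effect(p, grid))
    return SlopeRange(min_effect=float(eff.min()), max_effect=float(eff.max()))


def classify_direction(
    pair,
    w_interval,
    grid_step: float = DEFAULT_GRID_STEP,
    neg_threshold: float = 0.8,
    pos_threshold: float = 0.2,
) -> DirectionClass:
    """Classify the effect–Weber-fraction relation over an interval.

    Successive finite differences of the effect curve are signed (steps
    smaller than 1e-6 in magnitude count as neither sign); the fraction
    of negative steps maps to a label via the two thresholds.
    """
    p = _as_pair(pair)
    grid = _interval_grid(w_interval, grid_step)
    if grid.size < 2:
        return DirectionClass(label="mixed", fraction_negative_steps=0.0)
    eff = np.asarray(ratio_effect(p, grid))
    steps = np.diff(eff)
    signed = steps[np.abs(steps) > _STEP_SIGN_TOL]
    if signed.size == 0:
        return DirectionClass(label="mixed", fraction_negative_steps=0.0)
    frac_neg = float(np.mean(signed < 0))
    if frac_neg >= neg_threshold:
        label = "negative"
    elif frac_neg <= pos_threshold:
        label = "positive"
    else:
        label = "mixed"
    return DirectionClass(label=label, fraction_negative_steps=frac_neg)


def range_table(
    pairs=PAPER_RATIO_PAIRS,
    w_intervals=((0.03, 0.31), (0.087, 0.471), (0.04, 1.0)),
    grid_step: float = DEFAULT_GRID_STEP,
) -> pd.DataFrame:
    """Expected ratio-effect ranges for each (ratio pair, Weber interval).

    Reproduces the structure of the reference range table: one row per
    combination with columns ``ratio_pair, w_lo, w_hi, min, max, range``.
    Default intervals are the adult (0.03–0.31), adolescent
    (0.087–0.471) and full simulation (0.04–1.0) Weber ranges.
    """
    rows = []
    for pair in pairs:
        p = _as_pair(pair)
        for w_lo, w_hi in w_intervals:
            sr = expected_range(p, (w_lo, w_hi), grid_step)
            rows.append(
                {
                    "ratio_pair": p.label,
                    "w_lo": w_lo,
                    "w_hi": w_hi,
                    "min": sr.min_effect,
                    "max": sr.max_effect,
                    "range": sr.range,
                }
            )
    return pd.DataFrame(rows)


def direction_table(
    pairs=PAPER_RATIO_PAIRS,
    w_interval=(0.04, 1.0),
    grid_step: float = DEFAULT_GRID_STEP,
) -> pd.DataFrame:
    """Direction classification report for a set of ratio pairs."""
    rows = []
    for pair in pairs:
        p = _as_pair(pair)
        dc = classify_direction(p, w_interval, grid_step)
        rows.append(
            {
                "ratio_pair": p.label,
                "label": dc.label,
                "fraction_negative_steps": dc.fraction_negative_steps,
            }
        )
    return pd.DataFrame(rows)
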