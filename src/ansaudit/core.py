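"""Gaussian representational model of the approximate number system (ANS).

A magnitude ``n`` is represented as a Gaussian random variable with mean
``n`` and standard deviation ``w * n``, where ``w`` is the observer's
Weber fraction.  For a comparison of two numbers with ratio ``r``
(larger / smaller, so ``r >= 1``) the representations can be placed on a
normalized axis: means ``1`` and ``r`` with standard deviations ``w``
and ``r * w``.  Discriminability is governed by the *representational
overlap* — the integral of the pointwise minimum of the two densities —
a number in ``[0, 1]`` that does not depend on the absolute magnitudes
(Weber's law), only on ``r`` and ``w``.

The overlap integral is evaluated in closed form: the two Gaussian
log-densities are equal where a quadratic vanishes, so the real line
splits into at most three segments on each of which one density is
uniformly the smaller; the integral is then a sum of Gaussian CDF
segment masses.  A Riemann-grid oracle (:func:`overlap_oracle`) provides
an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "GaussianRepresentation",
    "normalize_ratio",
    "make_pair_representations",
    "overlap",
    "overlap_oracle",
]

# absolute tolerance on the overlap integral; results are clamped to [0, 1]
OVERLAP_ATOL = 1e-8


@dataclass(frozen=True)
class GaussianRepresentation:
    """Noisy mental representation of a magnitude.

    Attributes
    ----------
    mean : float
        The represented magnitude (> 0).
    sd : float
        Representation noise, ``mean * w`` for Weber fraction ``w``.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"representation mean must be positive, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"representation sd must be non-negative, got {self.sd}")


def _check_ratio_w(ratio: float, w: float) -> None:
    if not np.all(np.asarray(ratio) >= 1):
        raise ValueError(f"ratio must be >= 1 (larger/smaller convention), got {ratio}")
    if not np.all(np.asarray(w) >= 0):
        raise ValueError(f"Weber fraction must be non-negative, got {w}")


def normalize_ratio(a: float, b: float) -> float:
    """Return the ratio larger/smaller for a pair of positive numbers."""
    if a <= 0 or b <= 0:
        raise ValueError(f"numbers must be positive, got ({a}, {b})")
    return max(a, b) / min(a, b)


def make_pair_representations(
    ratio: float, w: float
) -> tuple[GaussianRepresentation, GaussianRepresentation]:
    """Representations of a number pair with the given ratio and Weber fraction.

    Means are ``(1, ratio)`` and standard deviations ``(w, ratio * w)``;
    by scale invariance of the model any pair with this ratio behaves
    identically.
    """
    _check_ratio_w(ratio, w)
    if w <= 0:
        raise ValueError(f"Weber fraction must be positive for representations, got {w}")
    return (
        GaussianRepresentation(mean=1.0, sd=float(w)),
        GaussianRepresentation(mean=float(ratio), sd=float(ratio) * float(w)),
    )


def overlap(ratio, w):
    """Representational overlap of the two magnitudes of a comparison pair.

    Computes ``integral of min(f1, f2)`` for Gaussian densities ``f1 =
    N(1, w^2)`` and ``f2 = N(ratio, (ratio*w)^2)``.  Returns a value in
    ``[0, 1]``: 1 for ``ratio == 1`` (identical representations), and in
    the degenerate noiseless limit ``w == 0`` the point-mass convention
    (1 if ``ratio == 1``, else 0).

    Parameters
    ----------
    ratio : float or array_like
        Number ratio, ``>= 1``.
    w : float or array_like
        Weber fraction, ``>= 0``.  Broadcasts against ``ratio``.

    Returns
    -------
    float or ndarray
        Overlap fraction(s) in ``[0, 1]``.
    """
    _check_ratio_w(ratio, w)
    r = np.asarray(ratio, dtype=float)
    wv = np.asarray(w, dtype=float)
    r, wv = np.broadcast_arrays(r, wv)
    scalar = r.ndim == 0
    r = np.atleast_1d(r).copy()
    wv = np.atleast_1d(wv).copy()

    out = np.empty_like(r)
    equal = np.isclose(r, 1.0, rtol=0.0, atol=1e-15)
    zero_w = wv == 0.0
    out[equal] = 1.0
    out[zero_w & ~equal] = 0.0

    active = ~equal & ~zero_w
    if np.any(active):
        out[active] = _overlap_closed_form(r[active], wv[active])

    np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar else out


def _overlap_closed_form(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized closed-form overlap for r > 1, w > 0 (unequal variances)."""
    m1 = np.ones_like(r)
    s1 = w
    m2 = r
    s2 = r * w

    # log f1(x) = log f2(x)  <=>  a x^2 + b x + c = 0
    a = 1.0 / s2**2 - 1.0 / s1**2          # < 0 since s2 > s1
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 + 2.0 * np.log(s2 / s1)

    disc = b**2 - 4.0 * a * c
    # with s1 != s2 the densities always cross twice; guard rounding
    disc = np.maximum(disc, 0.0)
    sq = np.sqrt(disc)
    x_lo = (-b + sq) / (2.0 * a)           # a < 0 flips the usual ordering
    x_hi = (-b - sq) / (2.0 * a)

    cdf1_lo = norm.cdf(x_lo, m1, s1)
    cdf1_hi = norm.cdf(x_hi, m1, s1)
    cdf2_lo = norm.cdf(x_lo, m2, s2)
    cdf2_hi = norm.cdf(x_hi, m2, s2)

    # decide which density is the smaller between the crossings
    mid = 0.5 * (x_lo + x_hi)
    f1_mid = norm.logpdf(mid, m1, s1)
    f2_mid = norm.logpdf(mid, m2, s2)
    mid_is_f1 = f1_mid < f2_mid

    # outside the crossings the other density is the smaller
    middle = np.where(mid_is_f1, cdf1_hi - cdf1_lo, cdf2_hi - cdf2_lo)
    tails = np.where(mid_is_f1, cdf2_lo + 1.0 - cdf2_hi, cdf1_lo + 1.0 - cdf1_hi)
    return middle + tails


def overlap_oracle(ratio: float, w: float, grid_step: float = 1e-4) -> float:
    """Riemann-grid approximation of the overlap integral (testing aid).

    Evaluates both densities on a dense grid spanning +/- 8 SD beyond the
    two means and integrates the pointwise minimum with the trapezoid
    rule.  Slower than :func:`overlap` but entirely independent of the
    closed-form path; intended for verification only.
    """
    _check_ratio_w(ratio, w)
    if grid_step <= 0:
        raise ValueError(f"grid_step must be positive, got {grid_step}")
    if w == 0 or ratio == 1:
        return overlap(ratio, w)
    m1, s1, m2, s2 = 1.0, w, float(ratio), float(ratio) * w
    lo = min(m1 - 8.0 * s1, m2 - 8.0 * s2)
    hi = max(m1 + 8.0 * s1, m2 + 8.0 * s2)
    x = np.arange(lo, hi + grid_step, grid_step)
    y = np.minimum(norm.pdf(x, m1, s1), norm.pdf(x, m2, s2))
    return float(min(np.trapezoid(y, x), 1.0))
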