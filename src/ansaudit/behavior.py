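"""Synthetic number-comparison trials and Weber-fraction recovery.

The generator and the estimator share one observation model.  An
observer with Weber fraction ``w`` comparing a pair with ratio ``r``
errs with probability ``overlap(r, w) / 2`` — the misclassification
mass of an equal-prior optimal observer deciding at the point where the
two representational densities cross.  This overlap-derived accuracy
curve plays the role of the "sigmoid" psychometric function: error
probability falls from chance (0.5 at ratio 1) towards 0 as the ratio
grows, at a rate governed by ``w``.

``estimate_weber`` inverts the model by binomial maximum likelihood:
given error counts per ratio, a bounded one-dimensional search returns
the ``w`` whose predicted error rates best explain the counts.  Because
generator and estimator share the model, parameter-recovery tests are
well-posed: the mapping from overlap to behavior is a modelling
extension of this package, not a unique consequence of the Gaussian
representation itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import binom

from .core import overlap

__all__ = [
    "TrialSet",
    "WeberEstimate",
    "error_rate",
    "simulate_trials",
    "estimate_weber",
]

# search bracket for the ML Weber fraction
W_BOUNDS = (1e-3, 2.0)
# optimizer tolerance on w
W_XATOL = 1e-6
# error probabilities are clipped away from {0, 0.5} in the likelihood
_P_EPS = 1e-12


@dataclass(frozen=True)
class TrialSet:
    """Per-ratio error counts from a two-alternative comparison task."""

    ratios: np.ndarray
    n_trials: np.ndarray
    n_errors: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        nt = np.asarray(self.n_trials, dtype=int)
        ne = np.asarray(self.n_errors, dtype=int)
        if not (r.size == nt.size == ne.size):
            raise ValueError("ratios, n_trials and n_errors must have equal length")
        if np.unique(r).size != r.size or np.any(r < 1):
            raise ValueError("ratios must be distinct and >= 1")
        if np.any(nt < 0) or np.any(ne < 0) or np.any(ne > nt):
            raise ValueError("need 0 <= n_errors <= n_trials per ratio")
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "n_trials", nt)
        object.__setattr__(self, "n_errors", ne)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ratio": self.ratios, "n_trials": self.n_trials, "n_errors": self.n_errors}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialSet":
        df = pd.read_csv(path)
        return cls(
            ratios=df["ratio"].to_numpy(),
            n_trials=df["n_trials"].to_numpy(),
            n_errors=df["n_errors"].to_numpy(),
        )


@dataclass(frozen=True)
class WeberEstimate:
    """Maximum-likelihood Weber fraction with fit diagnostics."""

    w_hat: float
    log_likelihood: float
    converged: bool

    def summary(self) -> str:
        status = "converged" if self.converged else "NOT converged (boundary/degenerate)"
        return (
            f"Weber fraction estimate\n"
            f"  w_hat          {self.w_hat:.4f}\n"
            f"  log-likelihood {self.log_likelihood:.3f}\n"
            f"  status         {status}"
        )


def error_rate(ratio, w):
    """Predicted error probability for a comparison at ``ratio`` given ``w``.

    Equals ``overlap(ratio, w) / 2``: with equal priors, the optimal
    decision boundary misclassifies half the overlapping mass.  Lies in
    ``[0, 0.5]``; at ratio 1 the stimuli are indistinguishable and
    performance is at chance.
    """
    ov = overlap(ratio, w)
    return ov / 2.0


def simulate_trials(
    w: float, ratios, trials_per_ratio: int, rng: np.random.Generator
) -> TrialSet:
    """Draw binomial error counts per ratio under the observation model."""
    if trials_per_ratio < 1:
        raise ValueError(f"trials_per_ratio must be >= 1, got {trials_per_ratio}")
    r = np.asarray(ratios, dtype=float)
    p = np.asarray([error_rate(ri, w) for ri in r])
    errors = rng.binomial(trials_per_ratio, p)
    return TrialSet(
        ratios=r,
        n_trials=np.full(r.size, trials_per_ratio),
        n_errors=errors,
    )


def _neg_log_likelihood(w: float, trials: TrialSet) -> float:
    p = np.clip(
        np.asarray([error_rate(r, w) for r in trials.ratios]), _P_EPS, 0.5 - _P_EPS
    )
    return -float(np.sum(binom.logpmf(trials.n_errors, trials.n_trials, p)))


def estimate_weber(trials: TrialSet) -> WeberEstimate:
    """Recover the Weber fraction from error counts by maximum likelihood.

    Bounded scalar minimization of the negative binomial log-likelihood
    over ``w`` in ``[1e-3, 2]``.  Degenerate data (all conditions at
    chance, or zero errors everywhere) push the optimum to a bracket
    boundary; such fits are returned with ``converged=False`` rather
    than raising.
    """
    if np.count_nonzero(trials.n_trials) < 2:
        raise ValueError("need at least 2 ratios with at least 1 trial each")
    res = minimize_scalar(
        _neg_log_likelihood,
        bounds=W_BOUNDS,
        args=(trials,),
        method="bounded",
        options={"xatol": W_XATOL},
    )
    w_hat = float(res.x)
    nll = float(res.fun)
    # degenerate data (e.g. zero errors everywhere, or all conditions at
    # chance) leave the likelihood flat out to a bracket boundary; report
    # the boundary as the estimate and flag non-convergence
    for bound in W_BOUNDS:
        if _neg_log_likelihood(bound, trials) <= nll + 1e-9:
            return WeberEstimate(
                w_hat=bound, log_likelihood=-nll, converged=False
            )
    at_boundary = (
        w_hat <= W_BOUNDS[0] + 10 * W_XATOL or w_hat >= W_BOUNDS[1] - 10 * W_XATOL
    )
    converged = bool(res.success) and not at_boundary
    return WeberEstimate(
        w_hat=w_hat, log_likelihood=-nll, converged=converged
    )
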