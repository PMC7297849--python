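"""Monte Carlo study of correlation attenuation.

Suppose some criterion correlates perfectly (r = 1) with ANS
sensitivity, i.e. with the Weber fraction ``w``, but sensitivity is
measured with the ratio effect slope.  Because the effect is a
nonlinear — possibly non-monotonic — function of ``w``, the observable
Pearson correlation between the slope and the criterion is attenuated,
sometimes to zero.  This module simulates that scenario: draw samples
of Weber fractions from a population, compute each participant's
model-implied ratio effect, correlate the two, and repeat.

The default populations are a typical adult group, Normal(0.17, 0.07),
and an adolescent group, Normal(0.279, 0.096); draws below a small
positive floor are resampled, since a non-positive Weber fraction is
undefined in the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .slopes import RatioPair, _as_pair, ratio_effect

__all__ = [
    "WeberDistribution",
    "ADULT_DIST",
    "ADOLESCENT_DIST",
    "SimConfig",
    "CorrelationDistribution",
    "sample_weber",
    "simulate_correlations",
    "paper_grid",
    "normal_coverage",
    "PAPER_GRID_PAIRS",
]


@dataclass(frozen=True)
class WeberDistribution:
    """Normal population model of Weber fractions, truncated from below.

    Draws below ``floor`` are resampled, keeping the distribution
    unimodal while excluding non-positive (model-undefined) values.
    """

    mean: float
    sd: float
    floor: float = 0.01
    label: str = ""

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0 or self.floor <= 0:
            raise ValueError("mean, sd and floor must all be positive")
        if self.floor >= self.mean + 6 * self.sd:
            raise ValueError(
                f"floor {self.floor} leaves essentially no mass above it "
                f"for Normal({self.mean}, {self.sd})"
            )

    def interval(self, k: float = 2.0) -> tuple[float, float]:
        """The mean +/- k*SD interval of the untruncated population."""
        return (self.mean - k * self.sd, self.mean + k * self.sd)


#: typical adult Weber-fraction population
ADULT_DIST = WeberDistribution(mean=0.17, sd=0.07, label="adult")
#: typical 14-year-old adolescent population
ADOLESCENT_DIST = WeberDistribution(mean=0.279, sd=0.096, label="adolescent")

#: the 3 ratio pairs crossed with the two populations in the reference grid
PAPER_GRID_PAIRS: tuple[tuple[float, float], ...] = ((1.125, 2.0), (1.25, 2.0), (2.0, 5.0))


def normal_coverage(k: float = 2.0) -> float:
    """Fraction of a normal population within mean +/- k*SD (in percent)."""
    return float(100.0 * (norm.cdf(k) - norm.cdf(-k)))


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo settings: sample size per replication, replications, seed."""

    n_participants: int = 50
    n_replications: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValueError("Pearson r needs at least 3 participants")
        if self.n_replications < 1:
            raise ValueError("need at least 1 replication")


@dataclass(frozen=True)
class CorrelationDistribution:
    """Distribution of per-sample Pearson correlations across replications."""

    r_values: np.ndarray
    n_dropped: int = 0
    dist_label: str = ""
    pair_label: str = ""

    def summary(self) -> dict:
        r = self.r_values
        q = np.quantile(r, [0.025, 0.25, 0.5, 0.75, 0.975]) if r.size else [np.nan] * 5
        return {
            "dist": self.dist_label,
            "pair": self.pair_label,
            "n": int(r.size),
            "n_dropped": self.n_dropped,
            "mean_r": float(np.mean(r)) if r.size else float("nan"),
            "mean_abs_r": float(np.mean(np.abs(r))) if r.size else float("nan"),
            "sd_r": float(np.std(r, ddof=1)) if r.size > 1 else float("nan"),
            "q025": float(q[0]),
            "q25": float(q[1]),
            "median": float(q[2]),
            "q75": float(q[3]),
            "q975": float(q[4]),
        }


def sample_weber(dist: WeberDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` Weber fractions from a truncated-normal population.

    Truncation is by resampling: values below ``dist.floor`` are redrawn
    until all ``n`` draws are valid, so every output is ``>= floor``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    w = rng.normal(dist.mean, dist.sd, size=n)
    bad = w < dist.floor
    while np.any(bad):
        w[bad] = rng.normal(dist.mean, dist.sd, size=int(bad.sum()))
        bad = w < dist.floor
    return w


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def simulate_correlations(
    dist: WeberDistribution,
    pair,
    config: SimConfig,
    effect_fn=None,
) -> CorrelationDistribution:
    """Monte Carlo distribution of corr(Weber fraction, ratio effect).

    Each replication draws ``n_participants`` Weber fractions from
    ``dist``, maps each to its model-implied ratio effect for ``pair``,
    and records the Pearson correlation between the two variables (sign
    retained).  Replications with zero variance in either variable are
    dropped and counted in ``n_dropped``.

    Per-replication RNG substreams are spawned deterministically from
    the root seed, so the first k replications are identical regardless
    of the total replication count.

    ``effect_fn`` (mapping an array of w to effects) replaces the model
    curve; it exists so tests can verify the perfectly linear limit.
    """
    p = _as_pair(pair)
    if effect_fn is None:
        effect_fn = lambda w: np.asarray(ratio_effect(p, w))
    children = np.random.SeedSequence(config.seed).spawn(config.n_replications)
    r_values = []
    n_dropped = 0
    for child in children:
        rng = np.random.default_rng(child)
        w = sample_weber(dist, config.n_participants, rng)
        eff = effect_fn(w)
        r = _pearson(w, eff)
        if np.isnan(r):
            n_dropped += 1
        else:
            r_values.append(r)
    return CorrelationDistribution(
        r_values=np.asarray(r_values),
        n_dropped=n_dropped,
        dist_label=dist.label,
        pair_label=p.label,
    )


def paper_grid(
    n_replications: int = 10_000,
    n_participants: int = 50,
    seed: int = 0,
    pairs=PAPER_GRID_PAIRS,
    dists=(ADULT_DIST, ADOLESCENT_DIST),
) -> list[CorrelationDistribution]:
    """Correlation distributions for the ratio-pair x population grid.

    Runs :func:`simulate_correlations` for every combination of the
    given ratio pairs (default 1.125–2, 1.25–2, 2–5) and Weber
    populations (default adult and adolescent), each cell with its own
    deterministic sub-seed.
    """
    results = []
    cell_seeds = np.random.SeedSequence(seed).generate_state(len(pairs) * len(dists)) % (2**31)
    i = 0
    for pair in pairs:
        for dist in dists:
            cfg = SimConfig(
                n_participants=n_participants,
                n_replications=n_replications,
                seed=int(cell_seeds[i]),
            )
            results.append(simulate_correlations(dist, pair, cfg))
            i += 1
    return results


def grid_summary(results: list[CorrelationDistribution]) -> pd.DataFrame:
    """Tabulate :meth:`CorrelationDistribution.summary` rows for a grid run."""
    return pd.DataFrame([res.summary() for res in results])
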