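"""Design audits and reproduction of the reference analysis products.

``run_audit`` answers the practical question: *for this set of ratios
and this expected Weber-fraction range, is the ratio effect slope a
usable index of ANS sensitivity?*  It composes the direction
classification, the expected-range index, and optionally the
correlation simulation into a single verdict:

- ``not-recommended`` — the slope cannot order observers by
  sensitivity: the effect–w relation is mixed (non-monotonic), the
  expected effect range is below the configurable floor, or the
  simulated correlation is attenuated below the correlation floor;
- ``recommended`` — the slope tracks the Weber fraction in the
  conventional (positive) direction with sufficient range;
- ``usable-with-reversed-sign`` — the slope is informative but its sign
  convention is the reverse of the usual one.

When the config gives a Weber *distribution* rather than an interval, a
correlation simulation is run and the verdict is based on the simulated
mean Pearson r — a finer instrument than the interval direction
heuristic, because mass near a peak of the effect curve barely moves
the correlation when most of the population sits on one limb.

``reproduce_paper`` regenerates the reference data products — the six
slope curves, the expected-range table, and the 3 x 2 correlation grid
— as CSV files with a JSON manifest of every parameter and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation as corr
from . import slopes

__all__ = ["AuditReport", "run_audit", "reproduce_paper"]

#: minimum expected effect range for a "usable" verdict
DEFAULT_RANGE_FLOOR = 0.1
#: minimum simulated |mean r| for a "usable" verdict in distribution mode
DEFAULT_CORR_FLOOR = 0.5

_ALLOWED_KEYS = {
    "pair",
    "w_interval",
    "distribution",
    "grid_step",
    "range_floor",
    "corr_floor",
    "n_participants",
    "n_replications",
    "seed",
}


@dataclass(frozen=True)
class AuditReport:
    """Verdict on a comparison-task design's slope validity."""

    pair: str
    w_interval: tuple[float, float]
    direction: slopes.DirectionClass
    slope_range: slopes.SlopeRange
    correlation_summary: dict | None
    verdict: str

    def to_dict(self) -> dict:
        d = {
            "pair": self.pair,
            "w_interval": list(self.w_interval),
            "direction": self.direction.label,
            "fraction_negative_steps": self.direction.fraction_negative_steps,
            "min_effect": self.slope_range.min_effect,
            "max_effect": self.slope_range.max_effect,
            "range": self.slope_range.range,
            "verdict": self.verdict,
        }
        if self.correlation_summary is not None:
            d["correlation"] = self.correlation_summary
        return d

    def summary(self) -> str:
        lines = [
            f"Design audit for ratio pair {self.pair}, Weber interval "
            f"[{self.w_interval[0]:g}, {self.w_interval[1]:g}]",
            f"  direction        {self.direction.label} "
            f"(fraction of negative steps {self.direction.fraction_negative_steps:.3f})",
            f"  effect range     {self.slope_range.range:.3f} "
            f"(min {self.slope_range.min_effect:.3f}, max {self.slope_range.max_effect:.3f})",
        ]
        if self.correlation_summary is not None:
            lines.append(
                f"  mean r           {self.correlation_summary['mean_r']:.3f} "
                f"(mean |r| {self.correlation_summary['mean_abs_r']:.3f})"
            )
        lines.append(f"  verdict          {self.verdict}")
        return "\n".join(lines)


def _validate_config(config: dict) -> None:
    bad = sorted(set(config) - _ALLOWED_KEYS)
    if bad:
        raise ValueError(f"unknown audit config keys: {bad}")
    if "pair" not in config:
        raise ValueError("audit config must name a ratio 'pair'")
    if "w_interval" not in config and "distribution" not in config:
        raise ValueError("audit config must give a 'w_interval' or a 'distribution'")


def run_audit(config: dict) -> AuditReport:
    """Audit a design given as a config mapping.

    Keys: ``pair`` (two ratios), and either ``w_interval`` ([lo, hi]) or
    ``distribution`` ({mean, sd, [floor]}; the audited interval is then
    mean +/- 2 SD and a correlation simulation is run).  Optional:
    ``grid_step``, ``range_floor``, ``n_participants``,
    ``n_replications``, ``seed``.
    """
    _validate_config(config)
    pair = slopes.RatioPair(*config["pair"])
    grid_step = float(config.get("grid_step", slopes.DEFAULT_GRID_STEP))
    range_floor = float(config.get("range_floor", DEFAULT_RANGE_FLOOR))

    corr_summary = None
    if "distribution" in config:
        d = config["distribution"]
        dist = corr.WeberDistribution(
            mean=float(d["mean"]),
            sd=float(d["sd"]),
            floor=float(d.get("floor", 0.01)),
            label=str(d.get("label", "custom")),
        )
        w_interval = dist.interval(2.0)
        w_interval = (max(w_interval[0], dist.floor), w_interval[1])
        cfg = corr.SimConfig(
            n_participants=int(config.get("n_participants", 50)),
            n_replications=int(config.get("n_replications", 1000)),
            seed=int(config.get("seed", 0)),
        )
        corr_summary = corr.simulate_correlations(dist, pair, cfg).summary()
    else:
        w_interval = (float(config["w_interval"][0]), float(config["w_interval"][1]))

    direction = slopes.classify_direction(pair, w_interval, grid_step)
    slope_range = slopes.expected_range(pair, w_interval, grid_step)

    if slope_range.range < range_floor:
        verdict = "not-recommended"
    elif corr_summary is not None:
        corr_floor = float(config.get("corr_floor", DEFAULT_CORR_FLOOR))
        mean_r = corr_summary["mean_r"]
        if mean_r >= corr_floor:
            verdict = "recommended"
        elif mean_r <= -corr_floor:
            verdict = "usable-with-reversed-sign"
        else:
            verdict = "not-recommended"
    elif direction.label == "mixed":
        verdict = "not-recommended"
    elif direction.label == "positive":
        verdict = "recommended"
    else:
        verdict = "usable-with-reversed-sign"

    return AuditReport(
        pair=pair.label,
        w_interval=w_interval,
        direction=direction,
        slope_range=slope_range,
        correlation_summary=corr_summary,
        verdict=verdict,
    )


def reproduce_paper(
    outdir,
    n_replications: int = 10_000,
    n_participants: int = 50,
    seed: int = 0,
    grid_step: float = slopes.DEFAULT_GRID_STEP,
    w_range: tuple[float, float] = (0.04, 1.0),
) -> list[Path]:
    """Regenerate the reference data products into ``outdir``.

    Writes one slope-curve CSV per ratio pair, the expected-range table,
    one correlation-distribution CSV per grid cell with a combined
    summary, and a JSON manifest of all parameters and seeds.  Returns
    the list of written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    grid = np.arange(w_range[0], w_range[1] + grid_step / 2, grid_step)
    for pair in slopes.PAPER_RATIO_PAIRS:
        curve = slopes.slope_curve(pair, grid)
        path = out / f"slope_curve_{curve.pair.label}.csv"
        curve.to_frame().to_csv(path, index=False)
        written.append(path)

    table = slopes.range_table(grid_step=grid_step)
    path = out / "range_table.csv"
    table.to_csv(path, index=False)
    written.append(path)

    directions = slopes.direction_table(w_interval=w_range, grid_step=grid_step)
    path = out / "direction_table.csv"
    directions.to_csv(path, index=False)
    written.append(path)

    results = corr.paper_grid(
        n_replications=n_replications, n_participants=n_participants, seed=seed
    )
    for res in results:
        path = out / f"correlations_{res.pair_label}_{res.dist_label}.csv"
        pd.DataFrame(
            {
                "dist_label": res.dist_label,
                "pair": res.pair_label,
                "replication": np.arange(res.r_values.size),
                "r": res.r_values,
            }
        ).to_csv(path, index=False)
        written.append(path)
    path = out / "correlation_summary.csv"
    corr.grid_summary(results).to_csv(path, index=False)
    written.append(path)

    manifest = {
        "seed": seed,
        "n_replications": n_replications,
        "n_participants": n_participants,
        "grid_step": grid_step,
        "w_range": list(w_range),
        "ratio_pairs": [list(p) for p in slopes.PAPER_RATIO_PAIRS],
        "correlation_pairs": [list(p) for p in corr.PAPER_GRID_PAIRS],
        "distributions": [asdict(corr.ADULT_DIST), asdict(corr.ADOLESCENT_DIST)],
        "files": [p.name for p in written],
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    written.append(path)
    return written
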