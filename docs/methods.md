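# Methods

## The representational model

The package assumes the standard Gaussian model of the approximate
number system (ANS): a magnitude *n* is represented as a normal random
variable with mean *n* and standard deviation *w·n*, where the Weber
fraction *w* indexes (in)sensitivity. For a two-alternative comparison
of numbers with ratio *r* = larger/smaller ≥ 1, the two representations
are placed on a normalized axis at means (1, *r*) with SDs (*w*, *r·w*).
The model is scale-invariant (Weber's law): any pair with the same ratio
yields the same predictions, which the test suite verifies directly by
integrating at several absolute scales.

Discriminability is summarized by the representational overlap, the
integral of the pointwise minimum of the two densities. It lies in
[0, 1], equals 1 for identical representations (*r* = 1), decreases in
*r*, and increases in *w*. The noiseless limit *w* = 0 is defined as the
point-mass convention (overlap 1 iff *r* = 1, else 0) rather than an
error, so interval scans may touch zero.

## Evaluating the overlap integral

`overlap` is closed-form. Equating the two Gaussian log-densities gives
a quadratic whose two real roots (guaranteed when the SDs differ, i.e.
whenever *r* > 1) split the real line into three segments; on each
segment one density is uniformly the smaller, decided by evaluating both
log-densities at the segment midpoint, and the integral is a sum of
normal-CDF segment masses. Results are clamped to [0, 1] (absolute
tolerance 1e-8 on rounding residue). The computation is vectorized over
*w* (and *r*), which is what makes the Monte Carlo study cheap.

`overlap_oracle` is an intentionally independent verification path: a
trapezoid Riemann sum of min(f₁, f₂) on a dense grid spanning ±8 SD
beyond both means. The two paths agree to < 1e-4 across the full
(ratio, Weber fraction) lattice used in the tests; the oracle is never
used outside tests.

## Ratio-effect diagnostics

The ratio effect for a pair r₁ < r₂ is o(r₁, w) − o(r₂, w), non-negative
by monotonicity of the overlap in the ratio (tiny negative rounding
residue is clamped). For multi-ratio designs `linear_slope` returns the
OLS slope of overlap against ratio with its natural (negative) sign; for
exactly two ratios it equals −effect/(r₂ − r₁), an identity the tests
check to 1e-10. The two-ratio effect is deliberately *not* normalized by
the ratio difference: the raw overlap difference is the standardized
[0, 1] index used throughout, and the OLS slope is provided for designs
that need the per-unit-ratio quantity.

`expected_range` evaluates the effect on a dense *w* grid (default step
1e-3, which resolves the interior peak of every reference curve well
below reporting precision) and reports min, max and range — a
standardized variability index: the larger the range over the Weber
interval a sample is expected to span, the better the slope can separate
observers (better signal-to-noise, hence a component of reliability).

`classify_direction` takes successive finite differences of the effect
curve on the same grid; steps smaller than 1e-6 in magnitude count as
neither sign. With fraction of negative steps ≥ 0.8 the relation is
labelled `negative`, ≤ 0.2 `positive`, otherwise `mixed`. The 0.8/0.2
thresholds quantify an inherently qualitative "mostly" and are
configurable; under the defaults the six reference ratio pairs on
[0.04, 1.0] classify as 1.125–1.4 negative, 1.125–2.0 negative,
1.125–4.0 mixed, 1.5–5.0 mixed, 2.0–5.0 mixed, 4.0–9.0 positive. A
mixed label means the slope cannot even order observers by sensitivity
over that interval.

## Correlation attenuation Monte Carlo

The simulation asks what Pearson correlation would be *observed* between
the ratio effect and a criterion that correlates perfectly with the
Weber fraction, when the effect — not *w* — is the measured index. Each
replication draws `n_participants` (default 50) Weber fractions from a
normal population, maps each through the model's effect curve for the
chosen ratio pair, and records corr(w, effect) with its sign retained.
Default populations: adults Normal(0.17, 0.07) and adolescents
Normal(0.279, 0.096); the reference grid crosses these with the ratio
pairs 1.125–2, 1.25–2 and 2–5 at 10,000 replications (library and CLI
expose the replication count; the test suite and audits use 200–1,000,
which keeps the Monte Carlo error on the mean r below ~0.01).

Normal draws below a floor (default 0.01) are resampled, since a
non-positive Weber fraction is undefined in the model; resampling keeps
the population unimodal. The floor and the truncation rule are
package-level modelling choices, configurable on `WeberDistribution`.
Replications with zero variance in either variable have no defined
Pearson r and are dropped and counted (`n_dropped`) rather than recorded
as 0, which would bias the distribution summaries.

Randomness policy: one root seed; per-replication substreams are spawned
deterministically (`numpy` `SeedSequence.spawn`), so the first *k*
replications are bit-identical regardless of the total replication
count, and grid cells derive independent sub-seeds from the root.

## Synthetic trials and Weber-fraction recovery

The behavioral layer needs a link from overlap to choice behavior, which
the representational model itself does not pin down. The package's
choice — an explicit modelling extension — is the equal-prior optimal
observer: the decision boundary sits where the two densities cross, and
the error probability is half the overlapping mass, error(r, w) =
o(r, w)/2 ∈ [0, 0.5]. This overlap-derived accuracy curve plays the role
of the psychometric "sigmoid" (chance at ratio 1, falling toward 0 as
the ratio grows); no lapse or guessing parameter is added, so the
generator and the estimator share exactly one model and parameter
recovery is well-posed. The cumulative-Gaussian-of-log-ratio family used
in some empirical work is a different, deliberately unimplemented
choice.

`simulate_trials` draws binomial error counts per ratio.
`estimate_weber` maximizes the binomial likelihood over *w* by bounded
scalar search on [1e-3, 2] (tolerance 1e-6 on *w*; predicted error
probabilities clipped to [1e-12, 0.5 − 1e-12] inside the likelihood).
Degenerate data — zero errors everywhere, or all conditions at chance —
leave the likelihood flat out to a bracket boundary; such fits return
the boundary value with `converged = False` instead of raising. Under
the reference recovery conditions (true w = 0.2, 8 log-spaced ratios in
[1.1, 3], 500 trials per ratio) the estimate lands within ±0.03 of truth
in over 95% of seeded runs, with bias below 0.001.

## Audit verdicts

`run_audit` composes the diagnostics into one of three verdicts.
Interval mode (only a Weber interval given): `not-recommended` if the
direction is mixed or the expected effect range falls below the range
floor (default 0.1 on the [0, 1] index); otherwise `recommended` for a
positive relation and `usable-with-reversed-sign` for a negative one
(the conventional sign being positive — larger effect, larger Weber
fraction — which holds on the rising limb of the effect curve).
Distribution mode (a population given): a correlation simulation is run
and the verdict follows the simulated mean r against a correlation floor
(default 0.5), because the interval heuristic is too coarse there — a
population whose mass sits mostly on one limb of the effect curve can
retain a high correlation even though the mean ± 2 SD interval straddles
the peak. Both floors are configurable; reversed-sign usability is
reported, never silently hidden.

## What the synthetic generator does and does not emulate

The generator produces exactly the world the model assumes: binomial
errors at model-predicted rates, one fixed *w* per simulated observer,
no lapses, no sequential effects, no reaction times, no perceptual
stimulus confounds (dot-array density and the like), and no measurement
noise beyond binomial sampling. Passing recovery tests therefore show
that the estimator inverts the model correctly at realistic trial
counts — not that real comparison data are this clean. Reaction-time
pathways and non-Gaussian (e.g. log-scaled) representational variants
are out of scope.

## Numerical choices and problem sizes

Grid step on *w* defaults to 1e-3 for curves, ranges and classification;
the overlap tolerance is 1e-8 with clamping to [0, 1]; direction steps
below 1e-6 are sign-neutral; the ML search bracket is [1e-3, 2] with
xatol 1e-6. The test suite runs the correlation grid at 200–1,000
replications and recovery at 30–200 seeds; the full 10,000-replication
grid is a one-liner (`paper_grid()`) and scales linearly.

## Known limitations

- The overlap→error link (optimal observer, error = overlap/2) is a
  modelling extension; other links change absolute error rates but not
  the overlap-based diagnostics.
- Direction labels near the 0.8/0.2 thresholds can flip with the grid
  step for pairs whose curves are nearly flat at one end; the six
  reference pairs are far from the thresholds.
- The truncation floor for population sampling is a convention; with the
  default populations fewer than ~1% of draws hit it, so summaries are
  insensitive to the exact rule.
- `WeberDistribution.interval` describes the untruncated normal; for
  heavily truncated populations the audited interval slightly overstates
  the lower tail.
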