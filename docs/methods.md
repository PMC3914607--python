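# Methods

This note records the model, its parameters and defaults, the numerical
choices behind the estimators, what the synthetic data do and do not
emulate, and the design decisions taken where the problem was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Movement model

Movement is a discrete-time biased random walk with a localizing tendency.
Per 5-minute interval (Δt = 300 s):

- with probability ψ the fish attempts a move; otherwise it holds
  position;
- the move distance d ~ Exponential(λ) is clamped at `max_move` = 6000 m
  (72 km/h sustained over one interval is implausible for reef fish; the
  draw is clamped, not resampled) and suppressed to "no move" when
  d < `min_move` = 200 m, the spatial resolution of acoustic positioning.
  Because suppression happens after the Bernoulli decision, the realised
  discernible-move rate is ψ·exp(−min_move/λ), slightly below ψ;
- the direction is von Mises with concentration κ about the bearing from
  the current position to the home-range center. The density used is the
  standard exp[+κ cos(θ − θ̄)] kernel, which peaks toward the center so
  that larger κ means stronger home-range affinity. When the fish sits
  exactly at its center the bearing is undefined and the direction is
  uniform — the limiting case of a vanishing bias vector.

Sampling uses numpy's von Mises generator (Best–Fisher rejection) with a
uniform fallback below κ = 1e-9. All randomness flows from one seeded
`numpy.random.Generator`; cohort runs derive an independent child
generator per fish, so results are reproducible and order-independent.

Parameter defaults (per species) are the field-derived values packaged in
`reefrange.params`: ψ ∈ {0.0080, 0.0056, 0.0576}, λ ∈ {561, 456, 608} m,
κ ∈ {3.67, 1.19, 3.20} for red grouper, black grouper and mutton snapper
respectively. These are treated as study conditions, not tuning knobs.

## Grid world and recording

The world is a square-cell tiling (default 200 m cells) of a rectangular
region at least 20 km on a side centred on the receiver array, so that
one-year paths rarely meet the boundary; if a fish does leave, the extent
auto-expands rather than reflecting (nothing in the movement rules stops
a fish at a map edge). Depth is carried as metadata only — movement is
independent of habitat. After each continuous-coordinate step the
destination snaps to the nearest cell center; if the clamp-then-snap
combination would exceed `max_move`, the destination retreats along the
move direction until the bound holds exactly. Tracks are recorded at
every interval (piecewise-constant between moves) and stored as dwell
segments, which makes one-year runs cheap: only move events are iterated.

## Detection and positioning

Expected detections per (interval, fish, receiver) are
(Δt / ping) · p(d): deterministic fractional counts, with an optional
Poisson mode for stochastic studies (off by default). The ping interval
defaults to 105 s, the mean of a uniform 30–180 s random tag delay. The
range curve is logistic, p(d) = p₀ / (1 + exp((d − d50)/slope)) with
p₀ = 1, d50 = 300 m, slope = 50 m. Real arrays calibrate p(d) per
receiver; the logistic stands in for such a calibration and every
experiment records the parameters used.

Fixes are estimated per 5-minute batch (batch windows are anchored on the
wall clock, not on the first detection). The estimator is a two-pass
weighted centroid: pass one weights receiver positions by raw counts;
pass two re-weights by countᵢ / p(r̂ᵢ), the inverse detection probability
at the distance from the provisional fix to receiver i. Inverse-p
weighting compensates for the detection fall-off that otherwise drags
fixes toward the nearest receiver. The fix always lies in the convex hull
of contributing receivers; a single-receiver batch fixes the fish at that
receiver. The weighting scheme is pluggable (raw-count centroid available
via `n_passes=1`).

## Home-range estimators

**MCP.** The 100 % minimum convex polygon is the convex hull area of all
distinct fixes (`scipy.spatial.ConvexHull`). Collinear fix sets are
flagged `linear` with zero area rather than reported as a number, matching
how degenerate tracks appear in field summaries.

**KD.** A bivariate Gaussian kernel density evaluated on a 20 m grid; the
x % home range is the smallest set of grid cells containing x % of the
density volume (cells sorted by density, mass accumulated — no
polygonization is needed for an area). The bandwidth is a full
(unconstrained) 2×2 matrix chosen by smoothed cross-validation:

SCV(H) = (4π)^(−1) n^(−1) |H|^(−1/2) +
n^(−2) Σᵢⱼ [φ_{2H+2G} − 2φ_{H+2G} + φ_{2G}](Xᵢ − Xⱼ)

with pilot G = n^(−1/3) S (normal-scale, S the weighted sample
covariance). Passive telemetry produces massive fix duplication — the
regime in which cross-validation selectors degenerate — so the selector
runs on binned data with multiplicity weights: fixes are histogrammed on
the evaluation grid, the pairwise-difference sum collapses onto the
difference lattice via one FFT autocorrelation, and each objective
evaluation is linear in the number of occupied difference cells. The
optimiser is Nelder–Mead over the log-Cholesky parameters of H, started
at the normal-scale matrix. Failures are detected, not crashed on: fewer
than five distinct fixes, a singular covariance, or an optimum below the
bin resolution (mass concentrated at one or two sites) yield
status `failed` with no area. With n ≈ 10⁵ heavily duplicated fixes the
selected bandwidths are small (tens of metres), so KD areas track the
dwell distribution closely; with hundreds of distinct fixes they approach
the normal-reference scale.

**Area-observation curves.** The estimator is re-applied to all fixes up
to each multiple of a time step (default one mean month, 30.4375 d). The
MCP curve is non-decreasing by construction. Asymptote classification is
deliberately explicit configuration, since no standard thresholds exist:
`Yes` if the relative area increase over the final step is < 5 %, `Maybe`
if < 15 %, else `No`.

## Parameter fitting

Moves are consecutive-fix displacements ≥ 200 m. ψ̂ = moves / intervals;
for simulated tracks the denominator is every tracked interval, for
observed-style data the intervals with fixes (both modes exposed). λ is
fit by the exponential MLE (sample mean, SE = λ̂/√n); on clamped data this
estimates the truncated mean λ(1 − e^(−C/λ)) — asserted against the
closed form in the tests, and the reason recovery tests compare against
the truncation-adjusted truth. κ is fit by inverting the Bessel ratio
A(κ) = I₁/I₀ = R̄ (Newton polish on standard series starts), with no
small-sample bias correction; R̄ = 0 gives κ = 0 and identical angles cap
at 10³. The home-range center for θ̄ defaults to the arithmetic centroid
of the fish's fixes; moves originating exactly at the center have no
defined bearing and are excluded from the circular fit (they still count
for ψ and λ). Grid snapping adds ~±100 m destination noise, which
attenuates κ̂ by a few percent for short moves; recovery tolerances
(±10 %) absorb this.

Two bootstrap procedures probe sensitivity: B subsamples of m moves
without replacement (default m = 437, B = 1000) test pure sample-size
effects, and the pair-pooling bootstrap (100 iterations of pooling two
random fish) tests individual representativeness — with a mixture of
movers the across-iteration range spans both modes.

## Evaluation experiments

A cohort experiment instantiates one fish per receiver (home ranges
centred atop the receivers), simulates one year, and computes MCP and
95 % KD from both the true paths and the array-derived fixes; group means
exclude linear/failed estimates with n reported, and paired differences
are recomputed from per-fish pairs. The per-receiver bias map reports
100·(SimDetect − SimActual)/SimActual and a one-tailed equal-variance
two-sample t for peripheral vs core receivers, where *peripheral* means
on the boundary (vertex or edge) of the array's convex hull — a receiver
on a hull edge is not completely surrounded by other receivers. The
filter analysis applies (days, detections, asymptote, peripheral-class)
criteria to a per-fish table; `Linear` rows stay in the filtered count N
but are excluded from area means.

The packaged per-fish tracking summary (44 red grouper, 2 black grouper,
2 mutton snapper) ships as a checksum-verified CSV so the filter analysis
runs with no external data. Peripheral classes in that table
(Low…Very high) are taken as given; for simulated fish only the binary
core/peripheral rule above is computed.

## Synthetic data: what it does and does not emulate

The generators produce receiver grids (staggered, 600 m default spacing,
32 receivers), movement tracks with known ground truth (sidecar files),
and deterministic detection logs. They emulate the *structure* of passive
telemetry data — duplicated fixes, gappy coverage, center-biased tracks —
but not: calibrated per-receiver range curves, tag collisions, habitat- or
depth-dependent movement, biphasic/spawning migrations, tide- or
diel-driven detection variability, or real bathymetry. Passing tests
therefore validate the estimators and the simulation machinery, not any
claim about a particular reef.

A further caution on magnitudes: the exponential step-length tail
dominates one-year convex hulls. With λ ≈ 560 m and ~600 discernible
moves per year, the largest yearly step is ≈ λ·ln(n) ≈ 3.6 km, and each
such excursion endpoint is a hull vertex, so simulated 100 % MCPs under
these parameter sets are on the order of 20 km² — an order of magnitude
above typical field estimates for the same species, whose observed
displacement distributions are far shorter-tailed than a fitted
exponential. Simulated MCP magnitudes should be read as upper bounds that
are extremely sensitive to the step-length tail; the *comparative*
quantities (Sim-Detect vs Sim-Actual, core vs periphery) are the robust
outputs. The same sensitivity analysis is recorded with the acceptance
results.

## Problem sizes and determinism

Default experiment sizes: 32 fish × 105,120 five-minute intervals (one
year); KD on 20 m grids via FFT convolution; SCV objective over occupied
difference cells only. A full three-species cohort run with KD completes
in a few minutes on one CPU. Every run is reproducible from its config
and a single integer seed; run directories echo the full configuration.

## Known limitations

- The SCV pilot is a one-step normal-scale choice; iterated pilots could
  shift selected bandwidths somewhat, and SCV on near-degenerate data is
  reported as failure rather than rescued.
- The positioning estimator is a documented contract, not a reconstruction
  of any proprietary system; absolute Sim-Detect magnitudes are
  array- and range-curve-specific.
- Movement is single-phase and habitat-blind; centers are fixed for life.
- Areas are planar (local metric coordinates); no geodesy.
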