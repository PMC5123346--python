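# Methods

## Model and assumptions

The package implements a continuous, one-sided model of duplicate-region
deletion after whole-genome duplication.  One genome copy (the
fractionating copy) is a line segment whose points are initially all
visible; the other copy is intact and provides a length-preserving
reference, so deleted ("invisible") intervals remain observable.  Deletion
proceeds in sweeps.  Within a sweep, successive events are placed along
the concatenation of the segments visible at the start of that sweep: a
spacing drawn from Exponential(mean ν) is followed by a deleted length
drawn from Exponential(mean μ), and the cursor advances by spacing +
length, so event intervals within one sweep are ordered and disjoint in
that frame.  Sweeps are mutually independent.  All deletions act on one
copy only; two-sided deletion and subgenome dominance are out of scope.

Each invisible run is anchored by the deletion point at its left end,
carrying an event counter: a new deletion that swallows q existing
deletion points with counters C₁…C_q produces one run with counter
1 + ΣC_j.  The proportion π_t(i) of counters equal to i is tracked both
empirically (simulator census) and analytically (per-event update).

Model quantities with exact or near-exact forms:

- mean spacing of surviving deletion points after sweep t: λ_t = ν/t
  (the one-step recursion λ_t = ν/(1 + ν/λ_{t−1}) telescopes);
- expected retained fraction after t sweeps: (1 − μ/(ν+μ))^t;
- overlap counts q geometric with parameter μ/(μ+λ).

An older two-sweep approximation of λ₂ with a (ν+μ) term is exposed as
`lambda_two_sweep_approx` for completeness; it disagrees with the
recursion (which gives ν/2) and is used nowhere.

## Simulator

Coordinates are continuous reals; segments are half-open [start, end) so
alternation is unambiguous at junctions.  A deletion point falling
exactly on a junction (a measure-zero float event) belongs to the visible
segment on its right.  A sweep generates events until the next deletion
point leaves the current visible extent; a final interval overhanging the
right edge is truncated there (its counter still merges swallowed
points).  The whole sweep is applied as one batch in the sweep-start
concatenated frame, which matches the sequential construction exactly and
keeps a sweep O(events + segments).

Randomness: one seed drives everything.  `run_fractionation` spawns an
independent RNG substream per (replicate, sweep) via `SeedSequence`, so
trajectories are bit-reproducible and replicates independent; spacings
and lengths are drawn in strict alternation within a sweep.

**Replenishment.**  With a finite window the genome would shrink by
(1 − μ/(ν+μ)) per sweep, so after each sweep visible material is copied
from a replicate's post-sweep snapshot (round-robin donor; a
single-replicate run falls back to self-copying) until the visible length
is back to G.  Copied segments keep their counters verbatim, since π_t is
tracked across sweeps.  Copying starts in the donor's bulk (at its
visible midpoint, wrapping cyclically) rather than at its left edge: each
sweep restarts its spacing at the origin, making edge segments
systematically denser, and repeatedly duplicating that edge material
measurably biased the visible spacing.  At a splice the donor chunk
starts with visible material; a visible-on-visible junction extends the
recipient's last visible segment (no donor mass is dropped), and the last
copied visible segment is truncated so the visible total hits G exactly.
Validation: simulated mean visible length matches ν/t and mean invisible
length matches (1−ρ_t)/ρ_t · ν/t (ρ_t the retained fraction) to a few
tenths of a percent at n > 10⁵.

The standard design is G = 10,000 with 5 replicates — G at least 100μ so
a genome survives the t ≤ 10 regime without artifacts; the code warns
below that ratio.

## Event-count update

Per deletion event, the expected change of the counter census is

    Δ(i) = gain(i) − π(i)·Σ_q q·p_q,   Σ_q q·p_q = μ/λ,
    gain(i) = p₀·1{i=1} + Σ_{q=1}^{i−1} p_q · (π*q)(i−1),

where (π*q)(m) is the q-fold convolution of π — the sum over ordered
compositions of i−1 into q positive parts of Ππ(c_j).  The update treats
swallowed counters as independent draws from π; they are in fact
positively dependent through genome geometry, and the census comparison
test bounds the resulting bias (total variation ≲ 1%, t ≤ 4 at μ=1, ν=3).

Turning per-event changes into a per-sweep update requires relative
rates.  The default mode ("event-rate") uses exact bookkeeping: with N
existing counters and E events, updated proportions are
(N·π + E·Δ)/(N + E(1 − μ/λ)), with E/N = λ_{t−1}/(ν+μ) under the sweep
model and λ_{t−1} = ν/(t−1) the spacing among points existing when sweep
t runs (sweep 1 is the exact point mass at 1).  A "renormalize" mode
(π + Δ, renormalized — one event per existing counter) is shipped for
comparison; at t = 2 with μ = ν the exact census is π₂(1) = 3/4, which
the event-rate mode reproduces and the renormalize mode (1/2) does not,
hence the default.

## Fitting

Visible lengths: exponential MLE, rate = 1/mean.  Invisible lengths:
gamma by MLE (`scipy.stats.gamma.fit` with location pinned at 0); the
method-of-moments estimate (shape = mean²/var, rate = mean/var) is the
fallback and diagnostic.  β is a *rate* throughout (1/β scales with μ).
Lengths below 1e−12 — float-truncation artifacts of splices — are dropped
with a logged count.  Cullen–Frey coordinates use unbiased sample
skewness and kurtosis in the Pearson convention (normal = 3), with an
optional bootstrap cloud.

The gamma is a working approximation, not a law of the model: the
fitted-gamma KS distance on per-genome samples grows from ≈2% of CDF at
t = 2 to ≈6–8% by t = 5 (also in pure, non-replenished runs).  Tests
bound this adequacy explicitly rather than asserting exact gamma-ness.
Moment (Cullen–Frey) diagnostics are far less sensitive than KS and show
the gamma family as the natural description, which is the sense in which
the package uses it.

## Calibration

The empirical laws are 1/α − 1 = s(r)(t−1) and 1/β = μ·exp(b(r)(t−1))
with r = μ/ν and s, b quadratic in r.  `calibrate` re-derives the
coefficients: simulate a grid of ratios, fit gammas per (r, t) from
pooled replicates, fit the two per-r lines through their pinned
intercepts (both laws force them at t = 1; free-intercept fits are
available for diagnostics), then fit unweighted quadratics of the slopes
vs r.  Defaults mirror the reference design: ratios (0.1, 0.2, 1/3, 0.5),
t = 1…7, G = 10,000, 5 replicates.  Calibration is seed-reproducible.

Two caveats, measured and documented rather than hidden:

- The quadratic coefficients themselves are ill-conditioned (four grid
  points); the slope *functions* on the grid are stable to a few percent
  across seeds, and they are what inference consumes.  A recalibrated
  set therefore carries its r-domain (grid minimum to 2× grid maximum),
  and the shape-law inversion rejects roots outside it: below the grid
  the quadratic is extrapolation and admits degenerate
  "many-sweeps-of-tiny-deletions" solutions, and far above it the fit has
  no support.  The reference coefficient set's negative intercept
  (s(r) < 0 for r < 0.077) plays the same role implicitly.
- The linear-in-(t−1) shape law is an approximation: the measured slope
  (1/α − 1)/(t−1) at fixed r drifts upward by several percent between
  t = 2 and t = 10 (with and without replenishment).  A single s(r)
  cannot match all t simultaneously; consequences for inference are
  below.

## Inference

Given observables (λ⁻¹, α, β), candidate t gives ν_t = t/λ⁻¹ (exact
arithmetic), r from the smaller admissible root of
s(r) = (1/α − 1)/(t−1) (s is increasing below its vertex, so that root
is the inverse; r_cap defaults to 1.5, tightened by a coefficient set's
r-domain), μ_t = r·ν_t, β_t from the rate law, and
δ = |β − β_t|/β — the absolute value matters because candidate tables
legitimately contain β_t > β.  t̂ is the δ-argmin; ties break toward
smaller t.  The scan range defaults to t = 1…30; no admissible candidate
raises an error carrying the full candidate table.

**Sensitivity.**  δ separates neighbouring t by as little as a few
hundredths of a percentage point (the reference worked example at t = 5
has δ = 3.364 vs 3.409 at t = 4), so t̂ is reliable only where the
calibrated laws match the simulator at the true t to ~1%.  In end-to-end
recovery at the four preset configurations this holds for (μ=1, ν=3,
t=3), and (μ=6, ν=12, t=2); at (1, 3, 5) the shape-law drift can flip t̂
to 4 (with μ̂, ν̂ then off by one sweep's worth), and at (5, 15, 8) the
predicted β_t curve is nearly flat (within ~0.3% across t = 5…11) while
sitting ~14% from the observed β, making the sweep count effectively
non-identifiable there.  ν̂ = t̂/λ⁻¹ remains accurate whenever t̂ is
right, and μ̂ is robust even along the flat ridge.

## Problem sizes in tests

The suite simulates at the standard design (G = 10,000, 5 replicates) for
distributional checks, 20 seeds for mean-law checks, and a 200,000-length
single-replicate run only during exploratory validation (not in the
suite).  Monte-Carlo assertions use 3-standard-error bands where the
compared quantity is exact in expectation, and explicit measured bounds
(stated in each test) where it is a documented approximation.

## Known limitations

- One-sided deletion only; no subgenome dominance, no discrete
  gene-order geometry, no mapping to genome annotation formats
  (coordinates are abstract reals; the BED-like export rounds for
  visualization only).
- The gamma description of invisible lengths and the linear shape law
  are approximations whose error grows with t; inference of t beyond
  t ≈ 7 should be treated as an interval, not a point estimate.
- No uncertainty quantification on (μ̂, ν̂, t̂): the procedure is a
  discrete scan by construction.
- Replenishment splices introduce weak dependence between replicates
  (copied material); pooled-fit standard errors are slightly optimistic.
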