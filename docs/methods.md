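# Methods

## Model

The decision process is a Wiener diffusion with drift `ν` and infinitesimal
variance `s²` on the interval `[0, a]`, started at `z = z_rel·a` and stopped
at the first boundary hit. Upper-boundary hits are "positive" responses,
lower-boundary hits "negative" ones; the observed response time adds a
non-decision component `t0`. The lower-boundary absorption probability is
the continuum gambler's-ruin formula, and the density of lower-boundary
hitting times is the classical large-time sine series (Fürth's formula for
first passages); upper-boundary quantities follow from the reflection
`ν → −ν`, `z → a − z`. `s` is a scale convention, not a parameter: the
simultaneous map `(a, ν, s) → (ca, cν, cs)` leaves every observable
unchanged, which the tests verify to floating-point accuracy.

Units: the process runs in seconds; `t0`, `s_t0` and all output grids are
milliseconds; densities are per second. The defaults (`a=1, z_rel=0.5,
ν=0.2, t0=300 ms, s²=1`) then put the density mode a few hundred
milliseconds after `t0`, in the range typical of speeded decisions.

## Series evaluation and its artifact layer

The infinite sum is truncated at `kmax` terms (default 100), with an early
exit once two consecutive terms fall below 1e-15 of the running maximum
(two, because individual sine factors can vanish exactly — every even `k`
at `z_rel = 1/2` — and a single tiny term does not imply convergence).
Exponents are clipped at −746 so deep tails underflow cleanly to zero, and
the prefactor `e^(−zν/s²)` is folded into each term's exponent so extreme
drifts cannot overflow.

A fixed truncation leaves a thin layer just above `t0` where the series has
not converged: partial sums there oscillate, dip below zero, and for
strongly drift-amplified parameter sets (`e^{|z'ν'|/s²}` large) can reach
absurd magnitudes even though the true density is effectively zero (any
appreciable first-passage mass at such small times would imply a converged
series). Both symptoms are treated as one artifact: after the truncated
sum, the first two omitted terms serve as a convergence probe, and any
point whose probe exceeds 1% of the partial sum (or whose sum is negative)
is reported as zero density, with a `TruncationArtifactWarning` giving the
count. Without this diagnostic, clamping negatives alone would leave
spurious positive spike mass of up to ~0.4 probability units for extreme
parameter sets; with it, probability mass is conserved to better than 1e-6
on adequately fine grids across `a ∈ [0.5, 3]`, `|ν| ≤ 3`,
`z_rel ∈ [0.1, 0.9]`.

One caveat on bit-level reproducibility: where terms of magnitude
`~e^{|z'ν'|/s²}` cancel catastrophically (the layer's outer edge), results
carry no reliable digits; exact-identity tests are therefore restricted to
well-conditioned sets (`a|ν|/s² ≤ 6`).

## Numerical integration of densities

`density_curve` evaluates on a uniform closed grid (`n_points` over
`[0, t_max_ms]`, default 1000 points to 2000 ms) — a rendering canvas, not
a quadrature rule. Where integrals matter (normalization checks, moments),
grids are refined (0.1–0.5 ms steps) and the axis end is chosen adaptively
as `t0 + 40/λ₁`, where `λ₁ = (ν²/s² + π²s²/a²)/2` is the slowest
exponential decay rate, so the neglected tail is ~e⁻⁴⁰. Conditional means
and SDs are trapezoid moments of the gridded curve rather than closed
forms: the paper-level moment formulas would not extend to variability
mixtures, while the numeric route handles them for free. Doubling the grid
changes default-set means by well under 0.5 ms.

## Variability quadrature

Trial-to-trial variability multiplies the density by mixing distributions:
normal drift (`σ = s_ν`), uniform starting point (full range `s_z`, on the
relative-z scale, consistent with how `z` itself is expressed), uniform
non-decision time (full range `s_t0` ms). Each active dimension gets
`nodes` (default 10) equally spaced trapezoidal nodes across its exact
range; the unbounded drift dimension is truncated at `ν ± 4s_ν` (missing
~6e-5 of normal mass) and its weights are renormalized to sum to one so
probabilities remain probabilities. Dimensions of zero width are omitted
entirely, making the no-variability case bit-identical to the fixed-
parameter computation. The tensor product is evaluated exactly — `t0`
nodes enter as exact time shifts of the grid evaluation, not as
interpolated shifts — and out-of-range nodes (`z* ∉ (0,1)`, `t0* < 0`) are
rejected rather than clipped, since clipping would silently change the
stated mixing distribution. Ten nodes agree with a 1000-node reference to
< 5e-3 relative error per dimension at the default set.

## Simulator (the independent oracle)

`simulate_trials` never touches the series solution. Per trial it draws
`ν*`, `z*`, `t0*` from the mixing distributions (parameter draws before
path noise, one RNG stream per sample, so samples are bit-reproducible by
seed), then integrates `x += ν*dt + s√dt·ε` from `x = z*a` with
`dt = 1e-4 s` by default. Absorption within a step is detected with the
exact Brownian-bridge crossing probability
`exp(−2(a−x_t)(a−x_{t+dt})/(s²dt))` (and the lower-boundary analogue):
naive post-step threshold checks miss within-step crossings and bias mean
hitting times upward by ~0.58·s·√dt of effective boundary displacement —
about +9 ms at the default set, far outside Monte-Carlo error at
n = 200,000 — whereas the bridge test leaves residual bias of order `dt`
(≲0.1 ms), verified against analytic values to within 0.3 standard errors.
Decision times above 100 s are censored (with a logged count); this cap
guarantees termination for near-zero drift with wide boundaries and is hit
with negligible probability everywhere the tests operate. The hot loop is
JIT-compiled (numba); RTs are recorded at the end of the crossing step, a
+dt/2 quantization that is negligible at the default step size.

Simulation problem sizes in the tests (200,000 trials for oracle
comparisons, 40–100k for unit-level checks) are chosen so Monte-Carlo
standard errors are small enough to resolve sub-millisecond biases while a
full run of the suite stays in the minutes range on a single core.

## What the simulator does and does not emulate

The simulator generates exactly the model's own data: independent trials,
stationary parameters within trial, normally/uniformly mixed parameters
across trials, no contaminant responses. Passing oracle tests therefore
demonstrates internal consistency of the analytic and stochastic routes —
not that real response-time data (with outliers, sequential effects,
non-stationarity) follow the model.

## Plotting and CLI

The canvas mirrors the field's standard layout: upper-boundary density
above the time axis (green), lower-boundary density negated below (red),
dashed verticals at the conditional means, a stacked proportion bar at the
right edge, and shaded bands for the variability ranges. Superimposing
several parameter sets is refused when the model-parameter annotations are
also requested and the sets differ in `a`, because the dislocated
baselines would overdraw each other; dropping either option resolves it.
The interactive animation of the original idea is replaced by `--sweep
PARAM:FROM:TO:STEPS`, which renders an image sequence over a parameter
range. Only mathematical constraints are validated on parameters — the
CLI imposes no arbitrary slider-style bounds, and `--allow-extreme`
silences the advisory note about atypical values. Exports are plain text:
a `time_ms,g_upper,g_lower` CSV at full float precision plus a JSON
sidecar with parameters, numerics and summary statistics.

## Known limitations

* The large-time series is the only density representation implemented;
  small-time expansions are out of scope, so the artifact layer above `t0`
  is reported as zero rather than evaluated.
* Fixed `kmax` means extremely drift-amplified parameter sets
  (`|z'ν'/s²| ≫ 5`) widen the zeroed layer; raising `kmax` narrows it at
  linear cost.
* Quadrature is non-adaptive by design (fixed trapezoidal nodes); strongly
  skewed mixtures would need more nodes.
* The simulator censors at 100 s of decision time; for parameter sets with
  appreciable mass beyond that, empirical and analytic curves will differ
  by the censored fraction (which is logged).
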