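# wienerdm

Exact response-time densities, choice probabilities, trial-level simulation
and publication-style plots for the **two-boundary Wiener diffusion model**
of speeded binary decisions (two-alternative forced choice).

The model assumes that noisy evidence accumulates from a starting point
`z = z_rel · a` between two absorbing boundaries (0 and `a`) with drift `ν`
and within-trial noise variance `s²` per second. The first boundary hit
determines the response; the hitting time plus a non-decision component
`t0` (encoding + motor execution) is the observed response time. The
package evaluates

* the lower-boundary ("negative" response) probability

  `P(−) = (e^(−2νa/s²) − e^(−2νz/s²)) / (e^(−2νa/s²) − 1)`,

  the continuum limit of the gambler's-ruin probability, with the driftless
  limit `P(−) = 1 − z_rel` handled continuously;

* the first-passage-time density of lower-boundary hits (Fürth's series),

  `g−(t) = (πs²/a²) · e^(−zν/s²) · Σ_{k≥1} k · sin(πzk/a) · e^(−(ν²/s² + π²k²s²/a²)t/2)`,

  truncated at `kmax` terms (default 100), with upper-boundary quantities
  obtained by the reflection `ν → −ν`, `z → a − z`;

* marginal densities under trial-to-trial variability of drift
  (`ν* ~ N(ν, s_ν²)`), starting point (`z* ~ U(z ± s_z/2)`) and non-decision
  time (`t0* ~ U(t0 ± s_t0/2)`), integrated by trapezoidal quadrature
  (default 10 nodes per active dimension, drift on `ν ± 4s_ν`);

* conditional RT means/SDs and boundary probabilities (the plot
  annotations), and

* a seeded Euler–Maruyama simulator with exact Brownian-bridge
  within-step absorption — an independent Monte-Carlo oracle for all of
  the above.

Time is split between units on purpose: the stochastic process runs in
seconds (`s² = 1` per second by convention), while `t0`, `s_t0` and every
output time axis are in milliseconds. Densities are per second, so they
integrate to probabilities on a seconds axis.

## Worked example

```python
import wienerdm as w

params = w.DMParameters()            # a=1, z_rel=0.5, nu=0.2, t0=300 ms, s2=1
num = w.NumericsConfig()             # kmax=100, 10 nodes, 1000 points to 2000 ms

w.lower_choice_probability(params)   # 0.4501660026875219
curve = w.density_curve(params, w.NumericsConfig(t_max_ms=5000, n_points=50001))
stats = w.summarize(curve)
print(stats.p_upper, stats.mean_upper_ms, stats.sd_upper_ms)
# 0.5498339973124781 549.1699865623895 203.31095952564814
```

So with a mild drift of 0.2 toward the upper boundary, 55.0% of trials end
in the upper (e.g. "match") response, and both conditional mean RTs are
~549 ms: 300 ms of non-decision time plus ~249 ms of decision time.
An independent 200,000-trial simulation reproduces these values:

```python
s = w.simulate_trials(params, n=200_000, dt_s=1e-4, seed=1)
s.lower_fraction()                   # 0.45129  (analytic: 0.45017)
s.rts_ms[s.is_upper].mean()          # 548.77   (analytic: 549.17)
```

The command-line tool renders the classic mirrored canvas (upper-boundary
density in green above the time axis, lower-boundary density mirrored in
red below, dashed conditional means, a stacked probability bar, and shaded
variability bands) and exports density grids:

```sh
wienerdm --out densities.png --csv densities.csv
wienerdm --nu 1 --snu 0.3 --st0 100 --out variable.png
wienerdm --sweep a:0.5:2:10 --out frames.png      # animation frames over a
wienerdm --simulate 10000 --seed 7 --trials-csv trials.csv
```

## Scope

The package is a forward-model calculator and visualizer: parameters in,
densities out. Parameter *estimation* from data, alternative small-time
series expansions, and PDE (Fokker–Planck) solution routes are out of
scope.
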