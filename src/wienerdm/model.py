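"""Choice probabilities and first-passage-time densities of the Wiener diffusion model.

The probability that the process starting at ``z`` is absorbed at the lower
boundary (the "negative" response) is

    P(-) = (exp(-2 nu a / s^2) - exp(-2 nu z / s^2)) / (exp(-2 nu a / s^2) - 1),

the continuous-time limit of the classical gambler's-ruin probability.  The
density of lower-boundary hitting times is the classical sine-series
first-passage solution (Fuerth's formula):

    g-(t) = (pi s^2 / a^2) exp(-z nu / s^2)
            * sum_{k>=1} k sin(pi z k / a) exp(-(nu^2/s^2 + pi^2 k^2 s^2/a^2) t / 2).

The upper-boundary quantities follow from the reflection nu -> -nu,
z -> a - z.  The series is truncated at ``kmax`` terms; truncation can make
the partial sum dip below zero just above t0 ("spikes"), which is clamped to
zero with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import DMParameters, NumericsConfig, ParameterError

__all__ = [
    "DensityCurve",
    "TruncationArtifactWarning",
    "lower_choice_probability",
    "evaluate_series",
    "fpt_density_lower",
    "fpt_density_upper",
    "density_curve",
]

# below this value of |nu * a / s2| Eq. P(-) is evaluated by its nu -> 0 limit
_NU_ZERO_THRESHOLD = 1e-9
# early exit once a series term falls below this fraction of the running sum
_SERIES_RTOL = 1e-15
# relative size of the first omitted terms above which a point counts as
# unconverged (the spike-artifact layer just above t0) and is reported as 0
_CONV_RTOL = 1e-2
_CONV_ATOL = 1e-12


class TruncationArtifactWarning(RuntimeWarning):
    """Truncated series produced a negative density value (clamped to zero)."""


@dataclass(frozen=True)
class DensityCurve:
    """Paired upper/lower response-time densities on a common time grid.

    ``times_ms`` is a monotone grid in milliseconds; ``g_upper`` and
    ``g_lower`` are non-negative defective densities on the per-second scale
    (each integrates, in seconds, to its boundary's absorption probability).
    Densities are exactly zero at all times at or below the non-decision
    time.
    """

    times_ms: np.ndarray
    g_upper: np.ndarray
    g_lower: np.ndarray
    p_lower: float

    @property
    def p_upper(self) -> float:
        return 1.0 - self.p_lower

    @property
    def times_s(self) -> np.ndarray:
        return self.times_ms / 1000.0

    def mass_lower(self) -> float:
        """Trapezoid integral of the lower density over the grid (seconds)."""
        return float(np.trapezoid(self.g_lower, self.times_s))

    def mass_upper(self) -> float:
        return float(np.trapezoid(self.g_upper, self.times_s))

    def total_mass(self) -> float:
        """Integrated probability mass captured by the grid; 1 minus the tail."""
        return self.mass_lower() + self.mass_upper()


def lower_choice_probability(params: DMParameters) -> float:
    """Probability of absorption at the lower boundary (negative response).

    Evaluated in the numerically stable ``expm1`` form on either side of
    nu = 0; for |nu a / s2| below 1e-9 the continuous driftless limit
    1 - z_rel (gambler's ruin without drift) is returned.
    """
    a, z, nu, s2 = params.a, params.z_abs, params.nu, params.s2
    if abs(nu * a / s2) < _NU_ZERO_THRESHOLD:
        return 1.0 - params.z_rel
    x = 2.0 * nu / s2
    if x > 0:
        # both exponents are <= 0: no overflow
        return (math.exp(-x * a) - math.exp(-x * z)) / math.expm1(-x * a)
    # factor exp(-x a) out for the negative-drift branch
    y = -x
    return math.expm1(-y * (a - z)) / math.expm1(-y * a)


def _series_terms_needed(t_min_s: float, a: float, nu: float, s2: float, kmax: int) -> int:
    """Largest k whose term can exceed the underflow floor at the earliest time.

    Terms decay in k like exp(-pi^2 k^2 s2 t / (2 a^2)); beyond the returned
    index every term underflows to zero for all t >= t_min_s, so the fixed
    truncation can be shortened without changing the result.
    """
    if t_min_s <= 0.0:
        return kmax
    # solve pi^2 k^2 s2 t / (2 a^2) = 746 (exp underflow threshold)
    k_under = math.sqrt(2.0 * 746.0 * a * a / (math.pi**2 * s2 * t_min_s))
    return min(kmax, max(1, int(math.ceil(k_under))))


def _series_density(
    t_dec_s: np.ndarray,
    a: float,
    z_abs: float,
    nu: float,
    s2: float,
    kmax: int,
) -> tuple[np.ndarray, int]:
    """Vectorised truncated-series lower-boundary density at decision times (s).

    Returns the clamped non-negative densities and the count of grid points
    flagged as truncation artifacts.  Two kinds of artifact are suppressed,
    both confined to a thin layer just above t0 where the sine series has
    not yet converged at ``kmax`` terms: raw partial sums below zero (the
    classic negative spikes) and points where a convergence probe — the
    first two omitted terms — is still a non-negligible fraction of the
    partial sum, so the value is numerically meaningless.  Both are set to
    zero (the true density in that layer is vanishingly small, since any
    appreciable first-passage mass implies a converged series there).

    The per-term log prefactor ``-z nu / s2`` is folded into each exponent
    so extreme drifts cannot overflow a standalone prefactor.
    """
    t = np.asarray(t_dec_s, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0.0
    if not pos.any():
        return out, 0
    tp = t[pos]

    log_pref = math.log(math.pi * s2 / (a * a)) - z_abs * nu / s2
    lam = 0.5 * (nu * nu / s2)  # drift part of the decay rate
    c = 0.5 * math.pi**2 * s2 / (a * a)  # k^2 coefficient

    k_eff = _series_terms_needed(float(tp.min()), a, nu, s2, kmax)
    total = np.zeros_like(tp)
    running_max = 0.0
    n_small = 0
    k_last = 0
    for k in range(1, k_eff + 1):
        k_last = k
        sin_k = math.sin(math.pi * z_abs * k / a)
        expo = log_pref - (lam + c * k * k) * tp
        term = k * sin_k * np.exp(np.clip(expo, -746.0, None))
        total += term
        term_max = float(np.abs(term).max())
        running_max = max(running_max, float(np.abs(total).max()))
        # fixed-kmax truncation with an early exit once terms stay negligible;
        # two consecutive small terms are required because single sine factors
        # can vanish identically (e.g. every even k at z_rel = 1/2)
        if running_max > 0.0 and term_max < _SERIES_RTOL * running_max:
            n_small += 1
            if n_small >= 2:
                break
        else:
            n_small = 0

    # convergence probe: where the first omitted terms are still appreciable
    # relative to the partial sum, the series is unconverged at this kmax
    probe = np.zeros_like(tp)
    for k in (k_last + 1, k_last + 2):
        sin_k = math.sin(math.pi * z_abs * k / a)
        expo = log_pref - (lam + c * k * k) * tp
        np.maximum(probe, np.abs(k * sin_k) * np.exp(np.clip(expo, -746.0, None)), out=probe)
    bad = (total < 0.0) | (probe > _CONV_RTOL * np.abs(total) + _CONV_ATOL)
    n_clamped = int(np.count_nonzero(bad & ((total != 0.0) | (probe > _CONV_ATOL))))
    total[bad] = 0.0
    out[pos] = total
    return out, n_clamped


def _warn_clamped(n_clamped: int, kmax: int) -> None:
    if n_clamped:
        warnings.warn(
            f"truncated series (kmax={kmax}) is unconverged or negative at "
            f"{n_clamped} point(s) near t0 (spike artifacts); reported as 0",
            TruncationArtifactWarning,
            stacklevel=3,
        )


def evaluate_series(
    t_dec_s: float, a: float, z_abs: float, nu: float, s2: float, kmax: int
) -> float:
    """Truncated sine-series density of lower-boundary absorption at ``t_dec_s``.

    ``t_dec_s`` is the decision time in seconds, already net of the
    non-decision component, and must be strictly positive.  Negative partial
    sums (a small-``kmax`` artifact near t0) are clamped to zero with a
    :class:`TruncationArtifactWarning`.
    """
    if t_dec_s <= 0.0:
        raise ParameterError(f"t_dec_s: decision time must be > 0, got {t_dec_s}")
    val, n_clamped = _series_density(np.array([t_dec_s]), a, z_abs, nu, s2, kmax)
    _warn_clamped(n_clamped, kmax)
    return float(val[0])


def _density_grid_lower(
    t_ms: np.ndarray, params: DMParameters, num: NumericsConfig, t0_ms: float | None = None
) -> tuple[np.ndarray, int]:
    """Lower-boundary density on a millisecond grid; zero at/below t0."""
    t0 = params.t0_ms if t0_ms is None else t0_ms
    t_dec = (np.asarray(t_ms, dtype=float) - t0) / 1000.0
    return _series_density(t_dec, params.a, params.z_abs, params.nu, params.s2, num.kmax)


def fpt_density_lower(t_ms, params: DMParameters, num: NumericsConfig):
    """Density (per second) of a lower-boundary response at time(s) ``t_ms``.

    Zero for all times at or before the non-decision time t0.  Accepts a
    scalar or an array of times in milliseconds.
    """
    scalar = np.ndim(t_ms) == 0
    val, n_clamped = _density_grid_lower(np.atleast_1d(np.asarray(t_ms, dtype=float)), params, num)
    _warn_clamped(n_clamped, num.kmax)
    return float(val[0]) if scalar else val


def _reflected(params: DMParameters) -> DMParameters:
    """Parameters of the mirror process: upper-boundary quantities of the
    original equal lower-boundary quantities of the reflected process."""
    return DMParameters(
        a=params.a,
        z_rel=1.0 - params.z_rel,
        nu=-params.nu,
        t0_ms=params.t0_ms,
        s2=params.s2,
    )


def fpt_density_upper(t_ms, params: DMParameters, num: NumericsConfig):
    """Density (per second) of an upper-boundary response at time(s) ``t_ms``."""
    return fpt_density_lower(t_ms, _reflected(params), num)


def slowest_decay_rate(params: DMParameters) -> float:
    """Asymptotic exponential decay rate (1/s) of both FPT densities.

    Every series term decays at least as fast as the k = 1 term,
    (nu^2/s^2 + pi^2 s^2/a^2) / 2, so the probability mass beyond decision
    time T shrinks like exp(-rate * T)."""
    return 0.5 * (params.nu**2 / params.s2 + math.pi**2 * params.s2 / params.a**2)


def suggested_t_max_ms(
    params: DMParameters, extra_t0_ms: float = 0.0, log_tail: float = 40.0
) -> float:
    """Grid end (ms) that keeps the neglected tail mass below ~exp(-log_tail).

    ``extra_t0_ms`` accommodates the upper end of a non-decision-time
    variability range."""
    t_dec = log_tail / slowest_decay_rate(params)
    return params.t0_ms + extra_t0_ms + 1000.0 * t_dec


def time_grid(num: NumericsConfig) -> np.ndarray:
    """Uniform closed grid of ``n_points`` times (ms) on [0, t_max_ms]."""
    return np.linspace(0.0, num.t_max_ms, num.n_points)


def density_curve(
    params: DMParameters, num: NumericsConfig, t0_ms: float | None = None
) -> DensityCurve:
    """Evaluate both boundary densities and P(-) on the uniform time grid.

    ``t0_ms`` optionally overrides the parameter set's non-decision time
    (used by the variability quadrature, which shifts t0 per node).
    """
    t0 = params.t0_ms if t0_ms is None else t0_ms
    if num.t_max_ms <= t0:
        raise ParameterError(
            f"t_max_ms: grid end {num.t_max_ms} must exceed non-decision time {t0}"
        )
    t = time_grid(num)
    g_lower, n_lo = _density_grid_lower(t, params, num, t0_ms=t0)
    g_upper, n_up = _density_grid_lower(t, _reflected(params), num, t0_ms=t0)
    _warn_clamped(n_lo + n_up, num.kmax)
    return DensityCurve(
        times_ms=t,
        g_upper=g_upper,
        g_lower=g_lower,
        p_lower=lower_choice_probability(params),
    )
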