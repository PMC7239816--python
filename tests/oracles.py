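"""Independent reference computations used by the tests.

Everything here is deliberately written the dumb way — plain-Python
exhaustive summation and dense Riemann grids — so that it shares no code
path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def series_density_oracle(t: float, a: float, z_abs: float, nu: float, s2: float = 1.0) -> float:
    """Lower-boundary FPT density by exhaustive summation to machine convergence."""
    pref = math.pi * s2 / a**2 * math.exp(-z_abs * nu / s2)
    total = 0.0
    k = 0
    while True:
        k += 1
        expo = -0.5 * (nu * nu / s2 + math.pi**2 * k * k * s2 / a**2) * t
        if expo < -746.0 and k > 3:
            break
        total += k * math.sin(math.pi * z_abs * k / a) * math.exp(max(expo, -746.0))
        if k > 200_000:  # pragma: no cover - safety net
            break
    return pref * max(total, 0.0)


def choice_probability_oracle(a: float, z_rel: float, nu: float, s2: float = 1.0) -> float:
    """Lower-boundary absorption probability, naive formula (or driftless limit)."""
    if nu == 0.0:
        return 1.0 - z_rel
    z = z_rel * a
    x = 2.0 * nu / s2
    return (math.exp(-x * a) - math.exp(-x * z)) / (math.exp(-x * a) - 1.0)


def drift_mixture_probability_oracle(
    a: float, z_rel: float, nu: float, s_nu: float, s2: float = 1.0, n_grid: int = 10_001
) -> float:
    """P(lower) under normal drift variability via a dense Riemann sum on nu +/- 4 s_nu."""
    nus = np.linspace(nu - 4 * s_nu, nu + 4 * s_nu, n_grid)
    w = stats.norm.pdf(nus, loc=nu, scale=s_nu)
    w = w / w.sum()
    return float(sum(wi * choice_probability_oracle(a, z_rel, float(ni), s2) for ni, wi in zip(nus, w)))


def binomial_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 1e-12) / n)
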