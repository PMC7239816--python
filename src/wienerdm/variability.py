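"""Marginal densities under trial-to-trial parameter variability.

Across trials the effective parameters are assumed to fluctuate:

* drift       nu* ~ Normal(nu, s_nu^2)
* start point z*  ~ Uniform(z - s_z/2, z + s_z/2)          (relative scale)
* non-decision t0* ~ Uniform(t0 - s_t0/2, t0 + s_t0/2)     (milliseconds)

The observable density is the mixture (integral) of the fixed-parameter
density over these distributions.  Each integral is approximated by the
trapezoidal rule on equally spaced nodes spanning the full uniform range,
or nu +/- 4 s_nu for the unbounded normal dimension; the +/-4 sigma window
holds all but ~6e-5 of the normal mass and its weights are renormalised to
sum to exactly one so that probabilities remain probabilities.  Dimensions
with zero width are omitted and leave results exactly unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy import stats

from .model import DensityCurve, _density_grid_lower, _reflected, _warn_clamped, density_curve, lower_choice_probability, time_grid
from .params import DMParameters, NumericsConfig, ParameterError, VariabilityParameters

__all__ = ["QuadratureGrid", "build_quadrature", "marginal_density_curve", "marginal_choice_probability"]

_DRIFT_HALF_WIDTH_SIGMAS = 4.0


@dataclass(frozen=True)
class QuadratureGrid:
    """Per-dimension quadrature nodes and normalised weights.

    ``dims`` maps each active variability dimension ("nu", "z_rel",
    "t0_ms") to a ``(nodes, weights)`` pair; weights are non-negative and
    sum to one within each dimension.  An empty mapping is the
    no-variability case (a single implicit node of weight one).
    """

    dims: dict[str, tuple[np.ndarray, np.ndarray]]

    def combinations(self):
        """Iterate over the tensor product: (dict of parameter overrides, weight)."""
        if not self.dims:
            yield {}, 1.0
            return
        names = list(self.dims)
        node_lists = [self.dims[n][0] for n in names]
        weight_lists = [self.dims[n][1] for n in names]
        for values, weights in zip(
            product(*node_lists), product(*weight_lists)
        ):
            yield dict(zip(names, values)), float(np.prod(weights))


def _trapezoid_coeffs(n: int) -> np.ndarray:
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return w


def build_quadrature(
    params: DMParameters, vparams: VariabilityParameters, num: NumericsConfig
) -> QuadratureGrid:
    """Build the trapezoidal quadrature grid for the active variability dims.

    Uniform dimensions get ``num.nodes`` equally spaced nodes spanning
    exactly the stated range with endpoint weights half the interior ones;
    the drift dimension spans nu +/- 4 s_nu with weights proportional to the
    normal ordinates times the trapezoid coefficients, renormalised to one.
    """
    vparams.validate_with(params)
    n = num.nodes
    coeffs = _trapezoid_coeffs(n)
    dims: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if vparams.s_nu > 0:
        half = _DRIFT_HALF_WIDTH_SIGMAS * vparams.s_nu
        nodes = np.linspace(params.nu - half, params.nu + half, n)
        w = stats.norm.pdf(nodes, loc=params.nu, scale=vparams.s_nu) * coeffs
        dims["nu"] = (nodes, w / w.sum())
    if vparams.s_z > 0:
        nodes = np.linspace(
            params.z_rel - vparams.s_z / 2, params.z_rel + vparams.s_z / 2, n
        )
        if nodes[0] <= 0.0 or nodes[-1] >= 1.0:
            raise ParameterError(
                f"s_z: quadrature nodes [{nodes[0]}, {nodes[-1]}] leave (0, 1)"
            )
        dims["z_rel"] = (nodes, coeffs / coeffs.sum())
    if vparams.s_t0_ms > 0:
        nodes = np.linspace(
            params.t0_ms - vparams.s_t0_ms / 2,
            params.t0_ms + vparams.s_t0_ms / 2,
            n,
        )
        if nodes[0] < 0.0:
            raise ParameterError(f"s_t0_ms: quadrature node {nodes[0]} is < 0")
        dims["t0_ms"] = (nodes, coeffs / coeffs.sum())
    return QuadratureGrid(dims)


def _with_overrides(params: DMParameters, overrides: dict[str, float]) -> DMParameters:
    kw = {k: v for k, v in overrides.items() if k in ("nu", "z_rel")}
    return replace(params, **kw) if kw else params


def marginal_choice_probability(
    params: DMParameters, vparams: VariabilityParameters, num: NumericsConfig
) -> float:
    """Lower-boundary probability averaged over the drift and start-point mixes.

    Non-decision-time variability shifts responses in time but cannot change
    which boundary absorbs, so the t0 dimension is skipped.
    """
    grid = build_quadrature(params, vparams, num)
    dims = {k: v for k, v in grid.dims.items() if k != "t0_ms"}
    p = 0.0
    for overrides, w in QuadratureGrid(dims).combinations():
        p += w * lower_choice_probability(_with_overrides(params, overrides))
    return p


def marginal_density_curve(
    params: DMParameters, vparams: VariabilityParameters, num: NumericsConfig
) -> DensityCurve:
    """Quadrature average of the density curve over all active variability dims.

    With no active dimension this is bit-identical to
    :func:`wienerdm.model.density_curve`.  Each (nu*, z*, t0*) node triple is
    evaluated exactly (the t0 nodes enter as time shifts of the grid), and
    the weighted average is returned together with the marginal P(-).
    """
    grid = build_quadrature(params, vparams, num)
    if not grid.dims:
        return density_curve(params, num)
    t0_max = params.t0_ms + vparams.s_t0_ms / 2
    if num.t_max_ms <= t0_max:
        raise ParameterError(
            f"t_max_ms: grid end {num.t_max_ms} must exceed max non-decision "
            f"time {t0_max}"
        )
    t = time_grid(num)
    g_lower = np.zeros_like(t)
    g_upper = np.zeros_like(t)
    n_clamped = 0
    for overrides, w in grid.combinations():
        p = _with_overrides(params, overrides)
        t0 = overrides.get("t0_ms", params.t0_ms)
        lo, c1 = _density_grid_lower(t, p, num, t0_ms=t0)
        up, c2 = _density_grid_lower(t, _reflected(p), num, t0_ms=t0)
        g_lower += w * lo
        g_upper += w * up
        n_clamped += c1 + c2
    _warn_clamped(n_clamped, num.kmax)
    return DensityCurve(
        times_ms=t,
        g_upper=g_upper,
        g_lower=g_lower,
        p_lower=marginal_choice_probability(params, vparams, num),
    )
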