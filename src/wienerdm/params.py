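"""Parameter containers and validation for the two-boundary Wiener diffusion model.

The model describes speeded binary decisions (two-alternative forced choice):
evidence accumulates as a Brownian motion with drift ``nu`` between an upper
absorbing boundary at ``a`` and a lower one at 0, starting from ``z_rel * a``.
The first boundary hit determines the response; the hitting time plus a
non-decision component ``t0`` is the observed response time.

Conventions used throughout the package:

* the diffusion equations operate in **seconds** with intra-trial noise
  variance ``s2`` (a fixed scale constant, not a free parameter);
* non-decision time ``t0`` and every output time axis are in **milliseconds**;
* densities are reported on the **per-second** scale, so that integrating a
  density over the time axis expressed in seconds yields a probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DMParameters",
    "VariabilityParameters",
    "NumericsConfig",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a parameter value violates its mathematical constraints."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ParameterError(f"{field_name}: {message}")


@dataclass(frozen=True)
class DMParameters:
    """The four main diffusion-model parameters plus the noise scale constant.

    Parameters
    ----------
    a :
        Boundary separation (evidence units); indexes response caution.
    z_rel :
        Starting point relative to ``a``, strictly inside (0, 1); 0.5 is
        unbiased.  The absolute start is ``z_abs = z_rel * a``.
    nu :
        Drift rate (evidence per second); sign selects the favoured boundary.
    t0_ms :
        Non-decision time (stimulus encoding + motor response) in ms.
    s2 :
        Intra-trial variance of the Brownian noise per second.  A scale
        constant fixed by convention (1 here; 0.1 is also common elsewhere),
        not an estimated parameter.
    """

    a: float = 1.0
    z_rel: float = 0.5
    nu: float = 0.2
    t0_ms: float = 300.0
    s2: float = 1.0

    def __post_init__(self) -> None:
        _require(self.a > 0, "a", f"boundary separation must be > 0, got {self.a}")
        _require(
            0.0 < self.z_rel < 1.0,
            "z_rel",
            f"relative starting point must lie strictly in (0, 1), got {self.z_rel}",
        )
        _require(self.s2 > 0, "s2", f"intra-trial variance must be > 0, got {self.s2}")
        _require(
            self.t0_ms >= 0, "t0_ms", f"non-decision time must be >= 0, got {self.t0_ms}"
        )

    @property
    def z_abs(self) -> float:
        """Absolute starting point ``z_rel * a``, strictly between 0 and a."""
        return self.z_rel * self.a


@dataclass(frozen=True)
class VariabilityParameters:
    """Trial-to-trial variability of drift, starting point and non-decision time.

    ``s_nu`` is the standard deviation of a normal drift distribution,
    ``s_z`` the full range of a uniform starting-point distribution (on the
    relative-z scale) and ``s_t0_ms`` the full range (ms) of a uniform
    non-decision-time distribution.  A width of zero switches that source of
    variability off; with all three zero every operation reduces exactly to
    the fixed-parameter model.
    """

    s_nu: float = 0.0
    s_z: float = 0.0
    s_t0_ms: float = 0.0

    def __post_init__(self) -> None:
        _require(self.s_nu >= 0, "s_nu", f"must be >= 0, got {self.s_nu}")
        _require(self.s_z >= 0, "s_z", f"must be >= 0, got {self.s_z}")
        _require(self.s_t0_ms >= 0, "s_t0_ms", f"must be >= 0, got {self.s_t0_ms}")

    @property
    def any_active(self) -> bool:
        return self.s_nu > 0 or self.s_z > 0 or self.s_t0_ms > 0

    def validate_with(self, params: DMParameters) -> None:
        """Check that the variability ranges stay inside the legal domain.

        The uniform starting-point range must keep ``z_rel`` strictly inside
        (0, 1) and the non-decision-time range must not reach below zero.
        Out-of-range quadrature nodes are rejected rather than clipped:
        silent clipping would change the stated mixing distribution.
        """
        if self.s_z > 0:
            lo, hi = params.z_rel - self.s_z / 2, params.z_rel + self.s_z / 2
            _require(
                lo > 0 and hi < 1,
                "s_z",
                f"z_rel +/- s_z/2 = [{lo}, {hi}] must stay strictly within (0, 1)",
            )
        if self.s_t0_ms > 0:
            lo = params.t0_ms - self.s_t0_ms / 2
            _require(
                lo >= 0,
                "s_t0_ms",
                f"t0_ms - s_t0_ms/2 = {lo} must be >= 0",
            )


@dataclass(frozen=True)
class NumericsConfig:
    """Numerical settings: series truncation, quadrature nodes, time grid.

    ``kmax`` terms of the infinite sine series are retained (100 by default;
    values much below ~50 can produce negative-density spikes just above t0).
    ``nodes`` is the number of trapezoidal quadrature nodes used per active
    variability dimension.  The output grid has ``n_points`` uniform points
    on [0, ``t_max_ms``].
    """

    kmax: int = 100
    nodes: int = 10
    t_max_ms: float = 2000.0
    n_points: int = 1000

    def __post_init__(self) -> None:
        _require(self.kmax >= 1, "kmax", f"must be >= 1, got {self.kmax}")
        _require(self.nodes >= 2, "nodes", f"must be >= 2, got {self.nodes}")
        _require(self.n_points >= 2, "n_points", f"must be >= 2, got {self.n_points}")
        _require(self.t_max_ms > 0, "t_max_ms", f"must be > 0, got {self.t_max_ms}")
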