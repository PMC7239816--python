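"""Mirrored two-panel rendering of response-time densities.

The canvas follows the classic diffusion-model layout: the upper-boundary
density is drawn above a shared horizontal time axis (green), the
lower-boundary density is mirrored below it (red), vertical dashed lines
mark the conditional mean RTs, a stacked bar at the right edge shows the
expected response proportions, and shaded bands visualise the variability
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # noqa: E402 - headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .model import DensityCurve
from .params import DMParameters, VariabilityParameters
from .summaries import SummaryStats

__all__ = ["PlotOptions", "PlotOptionError", "render_plot"]

UPPER_COLOR = "forestgreen"
LOWER_COLOR = "firebrick"
ANNOT_COLOR = "royalblue"


class PlotOptionError(ValueError):
    """Raised when plot options are mutually inconsistent."""


@dataclass(frozen=True)
class PlotOptions:
    """Rendering switches for the mirrored density canvas.

    ``superimpose`` overlays several parameter sets on one canvas;
    ``draw_model_parameters`` adds the baseline/threshold annotations for
    a, z, t0 and the variability bands.  The two are refused together when
    the overlaid sets differ in ``a``: the dislocated baselines would be
    drawn over each other and distort the diagram.
    """

    superimpose: bool = False
    fill_area: bool = False
    draw_model_parameters: bool = True
    time_span_ms: float | None = None


def _check_options(opts: PlotOptions, param_sets: list[DMParameters]) -> None:
    if opts.superimpose and opts.draw_model_parameters and len(param_sets) > 1:
        a_values = {p.a for p in param_sets}
        if len(a_values) > 1:
            raise PlotOptionError(
                "superimposed parameter sets differ in boundary separation a "
                f"({sorted(a_values)}); drawing model parameters would overlay "
                "dislocated baselines and distort the diagram — disable "
                "parameter annotations or superimposition"
            )


def render_plot(
    curves: list[tuple[DensityCurve, SummaryStats]],
    opts: PlotOptions,
    path,
    param_sets: list[DMParameters] | None = None,
    vparam_sets: list[VariabilityParameters] | None = None,
    labels: list[str] | None = None,
) -> None:
    """Write the mirrored density plot for one or more curves to ``path``.

    All curves must share their time axis.  The output format follows the
    file extension (PNG or SVG).
    """
    if not curves:
        raise ValueError("at least one curve is required")
    t0 = curves[0][0].times_ms
    for c, _ in curves[1:]:
        if len(c.times_ms) != len(t0) or not np.array_equal(c.times_ms, t0):
            raise ValueError("all curves must share one time axis")
    param_sets = param_sets or []
    _check_options(opts, param_sets)

    fig, ax = plt.subplots(figsize=(9, 5))
    n = len(curves)
    for i, (curve, stats) in enumerate(curves):
        alpha = 1.0 if n == 1 else 0.45 + 0.55 * (i + 1) / n
        lab = labels[i] if labels else None
        ax.plot(curve.times_ms, curve.g_upper, color=UPPER_COLOR, alpha=alpha, label=lab)
        ax.plot(curve.times_ms, -curve.g_lower, color=LOWER_COLOR, alpha=alpha)
        if opts.fill_area:
            ax.fill_between(curve.times_ms, curve.g_upper, 0, color=UPPER_COLOR, alpha=0.25 * alpha)
            ax.fill_between(curve.times_ms, -curve.g_lower, 0, color=LOWER_COLOR, alpha=0.25 * alpha)
        if np.isfinite(stats.mean_upper_ms):
            ax.axvline(stats.mean_upper_ms, color=UPPER_COLOR, ls="--", lw=1, alpha=alpha)
        if np.isfinite(stats.mean_lower_ms):
            ax.axvline(stats.mean_lower_ms, color=LOWER_COLOR, ls="--", lw=1, alpha=alpha)

    span = opts.time_span_ms or float(t0[-1])
    ymax = max(float(np.max(c.g_upper)) for c, _ in curves)
    ymin = max(float(np.max(c.g_lower)) for c, _ in curves)
    top = 1.1 * max(ymax, ymin, 1e-12)
    ax.set_xlim(0, span)
    ax.set_ylim(-top, top)
    ax.axhline(0.0, color="black", lw=0.8)

    # stacked proportion bar at the right edge
    bar_x = span * 0.985
    bar_w = span * 0.02
    p_up = curves[0][1].p_upper
    ax.bar([bar_x], [p_up * top], width=bar_w, bottom=0, color=UPPER_COLOR, alpha=0.8)
    ax.bar([bar_x], [-(1 - p_up) * top], width=bar_w, bottom=0, color=LOWER_COLOR, alpha=0.8)

    if opts.draw_model_parameters and param_sets:
        p = param_sets[0]
        vp = (vparam_sets or [VariabilityParameters()])[0]
        ax.axvline(p.t0_ms, color=ANNOT_COLOR, lw=1, ls=":")
        ax.text(p.t0_ms, -0.98 * top, " t0", color=ANNOT_COLOR, fontsize=8, va="bottom")
        if vp.s_t0_ms > 0:
            ax.axvspan(
                p.t0_ms - vp.s_t0_ms / 2,
                p.t0_ms + vp.s_t0_ms / 2,
                color=ANNOT_COLOR,
                alpha=0.15,
            )
        # start-point marker on a symbolic evidence scale at the left edge
        z_y = (2 * p.z_rel - 1) * 0.9 * top
        ax.plot([0], [z_y], marker=">", color=ANNOT_COLOR, ms=7, clip_on=False)
        if vp.s_z > 0:
            half = vp.s_z * 0.9 * top  # full range maps to 2*(s_z/2) on the z scale
            ax.fill_betweenx(
                [z_y - half, z_y + half], 0, span * 0.012, color=ANNOT_COLOR, alpha=0.3
            )
        if vp.s_nu > 0:
            ax.axhspan(0.88 * top, 0.92 * top, xmax=0.05, color=ANNOT_COLOR, alpha=0.3)

    ax.set_xlabel("response time (ms)")
    ax.set_ylabel("density (1/s); lower boundary mirrored")
    if labels:
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
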