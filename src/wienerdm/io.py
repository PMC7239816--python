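"""Density-grid CSV export with a JSON metadata sidecar."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .model import DensityCurve
from .params import DMParameters, NumericsConfig, VariabilityParameters
from .summaries import SummaryStats

__all__ = ["write_csv", "sidecar_path"]


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_csv(
    curve: DensityCurve,
    stats: SummaryStats,
    path,
    params: DMParameters | None = None,
    vparams: VariabilityParameters | None = None,
    num: NumericsConfig | None = None,
) -> None:
    """Write ``time_ms,g_upper,g_lower`` at full float precision plus a sidecar.

    The sidecar JSON (same stem, ``.json``) records the parameter set, the
    numerical configuration and the summary statistics so the grid is fully
    reproducible from its own metadata.
    """
    path = Path(path)
    data = np.column_stack([curve.times_ms, curve.g_upper, curve.g_lower])
    np.savetxt(
        path,
        data,
        fmt="%.17g",
        delimiter=",",
        header="time_ms,g_upper,g_lower",
        comments="",
    )
    meta = {
        "parameters": asdict(params) if params is not None else None,
        "variability": asdict(vparams) if vparams is not None else None,
        "numerics": asdict(num) if num is not None else None,
        "p_lower": curve.p_lower,
        "p_upper": curve.p_upper,
        "summary": stats.as_dict(),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, allow_nan=True))
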