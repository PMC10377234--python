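"""Junctional-conductance computation from voltage-ramp measurements and
three-parameter Hill dose-response fitting.

Conventions: junctional current in nA, transjunctional voltage step in mV,
conductance in nS (nA/mV = uS, returned x1000).  Concentrations are in uM
throughout this module.  The Hill model is the sigmoidal inhibition form
``response = y_max / (1 + (C / IC50)**h)``; the zero-dose baseline anchors
``y_max``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .compound_table import DataError

__all__ = [
    "RampMeasurement",
    "DoseResponsePoint",
    "HillFit",
    "compute_gj",
    "normalize_timecourse",
    "hill_response",
    "fit_hill",
    "read_dose_response_csv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RampMeasurement:
    """One voltage-ramp sample: step amplitude (mV), junctional current (nA)."""

    delta_v1_mv: float
    i_j_na: float
    timestamp_s: float = 0.0


@dataclass(frozen=True)
class DoseResponsePoint:
    """Normalized conductance (1 = no block) at a concentration in uM."""

    concentration_um: float
    response: float

    def __post_init__(self) -> None:
        if self.concentration_um < 0:
            raise DataError("concentration must be >= 0")
        if self.response < 0:
            raise DataError("response must be >= 0")


@dataclass(frozen=True)
class HillFit:
    ic50_um: float
    hill_h: float
    y_max: float
    converged: bool
    residual_sse: float


def compute_gj(i_j_na: float, delta_v1_mv: float) -> float:
    """Junctional conductance -I_j / dV_1 in nS.

    The minus sign reflects that the current measured in the second cell is
    oppositely oriented; a negative result flags a non-junctional artifact.
    """
    if delta_v1_mv == 0:
        raise DataError("voltage step must be non-zero")
    return -i_j_na / delta_v1_mv * 1000.0


def normalize_timecourse(
    series: Sequence[tuple[float, float]],
    baseline_window_s: float,
    plateau_fraction: float = 0.25,
) -> float:
    """Plateau conductance divided by mean baseline conductance.

    Baseline = mean over samples within ``baseline_window_s`` of the first
    timestamp (>= 3 samples required); plateau = mean over the final
    stationary segment, taken as the last ``plateau_fraction`` of the
    record's duration.
    """
    if not series:
        raise DataError("empty conductance series")
    t = np.asarray([s[0] for s in series], dtype=float)
    g = np.asarray([s[1] for s in series], dtype=float)
    base_mask = t <= t[0] + baseline_window_s
    if base_mask.sum() < 3:
        raise DataError("need >= 3 baseline samples inside the baseline window")
    baseline = float(g[base_mask].mean())
    if baseline <= 0:
        raise DataError(f"non-positive baseline conductance ({baseline:.4g})")
    t_cut = t[-1] - plateau_fraction * (t[-1] - t[0])
    plateau_mask = t >= t_cut
    plateau = float(g[plateau_mask].mean())
    return plateau / baseline


def hill_response(
    c: float | np.ndarray, y_max: float, ic50_um: float, hill_h: float
) -> float | np.ndarray:
    """Inhibition Hill curve; equals y_max at C=0 and y_max/2 at C=IC50."""
    c = np.asarray(c, dtype=float)
    out = y_max / (1.0 + (c / ic50_um) ** hill_h)
    return float(out) if out.ndim == 0 else out


_H_STARTS = (1.0, 2.0, 4.0)
_Y_MAX_BOUND = 1.5


def fit_hill(
    points: Sequence[DoseResponsePoint],
    residual: str = "multiplicative",
) -> HillFit:
    """Three-parameter Hill fit (y_max, IC50, h) by multistart nonlinear
    least squares.

    ``residual='multiplicative'`` (default) minimizes log-space residuals,
    the maximum-likelihood choice for the multiplicative errors typical of
    baseline-normalized conductance ratios; ``'additive'`` minimizes plain
    residuals.  IC50 is initialized at the measured concentration closest
    to half-maximal response, h at each of {1, 2, 4}, y_max at the maximum
    observed response; the lowest-cost start wins.
    """
    if len(points) < 4:
        raise DataError("need at least 4 dose-response points")
    c = np.asarray([p.concentration_um for p in points], dtype=float)
    y = np.asarray([p.response for p in points], dtype=float)
    if not np.any(c == 0):
        raise DataError("need a zero-dose baseline point")
    if residual not in ("multiplicative", "additive"):
        raise DataError(f"unknown residual mode {residual!r}")

    def resid(p: np.ndarray) -> np.ndarray:
        model = hill_response(c, *p)
        if residual == "multiplicative":
            return np.log(np.maximum(model, 1e-12)) - np.log(np.maximum(y, 1e-12))
        return model - y

    y_max0 = min(max(float(y.max()), 1e-6), _Y_MAX_BOUND)
    pos = c[c > 0]
    half_gap = np.abs(y[c > 0] - y_max0 / 2.0)
    ic50_0 = float(pos[np.argmin(half_gap)]) if pos.size else 1.0
    best = None
    for h0 in _H_STARTS:
        res = least_squares(
            resid,
            x0=[y_max0, ic50_0, h0],
            bounds=([1e-9, 1e-9, 1e-9], [_Y_MAX_BOUND, 1e9, 50.0]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    converged = bool(best.success)
    if not converged:
        log.warning("fit_hill: no start converged; returning best-effort parameters")
    y_max, ic50, h = (float(v) for v in best.x)
    sse = float(np.sum((hill_response(c, y_max, ic50, h) - y) ** 2))
    return HillFit(
        ic50_um=ic50, hill_h=h, y_max=y_max, converged=converged, residual_sse=sse
    )


def read_dose_response_csv(path: str | Path) -> list[DoseResponsePoint]:
    """Read columns concentration_um, response."""
    points = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        need = {"concentration_um", "response"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise DataError(f"{path}: need columns {sorted(need)}")
        for row in reader:
            points.append(
                DoseResponsePoint(
                    concentration_um=float(row["concentration_um"]),
                    response=float(row["response"]),
                )
            )
    return points
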