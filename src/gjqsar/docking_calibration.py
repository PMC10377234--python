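"""Affine calibration mapping docking minimized affinity (DMA, kcal/mol)
to potency on the -log10 molar scale."""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .compound_table import DataError
from .mlr_qsar import FitStats, validation_stats

__all__ = [
    "DmaRecord",
    "DockingCalibration",
    "PAPER_PRESET",
    "fit_calibration",
    "predict_from_dma",
    "read_dma_csv",
]


@dataclass(frozen=True)
class DmaRecord:
    """Docking minimized affinity for one compound (kcal/mol, usually < 0)."""

    cid: int
    dma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.dma):
            raise DataError(f"cid {self.cid}: non-finite DMA")


@dataclass(frozen=True)
class DockingCalibration:
    """potency = slope_m * dma + intercept_n."""

    slope_m: float
    intercept_n: float


#: published calibration for the Cx43 inhibitor study
PAPER_PRESET = DockingCalibration(slope_m=-0.18, intercept_n=0.75)


def fit_calibration(
    pairs: Sequence[tuple[float, float]]
) -> tuple[DockingCalibration, FitStats]:
    """Simple least-squares line through (dma, potency) pairs."""
    if len(pairs) < 3:
        raise DataError("need at least 3 (dma, potency) pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.std(x) == 0:
        raise DataError("zero variance in DMA values")
    res = _stats.linregress(x, y)
    cal = DockingCalibration(slope_m=float(res.slope), intercept_n=float(res.intercept))
    fitted = res.slope * x + res.intercept
    return cal, validation_stats(y, fitted, n_predictors=1)


def predict_from_dma(cal: DockingCalibration, dma: float) -> float:
    """Map one DMA score to a -log10 molar potency prediction."""
    return cal.slope_m * dma + cal.intercept_n


def read_dma_csv(path: str | Path) -> list[DmaRecord]:
    """Read a score table with columns cid, dma."""
    records = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"cid", "dma"} <= set(reader.fieldnames):
            raise DataError(f"{path}: need columns cid, dma")
        for row in reader:
            records.append(DmaRecord(cid=int(row["cid"]), dma=float(row["dma"])))
    return records
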