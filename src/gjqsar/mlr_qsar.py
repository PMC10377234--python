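"""Linear QSAR modeling: constant-descriptor filtering, OLS fitting,
exhaustive best-subset search, validation statistics and prediction.

The packaged three-descriptor model :data:`PACKAGED_QSAR_MODEL` maps
(SpMin5_Bhm, SpMax3_Bhi, minHBd) to -log10 molar potency.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .compound_table import DataError

__all__ = [
    "DescriptorMatrix",
    "MlrModel",
    "FitStats",
    "SubsetSearchResult",
    "PACKAGED_QSAR_MODEL",
    "drop_constant_descriptors",
    "fit_ols",
    "exhaustive_subset_search",
    "predict",
    "validation_stats",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

_MODEL_FORMAT_VERSION = "gjqsar-mlr-model/1"


@dataclass(frozen=True)
class DescriptorMatrix:
    """Rectangular compounds x descriptors table with no missing values."""

    compound_ids: tuple[int, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray  # shape (n_compounds, n_descriptors)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise DataError("descriptor values must be 2-D")
        if v.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise DataError(
                f"shape {v.shape} inconsistent with {len(self.compound_ids)} "
                f"compounds x {len(self.descriptor_names)} descriptors"
            )
        if not np.all(np.isfinite(v)):
            raise DataError("descriptor matrix contains non-finite values")

    def select(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Restrict to the given descriptor columns, in the given order."""
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorMatrix(
            self.compound_ids, tuple(names), self.values[:, idx]
        )


@dataclass(frozen=True)
class MlrModel:
    """Linear model: potency = intercept + sum(coefficients * descriptors)."""

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float

    def __post_init__(self) -> None:
        if len(self.descriptor_names) != len(self.coefficients):
            raise DataError("coefficient count must equal descriptor count")


@dataclass(frozen=True)
class FitStats:
    """Pearson r, r^2 and adjusted r^2 for observed vs predicted activity."""

    r: float
    r2: float
    r2_adj: float
    n_obs: int
    n_predictors: int


@dataclass(frozen=True)
class SubsetSearchResult:
    """Ranked subset-search output, best r^2 first."""

    entries: tuple[tuple[tuple[str, ...], FitStats, MlrModel], ...]
    n_evaluated: int
    n_skipped: int

    @property
    def best(self) -> tuple[tuple[str, ...], FitStats, MlrModel]:
        return self.entries[0]


#: the published three-descriptor gap-junction inhibition model
PACKAGED_QSAR_MODEL = MlrModel(
    descriptor_names=("SpMin5_Bhm", "SpMax3_Bhi", "minHBd"),
    coefficients=(-4.87, 5.67, -5.70),
    intercept=-7.24,
)


def drop_constant_descriptors(m: DescriptorMatrix) -> DescriptorMatrix:
    """Remove columns identical across all compounds; order preserved."""
    if len(m.compound_ids) == 0:
        raise DataError("need at least one compound")
    keep = [
        i
        for i in range(len(m.descriptor_names))
        if np.unique(m.values[:, i]).size > 1
    ]
    return DescriptorMatrix(
        m.compound_ids,
        tuple(m.descriptor_names[i] for i in keep),
        m.values[:, keep],
    )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns whose removal restores full column rank."""
    full = np.linalg.matrix_rank(X)
    out = []
    for i in range(X.shape[1]):
        reduced = np.delete(X, i, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(names[i])
    return out


def fit_ols(m: DescriptorMatrix, y: Sequence[float]) -> tuple[MlrModel, FitStats]:
    """Least-squares fit with intercept via orthogonal decomposition.

    Raises :class:`DataError` for too few observations or rank-deficient
    designs (the offending collinear columns are named).
    """
    y = np.asarray(y, dtype=float)
    n, k = m.values.shape
    if y.shape != (n,):
        raise DataError(f"activity length {y.shape} does not match {n} compounds")
    if n <= k + 1:
        raise DataError(f"need n_obs > k+1 (got n={n}, k={k})")
    design = np.column_stack([m.values, np.ones(n)])
    if np.linalg.matrix_rank(design) < k + 1:
        bad = _collinear_columns(design[:, :k], m.descriptor_names)
        raise DataError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    model = MlrModel(
        descriptor_names=m.descriptor_names,
        coefficients=tuple(float(b) for b in beta[:k]),
        intercept=float(beta[k]),
    )
    fitted = design @ beta
    stats = validation_stats(y, fitted, n_predictors=k)
    return model, stats


def predict(model: MlrModel, descriptors: Mapping[str, float]) -> float:
    """Evaluate the linear model on one descriptor map."""
    missing = [n for n in model.descriptor_names if n not in descriptors]
    if missing:
        raise DataError(f"missing descriptor(s): {missing}")
    return model.intercept + sum(
        a * float(descriptors[n])
        for a, n in zip(model.coefficients, model.descriptor_names)
    )


def predict_matrix(model: MlrModel, m: DescriptorMatrix) -> np.ndarray:
    """Vectorized :func:`predict` over a descriptor matrix."""
    sub = m.select(model.descriptor_names)
    return sub.values @ np.asarray(model.coefficients) + model.intercept


def validation_stats(
    observed: Sequence[float], predicted: Sequence[float], n_predictors: int
) -> FitStats:
    """Pearson r, r^2 and adjusted r^2 between two activity vectors.

    adjusted r^2 = 1 - (1 - r^2) (n - 1) / (n - k - 1).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise DataError("observed and predicted must be equal-length vectors")
    n = obs.size
    if n < 3:
        raise DataError("need at least 3 observations")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise DataError("zero variance in observed or predicted values")
    r = float(np.corrcoef(obs, pred)[0, 1])
    r2 = r * r
    denom = n - n_predictors - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else float("nan")
    return FitStats(r=r, r2=r2, r2_adj=r2_adj, n_obs=n, n_predictors=n_predictors)


def exhaustive_subset_search(
    m: DescriptorMatrix,
    y: Sequence[float],
    k: int = 3,
    top: int | None = None,
) -> SubsetSearchResult:
    """Fit every size-k descriptor subset and rank by r^2 (descending).

    Rank-deficient subsets are skipped (and logged), not fatal.  Ties are
    broken lexicographically by descriptor-name tuple for determinism.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    names = m.descriptor_names
    if len(names) < k:
        raise DataError(f"only {len(names)} descriptors, cannot choose {k}")
    y = np.asarray(y, dtype=float)
    entries = []
    n_skipped = 0
    for combo in itertools.combinations(range(len(names)), k):
        subset = tuple(names[i] for i in combo)
        try:
            model, stats = fit_ols(m.select(subset), y)
        except DataError as exc:
            log.warning("skipping subset %s: %s", subset, exc)
            n_skipped += 1
            continue
        entries.append((subset, stats, model))
    entries.sort(key=lambda e: (-e[1].r2, e[0]))
    n_evaluated = len(entries) + n_skipped
    if top is not None:
        entries = entries[:top]
    return SubsetSearchResult(
        entries=tuple(entries), n_evaluated=n_evaluated, n_skipped=n_skipped
    )


def save_model(model: MlrModel, path: str | Path) -> None:
    """Serialize a model to a versioned plain-text key-value file."""
    lines = [_MODEL_FORMAT_VERSION]
    for name, coef in zip(model.descriptor_names, model.coefficients):
        lines.append(f"descriptor\t{name}\t{coef!r}")
    lines.append(f"intercept\t{model.intercept!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> MlrModel:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != _MODEL_FORMAT_VERSION:
        raise DataError(f"{path}: not a {_MODEL_FORMAT_VERSION} file")
    names: list[str] = []
    coefs: list[float] = []
    intercept = None
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "descriptor":
            names.append(parts[1])
            coefs.append(float(parts[2]))
        elif parts[0] == "intercept":
            intercept = float(parts[1])
        else:
            raise DataError(f"{path}: unknown record {parts[0]!r}")
    if intercept is None:
        raise DataError(f"{path}: missing intercept")
    return MlrModel(tuple(names), tuple(coefs), intercept)
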