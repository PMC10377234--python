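"""Seeded synthetic-data generators.

Each generator draws from its own pseudo-random stream derived from the
master seed by a fixed offset (``default_rng([seed, offset, ...])``), so
adding a generator call never perturbs the draws of another.  Fixed seed
implies byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compound_table import DataError
from .docking_calibration import DmaRecord
from .dose_response import DoseResponsePoint, hill_response
from .field_qsar import AlignedMolecule, Atom, GridSpec, build_grid, mif_matrix
from .mlr_qsar import DescriptorMatrix

__all__ = [
    "SyntheticSpec",
    "gen_descriptor_dataset",
    "gen_dma_scores",
    "gen_dose_response",
    "gen_aligned_molecules",
]

# per-generator stream offsets (stable; never reorder)
_STREAM_DESCRIPTORS = 101
_STREAM_DMA = 202
_STREAM_DOSE = 303
_STREAM_MOLECULES = 404


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs for the synthetic generators; defaults mirror the study
    scale (17 compounds, 3-descriptor truth, published docking calibration
    and Hill parameters)."""

    seed: int = 1
    # descriptor/activity generator
    n_compounds: int = 17
    n_descriptors: int = 10
    n_constant_descriptors: int = 0
    descriptor_correlation: float = 0.3
    planted_subset: tuple[str, ...] = ("D001", "D002", "D003")
    planted_coefficients: tuple[float, ...] = (1.5, -2.0, 0.8)
    planted_intercept: float = 0.5
    noise_sd: float = 0.1
    # docking-affinity generator
    dma_slope: float = -0.18
    dma_intercept: float = 0.75
    dma_noise_sd: float = 0.3
    # dose-response generator
    hill_params: tuple[float, float, float] = (1.0, 30.0, 2.8)  # y_max, ic50 uM, h
    hill_concentrations: tuple[float, ...] = (0.0, 10.0, 30.0, 50.0, 100.0)
    hill_noise_cv: float = 0.05
    # aligned-molecule generator
    n_molecules: int = 8
    atoms_per_molecule: tuple[int, int] = (3, 10)
    field_step: float = 2.0
    field_outgap: float = 4.0
    field_hotspots: tuple[tuple[int, float], ...] | None = None
    field_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.dma_noise_sd < 0 or self.hill_noise_cv < 0:
            raise DataError("noise parameters must be >= 0")
        if self.field_noise_sd < 0:
            raise DataError("noise parameters must be >= 0")


def _descriptor_names(spec: SyntheticSpec) -> tuple[str, ...]:
    return tuple(f"D{i + 1:03d}" for i in range(spec.n_descriptors))


def gen_descriptor_dataset(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Correlated-Gaussian descriptor matrix with a planted linear activity.

    Activity = planted linear model over ``planted_subset`` + N(0, noise_sd).
    ``n_constant_descriptors`` extra all-constant columns are appended
    (named C001..) for exercising the constant filter.
    """
    names = _descriptor_names(spec)
    missing = set(spec.planted_subset) - set(names)
    if missing:
        raise DataError(f"planted subset not among descriptors: {sorted(missing)}")
    if spec.n_compounds <= len(spec.planted_subset) + 1:
        raise DataError("need n_compounds > |planted subset| + 1")
    rng = np.random.default_rng([spec.seed, _STREAM_DESCRIPTORS])
    p = spec.n_descriptors
    rho = spec.descriptor_correlation
    cov = np.full((p, p), rho) + (1.0 - rho) * np.eye(p)
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((spec.n_compounds, p)) @ L.T
    idx = [names.index(n) for n in spec.planted_subset]
    y = (
        X[:, idx] @ np.asarray(spec.planted_coefficients)
        + spec.planted_intercept
        + rng.standard_normal(spec.n_compounds) * spec.noise_sd
    )
    if spec.n_constant_descriptors:
        const_names = tuple(
            f"C{i + 1:03d}" for i in range(spec.n_constant_descriptors)
        )
        const_vals = np.tile(
            rng.uniform(-1, 1, size=spec.n_constant_descriptors),
            (spec.n_compounds, 1),
        )
        names = names + const_names
        X = np.hstack([X, const_vals])
    matrix = DescriptorMatrix(
        compound_ids=tuple(range(1, spec.n_compounds + 1)),
        descriptor_names=names,
        values=X,
    )
    return matrix, y


def gen_dma_scores(
    spec: SyntheticSpec, activities: Sequence[float]
) -> list[DmaRecord]:
    """Docking scores affinely related to potency: inverts the calibration
    line then adds Gaussian noise."""
    if spec.dma_slope == 0:
        raise DataError("dma_slope must be non-zero")
    rng = np.random.default_rng([spec.seed, _STREAM_DMA])
    a = np.asarray(activities, dtype=float)
    dma = (a - spec.dma_intercept) / spec.dma_slope
    dma = dma + rng.standard_normal(a.size) * spec.dma_noise_sd
    return [DmaRecord(cid=i + 1, dma=float(v)) for i, v in enumerate(dma)]


def gen_dose_response(
    spec: SyntheticSpec, replicate: int = 0
) -> list[DoseResponsePoint]:
    """Hill-curve responses with multiplicative lognormal noise.

    The noise factor has median 1 and coefficient of variation
    ``hill_noise_cv``.  A zero-dose baseline point is always included
    (prepended if absent from the configured concentrations).
    """
    y_max, ic50, h = spec.hill_params
    if not (y_max > 0 and ic50 > 0 and h > 0):
        raise DataError("hill parameters must be positive")
    conc = tuple(spec.hill_concentrations)
    if 0.0 not in conc:
        conc = (0.0,) + conc
    rng = np.random.default_rng([spec.seed, _STREAM_DOSE, replicate])
    c = np.asarray(conc, dtype=float)
    clean = hill_response(c, y_max, ic50, h)
    sigma = math.sqrt(math.log1p(spec.hill_noise_cv**2))
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=c.size) if sigma > 0 else 1.0
    y = clean * noise
    return [
        DoseResponsePoint(concentration_um=float(ci), response=float(yi))
        for ci, yi in zip(c, y)
    ]


def gen_aligned_molecules(
    spec: SyntheticSpec,
) -> tuple[list[AlignedMolecule], np.ndarray, GridSpec, tuple[tuple[int, float], ...]]:
    """Random point-atom molecules plus activities from a planted field
    functional.

    Molecules share one coordinate frame; activity = sum of hotspot
    weights times the molecule's truncated field value at those indices of
    the stacked (steric + electrostatic) vector, plus Gaussian noise.
    When ``field_hotspots`` is None a single hotspot is planted at the
    grid point whose steric field varies most across molecules (weight 1),
    guaranteeing signal.  Returns (molecules, activities, grid, hotspots).
    """
    if spec.n_molecules < 3:
        raise DataError("need at least 3 molecules")
    rng = np.random.default_rng([spec.seed, _STREAM_MOLECULES])
    lo, hi = spec.atoms_per_molecule
    molecules = []
    for i in range(spec.n_molecules):
        n_atoms = int(rng.integers(lo, hi + 1))
        coords = rng.normal(scale=2.0, size=(n_atoms, 3))
        charges = rng.uniform(-0.5, 0.5, size=n_atoms)
        atoms = tuple(
            Atom(
                element="C",
                x=float(cx),
                y=float(cy),
                z=float(cz),
                charge=float(q),
                rmin=3.8,
                epsilon=0.107,
            )
            for (cx, cy, cz), q in zip(coords, charges)
        )
        molecules.append(AlignedMolecule(cid=i + 1, atoms=atoms))
    grid = build_grid(molecules, step=spec.field_step, outgap=spec.field_outgap)
    X = mif_matrix(molecules, grid)
    hotspots = spec.field_hotspots
    if hotspots is None:
        steric_var = X[:, : grid.n_points].var(axis=0)
        hotspots = ((int(np.argmax(steric_var)), 1.0),)
    activities = np.zeros(spec.n_molecules)
    for idx, weight in hotspots:
        activities += weight * X[:, idx]
    activities = activities + rng.standard_normal(spec.n_molecules) * spec.field_noise_sd
    return molecules, activities, grid, tuple(hotspots)
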