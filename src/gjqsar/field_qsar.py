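"""Grid-based 3D field QSAR.

Molecular interaction fields (steric Lennard-Jones 12-6 and Coulomb
electrostatic probe energies, kcal/mol) are evaluated on a shared
rectangular grid around pre-aligned molecules, clamped at configurable
extreme-value bounds, and regressed against activity with a mean-centered
NIPALS partial-least-squares model.  Coefficient maps are exported as
OpenDX scalar grids.

Grid arrays are stored x-fastest: flat index = ix + nx*(iy + ny*iz), with
absolute coordinates in the shared alignment frame (Angstrom).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .compound_table import DataError
from .mlr_qsar import FitStats, validation_stats

__all__ = [
    "Atom",
    "AlignedMolecule",
    "GridSpec",
    "MifField",
    "PlsModel",
    "CoefficientMap",
    "ProbeParams",
    "DEFAULT_PROBE",
    "COULOMB_KCAL",
    "DEFAULT_STERIC_MAX",
    "DEFAULT_ELEC_ABS_MAX",
    "DEFAULT_MAP_CUTOFF",
    "build_grid",
    "compute_mif",
    "truncate_extremes",
    "mif_matrix",
    "fit_pls",
    "pls_predict",
    "select_components_loo",
    "apply_cutoff",
    "export_coefficient_map",
    "write_dx",
    "read_aligned_sdf",
]

log = logging.getLogger(__name__)

#: Coulomb constant for charges in e, distance in Angstrom, energy in kcal/mol
COULOMB_KCAL = 332.0637

#: clamp bounds for extreme field values (kcal/mol); the original grid
#: software documents its own manual defaults, these are conventional ones
DEFAULT_STERIC_MAX = 30.0
DEFAULT_ELEC_ABS_MAX = 10.0

#: coefficient-map isosurface cutoff
DEFAULT_MAP_CUTOFF = 0.0002

PROBES = ("steric_vdw", "electrostatic")


@dataclass(frozen=True)
class Atom:
    """Point atom: element, position (A), partial charge (e), LJ parameters.

    ``rmin`` is the minimum-energy pair distance contribution (A) and
    ``epsilon`` the well depth (kcal/mol); both are combined with the probe
    parameters (arithmetic / geometric mean respectively).
    """

    element: str
    x: float
    y: float
    z: float
    charge: float = 0.0
    rmin: float = 3.8
    epsilon: float = 0.1


@dataclass(frozen=True)
class AlignedMolecule:
    """A pre-aligned molecule in the shared study coordinate frame."""

    cid: int
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise DataError(f"cid {self.cid}: molecule has no atoms")
        if not np.all(np.isfinite(self.coords())):
            raise DataError(f"cid {self.cid}: non-finite coordinates")

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ProbeParams:
    """Probe definition: sp3-carbon-like steric probe, +1 e point charge."""

    rmin: float = 4.0
    epsilon: float = 0.107
    charge: float = 1.0
    dielectric: float = 1.0


DEFAULT_PROBE = ProbeParams()


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned grid: origin, step (A), node counts, boundary outgap."""

    origin: tuple[float, float, float]
    step: float
    dims: tuple[int, int, int]
    outgap: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise DataError("grid step must be positive")
        if any(d < 1 for d in self.dims):
            raise DataError("grid dims must be >= 1")

    @property
    def n_points(self) -> int:
        return self.dims[0] * self.dims[1] * self.dims[2]

    def points(self) -> np.ndarray:
        """All grid nodes, shape (n_points, 3), x-fastest ordering."""
        nx, ny, nz = self.dims
        ax = self.origin[0] + self.step * np.arange(nx)
        ay = self.origin[1] + self.step * np.arange(ny)
        az = self.origin[2] + self.step * np.arange(nz)
        zz, yy, xx = np.meshgrid(az, ay, ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


@dataclass(frozen=True)
class MifField:
    """One probe's interaction energies over a grid, with clamp mask."""

    grid: GridSpec
    probe: str
    values: np.ndarray
    truncated_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.probe not in PROBES:
            raise DataError(f"unknown probe {self.probe!r}")
        if self.values.shape != (self.grid.n_points,):
            raise DataError("field length does not match grid")


@dataclass(frozen=True)
class PlsModel:
    """Mean-centered PLS1 regression on concatenated field vectors."""

    n_components: int
    coefficients: np.ndarray  # (n_predictors,)
    x_mean: np.ndarray
    y_mean: float


@dataclass(frozen=True)
class CoefficientMap:
    grid: GridSpec
    values: np.ndarray
    positive_cutoff: float = DEFAULT_MAP_CUTOFF
    negative_cutoff: float = -DEFAULT_MAP_CUTOFF


def build_grid(
    molecules: Sequence[AlignedMolecule], step: float = 1.0, outgap: float = 5.0
) -> GridSpec:
    """Joint bounding box of all atoms, expanded by ``outgap`` per side,
    discretized at ``step``; dims = floor(extent/step) + 1 per axis."""
    if not molecules:
        raise DataError("need at least one molecule")
    coords = np.vstack([m.coords() for m in molecules])
    lo = coords.min(axis=0) - outgap
    hi = coords.max(axis=0) + outgap
    dims = tuple(int(math.floor((h - l) / step)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(float(v) for v in lo), step=step, dims=dims, outgap=outgap)


def compute_mif(
    mol: AlignedMolecule,
    grid: GridSpec,
    probe: str,
    probe_params: ProbeParams = DEFAULT_PROBE,
    coincident_bound: float | None = None,
) -> MifField:
    """Probe interaction energy at every grid node, kcal/mol.

    steric_vdw:     sum over atoms of eps_c [(rmin_c/r)^12 - 2 (rmin_c/r)^6]
                    with rmin_c = (rmin_atom + rmin_probe)/2 and
                    eps_c = sqrt(eps_atom * eps_probe).
    electrostatic:  sum over atoms of k q_atom q_probe / (D r).

    A node coincident with an atom center is set to the positive clamp
    bound and flagged in the mask.
    """
    if probe not in PROBES:
        raise DataError(f"unknown probe {probe!r}")
    if coincident_bound is None:
        coincident_bound = (
            DEFAULT_STERIC_MAX if probe == "steric_vdw" else DEFAULT_ELEC_ABS_MAX
        )
    pts = grid.points()
    coords = mol.coords()
    # (n_points, n_atoms) distances
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
    coincident = d < 1e-9
    d_safe = np.where(coincident, 1.0, d)
    if probe == "steric_vdw":
        rmin_c = np.array([(a.rmin + probe_params.rmin) / 2.0 for a in mol.atoms])
        eps_c = np.array(
            [math.sqrt(a.epsilon * probe_params.epsilon) for a in mol.atoms]
        )
        ratio = rmin_c[None, :] / d_safe
        e = eps_c[None, :] * (ratio**12 - 2.0 * ratio**6)
    else:
        q = mol.charges()
        e = (
            COULOMB_KCAL
            * probe_params.charge
            * q[None, :]
            / (probe_params.dielectric * d_safe)
        )
        # a zero-charge atom contributes nothing even at its own center
        coincident = coincident & (q[None, :] != 0)
    e = np.where(coincident, 0.0, e)
    values = e.sum(axis=1)
    hit = coincident.any(axis=1)
    if hit.any():
        log.warning(
            "cid %d %s: %d grid node(s) coincide with atom centers; "
            "set to clamp bound %.3g",
            mol.cid,
            probe,
            int(hit.sum()),
            coincident_bound,
        )
        values = np.where(hit, coincident_bound, values)
    return MifField(grid=grid, probe=probe, values=values, truncated_mask=hit.copy())


def truncate_extremes(
    f: MifField,
    steric_max: float = DEFAULT_STERIC_MAX,
    elec_abs_max: float = DEFAULT_ELEC_ABS_MAX,
) -> MifField:
    """Clamp extreme values: steric above +steric_max, electrostatic to
    [-elec_abs_max, +elec_abs_max].  Clamping (not deletion) keeps vector
    lengths aligned across molecules."""
    if steric_max <= 0 or elec_abs_max <= 0:
        raise DataError("truncation bounds must be positive")
    if f.probe == "steric_vdw":
        clamped = np.minimum(f.values, steric_max)
    else:
        clamped = np.clip(f.values, -elec_abs_max, elec_abs_max)
    mask = f.truncated_mask | (clamped != f.values)
    return MifField(grid=f.grid, probe=f.probe, values=clamped, truncated_mask=mask)


def mif_matrix(
    molecules: Sequence[AlignedMolecule],
    grid: GridSpec,
    probes: Sequence[str] = PROBES,
    probe_params: ProbeParams = DEFAULT_PROBE,
    steric_max: float = DEFAULT_STERIC_MAX,
    elec_abs_max: float = DEFAULT_ELEC_ABS_MAX,
) -> np.ndarray:
    """Stack truncated per-molecule fields into an (n_molecules,
    n_probes * n_points) predictor matrix, probe blocks concatenated in
    the given order."""
    rows = []
    for mol in molecules:
        blocks = []
        for probe in probes:
            f = compute_mif(mol, grid, probe, probe_params=probe_params)
            f = truncate_extremes(f, steric_max=steric_max, elec_abs_max=elec_abs_max)
            blocks.append(f.values)
        rows.append(np.concatenate(blocks))
    return np.vstack(rows)


def fit_pls(
    X: np.ndarray, y: Sequence[float], n_components: int
) -> tuple[PlsModel, FitStats]:
    """Mean-centered PLS1 (NIPALS): successive score/loading pairs
    maximizing covariance with the response."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise DataError("need at least 3 molecules")
    if y.shape != (n,):
        raise DataError("activity length does not match predictor rows")
    if n_components < 1 or n_components >= n:
        raise DataError(
            f"n_components must be in [1, n_molecules-1], got {n_components}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xa = X - x_mean
    ya = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    qv = np.zeros(n_components)
    a_used = 0
    for a in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            log.warning("PLS: residual covariance vanished at component %d", a + 1)
            break
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        P[:, a] = Xa.T @ t / tt
        qv[a] = float(ya @ t) / tt
        W[:, a] = w
        Xa = Xa - np.outer(t, P[:, a])
        ya = ya - qv[a] * t
        a_used += 1
    W, P, qv = W[:, :a_used], P[:, :a_used], qv[:a_used]
    coef = W @ np.linalg.solve(P.T @ W, qv)
    model = PlsModel(
        n_components=a_used, coefficients=coef, x_mean=x_mean, y_mean=y_mean
    )
    fitted = (X - x_mean) @ coef + y_mean
    stats = validation_stats(y, fitted, n_predictors=a_used)
    return model, stats


def pls_predict(model: PlsModel, field_vector: np.ndarray) -> float:
    """Apply the centered linear functional to one field vector."""
    v = np.asarray(field_vector, dtype=float)
    if v.shape != model.x_mean.shape:
        raise DataError(
            f"field length {v.shape} does not match training length "
            f"{model.x_mean.shape}"
        )
    return model.y_mean + float((v - model.x_mean) @ model.coefficients)


def select_components_loo(
    X: np.ndarray, y: Sequence[float], max_components: int = 5
) -> int:
    """Smallest component count in 1..max_components maximizing
    leave-one-out q^2."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    best_a, best_q2 = 1, -np.inf
    ss_tot = float(((y - y.mean()) ** 2).sum())
    for a in range(1, min(max_components, n - 2) + 1):
        press = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            model, _ = fit_pls(X[keep], y[keep], a)
            press += (pls_predict(model, X[i]) - y[i]) ** 2
        q2 = 1.0 - press / ss_tot
        if q2 > best_q2 + 1e-12:
            best_a, best_q2 = a, q2
    return best_a


def apply_cutoff(values: np.ndarray, cutoff: float = DEFAULT_MAP_CUTOFF) -> np.ndarray:
    """Zero every coefficient with magnitude below the isosurface cutoff."""
    if not cutoff > 0:
        raise DataError("cutoff magnitude must be positive")
    out = np.asarray(values, dtype=float).copy()
    out[np.abs(out) < cutoff] = 0.0
    return out


def write_dx(grid: GridSpec, values: np.ndarray, path: str | Path) -> None:
    """Write one scalar grid in OpenDX format (data ordered z-fastest as
    the format requires; internal storage is x-fastest)."""
    nx, ny, nz = grid.dims
    v = np.asarray(values, dtype=float)
    if v.shape != (grid.n_points,):
        raise DataError("value length does not match grid")
    # internal (z,y,x) blocks -> dx wants x slowest
    data = v.reshape(nz, ny, nx).transpose(2, 1, 0).ravel()
    lines = [
        "# gjqsar coefficient map",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {grid.step:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.step:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.step:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {data.size} data follows",
    ]
    for i in range(0, data.size, 3):
        lines.append(" ".join(f"{x:.6e}" for x in data[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_coefficient_map(
    model: PlsModel,
    grid: GridSpec,
    out_dir: str | Path,
    cutoff: float = DEFAULT_MAP_CUTOFF,
    probes: Sequence[str] = PROBES,
) -> dict[str, Path]:
    """Write one OpenDX map per probe and sign.

    The model's coefficient vector is split into consecutive per-probe
    blocks of ``grid.n_points`` each, matching :func:`mif_matrix` layout.
    Returns probe/sign -> written path.
    """
    if len(model.coefficients) != grid.n_points * len(probes):
        raise DataError("coefficient length does not match grid x probes")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for bi, probe in enumerate(probes):
        block = model.coefficients[bi * grid.n_points : (bi + 1) * grid.n_points]
        cut = apply_cutoff(block, cutoff)
        for sign, keep in (("positive", cut > 0), ("negative", cut < 0)):
            vals = np.where(keep, cut, 0.0)
            path = out_dir / f"{probe}_{sign}.dx"
            write_dx(grid, vals, path)
            written[f"{probe}_{sign}"] = path
    return written


# default per-element LJ parameters for SDF input (rmin A, epsilon kcal/mol)
DEFAULT_LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (2.4, 0.030),
    "C": (3.8, 0.107),
    "N": (3.5, 0.095),
    "O": (3.4, 0.116),
    "F": (3.2, 0.080),
    "S": (4.0, 0.250),
    "Cl": (3.9, 0.240),
}
_DEFAULT_LJ = (3.8, 0.100)


def read_aligned_sdf(
    path: str | Path,
    charges_csv: str | Path | None = None,
    lj_params: dict[str, tuple[float, float]] | None = None,
) -> list[AlignedMolecule]:
    """Read pre-aligned V2000 SDF structures into point-atom molecules.

    Partial charges come from a sidecar CSV (columns cid, atom_index,
    charge and optionally rmin, epsilon); atoms absent from the sidecar
    fall back to zero charge and per-element LJ defaults.  Requires RDKit.
    """
    from rdkit import Chem  # heavyweight; imported on demand

    lj = dict(DEFAULT_LJ_PARAMS)
    if lj_params:
        lj.update(lj_params)
    sidecar: dict[tuple[int, int], dict[str, float]] = {}
    if charges_csv is not None:
        with Path(charges_csv).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                key = (int(row["cid"]), int(row["atom_index"]))
                sidecar[key] = {
                    k: float(row[k]) for k in ("charge", "rmin", "epsilon") if row.get(k)
                }
    molecules = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for mol in supplier:
        if mol is None:
            raise DataError(f"{path}: unparsable SDF record")
        try:
            cid = int(mol.GetProp("_Name"))
        except (KeyError, ValueError):
            cid = len(molecules)
        conf = mol.GetConformer()
        atoms = []
        for i, atom in enumerate(mol.GetAtoms()):
            pos = conf.GetAtomPosition(i)
            elem = atom.GetSymbol()
            rmin, eps = lj.get(elem, _DEFAULT_LJ)
            extra = sidecar.get((cid, i), {})
            atoms.append(
                Atom(
                    element=elem,
                    x=pos.x,
                    y=pos.y,
                    z=pos.z,
                    charge=extra.get("charge", 0.0),
                    rmin=extra.get("rmin", rmin),
                    epsilon=extra.get("epsilon", eps),
                )
            )
        molecules.append(AlignedMolecule(cid=cid, atoms=tuple(atoms)))
    return molecules
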