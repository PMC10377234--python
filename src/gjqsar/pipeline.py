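"""End-to-end orchestration: the study-reproduction report and the
synthetic recovery suite.

Reports are plain dicts (JSON-serializable, deterministically ordered) so
re-running with the same config and seed reproduces them byte-for-byte.
"""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import (
    compound_table,
    docking_calibration,
    dose_response,
    field_qsar,
    mlr_qsar,
    synthetic,
)
from .compound_table import DataError

__all__ = ["RunConfig", "run_reproduction", "run_synthetic_suite", "write_report"]

ALL_STAGES = ("qsar", "docking", "qsar3d", "conversions")

#: -log10 molar potency of the experimentally measured 30 uM IC50
_LIMONENE_CID = 22311


@dataclass(frozen=True)
class RunConfig:
    stages: tuple[str, ...] = ALL_STAGES
    subset_k: int = 3
    grid_step: float = 1.0
    grid_outgap: float = 5.0
    map_cutoff: float = field_qsar.DEFAULT_MAP_CUTOFF
    steric_max: float = field_qsar.DEFAULT_STERIC_MAX
    elec_abs_max: float = field_qsar.DEFAULT_ELEC_ABS_MAX
    hill_residual: str = "multiplicative"
    hill_replicates: int = 200
    measured_ic50_um: float = 30.0
    seed: int = 1
    out_dir: str | None = None


def _round(x: float, nd: int = 6) -> float:
    return float(round(x, nd))


def run_reproduction(config: RunConfig = RunConfig()) -> dict:
    """Reproduce the study's desk-computable results from the packaged
    fixture: per-compound linear-model predictions, validation statistics
    of the three prediction columns, unit conversions, eligibility counts,
    and pass/fail for the desk acceptance targets."""
    ds = compound_table.load_packaged_dataset()
    eligible = compound_table.filter_docking_eligible(ds)
    report: dict = {
        "counts": {"total": len(ds), "docking_eligible": len(eligible)},
        "predictions": [],
        "stats": {},
        "conversions": {},
        "targets": {},
    }

    model = mlr_qsar.PACKAGED_QSAR_MODEL
    e_all = np.array([r.neg_log_e_ic50 for r in ds])

    if "qsar" in config.stages:
        for r in ds:
            report["predictions"].append(
                {
                    "cid": r.cid,
                    "name": r.name,
                    "neg_log_e_ic50": r.neg_log_e_ic50,
                    "model_prediction": _round(mlr_qsar.predict(model, r.descriptors)),
                    "printed_qsar": r.pred_qsar,
                    "printed_docking": r.pred_docking,
                    "printed_3dqsar": r.pred_3dqsar,
                }
            )
        q_all = np.array([r.pred_qsar for r in ds])
        st = mlr_qsar.validation_stats(e_all, q_all, n_predictors=3)
        report["stats"]["qsar"] = {
            "n": st.n_obs,
            "r": _round(st.r),
            "r2": _round(st.r2),
            "r2_adj": _round(st.r2_adj),
        }
        # refit the three-descriptor model from the printed values
        matrix = mlr_qsar.DescriptorMatrix(
            compound_ids=tuple(r.cid for r in ds),
            descriptor_names=ds.descriptor_names,
            values=np.array([[r.descriptors[n] for n in ds.descriptor_names] for r in ds]),
        )
        refit, refit_stats = mlr_qsar.fit_ols(matrix, e_all)
        report["stats"]["qsar_refit"] = {
            "coefficients": [_round(c) for c in refit.coefficients],
            "intercept": _round(refit.intercept),
            "r2": _round(refit_stats.r2),
            "r2_adj": _round(refit_stats.r2_adj),
        }

    if "docking" in config.stages:
        pairs = [(r.neg_log_e_ic50, r.pred_docking) for r in eligible]
        st = mlr_qsar.validation_stats(
            [p[0] for p in pairs], [p[1] for p in pairs], n_predictors=1
        )
        report["stats"]["docking"] = {
            "n": st.n_obs,
            "r": _round(st.r),
            "r2": _round(st.r2),
        }
        cal = docking_calibration.PAPER_PRESET
        report["stats"]["docking_calibration"] = {
            "slope_m": cal.slope_m,
            "intercept_n": cal.intercept_n,
        }

    if "qsar3d" in config.stages:
        pairs = [(r.neg_log_e_ic50, r.pred_3dqsar) for r in eligible]
        st = mlr_qsar.validation_stats(
            [p[0] for p in pairs], [p[1] for p in pairs], n_predictors=1
        )
        report["stats"]["qsar3d"] = {
            "n": st.n_obs,
            "r": _round(st.r),
            "r2": _round(st.r2),
            "r2_adj": _round(st.r2_adj),
        }

    if "conversions" in config.stages:
        lim = ds.get(_LIMONENE_CID)
        conv = {}
        for key, val in (
            ("docking", lim.pred_docking),
            ("qsar", lim.pred_qsar),
            ("qsar3d", lim.pred_3dqsar),
        ):
            if val is not None:
                conv[f"limonene_{key}_um"] = _round(
                    compound_table.neg_log_to_micromolar(val), 3
                )
        conv["measured_neg_log"] = _round(
            compound_table.micromolar_to_neg_log(config.measured_ic50_um), 4
        )
        report["conversions"] = conv

        report["targets"] = {
            "t3": {
                "value": round(conv["limonene_docking_um"]),
                "expected": 66,
            },
            "t4": {"value": round(conv["limonene_qsar_um"]), "expected": 14},
            "t5": {"value": round(conv["measured_neg_log"], 2), "expected": 4.52},
            "t6": {"value": len(eligible), "expected": 14},
        }
        for t in report["targets"].values():
            t["pass"] = t["value"] == t["expected"]

    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def run_synthetic_suite(config: RunConfig = RunConfig()) -> dict:
    """Generator -> stage -> recovery loops for every pipeline stage."""
    seed = config.seed
    checks: dict = {}

    # best-subset recovery in a non-trivial regime
    spec = synthetic.SyntheticSpec(
        seed=seed,
        n_compounds=40,
        n_descriptors=30,
        planted_subset=("D001", "D005", "D020"),
        planted_coefficients=(1.5, -2.0, 0.8),
        noise_sd=0.1,
    )
    matrix, y = synthetic.gen_descriptor_dataset(spec)
    result = mlr_qsar.exhaustive_subset_search(matrix, y, k=3, top=5)
    top = tuple(sorted(result.best[0]))
    checks["subset_recovery"] = {
        "top_subset": list(top),
        "planted": sorted(spec.planted_subset),
        "pass": top == tuple(sorted(spec.planted_subset)),
    }

    # calibration slope recovery over replicate seeds
    slope_errors = []
    for i in range(50):
        rep = synthetic.SyntheticSpec(
            seed=seed + 1000 + i, n_compounds=14, dma_noise_sd=0.3
        )
        _, acts = synthetic.gen_descriptor_dataset(
            synthetic.SyntheticSpec(seed=seed + 1000 + i, n_compounds=14)
        )
        scores = synthetic.gen_dma_scores(rep, acts)
        cal, _ = docking_calibration.fit_calibration(
            [(s.dma, a) for s, a in zip(scores, acts)]
        )
        slope_errors.append(abs(cal.slope_m - rep.dma_slope))
    med_err = statistics.median(slope_errors)
    checks["dma_slope_recovery"] = {
        "median_abs_slope_error": _round(med_err),
        "pass": med_err <= 0.05,
    }

    # Hill parameter recovery
    ic50s, hs = [], []
    spec_hill = synthetic.SyntheticSpec(seed=seed)
    for i in range(config.hill_replicates):
        points = synthetic.gen_dose_response(spec_hill, replicate=i)
        fit = dose_response.fit_hill(points, residual=config.hill_residual)
        ic50s.append(fit.ic50_um)
        hs.append(fit.hill_h)
    checks["hill_recovery"] = {
        "n_replicates": config.hill_replicates,
        "median_ic50_um": _round(statistics.median(ic50s), 4),
        "median_hill_h": _round(statistics.median(hs), 4),
        "pass": (
            round(statistics.median(ic50s)) == round(spec_hill.hill_params[1])
            and round(statistics.median(hs), 1) == round(spec_hill.hill_params[2], 1)
        ),
    }

    # field-PLS recovery on a planted hotspot
    mols, acts, grid, hotspots = synthetic.gen_aligned_molecules(
        synthetic.SyntheticSpec(seed=seed, field_noise_sd=0.0)
    )
    X = field_qsar.mif_matrix(mols, grid)
    model, stats = field_qsar.fit_pls(X, acts, n_components=len(mols) - 1)
    sign_ok = all(
        np.sign(model.coefficients[idx]) == np.sign(w) for idx, w in hotspots
    )
    checks["pls_recovery"] = {
        "r2": _round(stats.r2),
        "hotspot_sign_match": sign_ok,
        "pass": stats.r2 > 0.999 and sign_ok,
    }

    report = {"seed": seed, "checks": checks, "pass": all(c["pass"] for c in checks.values())}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "synthetic_suite.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return report


def write_report(report: dict, out_dir: str | Path) -> None:
    """Emit summary.json plus predictions.csv / stats.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    preds = report.get("predictions", [])
    if preds:
        with (out / "predictions.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(preds[0]))
            writer.writeheader()
            writer.writerows(preds)
    stats = report.get("stats", {})
    if stats:
        with (out / "stats.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["section", "key", "value"])
            for section, entries in stats.items():
                for key, value in entries.items():
                    writer.writerow([section, key, value])
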