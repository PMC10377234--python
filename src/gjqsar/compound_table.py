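"""Inhibitor dataset: records, CSV I/O, potency-unit conversions and
docking-eligibility filtering.

Potency is carried internally as -log10 molar concentration; micromolar
values appear only at I/O boundaries.  The packaged fixture ships the
17-compound Cx43 inhibitor study table (CSV, UTF-8, '.' decimal separator).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CompoundRecord",
    "CompoundDataset",
    "DataError",
    "EXCLUSION_FLAGS",
    "load_dataset",
    "load_packaged_dataset",
    "filter_docking_eligible",
    "neg_log_to_micromolar",
    "micromolar_to_neg_log",
]

#: recognised reasons a compound is excluded from docking-dependent stages
EXCLUSION_FLAGS = frozenset({"no_clear_3d_structure", "organoboron"})

_SPECIES = frozenset({"human", "rat"})
_ASSAYS = frozenset({"patch_clamp", "metabolic_communication"})

# fixed (non-descriptor) fixture columns
_META_COLUMNS = (
    "cid",
    "name",
    "species",
    "assay",
    "neg_log_e_ic50",
    "pred_docking",
    "pred_qsar",
    "pred_3dqsar",
    "o3a_score",
    "exclusion_flags",
)


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class CompoundRecord:
    """One inhibitor: identity, measured potency, descriptors, predictions.

    ``neg_log_e_ic50`` is the measured potency as -log10 molar.  The three
    ``pred_*`` fields are optional model predictions on the same scale.
    ``o3a_score`` is an externally computed alignment score carried as
    metadata only.
    """

    cid: int
    name: str
    species: str
    assay: str
    neg_log_e_ic50: float
    descriptors: Mapping[str, float]
    pred_docking: float | None = None
    pred_qsar: float | None = None
    pred_3dqsar: float | None = None
    o3a_score: float | None = None
    exclusion_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not math.isfinite(self.neg_log_e_ic50):
            raise DataError(f"cid {self.cid}: non-finite potency")
        if self.species not in _SPECIES:
            raise DataError(f"cid {self.cid}: unknown species {self.species!r}")
        if self.assay not in _ASSAYS:
            raise DataError(f"cid {self.cid}: unknown assay {self.assay!r}")
        unknown = set(self.exclusion_flags) - EXCLUSION_FLAGS
        if unknown:
            raise DataError(f"cid {self.cid}: unknown exclusion flags {sorted(unknown)}")

    @property
    def docking_eligible(self) -> bool:
        return not self.exclusion_flags


@dataclass(frozen=True)
class CompoundDataset:
    """Ordered collection of :class:`CompoundRecord` with a shared descriptor set."""

    records: tuple[CompoundRecord, ...]
    descriptor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        cids = [r.cid for r in self.records]
        if len(cids) != len(set(cids)):
            dupes = sorted({c for c in cids if cids.count(c) > 1})
            raise DataError(f"duplicate cid(s): {dupes}")
        keys = set(self.descriptor_names)
        for r in self.records:
            if set(r.descriptors) != keys:
                raise DataError(f"cid {r.cid}: descriptor keys differ from dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, cid: int) -> CompoundRecord:
        for r in self.records:
            if r.cid == cid:
                return r
        raise KeyError(cid)


def _parse_optional(text: str) -> float | None:
    text = text.strip()
    return float(text) if text else None


def load_dataset(path: str | Path) -> CompoundDataset:
    """Read a compound table CSV into a :class:`CompoundDataset`.

    Columns not in the fixed metadata set are treated as descriptors.
    Missing optional predictions are stored as ``None``, never zero.
    Duplicate cids and non-numeric potencies are hard errors naming the row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataError(f"{path}: empty file, header row required")
        missing = {"cid", "name", "neg_log_e_ic50"} - set(reader.fieldnames)
        if missing:
            raise DataError(f"{path}: missing required columns {sorted(missing)}")
        descriptor_names = tuple(
            c for c in reader.fieldnames if c not in _META_COLUMNS
        )
        records: list[CompoundRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                potency = float(row["neg_log_e_ic50"])
            except (TypeError, ValueError):
                raise DataError(
                    f"{path}:{lineno}: non-numeric potency "
                    f"{row['neg_log_e_ic50']!r} for {row.get('name', '?')}"
                ) from None
            flags = frozenset(
                f for f in (row.get("exclusion_flags") or "").split(";") if f
            )
            records.append(
                CompoundRecord(
                    cid=int(row["cid"]),
                    name=row["name"],
                    species=row.get("species", "human"),
                    assay=row.get("assay", "patch_clamp"),
                    neg_log_e_ic50=potency,
                    descriptors={k: float(row[k]) for k in descriptor_names},
                    pred_docking=_parse_optional(row.get("pred_docking") or ""),
                    pred_qsar=_parse_optional(row.get("pred_qsar") or ""),
                    pred_3dqsar=_parse_optional(row.get("pred_3dqsar") or ""),
                    o3a_score=_parse_optional(row.get("o3a_score") or ""),
                    exclusion_flags=flags,
                )
            )
    return CompoundDataset(records=tuple(records), descriptor_names=descriptor_names)


def load_packaged_dataset() -> CompoundDataset:
    """Load the packaged 17-compound Cx43 inhibitor fixture."""
    src = resources.files("gjqsar.data").joinpath("cx43_inhibitors.csv")
    with resources.as_file(src) as path:
        return load_dataset(path)


def filter_docking_eligible(ds: CompoundDataset) -> CompoundDataset:
    """Drop records carrying any exclusion flag; order preserved. Idempotent."""
    kept = tuple(r for r in ds.records if r.docking_eligible)
    return CompoundDataset(records=kept, descriptor_names=ds.descriptor_names)


def neg_log_to_micromolar(x: float) -> float:
    """Convert -log10 molar potency to a micromolar concentration."""
    if not math.isfinite(x):
        raise DataError("potency must be finite")
    return 10.0 ** (-x) * 1e6


def micromolar_to_neg_log(c: float) -> float:
    """Convert a micromolar concentration to -log10 molar potency."""
    if not (c > 0):
        raise DataError(f"concentration must be positive, got {c}")
    return -math.log10(c * 1e-6)
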