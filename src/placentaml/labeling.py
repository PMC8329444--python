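"""Compound tables and the cross / not-cross labeling rules.

Each compound carries up to three pieces of transfer evidence:

* ``fm_ratio`` — the fetal:maternal blood concentration ratio measured in vivo
  at delivery (primary evidence),
* ``clearance_index`` — the CI from the ex vivo human placental perfusion
  model (secondary evidence),
* ``literature_label`` — a curated C/NC call from the literature (fallback).

Precedence is F/M first: F/M <= 0.15 labels NC, F/M >= 0.3 labels C (in vivo
evidence outranks perfusion, so the CI is ignored whenever an F/M value
decides), and the dubious open band 0.15 < F/M < 0.3 is excluded from the
dataset. Without an F/M value, CI > 0.80 labels C; a CI at or below 0.80
never labels on its own and the literature call is used as a last resort.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .metrics import NEGATIVE_LABEL, POSITIVE_LABEL

logger = logging.getLogger(__name__)

LABEL_C = "C"
LABEL_NC = "NC"
LABEL_EXCLUDED = "EXCLUDED"
LABEL_UNLABELABLE = "UNLABELABLE"

FM_NC_MAX = 0.15
FM_C_MIN = 0.3
CI_C_MIN = 0.80

COMPOUND_COLUMNS = (
    "compound_id",
    "name",
    "smiles",
    "fm_ratio",
    "clearance_index",
    "literature_label",
)


class ValidationError(ValueError):
    """A field value violates its domain (negative, non-finite, unknown label)."""


class FormatError(ValueError):
    """A table does not have the expected shape or columns."""


class DegenerateDatasetError(ValueError):
    """Too few labeled compounds per class to support the protocol."""


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str = ""
    smiles: Optional[str] = None
    fm_ratio: Optional[float] = None
    clearance_index: Optional[float] = None
    literature_label: Optional[str] = None
    assigned_label: Optional[str] = None


@dataclass
class LabeledDataset:
    """Compounds with resolved binary labels plus class bookkeeping."""

    records: list[CompoundRecord]
    class_counts: dict[str, int]
    negative_class: str = NEGATIVE_LABEL
    n_excluded: int = 0
    n_unlabelable: int = 0

    @property
    def labels(self) -> pd.Series:
        """Assigned labels as a Series indexed by compound_id."""
        return pd.Series(
            {r.compound_id: r.assigned_label for r in self.records},
            name="assigned_label",
        )

    def summary(self) -> dict:
        return {
            "n_total": len(self.records),
            "n_C": self.class_counts.get(LABEL_C, 0),
            "n_NC": self.class_counts.get(LABEL_NC, 0),
            "n_excluded": self.n_excluded,
            "n_unlabelable": self.n_unlabelable,
        }


def _check_nonneg(value: Optional[float], name: str) -> Optional[float]:
    if value is None:
        return None
    v = float(value)
    if not (v == v) or v in (float("inf"), float("-inf")):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if v < 0:
        raise ValidationError(f"{name} must be non-negative, got {value!r}")
    return v


def assign_label(
    fm_ratio: Optional[float] = None,
    clearance_index: Optional[float] = None,
    literature_label: Optional[str] = None,
) -> str:
    """Resolve one compound's evidence to C / NC / EXCLUDED / UNLABELABLE."""
    fm = _check_nonneg(fm_ratio, "fm_ratio")
    ci = _check_nonneg(clearance_index, "clearance_index")
    if literature_label is not None and literature_label not in (LABEL_C, LABEL_NC):
        raise ValidationError(
            f"literature_label must be C or NC, got {literature_label!r}"
        )

    if fm is not None:
        if fm <= FM_NC_MAX:
            return LABEL_NC
        if fm >= FM_C_MIN:
            return LABEL_C
        # dubious band; F/M priority holds even when a CI value is present
        if ci is not None:
            logger.info(
                "F/M in the excluded band with CI=%s present; excluding (F/M priority)",
                ci,
            )
        return LABEL_EXCLUDED
    if ci is not None and ci > CI_C_MIN:
        return LABEL_C
    if literature_label is not None:
        return literature_label
    return LABEL_UNLABELABLE


def load_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound CSV into records; labels are not assigned yet.

    Required column: compound_id. Empty cells become absent values. Numeric
    cells that fail to parse raise a row-indexed error.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "compound_id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing mandatory column 'compound_id'")
        records = []
        for i, row in enumerate(reader):
            records.append(_record_from_row(row, i))
    return records


def _record_from_row(row: dict, index: int) -> CompoundRecord:
    def cell(col: str) -> Optional[str]:
        v = (row.get(col) or "").strip()
        return v or None

    def num(col: str) -> Optional[float]:
        v = cell(col)
        if v is None:
            return None
        try:
            return float(v)
        except ValueError:
            raise FormatError(f"row {index}: cannot parse {col}={v!r} as a number")

    cid = cell("compound_id")
    if cid is None:
        raise FormatError(f"row {index}: empty compound_id")
    return CompoundRecord(
        compound_id=cid,
        name=cell("name") or "",
        smiles=cell("smiles"),
        fm_ratio=num("fm_ratio"),
        clearance_index=num("clearance_index"),
        literature_label=cell("literature_label"),
    )


def label_records(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Return copies of *records* with ``assigned_label`` resolved."""
    return [
        replace(
            r,
            assigned_label=assign_label(r.fm_ratio, r.clearance_index, r.literature_label),
        )
        for r in records
    ]


def build_labeled_dataset(
    records: Iterable[CompoundRecord], min_per_class: int = 2
) -> LabeledDataset:
    """Drop excluded/unlabelable records and assemble the binary dataset.

    The majority class (C in practice) is designated the negative class; NC,
    the minority, is the positive class throughout metrics and modeling.
    """
    labeled = [
        r if r.assigned_label is not None else replace(
            r,
            assigned_label=assign_label(r.fm_ratio, r.clearance_index, r.literature_label),
        )
        for r in records
    ]
    seen = set()
    for r in labeled:
        if r.compound_id in seen:
            raise FormatError(f"duplicate compound_id {r.compound_id!r}")
        seen.add(r.compound_id)
    kept = [r for r in labeled if r.assigned_label in (LABEL_C, LABEL_NC)]
    n_excluded = sum(1 for r in labeled if r.assigned_label == LABEL_EXCLUDED)
    n_unlab = sum(1 for r in labeled if r.assigned_label == LABEL_UNLABELABLE)
    if n_excluded or n_unlab:
        logger.info(
            "dropped %d excluded and %d unlabelable compounds", n_excluded, n_unlab
        )
    counts = {
        LABEL_C: sum(1 for r in kept if r.assigned_label == LABEL_C),
        LABEL_NC: sum(1 for r in kept if r.assigned_label == LABEL_NC),
    }
    if min(counts.values(), default=0) < min_per_class:
        raise DegenerateDatasetError(
            f"need at least {min_per_class} compounds per class, got {counts}"
        )
    return LabeledDataset(
        records=kept,
        class_counts=counts,
        negative_class=NEGATIVE_LABEL,
        n_excluded=n_excluded,
        n_unlabelable=n_unlab,
    )


def save_labeled_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Write the labeled table back out with the assigned_label column added."""
    rows = []
    for r in dataset.records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "smiles": r.smiles or "",
                "fm_ratio": "" if r.fm_ratio is None else r.fm_ratio,
                "clearance_index": "" if r.clearance_index is None else r.clearance_index,
                "literature_label": r.literature_label or "",
                "assigned_label": r.assigned_label,
            }
        )
    pd.DataFrame(rows, columns=COMPOUND_COLUMNS + ("assigned_label",)).to_csv(
        path, index=False
    )


__all__ = [
    "CompoundRecord",
    "LabeledDataset",
    "ValidationError",
    "FormatError",
    "DegenerateDatasetError",
    "assign_label",
    "load_compound_table",
    "label_records",
    "build_labeled_dataset",
    "save_labeled_dataset",
    "LABEL_C",
    "LABEL_NC",
    "LABEL_EXCLUDED",
    "LABEL_UNLABELABLE",
    "POSITIVE_LABEL",
]
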