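"""Submitted eCRF records and the tabular dataset they form.

The clinical dataset is one row per patient x visit ("wide" CSV: fixed
metadata columns followed by one column per item). A long three-column
alternative (patient_id, visit, item_id, value) is also read and written.
"""

from __future__ import annotations

import datetime as dt
from typing import Any, Iterable, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .conditions import is_missing
from .schema_catalog import EcrfSchema

SUBMISSION_STATUSES = ("submitted_manual", "submitted_expired", "absent")
_META_COLUMNS = ["patient_id", "visit", "diagnosis_arm", "submission_status", "submission_date"]


class EcrfRecord(BaseModel):
    """One submitted (or expired, or absent) patient x visit form."""

    patient_id: str
    visit: str
    diagnosis_arm: str = ""
    submission_status: str = "submitted_manual"
    submission_date: Optional[dt.date] = None
    values: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _invariants(self) -> "EcrfRecord":
        if self.submission_status not in SUBMISSION_STATUSES:
            raise ValueError(f"unknown submission status {self.submission_status!r}")
        if self.submission_status == "absent" and self.values:
            raise ValueError("absent records carry no values")
        return self

    @property
    def submitted(self) -> bool:
        return self.submission_status != "absent"

    def filled_items(self) -> list[str]:
        return [k for k, v in self.values.items() if not is_missing(v)]

    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.visit)


Dataset = list[EcrfRecord]


def check_dataset(schema: EcrfSchema, dataset: Iterable[EcrfRecord]) -> None:
    """Raise if any record references a visit or item outside the schema."""
    item_visits = {i.item_id: set(i.visits) for i in schema.items}
    seen: set[tuple[str, str]] = set()
    for rec in dataset:
        if rec.visit not in schema.visit_ids:
            raise ValueError(f"{rec.patient_id}: unknown visit {rec.visit!r}")
        if rec.key() in seen:
            raise ValueError(f"duplicate record for {rec.key()}")
        seen.add(rec.key())
        for item_id in rec.values:
            visits = item_visits.get(item_id)
            if visits is None:
                raise ValueError(f"{rec.key()}: unknown item {item_id!r}")
            if rec.visit not in visits:
                raise ValueError(
                    f"{rec.key()}: item {item_id!r} not applicable at {rec.visit}"
                )


def dataset_to_frame(schema: EcrfSchema, dataset: Iterable[EcrfRecord]) -> pd.DataFrame:
    item_ids = [i.item_id for i in schema.items]
    rows = []
    for rec in dataset:
        row: dict[str, Any] = {
            "patient_id": rec.patient_id,
            "visit": rec.visit,
            "diagnosis_arm": rec.diagnosis_arm,
            "submission_status": rec.submission_status,
            "submission_date": rec.submission_date.isoformat() if rec.submission_date else "",
        }
        for item_id in item_ids:
            v = rec.values.get(item_id)
            row[item_id] = "" if is_missing(v) else v
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLUMNS + item_ids)


def write_dataset(schema: EcrfSchema, dataset: Iterable[EcrfRecord], path) -> None:
    dataset_to_frame(schema, dataset).to_csv(path, index=False)


def read_dataset(schema: EcrfSchema, path) -> Dataset:
    """Read a wide-format CSV dataset and validate it against the schema."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_meta = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing_meta:
        raise ValueError(f"dataset lacks metadata columns {missing_meta}")
    dataset: Dataset = []
    item_visits = {i.item_id: set(i.visits) for i in schema.items}
    for _, row in frame.iterrows():
        visit = row["visit"]
        values = {
            item_id: row[item_id]
            for item_id in item_visits
            if item_id in frame.columns
            and not is_missing(row[item_id])
            and visit in item_visits[item_id]
        }
        sub_date = row["submission_date"] or None
        dataset.append(
            EcrfRecord(
                patient_id=row["patient_id"],
                visit=visit,
                diagnosis_arm=row["diagnosis_arm"],
                submission_status=row["submission_status"] or "submitted_manual",
                submission_date=dt.date.fromisoformat(sub_date) if sub_date else None,
                values=values,
            )
        )
    check_dataset(schema, dataset)
    return dataset
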