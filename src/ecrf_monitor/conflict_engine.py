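"""Post-submission conflict detection.

Scans the accumulated clinical dataset against the conflict catalog and
emits the conflict list that feeds query generation. Two passes:

1. *Entire-eCRF pass*: for every enrolled patient (baseline form present),
   each expected-but-missing follow-up visit, and each submitted form that
   is nearly empty (at most ``near_empty_threshold`` non-mandatory items
   filled), yields one ``entire_ecrf`` conflict.
2. *Single-conflict pass*: every submitted record NOT flagged entire-eCRF
   is evaluated against every applicable catalog rule; each firing rule
   yields one conflict keyed (patient, visit, rule).

A record flagged entire-eCRF contributes no single conflicts — the whole
form is re-requested, so itemized queries would duplicate work. Detection
is deterministic and idempotent: output is sorted (patient, visit order,
rule_id) and re-running on unchanged data reproduces it exactly.
"""

from __future__ import annotations

import datetime as dt
from typing import Any, Optional

from pydantic import BaseModel, Field

from .conditions import ConditionError, evaluate_expression, is_missing, out_of_range
from .records import Dataset, EcrfRecord, check_dataset
from .schema_catalog import ConflictCatalog, ConflictRule, EcrfSchema

#: calendar slack added to a visit's nominal offset before the visit counts
#: as overdue (sites schedule follow-ups loosely around the nominal month)
DEFAULT_VISIT_WINDOW_DAYS = 42

#: a submitted form with at most this many non-mandatory items filled is
#: treated as effectively missing and queried as an entire-eCRF conflict
DEFAULT_NEAR_EMPTY_THRESHOLD = 3

ENTIRE_ECRF_RULE_ID = "entire_ecrf"


class Conflict(BaseModel):
    """One detected data problem on one patient x visit."""

    conflict_id: str
    patient_id: str
    visit: str
    rule_id: str
    conflict_type: str
    items: dict[str, Any] = Field(default_factory=dict)
    detected_in_run: int = 0

    @staticmethod
    def make_id(patient_id: str, visit: str, rule_id: str) -> str:
        return f"{patient_id}|{visit}|{rule_id}"


def evaluate_condition(rule: ConflictRule, record: EcrfRecord, schema: EcrfSchema) -> bool:
    """True iff *rule* fires on *record*.

    ``missing`` / ``range`` / ``date`` rules with no explicit condition get
    the canonical one derived from their type and first target item.
    """
    if rule.conflict_type == "entire_ecrf":
        raise ValueError("entire_ecrf rules are handled by detect_entire_ecrf")
    if not record.submitted:
        raise ValueError("cannot evaluate single-conflict rules on an absent record")
    expr = rule.condition.strip()
    if expr:
        return evaluate_expression(expr, schema, record.values)
    target = schema.item(rule.target_items[0])
    if rule.conflict_type == "missing":
        return is_missing(record.values.get(target.item_id))
    if rule.conflict_type == "range":
        return out_of_range(target, record.values.get(target.item_id))
    raise ConditionError(f"rule {rule.rule_id!r} ({rule.conflict_type}) needs a condition")


def expected_visits(
    schema: EcrfSchema,
    inclusion_date: dt.date,
    ref_date: dt.date,
    window_days: int = DEFAULT_VISIT_WINDOW_DAYS,
) -> list[str]:
    """Visits whose nominal offset (plus scheduling window) has elapsed."""
    due = []
    for visit in schema.visits:
        nominal = inclusion_date + dt.timedelta(days=round(visit.offset_months * 30.44))
        if nominal + dt.timedelta(days=window_days) <= ref_date:
            due.append(visit.visit_id)
    return due


def _inclusion_date(baseline: EcrfRecord) -> Optional[dt.date]:
    from .conditions import parse_date

    return (
        parse_date(baseline.values.get("inclusion_date"))
        or parse_date(baseline.values.get("survey_date"))
        or baseline.submission_date
    )


def is_near_empty(
    schema: EcrfSchema,
    record: EcrfRecord,
    threshold: int = DEFAULT_NEAR_EMPTY_THRESHOLD,
) -> bool:
    mandatory = set(schema.mandatory_items())
    filled = [i for i in record.filled_items() if i not in mandatory]
    return len(filled) <= threshold


def detect_entire_ecrf(
    schema: EcrfSchema,
    patient_records: list[EcrfRecord],
    ref_date: dt.date,
    *,
    near_empty_threshold: int = DEFAULT_NEAR_EMPTY_THRESHOLD,
    window_days: int = DEFAULT_VISIT_WINDOW_DAYS,
    run_id: int = 0,
) -> list[Conflict]:
    """Entire-eCRF conflicts for one patient: overdue-missing or near-empty forms.

    Requires a baseline record (study inclusion); patients without one are
    not yet enrolled and yield nothing.
    """
    baseline_visit = schema.visit_ids[0]
    by_visit = {r.visit: r for r in patient_records}
    baseline = by_visit.get(baseline_visit)
    if baseline is None or not baseline.submitted:
        return []
    patient_id = baseline.patient_id
    inclusion = _inclusion_date(baseline)

    conflicts: list[Conflict] = []
    due = (
        expected_visits(schema, inclusion, ref_date, window_days) if inclusion else
        [baseline_visit]
    )
    for visit in due:
        record = by_visit.get(visit)
        if record is None or not record.submitted:
            conflicts.append(
                Conflict(
                    conflict_id=Conflict.make_id(patient_id, visit, ENTIRE_ECRF_RULE_ID),
                    patient_id=patient_id,
                    visit=visit,
                    rule_id=ENTIRE_ECRF_RULE_ID,
                    conflict_type="entire_ecrf",
                    items={},
                    detected_in_run=run_id,
                )
            )
    for record in patient_records:
        if record.submitted and is_near_empty(schema, record, near_empty_threshold):
            cid = Conflict.make_id(patient_id, record.visit, ENTIRE_ECRF_RULE_ID)
            if all(c.conflict_id != cid for c in conflicts):
                conflicts.append(
                    Conflict(
                        conflict_id=cid,
                        patient_id=patient_id,
                        visit=record.visit,
                        rule_id=ENTIRE_ECRF_RULE_ID,
                        conflict_type="entire_ecrf",
                        items={},
                        detected_in_run=run_id,
                    )
                )
    return conflicts


def detect_conflicts(
    schema: EcrfSchema,
    catalog: ConflictCatalog,
    dataset: Dataset,
    ref_date: dt.date | str,
    *,
    run_id: int = 0,
    near_empty_threshold: int = DEFAULT_NEAR_EMPTY_THRESHOLD,
    window_days: int = DEFAULT_VISIT_WINDOW_DAYS,
) -> list[Conflict]:
    """Full detection pass over the dataset; see the module docstring."""
    from .conditions import parse_date

    catalog.validate_against(schema)
    check_dataset(schema, dataset)
    ref = parse_date(ref_date)
    if ref is None:
        raise ValueError(f"invalid reference date {ref_date!r}")

    by_patient: dict[str, list[EcrfRecord]] = {}
    for rec in dataset:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    conflicts: list[Conflict] = []
    entire_keys: set[tuple[str, str]] = set()
    for patient_id in sorted(by_patient):
        found = detect_entire_ecrf(
            schema,
            by_patient[patient_id],
            ref,
            near_empty_threshold=near_empty_threshold,
            window_days=window_days,
            run_id=run_id,
        )
        conflicts.extend(found)
        entire_keys.update((c.patient_id, c.visit) for c in found)

    single_rules = [r for r in catalog.rules if r.conflict_type != "entire_ecrf"]
    for rec in dataset:
        if not rec.submitted or rec.key() in entire_keys:
            continue
        for rule in single_rules:
            if not rule.applies(rec.visit, rec.diagnosis_arm or None):
                continue
            if evaluate_condition(rule, rec, schema):
                conflicts.append(
                    Conflict(
                        conflict_id=Conflict.make_id(rec.patient_id, rec.visit, rule.rule_id),
                        patient_id=rec.patient_id,
                        visit=rec.visit,
                        rule_id=rule.rule_id,
                        conflict_type=rule.conflict_type,
                        items={
                            i: rec.values.get(i) for i in rule.target_items
                        },
                        detected_in_run=run_id,
                    )
                )

    visit_order = {v: k for k, v in enumerate(schema.visit_ids)}
    conflicts.sort(key=lambda c: (c.patient_id, visit_order[c.visit], c.rule_id))
    return conflicts
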