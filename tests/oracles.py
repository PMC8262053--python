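"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: double loops, no shared code with the engine beyond the
predicate evaluator's published semantics re-derived by hand where cheap.
"""

from __future__ import annotations

import datetime as dt

from ecrf_monitor import ConflictCatalog, EcrfRecord, EcrfSchema
from ecrf_monitor.conditions import evaluate_expression, is_missing


def oracle_detect(
    schema: EcrfSchema,
    catalog: ConflictCatalog,
    dataset: list[EcrfRecord],
    ref_date: dt.date,
    near_empty_threshold: int = 3,
    window_days: int = 42,
) -> list[tuple[str, str, str]]:
    """Expected (patient, visit, rule) conflict keys via exhaustive scanning."""
    conflicts: set[tuple[str, str, str]] = set()
    baseline_visit = schema.visit_ids[0]
    mandatory = set(schema.mandatory_items())

    patients = sorted({r.patient_id for r in dataset})
    by_key = {(r.patient_id, r.visit): r for r in dataset}

    entire: set[tuple[str, str]] = set()
    for pid in patients:
        base = by_key.get((pid, baseline_visit))
        if base is None or not base.submitted:
            continue
        inclusion = None
        for field in ("inclusion_date", "survey_date"):
            raw = base.values.get(field)
            if raw and not is_missing(raw):
                inclusion = dt.date.fromisoformat(str(raw))
                break
        if inclusion is None:
            inclusion = base.submission_date
        for visit in schema.visits:
            rec = by_key.get((pid, visit.visit_id))
            overdue = (
                inclusion is not None
                and inclusion
                + dt.timedelta(days=round(visit.offset_months * 30.44) + window_days)
                <= ref_date
            )
            missing_form = rec is None or not rec.submitted
            near_empty = (
                rec is not None
                and rec.submitted
                and sum(
                    1
                    for k, v in rec.values.items()
                    if k not in mandatory and not is_missing(v)
                )
                <= near_empty_threshold
            )
            if (missing_form and overdue) or near_empty:
                entire.add((pid, visit.visit_id))

    for pid, visit in entire:
        conflicts.add((pid, visit, "entire_ecrf"))

    for rec in dataset:
        if not rec.submitted or (rec.patient_id, rec.visit) in entire:
            continue
        for rule in catalog.rules:
            if rule.conflict_type == "entire_ecrf":
                continue
            if rec.visit not in rule.visits:
                continue
            if rule.arms is not None and rec.diagnosis_arm and rec.diagnosis_arm not in rule.arms:
                continue
            if evaluate_expression(rule.condition, schema, rec.values):
                conflicts.add((rec.patient_id, rec.visit, rule.rule_id))
    return sorted(conflicts)


def oracle_group_queries(conflict_keys: list[tuple[str, str, str]]) -> dict:
    """Brute-force group-by (patient, visit) of conflict keys."""
    groups: dict[tuple[str, str], list[str]] = {}
    for pid, visit, rule_id in conflict_keys:
        groups.setdefault((pid, visit), []).append(rule_id)
    return {k: sorted(v) for k, v in groups.items()}
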