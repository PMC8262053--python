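"""Query lifecycle: grouping conflicts, transfer files, answer ingestion,
and traceable corrections.

A query bundles every open conflict of one patient at one visit, so a site
answers one screen per form rather than one message per error. Its
lifecycle is ``open -> answered | partially_answered | expired`` with
``partially_answered -> answered``. Each response is either a new value
(which generates a correction and updates the dataset) or one of the
no-change options ``unknown`` / ``not_done`` / ``value_correct``, all of
which permanently resolve the conflict unless the underlying value later
changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .conditions import is_missing
from .conflict_engine import ENTIRE_ECRF_RULE_ID, Conflict
from .entry_validation import ValidationFinding, validate_field
from .records import Dataset, EcrfRecord
from .schema_catalog import ConflictCatalog, ConflictRule, EcrfSchema
from .store import MonitoringStore

#: an open query not answered within this many subsequent monitoring runs expires
DEFAULT_EXPIRY_RUNS = 2

_ENTIRE_RULE_FALLBACK = ConflictRule(
    rule_id=ENTIRE_ECRF_RULE_ID,
    conflict_type="entire_ecrf",
    visits=["*"],
    query_label="The entire eCRF is missing or nearly empty; please complete it.",
    answer_options=["new_value", "unknown", "not_done", "value_correct"],
)


@dataclass
class Query:
    """All open conflicts of one patient at one visit, as sent to the site."""

    query_id: str
    patient_id: str
    visit: str
    conflicts: list[Conflict]
    display_sections: list[str] = field(default_factory=list)
    status: str = "open"
    created_run: int = 0
    closed_run: Optional[int] = None


@dataclass(frozen=True)
class AnswerItem:
    """One site response to one conflict inside a query."""

    conflict_id: str
    response_kind: str
    new_values: dict[str, str] = field(default_factory=dict)


def _rule_for(catalog: ConflictCatalog, rule_id: str) -> ConflictRule:
    if rule_id == ENTIRE_ECRF_RULE_ID:
        for r in catalog.rules:
            if r.conflict_type == "entire_ecrf":
                return r
        return _ENTIRE_RULE_FALLBACK
    return catalog.rule(rule_id)


def display_sections_for(
    schema: EcrfSchema, catalog: ConflictCatalog, conflicts: list[Conflict]
) -> list[str]:
    """Deduplicated union of the conflicts' display sections, in schema order."""
    wanted: set[str] = set()
    for c in conflicts:
        rule = _rule_for(catalog, c.rule_id)
        if rule.display_sections:
            wanted.update(rule.display_sections)
        else:
            for item_id in rule.target_items:
                wanted.add(schema.item(item_id).section)
    order = {s: i for i, s in enumerate(schema.section_order())}
    return sorted(wanted, key=lambda s: (order.get(s, len(order)), s))


def build_queries(
    schema: EcrfSchema,
    catalog: ConflictCatalog,
    conflicts: list[Conflict],
    store: MonitoringStore,
    run_id: int = 0,
    expiry_runs: int = DEFAULT_EXPIRY_RUNS,
) -> list[Query]:
    """Group one detection run's conflicts into queries and persist them.

    Conflicts already resolved with an unchanged value are excluded; a
    patient x visit with no remaining conflict gets no query. Queries from
    earlier runs still open after *expiry_runs* further runs are expired.
    """
    store.record_conflicts(conflicts)

    pending: dict[tuple[str, str], list[Conflict]] = {}
    already_queried: set[str] = set()
    for row in store.conn.execute(
        "SELECT qc.conflict_id FROM query_conflicts qc JOIN queries q"
        " ON q.query_id = qc.query_id WHERE q.status IN ('open','partially_answered')"
    ):
        already_queried.add(row["conflict_id"])

    for c in conflicts:
        if store.is_resolved(c.conflict_id, c.items):
            continue
        if c.conflict_id in already_queried:
            continue  # still sitting in an open query from an earlier run
        pending.setdefault((c.patient_id, c.visit), []).append(c)

    queries: list[Query] = []
    for (patient_id, visit) in sorted(pending):
        group = pending[(patient_id, visit)]
        query_id = f"{patient_id}|{visit}|r{run_id}"
        sections = display_sections_for(schema, catalog, group)
        store.insert_query(
            query_id, patient_id, visit, [c.conflict_id for c in group],
            sections, run_id,
        )
        queries.append(
            Query(
                query_id=query_id,
                patient_id=patient_id,
                visit=visit,
                conflicts=group,
                display_sections=sections,
                created_run=run_id,
            )
        )

    for row in store.conn.execute(
        "SELECT query_id, created_run FROM queries WHERE status='open'"
    ).fetchall():
        if run_id - row["created_run"] >= expiry_runs:
            store.set_query_status(row["query_id"], "expired", run_id)
    return queries


# ---------------------------------------------------------------------------
# Transfer files (JSON Lines, one query per line)

def export_transfer_file(
    schema: EcrfSchema,
    catalog: ConflictCatalog,
    queries: list[Query],
    path: str | Path,
) -> None:
    """Write the query list for the online documentation system."""
    with open(path, "w") as fh:
        for q in queries:
            payload = {
                "query_id": q.query_id,
                "patient_id": q.patient_id,
                "visit": q.visit,
                "display_sections": q.display_sections,
                "conflicts": [
                    {
                        "conflict_id": c.conflict_id,
                        "rule_id": c.rule_id,
                        "conflict_type": c.conflict_type,
                        "items": {k: None if is_missing(v) else str(v)
                                  for k, v in c.items.items()},
                        "query_label": _rule_for(catalog, c.rule_id).query_label,
                        "answer_options": _rule_for(catalog, c.rule_id).answer_options,
                    }
                    for c in q.conflicts
                ],
            }
            fh.write(json.dumps(payload, sort_keys=True) + "\n")


def read_transfer_file(path: str | Path) -> list[Query]:
    queries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        payload = json.loads(line)
        conflicts = [
            Conflict(
                conflict_id=c["conflict_id"],
                patient_id=payload["patient_id"],
                visit=payload["visit"],
                rule_id=c["rule_id"],
                conflict_type=c["conflict_type"],
                items=c["items"],
            )
            for c in payload["conflicts"]
        ]
        queries.append(
            Query(
                query_id=payload["query_id"],
                patient_id=payload["patient_id"],
                visit=payload["visit"],
                conflicts=conflicts,
                display_sections=payload["display_sections"],
            )
        )
    return queries


def write_answers_file(answers: dict[str, list[AnswerItem]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for query_id in sorted(answers):
            fh.write(
                json.dumps(
                    {
                        "query_id": query_id,
                        "responses": [
                            {
                                "conflict_id": a.conflict_id,
                                "response_kind": a.response_kind,
                                "new_values": a.new_values,
                            }
                            for a in answers[query_id]
                        ],
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_answers_file(path: str | Path) -> dict[str, list[AnswerItem]]:
    answers: dict[str, list[AnswerItem]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        payload = json.loads(line)
        answers[payload["query_id"]] = [
            AnswerItem(
                conflict_id=r["conflict_id"],
                response_kind=r["response_kind"],
                new_values=r.get("new_values", {}),
            )
            for r in payload["responses"]
        ]
    return answers


# ---------------------------------------------------------------------------
# Answer ingestion

class AnswerError(ValueError):
    pass


def import_answers(
    schema: EcrfSchema,
    catalog: ConflictCatalog,
    store: MonitoringStore,
    answers: dict[str, list[AnswerItem]] | str | Path,
    run_id: int,
) -> tuple[int, list[ValidationFinding]]:
    """Ingest site responses: update query statuses, log answers and corrections.

    Returns ``(n_corrections, rejected_findings)``. A ``new_value`` failing
    entry validation is rejected with its finding and does not resolve the
    conflict; the other response kinds resolve it without a value change.
    """
    if not isinstance(answers, dict):
        answers = read_answers_file(answers)

    n_corrections = 0
    rejected: list[ValidationFinding] = []
    for query_id, items in answers.items():
        row = store.query_row(query_id)
        if row is None:
            raise AnswerError(f"unknown query_id {query_id!r}")
        member_ids = set(store.query_conflict_ids(query_id))
        patient_id, visit = row["patient_id"], row["visit"]

        for ans in items:
            if ans.conflict_id not in member_ids:
                raise AnswerError(
                    f"conflict {ans.conflict_id!r} does not belong to query {query_id!r}"
                )
            rule_id = ans.conflict_id.rsplit("|", 1)[1]
            rule = _rule_for(catalog, rule_id)
            if ans.response_kind not in rule.answer_options:
                raise AnswerError(
                    f"response {ans.response_kind!r} not allowed for rule {rule.rule_id!r}"
                )

            if ans.response_kind == "new_value":
                findings: list[ValidationFinding] = []
                for item_id, value in ans.new_values.items():
                    if rule.conflict_type != "entire_ecrf" and item_id not in rule.target_items:
                        raise AnswerError(
                            f"item {item_id!r} is not targeted by rule {rule.rule_id!r}"
                        )
                    findings.extend(validate_field(schema.item(item_id), value))
                bad = [f for f in findings if f.kind in ("bad_type", "out_of_range")]
                if bad or not ans.new_values:
                    rejected.extend(bad)
                    continue  # conflict stays unresolved; site must re-answer
                old_row = store.conn.execute(
                    "SELECT items_json FROM conflicts WHERE conflict_id=?",
                    (ans.conflict_id,),
                ).fetchone()
                old_items = json.loads(old_row["items_json"]) if old_row else {}
                for item_id, value in ans.new_values.items():
                    store.append_correction(
                        patient_id, visit, item_id, old_items.get(item_id),
                        value, "new_value", query_id, run_id,
                    )
                    n_corrections += 1
            else:
                store.append_correction(
                    patient_id, visit, "|".join(sorted(ans.new_values) or ["-"]),
                    None, None, ans.response_kind, query_id, run_id,
                )

            store.append_answer(
                query_id, ans.conflict_id, ans.response_kind,
                json.dumps(ans.new_values, sort_keys=True) if ans.new_values else None,
                run_id,
            )
            store.resolve_conflict(ans.conflict_id, ans.response_kind, run_id)

        responded = store.answered_conflict_ids(query_id)
        if member_ids <= responded:
            store.set_query_status(query_id, "answered", run_id)
        elif responded & member_ids:
            store.set_query_status(query_id, "partially_answered")
    return n_corrections, rejected


def apply_corrections(dataset: Dataset, store: MonitoringStore) -> Dataset:
    """Replay the correction log on *dataset*, in log order (last write wins).

    Only ``new_value`` markers change data; the no-change response kinds are
    present in the log purely for audit. Replaying the full log on the
    original dataset always reproduces the corrected dataset.
    """
    by_key: dict[tuple[str, str], EcrfRecord] = {}
    corrected = []
    for rec in dataset:
        clone = rec.model_copy(deep=True)
        by_key[clone.key()] = clone
        corrected.append(clone)
    for row in store.corrections():
        if row["marker"] != "new_value":
            continue
        key = (row["patient_id"], row["visit"])
        rec = by_key.get(key)
        if rec is None:
            raise KeyError(f"correction targets nonexistent record {key}")
        rec.values[row["item_id"]] = row["new_value"]
    return corrected
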