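"""Synthetic longitudinal registry data and simulated site answer behaviour.

Emulates the data-generating situation of an observational registry fed by
routine clinical care: forms arrive with missing laboratory values,
occasional out-of-range entries and date mix-ups, follow-up visits are
skipped at the physician's discretion, and a small fraction of forms is
submitted nearly empty for technical reasons. Sites answer queries with a
configurable mixture of response kinds rather than always responding.

Default rates mirror the monitoring footprint of a real two-arm
spondyloarthritis registry: ~2/3 of answered queries carry a new value,
3-month visits are the most frequently skipped, and near-empty baseline
submissions are rare (<1%). Value distributions are uniform within each
item's declared plausible range — clinical realism is not the goal, rule
coverage is.

``published_table_ledger`` builds a monitoring-store state whose per-visit counts
transcribe a published response-status table, for exercising the reporting
module against known printed values.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .conditions import parse_date as parse_date_value
from .conflict_engine import Conflict
from .query_manager import AnswerItem, Query
from .records import Dataset, EcrfRecord
from .schema_catalog import ConflictCatalog, EcrfSchema, ItemDef
from .store import MonitoringStore

_EPOCH = dt.date(2017, 5, 1)  # start of the enrolment window


class SimConfig(BaseModel):
    """Knobs of the synthetic registry; all probabilities per draw."""

    n_patients: int = 200
    arm_fraction: float = 0.52          # share of axSpA vs PsA
    item_missing_prob: float = 0.003    # per applicable non-mandatory item
    item_missing_prob_per_item: dict[str, float] = Field(
        # laboratory results and a few clinical tests are the classic gaps:
        # they are often not yet available when the form is filled in
        default_factory=lambda: {
            "crp": 0.04, "esr": 0.04, "schober_test": 0.04,
            "glucocorticoid_therapy": 0.04, "enthesitis_present": 0.04,
        }
    )
    out_of_range_prob: float = 0.002    # per filled ranged numeric item
    date_error_prob: float = 0.002      # therapy_start placed before inclusion
    missing_visit_prob: dict[str, float] = Field(
        default_factory=lambda: {"T0": 0.0, "T1": 0.17, "T2": 0.11, "T3": 0.12}
    )
    near_empty_prob: float = 0.006      # near-empty technical submissions
    answer_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "new_value": 0.50, "unknown": 0.07, "not_done": 0.05, "value_correct": 0.04,
        }
    )
    enrolment_days: int = 1100          # enrolment window length
    seed: int

    @model_validator(mode="after")
    def _probabilities(self) -> "SimConfig":
        probs = [
            self.arm_fraction, self.item_missing_prob, self.out_of_range_prob,
            self.date_error_prob, self.near_empty_prob,
            *self.missing_visit_prob.values(),
            *self.item_missing_prob_per_item.values(),
            *self.answer_probs.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if sum(self.answer_probs.values()) > 1 + 1e-9:
            raise ValueError("answer-kind probabilities must sum to <= 1")
        return self

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _plausible_value(item: ItemDef, rng: np.random.Generator) -> object:
    if item.value_kind == "numeric":
        lo = item.range_min if item.range_min is not None else 0.0
        hi = item.range_max if item.range_max is not None else 100.0
        return str(round(float(rng.uniform(lo, hi)), 1))
    if item.value_kind == "categorical":
        return str(rng.choice(item.categories))
    if item.value_kind == "boolean":
        return "true" if rng.random() < 0.5 else "false"
    if item.value_kind == "date":
        return (_EPOCH + dt.timedelta(days=int(rng.integers(0, 1000)))).isoformat()
    return f"text-{int(rng.integers(0, 10_000))}"


def out_of_range_value(item: ItemDef, rng: np.random.Generator) -> str:
    assert item.value_kind == "numeric" and item.has_range()
    hi = item.range_max if item.range_max is not None else 0.0
    return str(round(hi + float(rng.uniform(10, 10_000)), 1))


def generate_registry(schema: EcrfSchema, config: SimConfig) -> Dataset:
    """Draw a full synthetic dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    dataset: Dataset = []

    for p in range(config.n_patients):
        patient_id = f"P{p+1:05d}"
        arm = "axSpA" if rng.random() < config.arm_fraction else "PsA"
        inclusion = _EPOCH + dt.timedelta(days=int(rng.integers(0, config.enrolment_days)))
        date_error = rng.random() < config.date_error_prob

        for visit in schema.visits:
            vid = visit.visit_id
            if rng.random() < config.missing_visit_prob.get(vid, 0.0):
                continue  # visit never performed; no record submitted
            survey = inclusion + dt.timedelta(
                days=round(visit.offset_months * 30.44) + int(rng.integers(-7, 8))
            )
            if survey < inclusion:
                survey = inclusion
            near_empty = rng.random() < config.near_empty_prob

            values: dict[str, object] = {}
            filled_budget = int(rng.integers(0, 4)) if near_empty else None
            n_filled = 0
            for item in schema.items_at(vid):
                if item.item_id == "survey_date":
                    values[item.item_id] = survey.isoformat()
                    continue
                if item.mandatory:
                    values[item.item_id] = _plausible_value(item, rng)
                    continue
                if near_empty:
                    # a technically broken submission: only the mandatory
                    # fields plus at most `filled_budget` further items arrive
                    if n_filled < filled_budget:
                        values[item.item_id] = _plausible_value(item, rng)
                        n_filled += 1
                    continue
                if item.item_id == "inclusion_date":
                    values[item.item_id] = inclusion.isoformat()
                    continue
                if item.item_id == "therapy_start":
                    start = (
                        inclusion - dt.timedelta(days=int(rng.integers(1, 60)))
                        if date_error and vid == "T0"
                        else inclusion + dt.timedelta(days=int(rng.integers(0, 14)))
                    )
                    values[item.item_id] = start.isoformat()
                    continue
                p_miss = config.item_missing_prob_per_item.get(
                    item.item_id, config.item_missing_prob
                )
                if rng.random() < p_miss:
                    continue
                if (
                    item.value_kind == "numeric"
                    and item.has_range()
                    and rng.random() < config.out_of_range_prob
                ):
                    values[item.item_id] = out_of_range_value(item, rng)
                else:
                    values[item.item_id] = _plausible_value(item, rng)

            dataset.append(
                EcrfRecord(
                    patient_id=patient_id,
                    visit=vid,
                    diagnosis_arm=arm,
                    submission_status="submitted_manual",
                    submission_date=survey,
                    values=values,
                )
            )
    return dataset


def simulation_ref_date(schema: EcrfSchema, config: SimConfig) -> dt.date:
    """A reference date by which every generated visit is overdue."""
    last = max(v.offset_months for v in schema.visits)
    return _EPOCH + dt.timedelta(
        days=config.enrolment_days + round(last * 30.44) + 120
    )


def simulate_answers(
    schema: EcrfSchema,
    catalog: ConflictCatalog,
    queries: list[Query],
    config: SimConfig,
    seed_offset: int = 1,
) -> dict[str, list[AnswerItem]]:
    """Simulate site responses per the configured response-kind mixture.

    Each conflict independently receives one response kind (or none);
    unanswered conflicts are simply absent from the result. ``new_value``
    responses carry fresh in-range values; entire-eCRF conflicts are
    answered ``not_done`` instead (the site declares the visit was not
    performed), so that no response ever targets a nonexistent record.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    kinds = list(config.answer_probs)
    probs = np.array([config.answer_probs[k] for k in kinds])
    p_none = max(0.0, 1.0 - probs.sum())

    answers: dict[str, list[AnswerItem]] = {}
    for q in queries:
        items: list[AnswerItem] = []
        for c in q.conflicts:
            u = rng.random()
            acc = 0.0
            kind = None
            for k, pk in zip(kinds, probs):
                acc += pk
                if u < acc:
                    kind = k
                    break
            if kind is None:
                continue  # site never responds to this conflict
            if c.conflict_type == "entire_ecrf":
                items.append(AnswerItem(c.conflict_id, "not_done"))
                continue
            rule = catalog.rule(c.rule_id)
            if kind not in rule.answer_options:
                kind = "new_value"
            if kind == "new_value":
                if rule.conflict_type == "date" and len(rule.target_items) == 2:
                    # the site corrects the implicated date so it no longer
                    # precedes/follows its anchor (observed in the conflict)
                    anchor = parse_date_value(c.items.get(rule.target_items[1]))
                    shift = int(rng.integers(1, 60))
                    if "date_after" in rule.condition:
                        shift = -shift
                    fixed = (anchor or _EPOCH) + dt.timedelta(days=shift)
                    new_values = {rule.target_items[0]: fixed.isoformat()}
                else:
                    new_values = {
                        item_id: str(_plausible_value(schema.item(item_id), rng))
                        for item_id in rule.target_items
                    }
                items.append(AnswerItem(c.conflict_id, "new_value", new_values))
            else:
                items.append(AnswerItem(c.conflict_id, kind))
        if items:
            answers[q.query_id] = items
    return answers


# ---------------------------------------------------------------------------
# Published-counts ledger

#: per-visit counts of a published registry response-status table:
#: (submitted, entire queried, entire answered, single answered,
#:  per-eCRF single-conflict multiplicities {count: n_ecrfs})
PUBLISHED_TABLE_COUNTS: dict[str, dict] = {
    "T0": {"submitted": 1883, "entire_queried": 12, "entire_answered": 12,
           "single_answered": 1949, "single_mix": {1: 642, 3: 493, 14: 51}},
    "T1": {"submitted": 1735, "entire_queried": 296, "entire_answered": 166,
           "single_answered": 430, "single_mix": {1: 314, 2: 134, 10: 15}},
    "T2": {"submitted": 1523, "entire_queried": 170, "entire_answered": 104,
           "single_answered": 409, "single_mix": {1: 287, 2: 128, 3: 30}},
    "T3": {"submitted": 1123, "entire_queried": 133, "entire_answered": 78,
           "single_answered": 585, "single_mix": {1: 317, 2: 83, 9: 40}},
}

_LEDGER_ITEMS = ["crp", "esr", "schober_test", "glucocorticoid_therapy",
                 "enthesitis_present"]


def published_table_ledger(path: str | Path = ":memory:") -> MonitoringStore:
    """Monitoring-store state transcribing the published per-visit counts.

    The per-eCRF distribution of single conflicts is not printed in such
    tables; the multiplicity mixtures above were chosen so that the totals,
    the means and the integer-precision SDs all reproduce the published
    cells. Entirely-missing forms are stored as ``absent`` records that
    carry an entire-eCRF conflict, mirroring how a live detection run
    represents an expected-but-missing visit.
    """
    store = MonitoringStore(path)
    cur = store.conn
    for visit, counts in PUBLISHED_TABLE_COUNTS.items():
        single_mix: dict[int, int] = counts["single_mix"]
        n_single_ecrfs = sum(single_mix.values())
        n_entire = counts["entire_queried"]
        n_plain = counts["submitted"] - n_single_ecrfs - n_entire

        patient_no = 0

        def next_patient() -> str:
            nonlocal patient_no
            patient_no += 1
            return f"{visit}-P{patient_no:05d}"

        rows = []
        for _ in range(n_plain):
            rows.append((next_patient(), visit, "", "submitted_manual", None))

        conflict_rows, qc_rows, query_rows, answer_rows = [], [], [], []

        def add_query(pid: str, cids: list[str], answered_cids: list[str]) -> None:
            qid = f"{pid}|{visit}|r0"
            n_resp = len(answered_cids)
            status = ("answered" if n_resp == len(cids)
                      else "partially_answered" if n_resp else "open")
            query_rows.append((qid, pid, visit, status, "[]", 0, None))
            qc_rows.extend((qid, cid) for cid in cids)
            answer_rows.extend(
                (qid, cid, "new_value", None, 0) for cid in answered_cids
            )

        entire_left = counts["entire_answered"]
        for _ in range(n_entire):
            pid = next_patient()
            rows.append((pid, visit, "", "absent", None))
            cid = f"{pid}|{visit}|entire_ecrf"
            conflict_rows.append((cid, pid, visit, "entire_ecrf", "entire_ecrf",
                                  "{}", 0, None, None, None))
            answered = entire_left > 0
            entire_left -= 1 if answered else 0
            add_query(pid, [cid], [cid] if answered else [])

        single_left = counts["single_answered"]
        item_cycle = 0
        for count, n_ecrfs in sorted(single_mix.items()):
            for _ in range(n_ecrfs):
                pid = next_patient()
                rows.append((pid, visit, "", "submitted_manual", None))
                cids = []
                for j in range(count):
                    item = _LEDGER_ITEMS[item_cycle % len(_LEDGER_ITEMS)]
                    item_cycle += 1
                    rid = f"missing_{item}_{j}"
                    cid = f"{pid}|{visit}|{rid}"
                    cids.append(cid)
                    conflict_rows.append(
                        (cid, pid, visit, rid, "missing",
                         json.dumps({item: None}), 0, None, None, None)
                    )
                n_ans = min(count, single_left)
                single_left -= n_ans
                add_query(pid, cids, cids[:n_ans])

        cur.executemany("INSERT INTO records VALUES (?,?,?,?,?)", rows)
        cur.executemany(
            "INSERT INTO conflicts VALUES (?,?,?,?,?,?,?,?,?,?)", conflict_rows
        )
        cur.executemany("INSERT INTO queries VALUES (?,?,?,?,?,?,?)", query_rows)
        cur.executemany("INSERT INTO query_conflicts VALUES (?,?)", qc_rows)
        cur.executemany(
            "INSERT INTO answers (query_id, conflict_id, response_kind, new_value,"
            " run_id) VALUES (?,?,?,?,?)",
            answer_rows,
        )
    store.conn.commit()
    return store
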