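import datetime as dt

import numpy as np
import pytest

from ecrf_monitor import (
    ConflictCatalog,
    ConflictRule,
    EcrfRecord,
    EcrfSchema,
    ItemDef,
    Visit,
)
from ecrf_monitor.demo import build_demo_catalog, build_demo_schema

REF_DATE = dt.date(2022, 1, 1)


@pytest.fixture(scope="session")
def demo_schema():
    return build_demo_schema()


@pytest.fixture(scope="session")
def demo_catalog(demo_schema):
    return build_demo_catalog(demo_schema)


@pytest.fixture(scope="session")
def tiny_schema():
    """A four-visit schema small enough for brute-force checking."""
    all_v = ["T0", "T1", "T2", "T3"]
    return EcrfSchema(
        name="tiny",
        visits=[
            Visit(visit_id="T0", offset_months=0),
            Visit(visit_id="T1", offset_months=3),
            Visit(visit_id="T2", offset_months=6),
            Visit(visit_id="T3", offset_months=12),
        ],
        items=[
            ItemDef(item_id="survey_date", value_kind="date", mandatory=True,
                    visits=all_v, section="administrative"),
            ItemDef(item_id="inclusion_date", value_kind="date", visits=all_v,
                    section="administrative"),
            ItemDef(item_id="therapy_start", value_kind="date", visits=all_v,
                    section="treatment"),
            ItemDef(item_id="crp", value_kind="numeric", unit="mg/L",
                    range_min=0, range_max=400, visits=all_v, section="laboratory"),
            ItemDef(item_id="esr", value_kind="numeric", unit="mm/h",
                    range_min=0, range_max=150, visits=all_v, section="laboratory"),
            ItemDef(item_id="schober_test", value_kind="numeric", unit="cm",
                    range_min=0, range_max=15, visits=["T0", "T3"], section="clinical"),
            ItemDef(item_id="enthesitis_present", value_kind="boolean",
                    visits=all_v, section="clinical"),
            ItemDef(item_id="gender", value_kind="categorical",
                    categories=["female", "male"], mandatory=True, visits=all_v,
                    section="administrative"),
        ],
    )


@pytest.fixture(scope="session")
def tiny_catalog(tiny_schema):
    all_v = ["T0", "T1", "T2", "T3"]
    rules = [
        ConflictRule(rule_id="entire_ecrf", conflict_type="entire_ecrf",
                     visits=all_v, query_label="eCRF missing",
                     display_sections=["administrative"]),
        ConflictRule(rule_id="missing_crp", conflict_type="missing", visits=all_v,
                     target_items=["crp"], condition="missing(crp)",
                     query_label="CRP missing"),
        ConflictRule(rule_id="missing_esr", conflict_type="missing", visits=all_v,
                     target_items=["esr"], condition="missing(esr)",
                     query_label="ESR missing"),
        ConflictRule(rule_id="missing_schober", conflict_type="missing",
                     visits=["T0", "T3"], target_items=["schober_test"],
                     condition="missing(schober_test)", query_label="Schober missing"),
        ConflictRule(rule_id="missing_enthesitis", conflict_type="missing",
                     visits=all_v, target_items=["enthesitis_present"],
                     condition="missing(enthesitis_present)",
                     query_label="Enthesitis missing"),
        ConflictRule(rule_id="range_crp", conflict_type="range", visits=all_v,
                     target_items=["crp"], condition="out_of_range(crp)",
                     query_label="CRP out of range"),
        ConflictRule(rule_id="range_esr", conflict_type="range", visits=all_v,
                     target_items=["esr"], condition="out_of_range(esr)",
                     query_label="ESR out of range"),
        ConflictRule(rule_id="date_therapy", conflict_type="date", visits=all_v,
                     target_items=["therapy_start", "inclusion_date"],
                     condition="date_before(therapy_start, inclusion_date)",
                     query_label="Therapy start before inclusion"),
    ]
    catalog = ConflictCatalog(version="tiny-1", schema_ref="tiny", rules=rules)
    catalog.validate_against(tiny_schema)
    return catalog


def random_tiny_dataset(schema: EcrfSchema, rng: np.random.Generator,
                        max_patients: int = 5) -> list[EcrfRecord]:
    """A small random dataset exercising every conflict pathway."""
    inclusion = dt.date(2020, 1, 1)
    dataset = []
    n_patients = int(rng.integers(1, max_patients + 1))
    for p in range(n_patients):
        pid = f"P{p:03d}"
        for vi, visit in enumerate(schema.visits):
            if vi > 0 and rng.random() < 0.25:
                continue  # skipped visit
            values = {
                "survey_date": (
                    inclusion + dt.timedelta(days=round(visit.offset_months * 30))
                ).isoformat(),
                "gender": "female" if rng.random() < 0.5 else "male",
            }
            if rng.random() < 0.9:
                values["inclusion_date"] = inclusion.isoformat()
            if rng.random() < 0.85:
                offset = int(rng.integers(-30, 30))
                values["therapy_start"] = (
                    inclusion + dt.timedelta(days=offset)
                ).isoformat()
            near_empty = rng.random() < 0.15
            if not near_empty:
                for item_id, hi in (("crp", 400), ("esr", 150)):
                    r = rng.random()
                    if r < 0.25:
                        continue  # missing
                    if r < 0.35:
                        values[item_id] = str(hi + float(rng.integers(1, 5000)))
                    else:
                        values[item_id] = str(round(float(rng.uniform(0, hi)), 1))
                if visit.visit_id in ("T0", "T3") and rng.random() < 0.7:
                    values["schober_test"] = str(round(float(rng.uniform(0, 15)), 1))
                if rng.random() < 0.7:
                    values["enthesitis_present"] = (
                        "true" if rng.random() < 0.5 else "false"
                    )
            dataset.append(
                EcrfRecord(
                    patient_id=pid,
                    visit=visit.visit_id,
                    diagnosis_arm="axSpA" if rng.random() < 0.5 else "PsA",
                    submission_status="submitted_manual",
                    submission_date=inclusion,
                    values=values,
                )
            )
    return dataset
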