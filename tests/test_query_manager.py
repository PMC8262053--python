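import datetime as dt

import numpy as np
import pytest

from ecrf_monitor import (
    AnswerItem,
    MonitoringStore,
    apply_corrections,
    build_queries,
    detect_conflicts,
    export_transfer_file,
    import_answers,
    read_answers_file,
    read_transfer_file,
    write_answers_file,
)
from ecrf_monitor.query_manager import AnswerError

from conftest import REF_DATE, random_tiny_dataset
from oracles import oracle_detect, oracle_group_queries


@pytest.fixture()
def pipeline(tiny_schema, tiny_catalog):
    """Fresh store + a seeded random dataset with its first detection run."""
    rng = np.random.default_rng(17)
    dataset = random_tiny_dataset(tiny_schema, rng, max_patients=6)
    store = MonitoringStore()
    store.upsert_records(dataset)
    conflicts = detect_conflicts(tiny_schema, tiny_catalog, dataset, REF_DATE, run_id=1)
    return tiny_schema, tiny_catalog, dataset, store, conflicts


def test_one_query_per_conflicted_patient_visit(pipeline):
    schema, catalog, dataset, store, conflicts = pipeline
    queries = build_queries(schema, catalog, conflicts, store, run_id=1)
    assert len(queries) == len({(c.patient_id, c.visit) for c in conflicts})
    for q in queries:
        assert len(q.conflicts) >= 1
        assert {(c.patient_id, c.visit) for c in q.conflicts} == {
            (q.patient_id, q.visit)
        }


def test_grouping_matches_brute_force_group_by(tiny_schema, tiny_catalog):
    rng = np.random.default_rng(23)
    for _ in range(20):
        dataset = random_tiny_dataset(tiny_schema, rng)
        store = MonitoringStore()
        conflicts = detect_conflicts(tiny_schema, tiny_catalog, dataset, REF_DATE)
        queries = build_queries(tiny_schema, tiny_catalog, conflicts, store)
        got = {
            (q.patient_id, q.visit): sorted(c.rule_id for c in q.conflicts)
            for q in queries
        }
        expected = oracle_group_queries(
            oracle_detect(tiny_schema, tiny_catalog, dataset, REF_DATE)
        )
        assert got == expected


def test_no_conflicts_no_queries(tiny_schema, tiny_catalog):
    assert build_queries(tiny_schema, tiny_catalog, [], MonitoringStore()) == []


def test_display_sections_deduplicated_in_schema_order(pipeline):
    schema, catalog, dataset, store, conflicts = pipeline
    queries = build_queries(schema, catalog, conflicts, store, run_id=1)
    order = {s: i for i, s in enumerate(schema.section_order())}
    for q in queries:
        assert len(set(q.display_sections)) == len(q.display_sections)
        assert q.display_sections == sorted(
            q.display_sections, key=lambda s: order[s]
        )
        expected = set()
        for c in q.conflicts:
            if c.rule_id == "entire_ecrf":
                expected.add("administrative")
            else:
                for item_id in catalog.rule(c.rule_id).target_items:
                    expected.add(schema.item(item_id).section)
        assert set(q.display_sections) == expected


def test_transfer_file_round_trip(pipeline, tmp_path):
    schema, catalog, dataset, store, conflicts = pipeline
    queries = build_queries(schema, catalog, conflicts, store, run_id=1)
    path = tmp_path / "transfer.jsonl"
    export_transfer_file(schema, catalog, queries, path)
    reloaded = read_transfer_file(path)
    assert [q.query_id for q in reloaded] == [q.query_id for q in queries]
    for a, b in zip(queries, reloaded):
        assert [c.conflict_id for c in a.conflicts] == [
            c.conflict_id for c in b.conflicts
        ]
        assert a.display_sections == b.display_sections


def test_answers_file_round_trip(tmp_path):
    answers = {
        "P1|T0|r1": [
            AnswerItem("P1|T0|missing_crp", "new_value", {"crp": "12"}),
            AnswerItem("P1|T0|missing_esr", "unknown"),
        ]
    }
    path = tmp_path / "answers.jsonl"
    write_answers_file(answers, path)
    assert read_answers_file(path) == answers


_VALID_VALUES = {
    "enthesitis_present": "true",
    "therapy_start": "2020-06-01",
    "inclusion_date": "2020-01-01",
}


def answer_all(queries):
    out = {}
    for q in queries:
        items = []
        for c in q.conflicts:
            if c.conflict_type == "entire_ecrf":
                items.append(AnswerItem(c.conflict_id, "not_done"))
            elif c.conflict_type == "date":
                items.append(AnswerItem(c.conflict_id, "value_correct"))
            else:
                items.append(
                    AnswerItem(
                        c.conflict_id, "new_value",
                        {i: _VALID_VALUES.get(i, "12.0") for i in c.items},
                    )
                )
        out[q.query_id] = items
    return out


class TestImportAnswers:
    def test_full_response_answers_query(self, pipeline):
        schema, catalog, dataset, store, conflicts = pipeline
        queries = build_queries(schema, catalog, conflicts, store, run_id=1)
        n_corr, rejected = import_answers(
            schema, catalog, store, answer_all(queries), run_id=1
        )
        assert rejected == []
        assert n_corr > 0
        for q in queries:
            assert store.query_row(q.query_id)["status"] == "answered"

    def test_partial_response_marks_partially_answered(self, pipeline):
        schema, catalog, dataset, store, conflicts = pipeline
        queries = build_queries(schema, catalog, conflicts, store, run_id=1)
        target = next(q for q in queries if len(q.conflicts) >= 2)
        one = answer_all([target])
        one[target.query_id] = one[target.query_id][:1]
        import_answers(schema, catalog, store, one, run_id=1)
        assert store.query_row(target.query_id)["status"] == "partially_answered"

    def test_partially_answered_can_reach_answered(self, pipeline):
        schema, catalog, dataset, store, conflicts = pipeline
        queries = build_queries(schema, catalog, conflicts, store, run_id=1)
        target = next(q for q in queries if len(q.conflicts) >= 2)
        full = answer_all([target])[target.query_id]
        import_answers(schema, catalog, store, {target.query_id: full[:1]}, run_id=1)
        import_answers(schema, catalog, store, {target.query_id: full[1:]}, run_id=2)
        assert store.query_row(target.query_id)["status"] == "answered"

    def test_unknown_query_id_rejected(self, pipeline):
        schema, catalog, dataset, store, conflicts = pipeline
        with pytest.raises(AnswerError, match="unknown query_id"):
            import_answers(
                schema, catalog, store,
                {"nope": [AnswerItem("x|T0|missing_crp", "unknown")]}, run_id=1,
            )

    def test_invalid_new_value_rejected_not_stored(self, pipeline):
        schema, catalog, dataset, store, conflicts = pipeline
        queries = build_queries(schema, catalog, conflicts, store, run_id=1)
        target = next(
            (q, c) for q in queries for c in q.conflicts
            if c.rule_id == "missing_crp"
        )
        q, c = target
        n_corr, rejected = import_answers(
            schema, catalog, store,
            {q.query_id: [AnswerItem(c.conflict_id, "new_value", {"crp": "goo"})]},
            run_id=1,
        )
        assert n_corr == 0
        assert [f.kind for f in rejected] == ["bad_type"]
        assert store.query_row(q.query_id)["status"] == "open"
        corrected = apply_corrections(dataset, store)
        assert corrected == dataset

    def test_confirmed_conflict_not_requeried(self, pipeline):
        schema, catalog, dataset, store, conflicts = pipeline
        queries = build_queries(schema, catalog, conflicts, store, run_id=1)
        q = queries[0]
        c = q.conflicts[0]
        kind = "not_done" if c.conflict_type == "entire_ecrf" else "value_correct"
        import_answers(
            schema, catalog, store, {q.query_id: [AnswerItem(c.conflict_id, kind)]},
            run_id=1,
        )
        corrected = apply_corrections(dataset, store)
        conflicts2 = detect_conflicts(schema, catalog, corrected, REF_DATE, run_id=2)
        queries2 = build_queries(schema, catalog, conflicts2, store, run_id=2)
        requeried = {
            cc.conflict_id for qq in queries2 for cc in qq.conflicts
        }
        assert c.conflict_id not in requeried


class TestCorrections:
    def test_empty_log_is_identity(self, tiny_schema, tiny_catalog):
        rng = np.random.default_rng(31)
        dataset = random_tiny_dataset(tiny_schema, rng)
        assert apply_corrections(dataset, MonitoringStore()) == dataset

    def test_single_correction_changes_only_that_cell(self, pipeline):
        schema, catalog, dataset, store, conflicts = pipeline
        queries = build_queries(schema, catalog, conflicts, store, run_id=1)
        q, c = next(
            (q, c) for q in queries for c in q.conflicts
            if c.rule_id == "missing_crp"
        )
        import_answers(
            schema, catalog, store,
            {q.query_id: [AnswerItem(c.conflict_id, "new_value", {"crp": "12"})]},
            run_id=1,
        )
        corrected = apply_corrections(dataset, store)
        diffs = [
            (a.patient_id, a.visit, k)
            for a, b in zip(dataset, corrected)
            for k in set(a.values) | set(b.values)
            if a.values.get(k) != b.values.get(k)
        ]
        assert diffs == [(q.patient_id, q.visit, "crp")]
        assert dataset == apply_corrections(dataset, MonitoringStore())  # untouched

    def test_last_write_wins_with_full_audit_trail(self, pipeline):
        schema, catalog, dataset, store, conflicts = pipeline
        queries = build_queries(schema, catalog, conflicts, store, run_id=1)
        q, c = next(
            (q, c) for q in queries for c in q.conflicts
            if c.rule_id == "missing_crp"
        )
        store.append_correction(q.patient_id, q.visit, "crp", None, "11", "new_value",
                                q.query_id, 1)
        store.append_correction(q.patient_id, q.visit, "crp", "11", "22", "new_value",
                                q.query_id, 2)
        corrected = apply_corrections(dataset, store)
        rec = next(r for r in corrected if r.key() == (q.patient_id, q.visit))
        assert rec.values["crp"] == "22"
        assert [r["new_value"] for r in store.corrections()] == ["11", "22"]

    def test_correction_to_unknown_record_raises(self, pipeline):
        schema, catalog, dataset, store, conflicts = pipeline
        store.append_correction("GHOST", "T0", "crp", None, "1", "new_value", "q", 1)
        with pytest.raises(KeyError):
            apply_corrections(dataset, store)


def test_status_conservation_and_expiry(pipeline):
    schema, catalog, dataset, store, conflicts = pipeline
    queries = build_queries(schema, catalog, conflicts, store, run_id=1)
    half = queries[: len(queries) // 2]
    import_answers(schema, catalog, store, answer_all(half), run_id=1)
    # two further runs with no new conflicts age out the unanswered queries
    build_queries(schema, catalog, [], store, run_id=2)
    build_queries(schema, catalog, [], store, run_id=3)
    rows = store.conn.execute(
        "SELECT status, COUNT(*) AS n FROM queries GROUP BY status"
    ).fetchall()
    by_status = {r["status"]: r["n"] for r in rows}
    assert sum(by_status.values()) == len(queries)
    assert by_status.get("answered", 0) == len(half)
    assert by_status.get("expired", 0) == len(queries) - len(half)


def test_convergence_within_two_cycles(tiny_schema, tiny_catalog):
    """detect -> answer-all-valid -> apply -> re-detect reaches zero newly
    queriable single conflicts in at most two iterations."""
    rng = np.random.default_rng(99)
    dataset = random_tiny_dataset(tiny_schema, rng, max_patients=8)
    store = MonitoringStore()
    store.upsert_records(dataset)
    for iteration in (1, 2):
        conflicts = detect_conflicts(
            tiny_schema, tiny_catalog, dataset, REF_DATE, run_id=iteration
        )
        queries = build_queries(
            tiny_schema, tiny_catalog, conflicts, store, run_id=iteration,
            expiry_runs=10,
        )
        import_answers(tiny_schema, tiny_catalog, store, answer_all(queries),
                       run_id=iteration)
        dataset = apply_corrections(dataset, store)
    conflicts = detect_conflicts(tiny_schema, tiny_catalog, dataset, REF_DATE, run_id=3)
    queries = build_queries(tiny_schema, tiny_catalog, conflicts, store, run_id=3,
                            expiry_runs=10)
    open_single = [
        c for q in queries for c in q.conflicts if c.conflict_type != "entire_ecrf"
    ]
    assert open_single == []
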