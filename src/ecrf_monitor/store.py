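"""The monitoring store: an embedded SQLite database of records, conflicts,
queries, answers and corrections.

Answers and corrections are append-only; every change ever made to the
clinical dataset maps to exactly one correction row, which is what makes
the monitoring process auditable. A single file (or ``:memory:``) holds
the complete state of the monitoring cycle between runs.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path
from typing import Any, Iterable, Optional

from .conflict_engine import Conflict
from .records import EcrfRecord

_SCHEMA_SQL = """
CREATE TABLE IF NOT EXISTS records (
    patient_id TEXT NOT NULL,
    visit TEXT NOT NULL,
    diagnosis_arm TEXT,
    submission_status TEXT NOT NULL,
    submission_date TEXT,
    PRIMARY KEY (patient_id, visit)
);
CREATE TABLE IF NOT EXISTS conflicts (
    conflict_id TEXT PRIMARY KEY,
    patient_id TEXT NOT NULL,
    visit TEXT NOT NULL,
    rule_id TEXT NOT NULL,
    conflict_type TEXT NOT NULL,
    items_json TEXT NOT NULL DEFAULT '{}',
    detected_in_run INTEGER NOT NULL,
    resolved_in_run INTEGER,
    resolution_kind TEXT,
    resolved_items_json TEXT
);
CREATE TABLE IF NOT EXISTS queries (
    query_id TEXT PRIMARY KEY,
    patient_id TEXT NOT NULL,
    visit TEXT NOT NULL,
    status TEXT NOT NULL DEFAULT 'open',
    display_sections_json TEXT NOT NULL DEFAULT '[]',
    created_run INTEGER NOT NULL,
    closed_run INTEGER
);
CREATE TABLE IF NOT EXISTS query_conflicts (
    query_id TEXT NOT NULL,
    conflict_id TEXT NOT NULL,
    PRIMARY KEY (query_id, conflict_id)
);
CREATE TABLE IF NOT EXISTS answers (
    answer_seq INTEGER PRIMARY KEY AUTOINCREMENT,
    query_id TEXT NOT NULL,
    conflict_id TEXT NOT NULL,
    response_kind TEXT NOT NULL,
    new_value TEXT,
    run_id INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS corrections (
    correction_seq INTEGER PRIMARY KEY AUTOINCREMENT,
    patient_id TEXT NOT NULL,
    visit TEXT NOT NULL,
    item_id TEXT NOT NULL,
    old_value TEXT,
    new_value TEXT,
    marker TEXT NOT NULL,
    query_id TEXT NOT NULL,
    run_id INTEGER NOT NULL
);
"""

QUERY_STATUSES = ("open", "answered", "partially_answered", "expired")


class MonitoringStore:
    """Persistent state of the monitoring cycle."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        self.conn.executescript(_SCHEMA_SQL)

    def close(self) -> None:
        self.conn.close()

    # -- records ----------------------------------------------------------
    def upsert_records(self, dataset: Iterable[EcrfRecord]) -> None:
        rows = [
            (
                r.patient_id,
                r.visit,
                r.diagnosis_arm,
                r.submission_status,
                r.submission_date.isoformat() if r.submission_date else None,
            )
            for r in dataset
        ]
        self.conn.executemany(
            "INSERT OR REPLACE INTO records VALUES (?,?,?,?,?)", rows
        )
        self.conn.commit()

    # -- conflicts --------------------------------------------------------
    def record_conflicts(self, conflicts: Iterable[Conflict]) -> None:
        """Insert newly detected conflicts, preserving prior resolutions.

        A re-detected conflict whose observed values changed since it was
        resolved loses its resolution (the site must be asked again); an
        unchanged resolved conflict keeps it.
        """
        cur = self.conn
        for c in conflicts:
            items_json = json.dumps(c.items, default=str, sort_keys=True)
            row = cur.execute(
                "SELECT resolution_kind, resolved_items_json FROM conflicts "
                "WHERE conflict_id=?",
                (c.conflict_id,),
            ).fetchone()
            if row is None:
                cur.execute(
                    "INSERT INTO conflicts (conflict_id, patient_id, visit, rule_id,"
                    " conflict_type, items_json, detected_in_run) VALUES (?,?,?,?,?,?,?)",
                    (
                        c.conflict_id, c.patient_id, c.visit, c.rule_id,
                        c.conflict_type, items_json, c.detected_in_run,
                    ),
                )
            elif row["resolution_kind"] and row["resolved_items_json"] != items_json:
                cur.execute(
                    "UPDATE conflicts SET items_json=?, detected_in_run=?,"
                    " resolved_in_run=NULL, resolution_kind=NULL,"
                    " resolved_items_json=NULL WHERE conflict_id=?",
                    (items_json, c.detected_in_run, c.conflict_id),
                )
            else:
                cur.execute(
                    "UPDATE conflicts SET items_json=? WHERE conflict_id=?",
                    (items_json, c.conflict_id),
                )
        self.conn.commit()

    def is_resolved(self, conflict_id: str, items: dict[str, Any]) -> bool:
        row = self.conn.execute(
            "SELECT resolution_kind, resolved_items_json FROM conflicts"
            " WHERE conflict_id=?",
            (conflict_id,),
        ).fetchone()
        if row is None or not row["resolution_kind"]:
            return False
        return row["resolved_items_json"] == json.dumps(items, default=str, sort_keys=True)

    def resolve_conflict(self, conflict_id: str, kind: str, run_id: int) -> None:
        self.conn.execute(
            "UPDATE conflicts SET resolved_in_run=?, resolution_kind=?,"
            " resolved_items_json=items_json WHERE conflict_id=?",
            (run_id, kind, conflict_id),
        )
        self.conn.commit()

    # -- queries ----------------------------------------------------------
    def insert_query(
        self,
        query_id: str,
        patient_id: str,
        visit: str,
        conflict_ids: list[str],
        display_sections: list[str],
        created_run: int,
    ) -> None:
        self.conn.execute(
            "INSERT INTO queries (query_id, patient_id, visit, status,"
            " display_sections_json, created_run) VALUES (?,?,?,'open',?,?)",
            (query_id, patient_id, visit, json.dumps(display_sections), created_run),
        )
        self.conn.executemany(
            "INSERT INTO query_conflicts VALUES (?,?)",
            [(query_id, cid) for cid in conflict_ids],
        )
        self.conn.commit()

    def set_query_status(self, query_id: str, status: str, run_id: Optional[int] = None) -> None:
        if status not in QUERY_STATUSES:
            raise ValueError(f"unknown query status {status!r}")
        closed = run_id if status in ("answered", "expired") else None
        self.conn.execute(
            "UPDATE queries SET status=?, closed_run=COALESCE(?, closed_run)"
            " WHERE query_id=?",
            (status, closed, query_id),
        )
        self.conn.commit()

    def query_row(self, query_id: str) -> Optional[sqlite3.Row]:
        return self.conn.execute(
            "SELECT * FROM queries WHERE query_id=?", (query_id,)
        ).fetchone()

    def query_conflict_ids(self, query_id: str) -> list[str]:
        return [
            r["conflict_id"]
            for r in self.conn.execute(
                "SELECT conflict_id FROM query_conflicts WHERE query_id=?"
                " ORDER BY conflict_id",
                (query_id,),
            )
        ]

    def open_queries(self) -> list[sqlite3.Row]:
        return self.conn.execute(
            "SELECT * FROM queries WHERE status IN ('open','partially_answered')"
            " ORDER BY query_id"
        ).fetchall()

    # -- answers / corrections -------------------------------------------
    def append_answer(
        self, query_id: str, conflict_id: str, response_kind: str,
        new_value: Optional[str], run_id: int,
    ) -> None:
        self.conn.execute(
            "INSERT INTO answers (query_id, conflict_id, response_kind, new_value,"
            " run_id) VALUES (?,?,?,?,?)",
            (query_id, conflict_id, response_kind, new_value, run_id),
        )
        self.conn.commit()

    def append_correction(
        self, patient_id: str, visit: str, item_id: str, old_value, new_value,
        marker: str, query_id: str, run_id: int,
    ) -> None:
        self.conn.execute(
            "INSERT INTO corrections (patient_id, visit, item_id, old_value,"
            " new_value, marker, query_id, run_id) VALUES (?,?,?,?,?,?,?,?)",
            (
                patient_id, visit, item_id,
                None if old_value is None else str(old_value),
                None if new_value is None else str(new_value),
                marker, query_id, run_id,
            ),
        )
        self.conn.commit()

    def corrections(self) -> list[sqlite3.Row]:
        return self.conn.execute(
            "SELECT * FROM corrections ORDER BY correction_seq"
        ).fetchall()

    def answered_conflict_ids(self, query_id: str) -> set[str]:
        return {
            r["conflict_id"]
            for r in self.conn.execute(
                "SELECT DISTINCT conflict_id FROM answers WHERE query_id=?",
                (query_id,),
            )
        }

    # -- convenience ------------------------------------------------------
    def frame(self, table: str):
        import pandas as pd

        return pd.read_sql_query(f"SELECT * FROM {table}", self.conn)  # noqa: S608
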