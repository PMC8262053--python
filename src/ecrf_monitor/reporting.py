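"""Per-visit descriptive quality reporting.

Produces, for each scheduled visit, the standard monitoring summary of a
longitudinal registry: how many eCRFs came in, how many had conflicts,
how the entire-eCRF and single-conflict queries were answered, and the
mean number of single conflicts per affected form. Percentages are printed
to the nearest integer and means to one decimal, both rounding halves away
from zero; standard deviations are printed at integer precision.

The per-visit eCRF universe is every patient x visit slot that was either
submitted or queried as an entirely missing form, so that
``without conflicts + with conflicts = N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd

from .store import MonitoringStore


def round_report(x: float, mode: str = "percent") -> float:
    """Round for display, halves away from zero (0.5 -> 1, 2.35 -> 2.4).

    ``percent``: a ratio, returned as a whole-number percentage;
    ``int``: nearest integer; ``mean1dp``: nearest tenth.
    """
    if not math.isfinite(x):
        raise ValueError(f"non-finite input {x!r}")
    sign = 1 if x >= 0 else -1
    if mode == "percent":
        return float(sign * math.floor(abs(x) * 100 + 0.5))
    if mode == "int":
        return float(sign * math.floor(abs(x) + 0.5))
    if mode == "mean1dp":
        return sign * math.floor(abs(x) * 10 + 0.5) / 10
    raise ValueError(f"unknown rounding mode {mode!r}")


def _pct(numer: int, denom: int) -> int:
    return int(round_report(numer / denom, "percent")) if denom else 0


@dataclass
class VisitSummary:
    """One column of the per-visit response-status table."""

    visit: str
    n_submitted: int = 0
    n_without_conflicts: int = 0
    n_with_conflicts: int = 0
    pct_with_conflicts: int = 0
    pct_without_conflicts: int = 0
    n_entire_queried: int = 0
    n_entire_answered: int = 0
    pct_entire_answered: int = 0
    n_entire_unanswered: int = 0
    pct_entire_unanswered: int = 0
    n_ecrfs_with_single: int = 0
    n_single_queried: int = 0
    mean_single_per_ecrf: float = 0.0
    sd_single_per_ecrf: int = 0
    n_single_answered: int = 0
    pct_single_answered: int = 0
    n_single_unanswered: int = 0
    pct_single_unanswered: int = 0
    empty: bool = False

    def check(self) -> "VisitSummary":
        assert self.n_without_conflicts + self.n_with_conflicts == self.n_submitted
        assert self.n_entire_answered + self.n_entire_unanswered == self.n_entire_queried
        assert self.n_single_answered + self.n_single_unanswered == self.n_single_queried
        return self


@dataclass(frozen=True)
class ItemConflictRank:
    item_id: str
    n_conflicts: int
    rank: int


def _visit_tables(store: MonitoringStore, visit: str):
    conflicts = pd.read_sql_query(
        "SELECT c.*, qc.query_id FROM conflicts c"
        " LEFT JOIN query_conflicts qc ON qc.conflict_id = c.conflict_id"
        " WHERE c.visit = ?",
        store.conn,
        params=(visit,),
    )
    records = pd.read_sql_query(
        "SELECT * FROM records WHERE visit = ?", store.conn, params=(visit,)
    )
    answered = {
        r["conflict_id"]
        for r in store.conn.execute(
            "SELECT DISTINCT a.conflict_id FROM answers a JOIN conflicts c"
            " ON c.conflict_id = a.conflict_id WHERE c.visit = ?",
            (visit,),
        )
    }
    return records, conflicts, answered


def summarize_visit(store: MonitoringStore, visit: str) -> VisitSummary:
    """Compute the full response-status summary for one visit from the store."""
    records, conflicts, answered = _visit_tables(store, visit)
    queried = conflicts[conflicts["query_id"].notna()]

    submitted_slots = set(
        records.loc[records["submission_status"] != "absent", "patient_id"]
    )
    conflict_slots = set(queried["patient_id"])
    universe = submitted_slots | conflict_slots
    if not universe:
        return VisitSummary(visit=visit, empty=True).check()

    entire = queried[queried["conflict_type"] == "entire_ecrf"]
    single = queried[queried["conflict_type"] != "entire_ecrf"]

    n_submitted = len(universe)
    n_with = len(conflict_slots)
    n_without = n_submitted - n_with

    n_entire = len(entire)
    n_entire_ans = int(entire["conflict_id"].isin(answered).sum())
    n_single = len(single)
    n_single_ans = int(single["conflict_id"].isin(answered).sum())

    per_ecrf = single.groupby("patient_id").size() if n_single else pd.Series(dtype=int)
    n_ecrfs_single = len(per_ecrf)
    mean = n_single / n_ecrfs_single if n_ecrfs_single else 0.0
    sd = float(per_ecrf.std(ddof=1)) if n_ecrfs_single > 1 else 0.0

    return VisitSummary(
        visit=visit,
        n_submitted=n_submitted,
        n_without_conflicts=n_without,
        n_with_conflicts=n_with,
        pct_with_conflicts=_pct(n_with, n_submitted),
        pct_without_conflicts=_pct(n_without, n_submitted),
        n_entire_queried=n_entire,
        n_entire_answered=n_entire_ans,
        pct_entire_answered=_pct(n_entire_ans, n_entire),
        n_entire_unanswered=n_entire - n_entire_ans,
        pct_entire_unanswered=_pct(n_entire - n_entire_ans, n_entire),
        n_ecrfs_with_single=n_ecrfs_single,
        n_single_queried=n_single,
        mean_single_per_ecrf=round_report(mean, "mean1dp"),
        sd_single_per_ecrf=int(round_report(sd, "int")),
        n_single_answered=n_single_ans,
        pct_single_answered=_pct(n_single_ans, n_single),
        n_single_unanswered=n_single - n_single_ans,
        pct_single_unanswered=_pct(n_single - n_single_ans, n_single),
    ).check()


@dataclass
class MonitoringReport:
    visits: list[VisitSummary]
    totals: VisitSummary
    pct_with_conflicts_range: tuple[int, int]


def summarize_all(store: MonitoringStore, visit_order: Optional[list[str]] = None) -> MonitoringReport:
    """Summaries for every visit in the store plus a totals row.

    The totals row sums the raw counts across visits; its percentages are
    recomputed from the summed numerators and denominators, and the
    with-conflict percentage range (min-max across visits) is reported
    alongside.
    """
    if visit_order is None:
        visit_order = [
            r["visit"]
            for r in store.conn.execute(
                "SELECT DISTINCT visit FROM records ORDER BY visit"
            )
        ]
    summaries = [summarize_visit(store, v) for v in visit_order]
    non_empty = [s for s in summaries if not s.empty]
    if not non_empty:
        raise ValueError("no visit with any eCRF to summarize")

    tot = VisitSummary(visit="total")
    for s in non_empty:
        tot.n_submitted += s.n_submitted
        tot.n_without_conflicts += s.n_without_conflicts
        tot.n_with_conflicts += s.n_with_conflicts
        tot.n_entire_queried += s.n_entire_queried
        tot.n_entire_answered += s.n_entire_answered
        tot.n_entire_unanswered += s.n_entire_unanswered
        tot.n_ecrfs_with_single += s.n_ecrfs_with_single
        tot.n_single_queried += s.n_single_queried
        tot.n_single_answered += s.n_single_answered
        tot.n_single_unanswered += s.n_single_unanswered
    tot.pct_with_conflicts = _pct(tot.n_with_conflicts, tot.n_submitted)
    tot.pct_without_conflicts = _pct(tot.n_without_conflicts, tot.n_submitted)
    tot.pct_entire_answered = _pct(tot.n_entire_answered, tot.n_entire_queried)
    tot.pct_entire_unanswered = _pct(tot.n_entire_unanswered, tot.n_entire_queried)
    tot.pct_single_answered = _pct(tot.n_single_answered, tot.n_single_queried)
    tot.pct_single_unanswered = _pct(tot.n_single_unanswered, tot.n_single_queried)
    if tot.n_ecrfs_with_single:
        tot.mean_single_per_ecrf = round_report(
            tot.n_single_queried / tot.n_ecrfs_with_single, "mean1dp"
        )
        pooled = pd.read_sql_query(
            "SELECT c.visit, c.patient_id, COUNT(*) AS n FROM conflicts c"
            " JOIN query_conflicts qc ON qc.conflict_id = c.conflict_id"
            " WHERE c.conflict_type != 'entire_ecrf'"
            " GROUP BY c.visit, c.patient_id",
            store.conn,
        )
        pooled = pooled[pooled["visit"].isin(visit_order)]
        if len(pooled) > 1:
            tot.sd_single_per_ecrf = int(round_report(float(pooled["n"].std(ddof=1)), "int"))
    tot.check()

    pcts = [s.pct_with_conflicts for s in non_empty]
    return MonitoringReport(
        visits=summaries, totals=tot,
        pct_with_conflicts_range=(min(pcts), max(pcts)),
    )


def rank_items(store: MonitoringStore, top_k: int) -> list[ItemConflictRank]:
    """Most frequently queried items, by single-conflict count.

    Every single conflict counts once toward each item it involves; ties
    break alphabetically by item_id.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    import json as _json

    counts: dict[str, int] = {}
    for row in store.conn.execute(
        "SELECT items_json FROM conflicts WHERE conflict_type != 'entire_ecrf'"
    ):
        for item_id in _json.loads(row["items_json"]):
            counts[item_id] = counts.get(item_id, 0) + 1
    if not counts:
        raise ValueError("no single conflicts recorded")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return [
        ItemConflictRank(item_id=i, n_conflicts=n, rank=r + 1)
        for r, (i, n) in enumerate(ordered)
    ]


# ---------------------------------------------------------------------------
# Rendering

_ROWS = [
    ("No. of submitted eCRFs, N", lambda s: str(s.n_submitted)),
    ("eCRFs without conflicts, n (%)",
     lambda s: f"{s.n_without_conflicts} ({s.pct_without_conflicts})"),
    ("eCRFs with conflicts, n (%)",
     lambda s: f"{s.n_with_conflicts} ({s.pct_with_conflicts})"),
    ("No. of entire eCRF conflicts queried, n", lambda s: str(s.n_entire_queried)),
    ("No. of entire eCRF conflicts answered, n (%)",
     lambda s: f"{s.n_entire_answered} ({s.pct_entire_answered})"),
    ("No. of entire eCRF conflicts unanswered, n (%)",
     lambda s: f"{s.n_entire_unanswered} ({s.pct_entire_unanswered})"),
    ("No. of eCRFs with single conflicts, n", lambda s: str(s.n_ecrfs_with_single)),
    ("No. of single conflicts queried, n", lambda s: str(s.n_single_queried)),
    ("Single conflicts per eCRF with single conflicts, mean (SD)",
     lambda s: f"{s.mean_single_per_ecrf} ({s.sd_single_per_ecrf})"),
    ("No. of single conflict queries answered, n (%)",
     lambda s: f"{s.n_single_answered} ({s.pct_single_answered})"),
    ("No. of single conflict queries unanswered, n (%)",
     lambda s: f"{s.n_single_unanswered} ({s.pct_single_unanswered})"),
]


def report_frame(report: MonitoringReport) -> pd.DataFrame:
    """The response-status table as a DataFrame (rows = metrics, cols = visits)."""
    cols = {s.visit: [fmt(s) for _, fmt in _ROWS] for s in report.visits}
    cols["total"] = [fmt(report.totals) for _, fmt in _ROWS]
    return pd.DataFrame(cols, index=[label for label, _ in _ROWS])


def report_to_tsv(report: MonitoringReport, path) -> None:
    report_frame(report).to_csv(path, sep="\t", index_label="metric")


def report_to_json(report: MonitoringReport, path) -> None:
    import json as _json

    payload = {
        "visits": [asdict(s) for s in report.visits],
        "totals": asdict(report.totals),
        "pct_with_conflicts_range": list(report.pct_with_conflicts_range),
    }
    with open(path, "w") as fh:
        _json.dump(payload, fh, indent=1)
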