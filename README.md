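# ecrf-monitor

Automated data monitoring for longitudinal observational registries that
collect electronic case report forms (eCRFs).

## The problem

Observational cohort studies document patients from routine clinical care:
laboratory values are often not yet available during the consultation,
follow-up visits happen at the physician's discretion, and — unlike in a
randomized trial — there is no budget for on-site source data verification.
Entry-time plausibility checks deliberately let such forms through (only a
handful of mandatory fields block submission), so incomplete and implausible
data keep accumulating. Because recruitment is continuous, data cleaning
cannot happen "once at the end"; it has to be an ongoing, automated cycle.

`ecrf-monitor` implements that cycle for a registry with visits T0
(baseline), T1 = 3, T2 = 6 and T3 = 12 months and two diagnosis arms:

1. **Entry validation** — per-field and whole-form plausibility checks with
   a permissive submission gate (`validate_field`, `validate_form`,
   `can_submit`).
2. **Conflict catalog** — every post-hoc check is a declarative rule of
   type *missing*, *range*, *date* or *entire eCRF*, with the query text and
   the answer options a site may use (`load_schema`, `load_catalog`).
3. **Conflict engine** — scans the accumulated dataset: expected-but-missing
   and nearly empty forms become entire-eCRF conflicts; every other
   submitted form is evaluated against all applicable rules
   (`detect_conflicts`).
4. **Query manager** — groups the conflicts of one patient × visit into one
   query, exports/imports JSON-Lines transfer files, ingests answers
   (`new_value`, `unknown`, `not_done`, `value_correct`), and applies
   corrections through an append-only audit log in an embedded SQLite store
   (`build_queries`, `import_answers`, `apply_corrections`).
5. **Reporting** — the per-visit response-status table: share of eCRFs with
   conflicts, entire-eCRF and single-conflict response rates, and the mean
   (SD) number of single conflicts per affected form (`summarize_visit`,
   `summarize_all`, `rank_items`).
6. **Synthetic registry** — a seeded generator of realistic-footprint
   registry datasets and simulated site answer behaviour, so the whole
   pipeline is testable without any real patient data (`generate_registry`,
   `simulate_answers`).

For a per-visit summary the key derived quantities are

```
pct_with_conflicts   = n_with_conflicts / n_submitted        (integer %)
mean_single_per_ecrf = n_single_queried / n_ecrfs_with_single (1 decimal)
pct_single_answered  = n_single_answered / n_single_queried   (integer %)
```

with halves rounded away from zero.

## Worked example

```python
from ecrf_monitor import (
    SimConfig, MonitoringStore, generate_registry, detect_conflicts,
    build_queries, simulate_answers, import_answers, summarize_all,
)
from ecrf_monitor.demo import build_demo_schema, build_demo_catalog
from ecrf_monitor.synthgen import simulation_ref_date

schema  = build_demo_schema()          # 261 items, visits T0..T3
catalog = build_demo_catalog(schema)   # 388/118/118/208 rules per visit

cfg = SimConfig(seed=7, n_patients=100)
ds  = generate_registry(schema, cfg)
ref = simulation_ref_date(schema, cfg)

conflicts = detect_conflicts(schema, catalog, ds, ref, run_id=1)
store = MonitoringStore(); store.upsert_records(ds)
queries = build_queries(schema, catalog, conflicts, store, run_id=1)
import_answers(schema, catalog, store,
               simulate_answers(schema, catalog, queries, cfg), run_id=1)

rep = summarize_all(store, schema.visit_ids)
print(len(conflicts), len(queries), rep.totals.pct_single_answered)
```

prints

```
315 217 65
```

— 315 conflicts were detected across 364 submitted forms, grouped into 217
queries (one per conflicted patient × visit), and with the default response
mixture 65% of the queried single conflicts received an answer.

The same pipeline is available from the shell:

```bash
ecrf-monitor write-demo --out-dir demo/
ecrf-monitor simulate --seed 7 --n-patients 100 --out records.csv
ecrf-monitor run-cycle --schema demo/demo_schema.json \
    --catalog demo/demo_catalog.json --records records.csv \
    --store monitor.db --ref-date 2021-09-02 --out transfer.jsonl
ecrf-monitor report --store monitor.db --out report.tsv
```

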