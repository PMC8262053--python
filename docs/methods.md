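# Methods

## The monitoring model

The package models post-submission data monitoring of a longitudinal
registry as a deterministic cycle over four persistent artifacts: an eCRF
**schema** (items with value kinds, plausibility ranges, mandatory flags and
per-visit applicability), a **conflict catalog** (declarative rules), the
accumulated **clinical dataset** (one record per patient × visit) and a
**monitoring store** (SQLite) holding conflicts, queries, answers and the
correction log.

A *conflict* is either an **entire-eCRF conflict** — the form for an
expected visit is missing, or a submitted form is nearly empty — or a
**single conflict** on specific items, of type *missing*, *range* or
*date*. A *query* bundles all open conflicts of one patient at one visit;
the site responds per conflict with a new value or one of the no-change
options (`unknown`, `not_done`, `value_correct`). All four response kinds
count as "answered"; only `new_value` changes data, through an append-only
correction log that fully determines the corrected dataset
(`corrected = apply_corrections(original, log)` is the only mutation path).

### Entry validation vs. post-hoc monitoring

Entry-time checks are intentionally permissive: a form with all mandatory
fields present and type-correct may always be submitted, whatever the
number of warnings. This mirrors how routine-care documentation works
(laboratory values arrive late) and is precisely why the post-hoc engine
exists. The submission gate is the only blocking mechanism in the package.

### Detection semantics

* **Expected visit**: a visit is due once `inclusion_date + nominal offset
  + window` lies on or before the reference date. The scheduling window
  defaults to 42 days; the reference date is always an explicit parameter,
  never the wall clock, so detection runs are reproducible.
* **Near-empty escalation**: a submitted form with at most K non-mandatory
  items filled (default K = 3) is queried as an entire-eCRF conflict.
* **Suppression**: a form flagged entire-eCRF contributes no single
  conflicts. Re-requesting the whole form and itemized queries for the same
  form would duplicate site work, and it keeps the two conflict classes
  disjoint in the per-visit report.
* **Predicate dialect**: rule conditions are boolean expressions over
  items (`missing(x)`, `out_of_range(x)`, `date_before(x,y)`,
  `date_after(x,y)`, comparisons, `and/or/not`), parsed with the Python
  grammar and evaluated on a strict node whitelist. A missing operand makes
  range, date and comparison predicates **false**: missingness is its own
  rule type, so one data gap produces one conflict, not a cascade.
* **Determinism**: conflict keys are `(patient, visit, rule)`; output is
  sorted by patient, visit order, rule id; re-running on unchanged data is
  a no-op.

### Query lifecycle

`open → answered | partially_answered | expired`, with
`partially_answered → answered`. "Partially answered" means at least one
but not all conflicts of the query received a response — the only
operationalizable reading of "submitted but not answered sufficiently".
A conflict resolved with any response kind is permanently excluded from
future queries unless its observed values change (the store compares the
value snapshot taken at resolution). Re-asking a site about a value it
already confirmed would undermine the low-burden design goal. Open queries
expire after a configurable number of subsequent monitoring runs
(default 2); expiry is run-count-based, not clock-based, for the same
reproducibility reason as above.

### Reporting conventions

Percentages are printed as integers and means to one decimal, halves
rounded away from zero; standard deviations are printed at integer
precision. The per-visit eCRF universe is every patient × visit slot that
was submitted **or** queried as entirely missing, which keeps
`without + with = N` while still counting never-performed visits that
generated queries. The totals row sums raw counts across visits and
recomputes its percentages from the summed numerators/denominators; the
mean and SD in the totals row are pooled over all conflicted forms.

## The demo schema and catalog

The bundled demo emulates a two-arm spondyloarthritis registry (axSpA /
PsA; visits at 0, 3, 6 and 12 months). Mandatory fields are
`survey_date`, `year_of_birth`, `gender`, `treatment` — the union of the
two plausible mandatory sets (survey date + medication vs. inclusion
date/year of birth/gender/treatment), chosen as the safe superset and
configurable per schema file. Named clinical items (CRP, ESR, Schober's
test, enthesitis, glucocorticoid therapy, global assessments) are padded
with generic laboratory/assessment/history items so that the catalog
exposes exactly 388 applicable rules at baseline, 118 at each interim
visit and 208 at the 12-month visit — the per-visit footprint of a real
registry catalog, whose concrete rule lists are not public. The composition
is 118 all-visit rules (1 entire-eCRF + 2 cross-field date rules + 75
missing + 40 range), 90 extra rules at T0+T3 and 180 baseline-only rules.
The entire-eCRF rule is counted inside these totals. Schema and catalog are
generated programmatically and can be materialized as JSON
(`write_demo_files`) for the file-based interfaces.

## The synthetic registry generator

`generate_registry` emulates the data-generating situation of routine-care
documentation. Per patient: a diagnosis arm (52% axSpA), an inclusion date
uniform over a ~3-year enrolment window, then per visit a skip draw, a
near-empty draw, and per item a missingness draw, an out-of-range draw
(ranged numerics only) and a date-error draw (therapy start placed before
inclusion). Defaults:

| parameter | default | rationale |
|---|---|---|
| `item_missing_prob` | 0.003 | background per-item gap rate |
| per-item overrides | 0.04 for CRP, ESR, Schober, glucocorticoids, enthesitis | laboratory results and a few clinical tests are the classic late/absent values |
| `out_of_range_prob` | 0.002 | typos per filled ranged numeric |
| `date_error_prob` | 0.002 | inverted date pairs per patient |
| `missing_visit_prob` | T1 0.17, T2 0.11, T3 0.12 | 3-month visits are skipped most often |
| `near_empty_prob` | 0.006 | rare technically broken submissions |
| `answer_probs` | new_value 0.50, unknown 0.07, not_done 0.05, value_correct 0.04 | ≈ two thirds of queried conflicts answered |

With these defaults the simulated registry reproduces the qualitative
footprint of a real one — roughly 40–65% of forms conflicted per visit,
1–3 single conflicts per conflicted form, interim visits cleanest — though
not any exact published cell. Values are drawn uniformly within declared
ranges: rule coverage, not clinical realism, is the generator's goal, so
passing tests say nothing about disease-activity distributions or
correlations in real data.

`simulate_answers` answers each conflict independently per the response
mixture. New values are drawn in-range; for a fired date rule the
implicated date is moved to the correct side of its anchor (a random
in-range date would not reliably clear the conflict); entire-eCRF conflicts
are answered `not_done`, so no simulated response ever targets a
nonexistent record.

## The transcribed ledger

`published_table_ledger` builds a store whose per-visit counts transcribe a
published response-status table (submitted forms, entire-eCRF query
outcomes, single-conflict query outcomes). The per-form distribution of
single conflicts is not printed in such tables; three-point mixtures were
solved per visit so that the totals, the means *and* the printed
integer-precision SDs are all reproduced (e.g. baseline: 642 forms with 1,
493 with 3 and 51 with 14 single conflicts). Expected-but-missing forms
are stored as `absent` records carrying an entire-eCRF conflict, exactly
as a live detection run represents them; the published table counts these
inside its per-visit N, and the reporting universe is defined accordingly.

## Numerical and design choices

* Rounding is half-away-from-zero everywhere a report is printed; this is
  the only convention consistent with every printed percentage and mean of
  the reference table.
* Rule applicability may carry a diagnosis-arm restriction (`arms` field,
  `None` = all arms); per-arm stratified reporting is supported but the
  standard report pools arms.
* Auto-expired submissions are a record status flag
  (`submitted_expired`), not a timer; the expiry period of the capture
  system is out of scope.
* Corrections replay strictly in log order; two corrections to the same
  cell keep both log rows and the last write wins.
* An invalid `new_value` answer (wrong type, out of range) is rejected
  with a validation finding and resolves nothing — silently storing it
  would defeat the purpose of monitoring.
* Problem sizes in the test-suite simulations (up to ~1,700 patients for
  the binomial answered-fraction check, 200 randomized small datasets for
  the oracle-equivalence checks) were chosen to give stable statistics at
  interactive runtimes.

## Known limitations

* No cross-patient or statistical outlier checks — only declared rules.
* The demo catalog is illustrative: it matches the published per-visit
  rule counts, not the original rule texts or their diagnosis-specific
  splits (neither is public).
* Overall multi-visit response rates quoted in prose alongside such tables
  (e.g. "about two thirds answered") depend on denominator choices that
  are not recoverable; the package reports only quantities it can compute
  from its own store.
* No web UI, notification delivery, role-based access control or
  concurrency beyond append-only semantics.
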