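"""Illustrative two-arm registry schema and conflict catalog.

Emulates a spondyloarthritis registry with visits T0 (baseline), T1
(3 months), T2 (6 months) and T3 (12 months) and two diagnosis arms.
The baseline and 12-month forms are deliberately the most complex: the
catalog exposes 388 checkable conflicts at T0, 208 at T3 and 118 at each
of the interim visits T1/T2, matching the published footprint of a real
registry catalog. The concrete rule lists are illustrative — the original
catalog is not public — so named clinical items (CRP, ESR, Schober's test,
enthesitis, glucocorticoid therapy, ...) are padded with generic
laboratory and assessment items to reach those counts.

Everything is generated programmatically; ``write_demo_files`` materializes
schema and catalog as JSON for the file-based interfaces.
"""

from __future__ import annotations

from pathlib import Path

from .schema_catalog import (
    ConflictCatalog,
    ConflictRule,
    EcrfSchema,
    ItemDef,
    Visit,
    save_catalog,
    save_schema,
)

ALL_VISITS = ["T0", "T1", "T2", "T3"]
T0_T3 = ["T0", "T3"]
T0_ONLY = ["T0"]

#: rules applicable at every visit (1 entire-eCRF + 2 date + 75 missing + 40 range)
N_CORE_ITEMS = 75
N_CORE_RANGED = 40
#: extra T0+T3 rules (60 missing + 30 range)
N_EXT_ITEMS = 60
N_EXT_RANGED = 30
#: extra baseline-only rules (120 missing + 60 range)
N_BASE_ITEMS = 120
N_BASE_RANGED = 60


def _named_core_items() -> list[ItemDef]:
    mk = ItemDef
    return [
        mk(item_id="survey_date", label="Date of survey", section="administrative",
           value_kind="date", mandatory=True, visits=ALL_VISITS),
        mk(item_id="year_of_birth", label="Year of birth", section="administrative",
           value_kind="numeric", range_min=1920, range_max=2010, mandatory=True,
           visits=ALL_VISITS),
        mk(item_id="gender", label="Gender", section="administrative",
           value_kind="categorical", categories=["female", "male"], mandatory=True,
           visits=ALL_VISITS),
        mk(item_id="treatment", label="Current b/tsDMARD treatment", section="treatment",
           value_kind="categorical",
           categories=["TNFi", "IL17i", "JAKi", "IL23i", "csDMARD", "other"],
           mandatory=True, visits=ALL_VISITS),
        mk(item_id="inclusion_date", label="Date of study inclusion",
           section="administrative", value_kind="date", visits=ALL_VISITS),
        mk(item_id="therapy_start", label="Start date of current therapy",
           section="treatment", value_kind="date", visits=ALL_VISITS),
        mk(item_id="crp", label="C-reactive protein", section="laboratory",
           value_kind="numeric", unit="mg/L", range_min=0, range_max=400,
           visits=ALL_VISITS),
        mk(item_id="esr", label="Erythrocyte sedimentation rate", section="laboratory",
           value_kind="numeric", unit="mm/h", range_min=0, range_max=150,
           visits=ALL_VISITS),
        mk(item_id="schober_test", label="Schober's test", section="clinical",
           value_kind="numeric", unit="cm", range_min=0, range_max=15,
           visits=ALL_VISITS),
        mk(item_id="enthesitis_present", label="Enthesitis present", section="clinical",
           value_kind="boolean", visits=ALL_VISITS),
        mk(item_id="glucocorticoid_therapy", label="Systemic glucocorticoid therapy",
           section="treatment", value_kind="boolean", visits=ALL_VISITS),
        mk(item_id="patient_global", label="Patient global assessment",
           section="clinical", value_kind="numeric", range_min=0, range_max=10,
           visits=ALL_VISITS),
        mk(item_id="physician_global", label="Physician global assessment",
           section="clinical", value_kind="numeric", range_min=0, range_max=10,
           visits=ALL_VISITS),
        mk(item_id="disease_activity", label="Disease activity score",
           section="clinical", value_kind="numeric", range_min=0, range_max=10,
           visits=ALL_VISITS),
    ]


def build_demo_schema() -> EcrfSchema:
    items = _named_core_items()
    # items that will carry missing/range rules: non-mandatory, and not the
    # pure date-plausibility helpers (those feed the two cross-field date rules)
    named_checkable = [
        i for i in items
        if not i.mandatory and i.item_id not in ("inclusion_date", "therapy_start")
    ]
    named_ranged = [i for i in named_checkable
                    if i.value_kind == "numeric" and i.has_range()]

    # pad the core block to 75 checkable items, 40 of them ranged numerics
    n_pad_ranged = N_CORE_RANGED - len(named_ranged)
    n_pad_other = N_CORE_ITEMS - len(named_checkable) - n_pad_ranged
    for k in range(n_pad_ranged):
        items.append(ItemDef(
            item_id=f"lab_{k+1:02d}", label=f"Laboratory value {k+1}",
            section="laboratory", value_kind="numeric", range_min=0, range_max=1000,
            visits=ALL_VISITS))
    for k in range(n_pad_other):
        items.append(ItemDef(
            item_id=f"assessment_{k+1:02d}", label=f"Clinical assessment {k+1}",
            section="clinical", value_kind="boolean", visits=ALL_VISITS))

    for k in range(N_EXT_ITEMS):
        ranged = k < N_EXT_RANGED
        items.append(ItemDef(
            item_id=f"extended_{k+1:02d}", label=f"Extended follow-up item {k+1}",
            section="extended",
            value_kind="numeric" if ranged else "boolean",
            range_min=0 if ranged else None, range_max=100 if ranged else None,
            visits=T0_T3))

    for k in range(N_BASE_ITEMS):
        ranged = k < N_BASE_RANGED
        items.append(ItemDef(
            item_id=f"baseline_{k+1:03d}", label=f"Baseline history item {k+1}",
            section="history",
            value_kind="numeric" if ranged else "boolean",
            range_min=0 if ranged else None, range_max=100 if ranged else None,
            visits=T0_ONLY))

    return EcrfSchema(
        name="demo-spa-registry",
        visits=[Visit(visit_id="T0", offset_months=0),
                Visit(visit_id="T1", offset_months=3),
                Visit(visit_id="T2", offset_months=6),
                Visit(visit_id="T3", offset_months=12)],
        items=items,
        diagnosis_arms=["axSpA", "PsA"],
    )


def build_demo_catalog(schema: EcrfSchema | None = None) -> ConflictCatalog:
    """Catalog with per-visit applicable-rule counts 388/118/118/208."""
    schema = schema or build_demo_schema()
    mandatory = set(schema.mandatory_items())
    rules: list[ConflictRule] = [
        ConflictRule(
            rule_id="entire_ecrf",
            conflict_type="entire_ecrf",
            visits=ALL_VISITS,
            query_label="The eCRF for this visit is missing or nearly empty; "
                        "please complete it.",
            display_sections=["administrative"],
        ),
        ConflictRule(
            rule_id="date_survey_before_inclusion",
            conflict_type="date",
            visits=ALL_VISITS,
            target_items=["survey_date", "inclusion_date"],
            condition="date_before(survey_date, inclusion_date)",
            query_label="The survey date lies before the inclusion date; "
                        "please check both dates.",
        ),
        ConflictRule(
            rule_id="date_therapy_before_inclusion",
            conflict_type="date",
            visits=ALL_VISITS,
            target_items=["therapy_start", "inclusion_date"],
            condition="date_before(therapy_start, inclusion_date)",
            query_label="The therapy start date lies before the inclusion date; "
                        "please check both dates.",
        ),
    ]

    def add_item_rules(item_id: str, visits: list[str]) -> None:
        item = schema.item(item_id)
        rules.append(ConflictRule(
            rule_id=f"missing_{item_id}",
            conflict_type="missing",
            visits=visits,
            target_items=[item_id],
            condition=f"missing({item_id})",
            query_label=f"{item.label or item_id} was not documented; "
                        "please supply the value.",
        ))
        if item.value_kind == "numeric" and item.has_range():
            rules.append(ConflictRule(
                rule_id=f"range_{item_id}",
                conflict_type="range",
                visits=visits,
                target_items=[item_id],
                condition=f"out_of_range({item_id})",
                query_label=f"{item.label or item_id} lies outside the plausible "
                            f"range [{item.range_min:g}, {item.range_max:g}]; "
                            "please verify.",
            ))

    for item in schema.items:
        if item.item_id in mandatory or item.item_id in ("inclusion_date", "therapy_start"):
            continue
        add_item_rules(item.item_id, list(item.visits))

    catalog = ConflictCatalog(version="demo-1", schema_ref=schema.name, rules=rules)
    catalog.validate_against(schema)
    return catalog


def write_demo_files(directory: str | Path) -> tuple[Path, Path]:
    """Materialize the demo schema and catalog as JSON files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema = build_demo_schema()
    catalog = build_demo_catalog(schema)
    schema_path = directory / "demo_schema.json"
    catalog_path = directory / "demo_catalog.json"
    save_schema(schema, schema_path)
    save_catalog(catalog, catalog_path)
    return schema_path, catalog_path
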