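"""eCRF schema and conflict-catalog definitions.

The schema declares every item a physician can document per visit (value
kind, plausibility range, mandatory flag, per-visit applicability); the
conflict catalog declares every post-submission check as a declarative rule
(missing / range / date / entire-eCRF) together with the query text and the
answer options a site may use. Both are the single source of truth for what
the monitoring engine can check and query.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

VALUE_KINDS = ("numeric", "date", "categorical", "boolean", "text")
CONFLICT_TYPES = ("missing", "range", "date", "entire_ecrf")
ANSWER_KINDS = ("new_value", "unknown", "not_done", "value_correct")


class SchemaError(ValueError):
    """Raised when a schema or catalog file violates an invariant."""


class ItemDef(BaseModel):
    """One eCRF field."""

    item_id: str
    label: str = ""
    section: str = "general"
    value_kind: str
    unit: Optional[str] = None
    range_min: Optional[float] = None
    range_max: Optional[float] = None
    categories: Optional[list[str]] = None
    mandatory: bool = False
    visits: list[str]

    @field_validator("value_kind")
    @classmethod
    def _kind_known(cls, v: str) -> str:
        if v not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {v!r}")
        return v

    @model_validator(mode="after")
    def _invariants(self) -> "ItemDef":
        if self.range_min is not None and self.range_max is not None:
            if self.range_min > self.range_max:
                raise ValueError(
                    f"item {self.item_id!r}: range_min {self.range_min} > "
                    f"range_max {self.range_max}"
                )
        if (self.value_kind == "categorical") != bool(self.categories):
            raise ValueError(
                f"item {self.item_id!r}: categories must be non-empty iff "
                "value_kind is categorical"
            )
        if self.range_min is not None or self.range_max is not None:
            if self.value_kind != "numeric":
                raise ValueError(
                    f"item {self.item_id!r}: range bounds only valid for numeric items"
                )
        if not self.visits:
            raise ValueError(f"item {self.item_id!r}: empty visit set")
        return self

    def has_range(self) -> bool:
        return self.range_min is not None or self.range_max is not None


class Visit(BaseModel):
    """One scheduled timepoint with its nominal offset from baseline."""

    visit_id: str
    offset_months: float


class EcrfSchema(BaseModel):
    """The full per-visit item inventory of a registry's physician eCRF."""

    name: str = "ecrf"
    visits: list[Visit]
    items: list[ItemDef]
    diagnosis_arms: list[str] = Field(default_factory=lambda: ["axSpA", "PsA"])

    @model_validator(mode="after")
    def _invariants(self) -> "EcrfSchema":
        ids = [v.visit_id for v in self.visits]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate visit identifiers")
        offsets = [v.offset_months for v in self.visits]
        if offsets != sorted(offsets):
            raise ValueError("visits must be ordered by offset")
        item_ids = [i.item_id for i in self.items]
        dupes = {i for i in item_ids if item_ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate item_ids: {sorted(dupes)}")
        known = set(ids)
        bad = [i.item_id for i in self.items if not set(i.visits) <= known]
        if bad:
            raise ValueError(f"items reference unknown visits: {bad}")
        return self

    @property
    def visit_ids(self) -> list[str]:
        return [v.visit_id for v in self.visits]

    def visit_offset(self, visit_id: str) -> float:
        for v in self.visits:
            if v.visit_id == visit_id:
                return v.offset_months
        raise KeyError(f"unknown visit {visit_id!r}")

    def item(self, item_id: str) -> ItemDef:
        got = self._index().get(item_id)
        if got is None:
            raise KeyError(f"unknown item {item_id!r}")
        return got

    def _index(self) -> dict[str, ItemDef]:
        cached = getattr(self, "_item_index", None)
        if cached is None or len(cached) != len(self.items):
            cached = {i.item_id: i for i in self.items}
            object.__setattr__(self, "_item_index", cached)
        return cached

    def items_at(self, visit_id: str) -> list[ItemDef]:
        """Items applicable at a visit, in schema order."""
        if visit_id not in self.visit_ids:
            raise KeyError(f"unknown visit {visit_id!r}")
        return [i for i in self.items if visit_id in i.visits]

    def mandatory_items(self) -> list[str]:
        return [i.item_id for i in self.items if i.mandatory]

    def section_order(self) -> list[str]:
        seen: list[str] = []
        for i in self.items:
            if i.section not in seen:
                seen.append(i.section)
        return seen


class ConflictRule(BaseModel):
    """One catalog entry: a checkable conflict plus its query presentation."""

    rule_id: str
    conflict_type: str
    visits: list[str]
    target_items: list[str] = Field(default_factory=list)
    condition: str = ""
    query_label: str = ""
    answer_options: list[str] = Field(
        default_factory=lambda: ["new_value", "unknown", "not_done", "value_correct"]
    )
    display_sections: list[str] = Field(default_factory=list)
    arms: Optional[list[str]] = None  # None = applies to every diagnosis arm

    @model_validator(mode="after")
    def _invariants(self) -> "ConflictRule":
        if self.conflict_type not in CONFLICT_TYPES:
            raise ValueError(f"rule {self.rule_id!r}: unknown type {self.conflict_type!r}")
        if self.conflict_type == "entire_ecrf":
            if self.target_items:
                raise ValueError(
                    f"rule {self.rule_id!r}: entire_ecrf rules take no target items"
                )
        elif not self.target_items:
            raise ValueError(f"rule {self.rule_id!r}: needs at least one target item")
        if "new_value" not in self.answer_options:
            raise ValueError(f"rule {self.rule_id!r}: answer_options must allow new_value")
        bad = [a for a in self.answer_options if a not in ANSWER_KINDS]
        if bad:
            raise ValueError(f"rule {self.rule_id!r}: unknown answer options {bad}")
        if not self.visits:
            raise ValueError(f"rule {self.rule_id!r}: empty visit set")
        return self

    def applies(self, visit: str, arm: Optional[str] = None) -> bool:
        if visit not in self.visits:
            return False
        return self.arms is None or arm is None or arm in self.arms


class ConflictCatalog(BaseModel):
    """A versioned collection of conflict rules bound to one schema."""

    version: str = "1"
    schema_ref: str = ""
    rules: list[ConflictRule]

    @model_validator(mode="after")
    def _unique_ids(self) -> "ConflictCatalog":
        ids = [r.rule_id for r in self.rules]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate rule_ids: {dupes}")
        return self

    def rule(self, rule_id: str) -> ConflictRule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(f"unknown rule {rule_id!r}")

    def validate_against(self, schema: EcrfSchema) -> None:
        """Cross-check every rule against the schema; raise listing all faults."""
        problems: list[str] = []
        known_visits = set(schema.visit_ids)
        item_ids = {i.item_id for i in schema.items}
        for rule in self.rules:
            for v in rule.visits:
                if v not in known_visits:
                    problems.append(f"rule {rule.rule_id}: unknown visit {v}")
            if rule.arms:
                for a in rule.arms:
                    if a not in schema.diagnosis_arms:
                        problems.append(f"rule {rule.rule_id}: unknown arm {a}")
            for item_id in rule.target_items:
                if item_id not in item_ids:
                    problems.append(f"rule {rule.rule_id}: unknown item {item_id}")
                    continue
                item = schema.item(item_id)
                absent = [v for v in rule.visits if v not in item.visits]
                if absent:
                    problems.append(
                        f"rule {rule.rule_id}: item {item_id} not applicable at {absent}"
                    )
        if problems:
            raise SchemaError("; ".join(problems))


# ---------------------------------------------------------------------------
# File I/O

def load_schema(path: str | Path) -> EcrfSchema:
    """Load and validate an eCRF schema from a JSON file."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: line {exc.lineno}, col {exc.colno}: {exc.msg}") from exc
    try:
        return EcrfSchema.model_validate(payload)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def save_schema(schema: EcrfSchema, path: str | Path) -> None:
    Path(path).write_text(schema.model_dump_json(indent=1, exclude_none=True))


def load_catalog(path: str | Path, schema: EcrfSchema) -> ConflictCatalog:
    """Load a conflict catalog (JSON, or CSV with one row per rule).

    Every rule is cross-checked against *schema*; unknown items, unknown
    visits and inapplicable target items are reported together.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        catalog = _catalog_from_csv(path)
    else:
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(
                f"{path}: line {exc.lineno}, col {exc.colno}: {exc.msg}"
            ) from exc
        try:
            catalog = ConflictCatalog.model_validate(payload)
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    catalog.validate_against(schema)
    return catalog


def _catalog_from_csv(path: Path) -> ConflictCatalog:
    rules = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rules.append(
                ConflictRule(
                    rule_id=row["rule_id"],
                    conflict_type=row["conflict_type"],
                    visits=row["visits"].split(";") if row["visits"] else [],
                    target_items=(
                        row["target_items"].split(";") if row.get("target_items") else []
                    ),
                    condition=row.get("condition", ""),
                    query_label=row.get("query_label", ""),
                    answer_options=(
                        row["answer_options"].split(";")
                        if row.get("answer_options")
                        else list(ANSWER_KINDS)
                    ),
                    display_sections=(
                        row["display_sections"].split(";")
                        if row.get("display_sections")
                        else []
                    ),
                    arms=row["arms"].split(";") if row.get("arms") else None,
                )
            )
    return ConflictCatalog(rules=rules)


def save_catalog(catalog: ConflictCatalog, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        fields = [
            "rule_id", "conflict_type", "visits", "target_items", "condition",
            "query_label", "answer_options", "display_sections", "arms",
        ]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for r in catalog.rules:
                writer.writerow(
                    {
                        "rule_id": r.rule_id,
                        "conflict_type": r.conflict_type,
                        "visits": ";".join(r.visits),
                        "target_items": ";".join(r.target_items),
                        "condition": r.condition,
                        "query_label": r.query_label,
                        "answer_options": ";".join(r.answer_options),
                        "display_sections": ";".join(r.display_sections),
                        "arms": ";".join(r.arms) if r.arms else "",
                    }
                )
    else:
        path.write_text(catalog.model_dump_json(indent=1, exclude_none=True))


def count_applicable(
    catalog: ConflictCatalog, visit: str, schema: Optional[EcrfSchema] = None
) -> int:
    """Number of catalog rules applicable at *visit* (any diagnosis arm).

    Pass the bound *schema* to have the visit identifier checked.
    """
    if schema is not None and visit not in schema.visit_ids:
        raise KeyError(f"unknown visit {visit!r}")
    return sum(1 for r in catalog.rules if visit in r.visits)


def rules_at(
    catalog: ConflictCatalog, visit: str, arm: Optional[str] = None
) -> Iterable[ConflictRule]:
    return [r for r in catalog.rules if r.applies(visit, arm)]
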