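"""Entry-time plausibility checks and the submission gate.

Emulates the in-page validation of a web eCRF: every field is checked the
moment it is entered, the whole form is checked again before submission,
and the form may still be submitted with warnings — only mandatory fields
block. This permissiveness is deliberate (laboratory values are often not
yet available during the consultation) and is exactly why the post-hoc
conflict engine exists.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Any, Optional

from .conditions import coerce_boolean, is_missing, parse_date, parse_numeric
from .records import EcrfRecord
from .schema_catalog import EcrfSchema, ItemDef

SEVERITIES = ("blocking", "warning")
FINDING_KINDS = (
    "out_of_range",
    "missing_mandatory",
    "missing_value",
    "implausible_cross_field",
    "bad_type",
)


@dataclass(frozen=True)
class ValidationFinding:
    """One alert raised for one field (or one cross-field check)."""

    item_id: str
    severity: str
    kind: str
    message: str

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.kind not in FINDING_KINDS:
            raise ValueError(f"unknown finding kind {self.kind!r}")


def _typeable(item: ItemDef, value: Any) -> bool:
    if item.value_kind == "numeric":
        return parse_numeric(value) is not None
    if item.value_kind == "date":
        return parse_date(value) is not None
    if item.value_kind == "boolean":
        return coerce_boolean(value) is not None
    if item.value_kind == "categorical":
        return str(value) in (item.categories or [])
    return True  # free text


def validate_field(item: ItemDef, value: Any) -> list[ValidationFinding]:
    """Check one value against its item definition.

    Empty result iff the value is present, type-correct and within range /
    among the allowed categories. A missing or untypeable value on a
    mandatory item blocks submission; everything else is a warning.
    """
    if is_missing(value):
        if item.mandatory:
            return [
                ValidationFinding(
                    item.item_id, "blocking", "missing_mandatory",
                    f"mandatory field {item.item_id} is empty",
                )
            ]
        return [
            ValidationFinding(
                item.item_id, "warning", "missing_value",
                f"{item.item_id} not filled in",
            )
        ]

    if not _typeable(item, value):
        severity = "blocking" if item.mandatory else "warning"
        return [
            ValidationFinding(
                item.item_id, severity, "bad_type",
                f"value {value!r} is not a valid {item.value_kind} for {item.item_id}",
            )
        ]

    if item.value_kind == "numeric" and item.has_range():
        num = parse_numeric(value)
        assert num is not None
        lo, hi = item.range_min, item.range_max
        if (lo is not None and num < lo) or (hi is not None and num > hi):
            unit = f" {item.unit}" if item.unit else ""
            return [
                ValidationFinding(
                    item.item_id, "warning", "out_of_range",
                    f"{item.item_id}={num:g}{unit} outside plausible range "
                    f"[{lo}, {hi}]",
                )
            ]
    return []


def validate_form(
    schema: EcrfSchema,
    record: EcrfRecord,
    ref_date: Optional[dt.date | str] = None,
) -> list[ValidationFinding]:
    """Whole-form check run before submission.

    Concatenates :func:`validate_field` over every item applicable at the
    record's visit and adds cross-field date checks: the survey date must
    not precede the inclusion date nor lie after *ref_date* (the export /
    reference date — always an explicit parameter, never the wall clock).
    """
    findings: list[ValidationFinding] = []
    for item in schema.items_at(record.visit):
        findings.extend(validate_field(item, record.values.get(item.item_id)))

    survey = parse_date(record.values.get("survey_date"))
    inclusion = parse_date(record.values.get("inclusion_date"))
    if survey and inclusion and survey < inclusion:
        findings.append(
            ValidationFinding(
                "survey_date", "warning", "implausible_cross_field",
                f"survey date {survey} precedes inclusion date {inclusion}",
            )
        )
    ref = parse_date(ref_date) if ref_date else None
    if survey and ref and survey > ref:
        findings.append(
            ValidationFinding(
                "survey_date", "warning", "implausible_cross_field",
                f"survey date {survey} lies after the reference date {ref}",
            )
        )
    return findings


def can_submit(findings: list[ValidationFinding]) -> bool:
    """A form may be submitted iff no finding blocks (mandatory fields only)."""
    return not any(f.severity == "blocking" for f in findings)
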