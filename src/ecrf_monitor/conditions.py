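"""Predicate dialect for conflict-rule conditions.

A condition is a small boolean expression over eCRF items, e.g.::

    missing(crp)
    out_of_range(crp) or out_of_range(esr)
    date_before(therapy_start, inclusion_date)
    not missing(crp) and crp > 400

Supported primitives: ``missing(x)``, ``out_of_range(x)``,
``date_before(x, y)``, ``date_after(x, y)``, comparisons of an item against
a constant or another item, combined with ``and`` / ``or`` / ``not``.

Missing operands make range, date and comparison predicates false:
missingness is its own rule type and is only ever reported by ``missing()``.
Expressions are parsed with the Python grammar and evaluated on a strict
whitelist of node types; nothing else executes.
"""

from __future__ import annotations

import ast
import datetime as dt
from typing import Any, Mapping, Optional

from .schema_catalog import EcrfSchema, ItemDef

_MISSING_TOKENS = {None, ""}


class ConditionError(ValueError):
    """Malformed condition, or a predicate applied to an unsupported item kind."""


def is_missing(value: Any) -> bool:
    if value in _MISSING_TOKENS:
        return True
    if isinstance(value, float) and value != value:  # NaN
        return True
    return False


def parse_date(value: Any) -> Optional[dt.date]:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        try:
            return dt.date.fromisoformat(value.strip())
        except ValueError:
            return None
    return None


def parse_numeric(value: Any) -> Optional[float]:
    if isinstance(value, bool):
        return float(value)
    if isinstance(value, (int, float)):
        return None if value != value else float(value)
    if isinstance(value, str):
        try:
            return float(value.strip())
        except ValueError:
            return None
    return None


def out_of_range(item: ItemDef, value: Any) -> bool:
    """True iff a *present* numeric value lies outside the item's declared range."""
    if item.value_kind != "numeric" or not item.has_range():
        raise ConditionError(f"out_of_range needs a ranged numeric item, got {item.item_id!r}")
    if is_missing(value):
        return False
    num = parse_numeric(value)
    if num is None:
        return False  # untypeable values are an entry-validation concern
    if item.range_min is not None and num < item.range_min:
        return True
    if item.range_max is not None and num > item.range_max:
        return True
    return False


_ALLOWED_COMPARE = (ast.Lt, ast.LtE, ast.Gt, ast.GtE, ast.Eq, ast.NotEq)


class _Evaluator(ast.NodeVisitor):
    def __init__(self, schema: EcrfSchema, values: Mapping[str, Any]):
        self.schema = schema
        self.values = values

    def run(self, expr: str) -> bool:
        try:
            tree = ast.parse(expr, mode="eval")
        except SyntaxError as exc:
            raise ConditionError(f"cannot parse condition {expr!r}: {exc.msg}") from exc
        return bool(self.visit(tree.body))

    # -- boolean structure ------------------------------------------------
    def visit_BoolOp(self, node: ast.BoolOp) -> bool:
        vals = (bool(self.visit(v)) for v in node.values)
        return all(vals) if isinstance(node.op, ast.And) else any(vals)

    def visit_UnaryOp(self, node: ast.UnaryOp) -> bool:
        if not isinstance(node.op, ast.Not):
            raise ConditionError("only 'not' is allowed as unary operator")
        return not self.visit(node.operand)

    # -- primitives -------------------------------------------------------
    def visit_Call(self, node: ast.Call) -> bool:
        if not isinstance(node.func, ast.Name):
            raise ConditionError("only named predicate calls are allowed")
        name = node.func.id
        args = [self._item_arg(a) for a in node.args]
        if name == "missing":
            (item,) = self._arity(name, args, 1)
            return is_missing(self.values.get(item.item_id))
        if name == "out_of_range":
            (item,) = self._arity(name, args, 1)
            return out_of_range(item, self.values.get(item.item_id))
        if name in ("date_before", "date_after"):
            a, b = self._arity(name, args, 2)
            for it in (a, b):
                if it.value_kind != "date":
                    raise ConditionError(f"{name} needs date items, got {it.item_id!r}")
            da = parse_date(self.values.get(a.item_id))
            db = parse_date(self.values.get(b.item_id))
            if da is None or db is None:
                return False
            return da < db if name == "date_before" else da > db
        raise ConditionError(f"unknown predicate {name!r}")

    def _arity(self, name: str, args: list[ItemDef], n: int) -> list[ItemDef]:
        if len(args) != n:
            raise ConditionError(f"{name} takes {n} argument(s), got {len(args)}")
        return args

    def _item_arg(self, node: ast.expr) -> ItemDef:
        if not isinstance(node, ast.Name):
            raise ConditionError("predicate arguments must be item names")
        try:
            return self.schema.item(node.id)
        except KeyError as exc:
            raise ConditionError(str(exc)) from exc

    # -- comparisons ------------------------------------------------------
    def visit_Compare(self, node: ast.Compare) -> bool:
        if len(node.ops) != 1 or len(node.comparators) != 1:
            raise ConditionError("chained comparisons are not supported")
        op = node.ops[0]
        if not isinstance(op, _ALLOWED_COMPARE):
            raise ConditionError(f"operator {type(op).__name__} not allowed")
        left = self._operand(node.left)
        right = self._operand(node.comparators[0])
        if left is None or right is None:
            return False  # missing operand: comparisons never fire
        if isinstance(left, dt.date) != isinstance(right, dt.date):
            raise ConditionError("cannot compare a date with a number")
        table = {
            ast.Lt: lambda a, b: a < b,
            ast.LtE: lambda a, b: a <= b,
            ast.Gt: lambda a, b: a > b,
            ast.GtE: lambda a, b: a >= b,
            ast.Eq: lambda a, b: a == b,
            ast.NotEq: lambda a, b: a != b,
        }
        return table[type(op)](left, right)

    def _operand(self, node: ast.expr):
        """Resolve a comparison operand to float, date, str, or None if missing."""
        if isinstance(node, ast.Constant):
            if isinstance(node.value, (int, float)):
                return float(node.value)
            if isinstance(node.value, str):
                return node.value
            raise ConditionError(f"unsupported constant {node.value!r}")
        if isinstance(node, ast.Name):
            item = self._item_arg(node)
            raw = self.values.get(item.item_id)
            if is_missing(raw):
                return None
            if item.value_kind == "numeric":
                return parse_numeric(raw)
            if item.value_kind == "date":
                return parse_date(raw)
            if item.value_kind == "boolean":
                b = coerce_boolean(raw)
                return None if b is None else float(b)
            return str(raw)
        raise ConditionError("comparison operands must be items or constants")

    def generic_visit(self, node: ast.AST):
        raise ConditionError(f"disallowed expression element {type(node).__name__}")


def coerce_boolean(value: Any) -> Optional[bool]:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in ("true", "yes", "1"):
            return True
        if lowered in ("false", "no", "0"):
            return False
    return None


def evaluate_expression(expr: str, schema: EcrfSchema, values: Mapping[str, Any]) -> bool:
    """Evaluate a condition string against one record's item values."""
    if not expr.strip():
        raise ConditionError("empty condition")
    return _Evaluator(schema, values).run(expr)
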