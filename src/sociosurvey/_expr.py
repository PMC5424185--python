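"""Minimal arithmetic expression engine for instrument scoring rules.

The grammar is deliberately small: item-id references, numeric literals,
``+ - * /``, unary minus, and the aggregate calls ``sum(...)`` and
``mean(...)``.  ``sum(*)`` / ``mean(*)`` expand to all items of the owning
instrument or question group before parsing.  Item ids referenced in an
expression must be valid Python identifiers.
"""

from __future__ import annotations

import ast
import itertools
import math
from typing import Iterable, Mapping, Sequence


class ExpressionError(ValueError):
    """Raised when a scoring expression is malformed or unsupported."""


_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)
_ALLOWED_CALLS = {"sum", "mean"}


def expand_wildcard(expression: str, item_ids: Sequence[str]) -> str:
    """Replace the ``(*)`` shorthand with an explicit item-id list."""
    if "(*)" not in expression:
        return expression
    joined = ", ".join(item_ids)
    return expression.replace("(*)", f"({joined})")


def parse(expression: str) -> ast.Expression:
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse scoring expression {expression!r}: {exc}") from exc
    for node in ast.walk(tree):
        if isinstance(node, (ast.Expression, ast.Load)):
            continue
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            continue
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
            continue
        if isinstance(node, (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.USub, ast.UAdd)):
            continue
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_CALLS:
                raise ExpressionError(
                    f"only sum(...) and mean(...) calls are allowed, got {ast.dump(node.func)}"
                )
            if node.keywords:
                raise ExpressionError("keyword arguments are not allowed in scoring expressions")
            continue
        if isinstance(node, ast.Name):
            continue
        if isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise ExpressionError(f"non-numeric literal {node.value!r} in scoring expression")
            continue
        raise ExpressionError(f"unsupported syntax in scoring expression: {type(node).__name__}")
    return tree


def referenced_ids(expression: str) -> list[str]:
    """Item ids referenced by the expression, in first-appearance order."""
    tree = parse(expression)
    seen: list[str] = []
    for node in ast.walk(tree):
        if isinstance(node, ast.Name) and node.id not in _ALLOWED_CALLS:
            if node.id not in seen:
                seen.append(node.id)
        elif isinstance(node, ast.Call):
            # strip the function name itself from the reference list
            pass
    return [s for s in seen if s not in _ALLOWED_CALLS]


def _eval_node(node: ast.AST, values: Mapping[str, float]) -> float:
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, values)
    if isinstance(node, ast.Constant):
        return float(node.value)
    if isinstance(node, ast.Name):
        try:
            return float(values[node.id])
        except KeyError:
            raise ExpressionError(f"unknown item id {node.id!r} in scoring expression") from None
    if isinstance(node, ast.UnaryOp):
        v = _eval_node(node.operand, values)
        return -v if isinstance(node.op, ast.USub) else v
    if isinstance(node, ast.BinOp):
        left = _eval_node(node.left, values)
        right = _eval_node(node.right, values)
        if isinstance(node.op, ast.Add):
            return left + right
        if isinstance(node.op, ast.Sub):
            return left - right
        if isinstance(node.op, ast.Mult):
            return left * right
        if isinstance(node.op, ast.Div):
            if right == 0:
                raise ExpressionError("division by zero in scoring expression")
            return left / right
    if isinstance(node, ast.Call):
        args = [_eval_node(a, values) for a in node.args]
        if not args:
            raise ExpressionError(f"{node.func.id}() needs at least one argument")
        if node.func.id == "sum":
            return float(sum(args))
        return float(sum(args)) / len(args)
    raise ExpressionError(f"unsupported node {type(node).__name__}")


def evaluate(expression: str, values: Mapping[str, float]) -> float:
    """Evaluate a scoring expression against an item-id -> value map."""
    result = _eval_node(parse(expression), values)
    if not math.isfinite(result):
        raise ExpressionError(f"expression {expression!r} evaluated to a non-finite value")
    return result


# ---------------------------------------------------------------------------
# Range analysis


class _Interval:
    __slots__ = ("lo", "hi")

    def __init__(self, lo: float, hi: float):
        self.lo, self.hi = lo, hi


def _interval_node(node: ast.AST, ranges: Mapping[str, tuple[float, float]]) -> _Interval:
    if isinstance(node, ast.Expression):
        return _interval_node(node.body, ranges)
    if isinstance(node, ast.Constant):
        v = float(node.value)
        return _Interval(v, v)
    if isinstance(node, ast.Name):
        lo, hi = ranges[node.id]
        return _Interval(lo, hi)
    if isinstance(node, ast.UnaryOp):
        iv = _interval_node(node.operand, ranges)
        if isinstance(node.op, ast.USub):
            return _Interval(-iv.hi, -iv.lo)
        return iv
    if isinstance(node, ast.BinOp):
        a = _interval_node(node.left, ranges)
        b = _interval_node(node.right, ranges)
        if isinstance(node.op, ast.Add):
            return _Interval(a.lo + b.lo, a.hi + b.hi)
        if isinstance(node.op, ast.Sub):
            return _Interval(a.lo - b.hi, a.hi - b.lo)
        products = [a.lo * b.lo, a.lo * b.hi, a.hi * b.lo, a.hi * b.hi]
        if isinstance(node.op, ast.Mult):
            return _Interval(min(products), max(products))
        if b.lo <= 0 <= b.hi:
            raise ExpressionError("cannot bound a division whose divisor range spans zero")
        quotients = [a.lo / b.lo, a.lo / b.hi, a.hi / b.lo, a.hi / b.hi]
        return _Interval(min(quotients), max(quotients))
    if isinstance(node, ast.Call):
        ivs = [_interval_node(a, ranges) for a in node.args]
        lo, hi = sum(i.lo for i in ivs), sum(i.hi for i in ivs)
        if node.func.id == "mean":
            lo, hi = lo / len(ivs), hi / len(ivs)
        return _Interval(lo, hi)
    raise ExpressionError(f"unsupported node {type(node).__name__}")


MAX_EXHAUSTIVE_COMBINATIONS = 10**6


def value_range(
    expression: str, option_values: Mapping[str, Iterable[float]]
) -> tuple[float, float]:
    """Exact min/max of the expression over all per-item option combinations.

    Each item id maps to the set of values its response options can take.
    When every referenced item appears exactly once, interval arithmetic is
    exact and cheap; otherwise all combinations are enumerated, provided
    their count stays below ``MAX_EXHAUSTIVE_COMBINATIONS``.
    """
    tree = parse(expression)
    counts: dict[str, int] = {}
    for node in ast.walk(tree):
        if isinstance(node, ast.Name) and node.id not in _ALLOWED_CALLS:
            counts[node.id] = counts.get(node.id, 0) + 1
    missing = [i for i in counts if i not in option_values]
    if missing:
        raise ExpressionError(f"expression references unknown item ids: {missing}")
    if all(c == 1 for c in counts.values()):
        ranges = {i: (min(option_values[i]), max(option_values[i])) for i in counts}
        iv = _interval_node(tree, ranges)
        return iv.lo, iv.hi
    ids = sorted(counts)
    n_comb = 1
    for i in ids:
        n_comb *= len(set(option_values[i]))
        if n_comb > MAX_EXHAUSTIVE_COMBINATIONS:
            raise ExpressionError(
                "expression is not monotone-decomposable and the combination space "
                f"exceeds {MAX_EXHAUSTIVE_COMBINATIONS} — cannot determine attainable range"
            )
    lo = math.inf
    hi = -math.inf
    for combo in itertools.product(*(sorted(set(option_values[i])) for i in ids)):
        v = evaluate(expression, dict(zip(ids, combo)))
        lo, hi = min(lo, v), max(hi, v)
    return lo, hi
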