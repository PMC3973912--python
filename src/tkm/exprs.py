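"""Safe arithmetic expressions over metabolite concentrations.

Transcription-factor signals are declared in the model file as plain
arithmetic over metabolite ids, e.g. ``pep/pyr`` or
``(q8h2+mql8)/(q8+q8h2+mqn8+mql8)``.  Expressions are compiled once from a
restricted AST (numbers, names, + - * / ** and parentheses) so model files
cannot execute arbitrary code.
"""

from __future__ import annotations

import ast
import operator
from typing import Callable, Mapping

__all__ = ["SignalExpression"]

_BINOPS: dict[type, Callable[[float, float], float]] = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Pow: operator.pow,
}


def _compile(node: ast.AST, names: set[str]) -> Callable[[Mapping[str, float]], float]:
    if isinstance(node, ast.Expression):
        return _compile(node.body, names)
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ValueError(f"non-numeric constant {node.value!r}")
        value = float(node.value)
        return lambda env: value
    if isinstance(node, ast.Name):
        names.add(node.id)
        key = node.id
        return lambda env: env[key]
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        op = _BINOPS[type(node.op)]
        left = _compile(node.left, names)
        right = _compile(node.right, names)
        return lambda env: op(left(env), right(env))
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        inner = _compile(node.operand, names)
        return lambda env: -inner(env)
    raise ValueError(f"unsupported syntax in signal expression: {ast.dump(node)}")


class SignalExpression:
    """A compiled arithmetic expression over named concentrations."""

    def __init__(self, text: str):
        self.text = text.strip()
        try:
            tree = ast.parse(self.text, mode="eval")
        except SyntaxError as exc:
            raise ValueError(f"malformed signal expression {text!r}: {exc}") from exc
        names: set[str] = set()
        self._fn = _compile(tree, names)
        #: metabolite ids referenced by the expression
        self.names = frozenset(names)

    def __call__(self, env: Mapping[str, float]) -> float:
        return self._fn(env)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SignalExpression({self.text!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SignalExpression) and self.text == other.text

    def __hash__(self) -> int:
        return hash(self.text)
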