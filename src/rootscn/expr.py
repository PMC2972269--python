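"""Parsing and evaluation of Boolean rule expressions.

Rules are written in a small logic dialect with the operators ``AND``,
``OR``, ``NOT``, parentheses and the constants ``0``/``1``.  Gene names may
contain letters, digits, underscores, ``/``, ``@``, ``'``, ``.`` and ``-``
(so names such as ``Aux/IAA`` or ``SHR@Q`` are single identifiers).

The same syntax tree drives three evaluations:

* Boolean evaluation on {0,1} assignments (truth-table construction);
* "fuzzy" evaluation on [0,1] levels, with AND -> min, OR -> max and
  NOT -> 1-x, used to build input functions for the continuous model;
* pretty-printing, so rule files round-trip losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ExprError",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "parse",
    "variables",
    "to_string",
    "eval_bool",
    "eval_fuzzy",
    "truth_table",
    "dnf_from_table",
]


class ExprError(ValueError):
    """Raised on malformed rule expressions."""


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Const:
    value: int


@dataclass(frozen=True)
class Not:
    arg: "Expr"


@dataclass(frozen=True)
class And:
    args: tuple


@dataclass(frozen=True)
class Or:
    args: tuple


Expr = Var | Const | Not | And | Or

_TOKEN = re.compile(
    r"\s*(?:(?P<lpar>\()"
    r"|(?P<rpar>\))"
    r"|(?P<const>[01])(?![\w/@'.\-])"
    r"|(?P<name>[A-Za-z][\w/@'.\-]*))"
)

_KEYWORDS = {"AND", "OR", "NOT"}


def _tokenize(text: str) -> Iterator[tuple[str, str]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ExprError(f"unexpected character {text[pos:].strip()[0]!r} in {text!r}")
            return
        pos = m.end()
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "name" and value.upper() in _KEYWORDS:
            yield value.upper(), value
        else:
            yield kind, value
    return


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        if self.pos >= len(self.tokens):
            raise ExprError(f"unexpected end of expression in {self.text!r}")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        node = self.expr()
        if self.pos != len(self.tokens):
            raise ExprError(f"trailing tokens in {self.text!r}")
        return node

    def expr(self) -> Expr:
        terms = [self.term()]
        while self.peek() == "OR":
            self.take()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term(self) -> Expr:
        factors = [self.factor()]
        while self.peek() == "AND":
            self.take()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor(self) -> Expr:
        kind, value = self.take()
        if kind == "NOT":
            return Not(self.factor())
        if kind == "lpar":
            inner = self.expr()
            kind, _ = self.take()
            if kind != "rpar":
                raise ExprError(f"unbalanced parentheses in {self.text!r}")
            return inner
        if kind == "const":
            return Const(int(value))
        if kind == "name":
            return Var(value)
        raise ExprError(f"unexpected token {value!r} in {self.text!r}")


def parse(text: str) -> Expr:
    """Parse a rule expression into a syntax tree."""
    return _Parser(text).parse()


def variables(node: Expr) -> tuple[str, ...]:
    """Variable names in order of first appearance."""
    seen: dict[str, None] = {}

    def walk(n: Expr) -> None:
        if isinstance(n, Var):
            seen.setdefault(n.name)
        elif isinstance(n, Not):
            walk(n.arg)
        elif isinstance(n, (And, Or)):
            for a in n.args:
                walk(a)

    walk(node)
    return tuple(seen)


def to_string(node: Expr, _parent: str = "") -> str:
    if isinstance(node, Var):
        return node.name
    if isinstance(node, Const):
        return str(node.value)
    if isinstance(node, Not):
        inner = to_string(node.arg, "NOT")
        return f"NOT {inner}"
    if isinstance(node, And):
        s = " AND ".join(to_string(a, "AND") for a in node.args)
        return f"({s})" if _parent in ("NOT",) else s
    if isinstance(node, Or):
        s = " OR ".join(to_string(a, "OR") for a in node.args)
        return f"({s})" if _parent in ("NOT", "AND") else s
    raise TypeError(type(node))


def eval_bool(node: Expr, env: Mapping[str, int]) -> int:
    if isinstance(node, Var):
        try:
            return int(env[node.name])
        except KeyError:
            raise ExprError(f"undefined variable {node.name!r}") from None
    if isinstance(node, Const):
        return node.value
    if isinstance(node, Not):
        return 1 - eval_bool(node.arg, env)
    if isinstance(node, And):
        return int(all(eval_bool(a, env) for a in node.args))
    if isinstance(node, Or):
        return int(any(eval_bool(a, env) for a in node.args))
    raise TypeError(type(node))


def eval_fuzzy(node: Expr, env: Mapping[str, np.ndarray | float]):
    """Evaluate with min/max/complement semantics on [0,1] levels.

    ``env`` values may be scalars or numpy arrays (broadcast together).
    On Boolean corners the result coincides with :func:`eval_bool`.
    """
    if isinstance(node, Var):
        try:
            return env[node.name]
        except KeyError:
            raise ExprError(f"undefined variable {node.name!r}") from None
    if isinstance(node, Const):
        return float(node.value)
    if isinstance(node, Not):
        return 1.0 - eval_fuzzy(node.arg, env)
    if isinstance(node, And):
        vals = [eval_fuzzy(a, env) for a in node.args]
        out = vals[0]
        for v in vals[1:]:
            out = np.minimum(out, v)
        return out
    if isinstance(node, Or):
        vals = [eval_fuzzy(a, env) for a in node.args]
        out = vals[0]
        for v in vals[1:]:
            out = np.maximum(out, v)
        return out
    raise TypeError(type(node))


def truth_table(node: Expr, inputs: tuple[str, ...]) -> np.ndarray:
    """Tabulate an expression over 2**k input rows.

    Rows enumerate the declared inputs most-significant-first: row 0 is
    all-zeros, the last row all-ones, and row ``r`` assigns input ``j``
    the bit ``(r >> (k-1-j)) & 1``.
    """
    k = len(inputs)
    free = set(variables(node)) - set(inputs)
    if free:
        raise ExprError(f"expression uses undeclared inputs: {sorted(free)}")
    out = np.zeros(2**k, dtype=np.uint8)
    for row in range(2**k):
        env = {name: (row >> (k - 1 - j)) & 1 for j, name in enumerate(inputs)}
        out[row] = eval_bool(node, env)
    return out


def dnf_from_table(inputs: tuple[str, ...], outputs: np.ndarray) -> Expr:
    """Minterm disjunctive normal form of a truth table.

    Used as a canonical expression for rules that were defined only as
    tables (e.g. after output-bit perturbations).
    """
    k = len(inputs)
    if len(outputs) != 2**k:
        raise ExprError("output vector length must be 2**k")
    ones = [r for r in range(2**k) if outputs[r]]
    if not ones:
        return Const(0)
    if len(ones) == 2**k:
        return Const(1)
    terms = []
    for row in ones:
        lits = []
        for j, name in enumerate(inputs):
            bit = (row >> (k - 1 - j)) & 1
            lits.append(Var(name) if bit else Not(Var(name)))
        terms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return terms[0] if len(terms) == 1 else Or(tuple(terms))
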