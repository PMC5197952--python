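"""Boolean threshold formulas over profile metrics.

Users screen positions with expressions such as::

    mism >= 0.1 AND (A >= 0.2 OR CSA >= 10)
    d_mism <= -0.2 AND cov1 >= 20 AND cov2 >= 20

Grammar: comparison atoms ``variable op constant`` with ops
``< <= > >= == !=``; logical operators with precedence
NOT > AND > XOR > OR, all left-associative; parentheses override.
Keywords are case-insensitive, variable names are not.

Comparisons against an undefined (NA) metric evaluate to false — screening
never flags positions whose metrics cannot be computed.  The ``ref``
variable compares against a base letter (``ref == A``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

SCALAR_VARIABLES = frozenset({
    "pos", "cov", "mism", "A", "CSA",
    "fA", "fC", "fG", "fT", "nA", "nC", "nG", "nT",
    "p", "p_adj",
})
BASE_VARIABLES = frozenset({"ref"})
DIFFERENTIAL_VARIABLES = frozenset({
    "d_mism", "d_A", "d_CSA",
    "cov1", "cov2", "mism1", "mism2", "A1", "A2", "CSA1", "CSA2",
})
ALL_VARIABLES = SCALAR_VARIABLES | BASE_VARIABLES | DIFFERENTIAL_VARIABLES

COMPARISON_OPS = ("<=", ">=", "==", "!=", "<", ">")


class FormulaError(ValueError):
    """Syntax or name error in a threshold formula."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


@dataclass(frozen=True)
class Comparison:
    variable: str
    op: str  # one of COMPARISON_OPS
    value: float | str  # str only for base-letter comparisons

    def __str__(self):
        return f"{self.variable} {self.op} {_fmt(self.value)}"


@dataclass(frozen=True)
class Logical:
    op: str  # AND | OR | XOR
    left: object
    right: object

    def __str__(self):
        return f"{_child(self.left, self.op)} {self.op} {_child(self.right, self.op)}"


@dataclass(frozen=True)
class Not:
    child: object

    def __str__(self):
        return f"NOT {_child(self.child, 'NOT')}"


_PRECEDENCE = {"OR": 0, "XOR": 1, "AND": 2, "NOT": 3}


def _fmt(v) -> str:
    return repr(float(v)) if isinstance(v, (int, float)) else str(v)


def _child(node, parent_op: str) -> str:
    # parenthesize children of strictly lower precedence; right-child ties
    # too, so the left-associative parse reproduces the same tree
    if isinstance(node, Logical) and _PRECEDENCE[node.op] <= _PRECEDENCE[parent_op]:
        return f"({node})"
    return str(node)


_TOKEN_RE = re.compile(r"""
    \s*(?:
      (?P<lpar>\()
    | (?P<rpar>\))
    | (?P<op><=|>=|==|!=|<|>)
    | (?P<num>[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?)
    | (?P<word>[A-Za-z_][A-Za-z0-9_]*)
    )""", re.VERBOSE)

_KEYWORDS = {"AND", "OR", "XOR", "NOT"}


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise FormulaError(f"unexpected character {stripped[0]!r}",
                               offset=len(text) - len(stripped))
        kind = m.lastgroup
        value = m.group(kind)
        offset = m.start(kind)
        if kind == "word" and value.upper() in _KEYWORDS:
            kind, value = "keyword", value.upper()
        tokens.append((kind, value, offset))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def take(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind, value=None):
        k, v, off = self.peek()
        if k != kind or (value is not None and v != value):
            want = value or kind
            raise FormulaError(f"expected {want!r}, found {v or 'end of input'!r}",
                               offset=off)
        return self.take()

    def parse(self):
        node = self.or_expr()
        k, v, off = self.peek()
        if k != "end":
            raise FormulaError(f"trailing input {v!r}", offset=off)
        return node

    def or_expr(self):
        node = self.xor_expr()
        while self.peek()[:2] == ("keyword", "OR"):
            self.take()
            node = Logical("OR", node, self.xor_expr())
        return node

    def xor_expr(self):
        node = self.and_expr()
        while self.peek()[:2] == ("keyword", "XOR"):
            self.take()
            node = Logical("XOR", node, self.and_expr())
        return node

    def and_expr(self):
        node = self.not_expr()
        while self.peek()[:2] == ("keyword", "AND"):
            self.take()
            node = Logical("AND", node, self.not_expr())
        return node

    def not_expr(self):
        if self.peek()[:2] == ("keyword", "NOT"):
            self.take()
            return Not(self.not_expr())
        return self.atom()

    def atom(self):
        k, v, off = self.peek()
        if k == "lpar":
            self.take()
            node = self.or_expr()
            self.expect("rpar")
            return node
        if k != "word":
            raise FormulaError(f"expected a variable or '(', found {v or 'end of input'!r}",
                               offset=off)
        _, var, var_off = self.take()
        if var not in ALL_VARIABLES:
            raise FormulaError(f"unknown variable {var!r}", offset=var_off)
        _, op, _ = self.expect("op")
        k, v, off = self.peek()
        if k == "num":
            self.take()
            value: float | str = float(v)
        elif k == "word" and var in BASE_VARIABLES and v.upper() in "ACGTN":
            self.take()
            value = v.upper()
        else:
            raise FormulaError(f"expected a constant, found {v or 'end of input'!r}",
                               offset=off)
        if var in BASE_VARIABLES and op not in ("==", "!="):
            raise FormulaError(f"base variable {var!r} supports only == and !=",
                               offset=var_off)
        return Comparison(var, op, value)


def parse_formula(text: str):
    """Parse a threshold formula into its syntax tree."""
    return _Parser(text).parse()


def serialize(node) -> str:
    """Formula text whose re-parse yields an identical tree."""
    return str(node)


def variables(node) -> set[str]:
    """All variable names referenced by a formula."""
    if isinstance(node, Comparison):
        return {node.variable}
    if isinstance(node, Not):
        return variables(node.child)
    return variables(node.left) | variables(node.right)


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


_OP_FUNCS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


def evaluate_formula(node, row) -> bool:
    """Evaluate a formula on a metric snapshot (mapping variable -> value).

    NA metrics make any comparison on them false; missing variables raise.
    """
    if isinstance(node, Comparison):
        if node.variable not in row:
            raise FormulaError(f"variable {node.variable!r} not available for this row")
        v = row[node.variable]
        if _is_na(v):
            return False
        return bool(_OP_FUNCS[node.op](v, node.value))
    if isinstance(node, Not):
        return not evaluate_formula(node.child, row)
    a = evaluate_formula(node.left, row)
    b = evaluate_formula(node.right, row)
    if node.op == "AND":
        return a and b
    if node.op == "OR":
        return a or b
    if node.op == "XOR":
        return a != b
    raise FormulaError(f"unknown logical operator {node.op!r}")
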