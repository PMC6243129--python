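"""A small deterministic expression language for model dynamics.

Expressions appear in derived variables, time derivatives, state assignments
and condition predicates.  The grammar covers identifiers, numeric literals,
``+ - * / ^``, unary minus, parentheses, the functions ``exp``, ``log``,
``sqrt`` and ``abs``, and — in predicates only — comparisons joined by
``and``.  Evaluation is a plain tree walk; dimension inference walks the same
tree so every well-typed expression has a well-defined physical dimension.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping

from .units import DIMENSIONLESS, Dimension


class ExpressionError(ValueError):
    """Raised for syntax errors, unknown symbols, or dimension mismatches."""


# ---------------------------------------------------------------- AST nodes


class Node:
    def evaluate(self, env: Mapping[str, float]) -> float:
        raise NotImplementedError

    def free_variables(self) -> set[str]:
        raise NotImplementedError

    def infer_dimension(self, dims: Mapping[str, Dimension]) -> Dimension:
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Num(Node):
    value: float

    def evaluate(self, env):
        return self.value

    def free_variables(self):
        return set()

    def infer_dimension(self, dims):
        return DIMENSIONLESS

    def to_text(self):
        return repr(self.value)


@dataclass(frozen=True)
class Var(Node):
    name: str

    def evaluate(self, env):
        try:
            return env[self.name]
        except KeyError:
            raise ExpressionError(f"unbound symbol {self.name!r}") from None

    def free_variables(self):
        return {self.name}

    def infer_dimension(self, dims):
        try:
            return dims[self.name]
        except KeyError:
            raise ExpressionError(f"symbol {self.name!r} has no dimension") from None

    def to_text(self):
        return self.name


@dataclass(frozen=True)
class Neg(Node):
    operand: Node

    def evaluate(self, env):
        return -self.operand.evaluate(env)

    def free_variables(self):
        return self.operand.free_variables()

    def infer_dimension(self, dims):
        return self.operand.infer_dimension(dims)

    def to_text(self):
        return f"(-{self.operand.to_text()})"


@dataclass(frozen=True)
class BinOp(Node):
    op: str  # + - * / ^
    left: Node
    right: Node

    def evaluate(self, env):
        a = self.left.evaluate(env)
        b = self.right.evaluate(env)
        if self.op == "+":
            return a + b
        if self.op == "-":
            return a - b
        if self.op == "*":
            return a * b
        if self.op == "/":
            return a / b
        if self.op == "^":
            return a ** b
        raise AssertionError(self.op)

    def free_variables(self):
        return self.left.free_variables() | self.right.free_variables()

    def infer_dimension(self, dims):
        dl = self.left.infer_dimension(dims)
        dr = self.right.infer_dimension(dims)
        if self.op in "+-":
            if dl != dr:
                raise ExpressionError(
                    f"dimension mismatch in {self.op!r}: {dl} vs {dr}"
                )
            return dl
        if self.op == "*":
            return dl * dr
        if self.op == "/":
            return dl / dr
        if self.op == "^":
            if not dl.is_dimensionless:
                if not isinstance(self.right, Num) or self.right.value != int(self.right.value):
                    raise ExpressionError("power of a dimensional quantity needs an integer literal exponent")
                return dl ** int(self.right.value)
            if not dr.is_dimensionless:
                raise ExpressionError("exponent must be dimensionless")
            return DIMENSIONLESS
        raise AssertionError(self.op)

    def to_text(self):
        return f"({self.left.to_text()} {self.op} {self.right.to_text()})"


_FUNCS = {"exp": math.exp, "log": math.log, "sqrt": math.sqrt, "abs": abs}


@dataclass(frozen=True)
class Call(Node):
    func: str
    arg: Node

    def evaluate(self, env):
        return _FUNCS[self.func](self.arg.evaluate(env))

    def free_variables(self):
        return self.arg.free_variables()

    def infer_dimension(self, dims):
        da = self.arg.infer_dimension(dims)
        if self.func == "abs":
            return da
        if not da.is_dimensionless:
            raise ExpressionError(f"{self.func}() requires a dimensionless argument, got {da}")
        return DIMENSIONLESS

    def to_text(self):
        return f"{self.func}({self.arg.to_text()})"


_CMP = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


@dataclass(frozen=True)
class Compare(Node):
    op: str
    left: Node
    right: Node

    def evaluate(self, env):
        return _CMP[self.op](self.left.evaluate(env), self.right.evaluate(env))

    def free_variables(self):
        return self.left.free_variables() | self.right.free_variables()

    def infer_dimension(self, dims):
        dl = self.left.infer_dimension(dims)
        dr = self.right.infer_dimension(dims)
        if dl != dr:
            raise ExpressionError(f"comparison of incompatible dimensions: {dl} vs {dr}")
        return DIMENSIONLESS  # boolean

    def to_text(self):
        return f"({self.left.to_text()} {self.op} {self.right.to_text()})"


@dataclass(frozen=True)
class And(Node):
    left: Node
    right: Node

    def evaluate(self, env):
        return bool(self.left.evaluate(env)) and bool(self.right.evaluate(env))

    def free_variables(self):
        return self.left.free_variables() | self.right.free_variables()

    def infer_dimension(self, dims):
        self.left.infer_dimension(dims)
        self.right.infer_dimension(dims)
        return DIMENSIONLESS

    def to_text(self):
        return f"({self.left.to_text()} and {self.right.to_text()})"


# ---------------------------------------------------------------- parser

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|==|!=|[-+*/^()<>]))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExpressionError(f"bad character {text[pos]!r} in expression {text!r}")
        pos = m.end()
        for kind in ("num", "name", "op"):
            v = m.group(kind)
            if v is not None:
                tokens.append((kind, v))
                break
    return tokens


class _Parser:
    """Recursive-descent parser.

    predicate := comparison ('and' comparison)*
    comparison := sum (cmpop sum)?
    sum := term (('+'|'-') term)*
    term := factor (('*'|'/') factor)*
    factor := ('-')* power
    power := atom ('^' factor)?        (right-associative)
    atom := number | name | func '(' predicate ')' | '(' predicate ')'
    """

    def __init__(self, text: str, allow_comparisons: bool):
        self.tokens = _tokenize(text)
        self.pos = 0
        self.allow_cmp = allow_comparisons
        self.text = text

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, value: str):
        kind, v = self.next()
        if v != value:
            raise ExpressionError(f"expected {value!r} in {self.text!r}, got {v!r}")

    def parse(self) -> Node:
        node = self.predicate()
        if self.pos != len(self.tokens):
            raise ExpressionError(f"trailing tokens in {self.text!r}")
        return node

    def predicate(self) -> Node:
        node = self.comparison()
        while self.peek() == ("name", "and"):
            if not self.allow_cmp:
                raise ExpressionError("'and' only allowed in predicates")
            self.next()
            node = And(node, self.comparison())
        return node

    def comparison(self) -> Node:
        node = self.sum()
        kind, v = self.peek()
        if kind == "op" and v in _CMP:
            if not self.allow_cmp:
                raise ExpressionError(f"comparison {v!r} only allowed in predicates")
            self.next()
            node = Compare(v, node, self.sum())
        return node

    def sum(self) -> Node:
        node = self.term()
        while self.peek()[1] in ("+", "-") and self.peek()[0] == "op":
            _, op = self.next()
            node = BinOp(op, node, self.term())
        return node

    def term(self) -> Node:
        node = self.factor()
        while self.peek()[1] in ("*", "/") and self.peek()[0] == "op":
            _, op = self.next()
            node = BinOp(op, node, self.factor())
        return node

    def factor(self) -> Node:
        if self.peek() == ("op", "-"):
            self.next()
            return Neg(self.factor())
        return self.power()

    def power(self) -> Node:
        node = self.atom()
        if self.peek() == ("op", "^"):
            self.next()
            node = BinOp("^", node, self.factor())
        return node

    def atom(self) -> Node:
        kind, v = self.next()
        if kind == "num":
            return Num(float(v))
        if kind == "name":
            if v in _FUNCS:
                self.expect("(")
                arg = self.predicate()
                self.expect(")")
                return Call(v, arg)
            if v == "and":
                raise ExpressionError(f"misplaced 'and' in {self.text!r}")
            return Var(v)
        if (kind, v) == ("op", "("):
            node = self.predicate()
            self.expect(")")
            return node
        raise ExpressionError(f"unexpected token {v!r} in {self.text!r}")


def parse_expression(text: str) -> Node:
    """Parse an arithmetic expression (no comparisons)."""
    return _Parser(text, allow_comparisons=False).parse()


def parse_predicate(text: str) -> Node:
    """Parse a boolean predicate: comparisons joined by ``and``."""
    return _Parser(text, allow_comparisons=True).parse()
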