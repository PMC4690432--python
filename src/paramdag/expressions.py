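"""Arithmetic expression language used for node-local assignments.

Grammar (recursive descent)::

    expr   := term (('+'|'-') term)*
    term   := factor (('*'|'/') factor)*
    factor := '-' factor | power
    power  := atom ('^' factor)?
    atom   := NUMBER | REF | '(' expr ')'
    REF    := IDENT ('@' IDENT)?
    IDENT  := [A-Za-z_][A-Za-z0-9_]*

``^`` is right-associative and binds tighter than unary minus, which binds
tighter than ``*``/``/``, which bind tighter than ``+``/``-``.

A reference ``k1@WT1`` names a value of key ``k1`` at node ``WT1``; the
reserved node name ``BASE`` addresses the base set.  A bare identifier
(``k1``) is represented with ``node=None`` (the BARE form) and denotes the
value the enclosing node would inherit for that key.

Function calls (``exp``, ``ln``, ...) are *not* part of the surface grammar:
they appear only in ASTs built from SBML MathML and are accepted by
:func:`evaluate` and :func:`to_string` so kinetic laws can share the AST.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Union

from .errors import ExprSyntaxError, MissingReference

#: reserved node name addressing the base set in references
BASE_NODE = "BASE"

#: sentinel used in the (key, node) pairs returned by :func:`references`
#: for bare identifiers
BARE = None


@dataclass(frozen=True)
class Num:
    value: float  # non-negative by construction; negatives are Neg(Num(..))


@dataclass(frozen=True)
class Ref:
    key: str
    node: str | None  # None = BARE, "BASE" = base set, else a node name


@dataclass(frozen=True)
class Neg:
    operand: "MathExpr"


@dataclass(frozen=True)
class BinOp:
    op: str  # one of + - * / ^
    left: "MathExpr"
    right: "MathExpr"


@dataclass(frozen=True)
class Call:
    """Function application; produced only by the SBML MathML reader."""

    name: str
    args: tuple


@dataclass(frozen=True)
class Time:
    """The simulation time symbol (SBML csymbol time)."""


MathExpr = Union[Num, Ref, Neg, BinOp, Call, Time]

IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>(?:\d+(?:\.\d*)?|\.\d+)(?:[eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op>[-+*/^@()])
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ExprSyntaxError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup != "ws":
            tokens.append((m.lastgroup, m.group(), pos))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    @property
    def cur(self):
        return self.tokens[self.i]

    def _advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def _expect_op(self, op: str):
        kind, text, pos = self.cur
        if kind != "op" or text != op:
            raise ExprSyntaxError(f"expected {op!r}", pos)
        self._advance()

    def parse(self) -> MathExpr:
        e = self.expr()
        kind, text, pos = self.cur
        if kind != "eof":
            raise ExprSyntaxError(f"unexpected token {text!r}", pos)
        return e

    def expr(self) -> MathExpr:
        e = self.term()
        while self.cur[0] == "op" and self.cur[1] in "+-":
            op = self._advance()[1]
            e = BinOp(op, e, self.term())
        return e

    def term(self) -> MathExpr:
        e = self.factor()
        while self.cur[0] == "op" and self.cur[1] in "*/":
            op = self._advance()[1]
            e = BinOp(op, e, self.factor())
        return e

    def factor(self) -> MathExpr:
        if self.cur[0] == "op" and self.cur[1] == "-":
            self._advance()
            return Neg(self.factor())
        return self.power()

    def power(self) -> MathExpr:
        e = self.atom()
        if self.cur[0] == "op" and self.cur[1] == "^":
            self._advance()
            e = BinOp("^", e, self.factor())
        return e

    def atom(self) -> MathExpr:
        kind, text, pos = self.cur
        if kind == "number":
            self._advance()
            return Num(float(text))
        if kind == "ident":
            self._advance()
            if self.cur[0] == "op" and self.cur[1] == "@":
                self._advance()
                nkind, ntext, npos = self.cur
                if nkind != "ident":
                    raise ExprSyntaxError("expected node name after '@'", npos)
                self._advance()
                return Ref(text, ntext)
            return Ref(text, BARE)
        if kind == "op" and text == "(":
            self._advance()
            e = self.expr()
            self._expect_op(")")
            return e
        raise ExprSyntaxError(f"unexpected token {text or '<end>'!r}", pos)


def parse(text: str) -> MathExpr:
    """Parse expression *text* into an AST.

    Raises :class:`~paramdag.errors.ExprSyntaxError` (with a character
    position) on malformed input.
    """
    if not text or not text.strip():
        raise ExprSyntaxError("empty expression", 0)
    return _Parser(text).parse()


def references(e: MathExpr) -> set[tuple[str, str | None]]:
    """The exact set of ``(key, node)`` reference leaves of *e*.

    Bare references are reported with ``node=None`` (:data:`BARE`).
    """
    return set(iter_references(e))


def iter_references(e: MathExpr) -> Iterator[tuple[str, str | None]]:
    """References in depth-first, left-to-right order (with duplicates)."""
    if isinstance(e, Ref):
        yield (e.key, e.node)
    elif isinstance(e, Neg):
        yield from iter_references(e.operand)
    elif isinstance(e, BinOp):
        yield from iter_references(e.left)
        yield from iter_references(e.right)
    elif isinstance(e, Call):
        for a in e.args:
            yield from iter_references(a)


_FUNCTIONS = {
    "exp": math.exp,
    "ln": math.log,
    "log": math.log10,
    "abs": abs,
    "sqrt": math.sqrt,
    "floor": math.floor,
    "ceil": math.ceil,
}


def evaluate(
    e: MathExpr,
    env: Mapping[tuple[str, str | None], float] | None = None,
    time: float | None = None,
) -> float:
    """Evaluate *e* with reference values taken from *env*.

    *env* maps ``(key, node)`` pairs — as returned by :func:`references` —
    to floats.  Raises :class:`MissingReference` when a reference is not
    covered and ``ArithmeticError`` for division by zero / domain errors.
    """
    env = env or {}
    if isinstance(e, Num):
        return e.value
    if isinstance(e, Ref):
        try:
            return float(env[(e.key, e.node)])
        except KeyError:
            label = e.key if e.node is None else f"{e.key}@{e.node}"
            raise MissingReference(f"no value for reference {label!r}") from None
    if isinstance(e, Neg):
        return -evaluate(e.operand, env, time)
    if isinstance(e, Time):
        if time is None:
            raise MissingReference("no value for the time symbol")
        return float(time)
    if isinstance(e, BinOp):
        lv = evaluate(e.left, env, time)
        rv = evaluate(e.right, env, time)
        if e.op == "+":
            return lv + rv
        if e.op == "-":
            return lv - rv
        if e.op == "*":
            return lv * rv
        if e.op == "/":
            return lv / rv  # ZeroDivisionError is an ArithmeticError
        if e.op == "^":
            try:
                result = lv**rv
            except (OverflowError, ValueError) as exc:
                raise ArithmeticError(str(exc)) from exc
            if isinstance(result, complex):
                raise ArithmeticError(
                    f"complex result for {lv} ^ {rv}"
                )
            return result
        raise ValueError(f"unknown operator {e.op!r}")
    if isinstance(e, Call):
        fn = _FUNCTIONS.get(e.name)
        if fn is None:
            raise MissingReference(f"unknown function {e.name!r}")
        args = [evaluate(a, env, time) for a in e.args]
        try:
            return float(fn(*args))
        except ValueError as exc:
            raise ArithmeticError(str(exc)) from exc
    raise TypeError(f"not a MathExpr node: {e!r}")


# precedence levels used by the printer
_ADD, _MUL, _UNARY, _POW, _ATOM = 1, 2, 3, 4, 5


def _level(e: MathExpr) -> int:
    if isinstance(e, BinOp):
        if e.op in "+-":
            return _ADD
        if e.op in "*/":
            return _MUL
        return _POW
    if isinstance(e, Neg):
        return _UNARY
    return _ATOM


def _fmt_number(v: float) -> str:
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def to_string(e: MathExpr) -> str:
    """Canonical text form with minimal parentheses.

    ``parse(to_string(e)) == e`` for every AST the surface grammar can
    produce (:class:`Call`/:class:`Time` nodes print readably but are not
    re-parseable — they exist only inside SBML math).
    """
    if isinstance(e, Num):
        return _fmt_number(e.value)
    if isinstance(e, Ref):
        return e.key if e.node is None else f"{e.key}@{e.node}"
    if isinstance(e, Time):
        return "time"
    if isinstance(e, Neg):
        s = to_string(e.operand)
        if _level(e.operand) < _UNARY:
            s = f"({s})"
        return f"-{s}"
    if isinstance(e, Call):
        return f"{e.name}({', '.join(to_string(a) for a in e.args)})"
    if isinstance(e, BinOp):
        lp = _level(e)
        ls = to_string(e.left)
        rs = to_string(e.right)
        if e.op == "^":
            # right-associative: parenthesise a left operand of equal level
            if _level(e.left) <= _POW:
                ls = f"({ls})"
            if _level(e.right) < _UNARY:
                rs = f"({rs})"
        else:
            if _level(e.left) < lp:
                ls = f"({ls})"
            # equal-level right child is parenthesised to preserve shape
            if _level(e.right) <= lp:
                rs = f"({rs})"
        return f"{ls} {e.op} {rs}" if e.op in "+-" else f"{ls}{e.op}{rs}"
    raise TypeError(f"not a MathExpr node: {e!r}")
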