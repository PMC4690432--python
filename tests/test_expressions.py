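import math
import random
import re

import pytest
from hypothesis import given, settings, strategies as hst

from paramdag import expressions as ex
from paramdag.errors import ExprSyntaxError, MissingReference


class TestParse:
    def test_ancestor_references(self):
        e = ex.parse("2*k1@P + 4*k2@G")
        assert ex.references(e) == {("k1", "P"), ("k2", "G")}

    def test_constant(self):
        e = ex.parse("150")
        assert e == ex.Num(150.0)
        assert ex.references(e) == set()

    def test_double_at_is_error(self):
        with pytest.raises(ExprSyntaxError):
            ex.parse("k1 @@ P")

    def test_error_carries_position(self):
        with pytest.raises(ExprSyntaxError) as err:
            ex.parse("1 + $")
        assert err.value.pos == 4

    def test_empty_is_error(self):
        with pytest.raises(ExprSyntaxError):
            ex.parse("   ")

    def test_trailing_garbage(self):
        with pytest.raises(ExprSyntaxError):
            ex.parse("1 + 2)")

    def test_scientific_notation(self):
        assert ex.parse("1.5e-3") == ex.Num(0.0015)
        assert ex.parse("2E4") == ex.Num(20000.0)

    def test_bare_reference(self):
        assert ex.references(ex.parse("2*k1")) == {("k1", None)}

    def test_two_parent_refs(self):
        assert ex.references(ex.parse("k1@WT1 + k1@WT2")) == {
            ("k1", "WT1"), ("k1", "WT2")
        }


class TestPrecedence:
    @pytest.mark.parametrize("text,value", [
        ("1 + 2*3", 7.0),
        ("2*3 ^ 2", 18.0),        # ^ binds tighter than *
        ("-2^2", -4.0),           # ^ binds tighter than unary minus
        ("(-2)^2", 4.0),
        ("2^-1", 0.5),
        ("2^3^2", 512.0),         # right-associative
        ("8 - 3 - 2", 3.0),       # left-associative
        ("8/4/2", 1.0),
        ("-3 + 5", 2.0),
        ("--4", 4.0),
    ])
    def test_cases(self, text, value):
        assert ex.evaluate(ex.parse(text)) == pytest.approx(value)


class TestEvaluate:
    def test_parent_sum(self):
        e = ex.parse("k1@WT1 + k1@WT2")
        assert ex.evaluate(e, {("k1", "WT1"): 2, ("k1", "WT2"): 4}) == 6.0

    def test_two_ancestors(self):
        e = ex.parse("2*x@P + 4*y@G")
        assert ex.evaluate(e, {("x", "P"): 1, ("y", "G"): 1}) == 6.0

    def test_division_by_zero(self):
        with pytest.raises(ArithmeticError):
            ex.evaluate(ex.parse("1/k@P"), {("k", "P"): 0})

    def test_missing_reference(self):
        with pytest.raises(MissingReference):
            ex.evaluate(ex.parse("k@P"), {})

    def test_complex_power_rejected(self):
        with pytest.raises(ArithmeticError):
            ex.evaluate(ex.parse("(0 - 1)^0.5"))


# --- round trip property ---------------------------------------------------

_idents = hst.from_regex(re.compile(r"\A[A-Za-z_][A-Za-z0-9_]{0,5}\Z"))
_numbers = hst.floats(
    min_value=0, max_value=1e6, allow_nan=False, allow_infinity=False
)


def _asts(depth=3):
    leaf = hst.one_of(
        _numbers.map(ex.Num),
        hst.tuples(_idents, hst.one_of(hst.none(), _idents)).map(
            lambda kn: ex.Ref(*kn)
        ),
    )
    return hst.recursive(
        leaf,
        lambda inner: hst.one_of(
            inner.map(ex.Neg),
            hst.tuples(
                hst.sampled_from("+-*/^"), inner, inner
            ).map(lambda t: ex.BinOp(*t)),
        ),
        max_leaves=12,
    )


@settings(max_examples=200, deadline=None)
@given(_asts())
def test_print_parse_round_trip(ast):
    assert ex.parse(ex.to_string(ast)) == ast


# --- independent shunting-yard comparison ----------------------------------

_PREC = {"+": (1, "L"), "-": (1, "L"), "*": (2, "L"), "/": (2, "L"),
         "u-": (3, "R"), "^": (4, "R")}


def _shunting_yard_eval(text: str) -> float:
    tokens = re.findall(r"\d+(?:\.\d+)?(?:[eE][+-]?\d+)?|[-+*/^()]", text)
    output: list[float] = []
    ops: list[str] = []

    def apply(op: str):
        if op == "u-":
            output.append(-output.pop())
            return
        b, a = output.pop(), output.pop()
        output.append({
            "+": a + b, "-": a - b, "*": a * b, "/": a / b, "^": a**b,
        }[op])

    expect_operand = True
    for tok in tokens:
        if re.match(r"\d", tok):
            output.append(float(tok))
            expect_operand = False
        elif tok == "(":
            ops.append(tok)
            expect_operand = True
        elif tok == ")":
            while ops[-1] != "(":
                apply(ops.pop())
            ops.pop()
            expect_operand = False
        else:
            op = "u-" if (tok == "-" and expect_operand) else tok
            prec, assoc = _PREC[op]
            while ops and ops[-1] != "(":
                tprec, _ = _PREC[ops[-1]]
                if tprec > prec or (tprec == prec and assoc == "L"):
                    apply(ops.pop())
                else:
                    break
            ops.append(op)
            expect_operand = True
    while ops:
        apply(ops.pop())
    assert len(output) == 1
    return output[0]


def _random_expr_text(rng: random.Random, depth: int) -> str:
    if depth == 0 or rng.random() < 0.3:
        return f"{rng.uniform(0.5, 9):.4f}"
    kind = rng.random()
    a = _random_expr_text(rng, depth - 1)
    b = _random_expr_text(rng, depth - 1)
    if kind < 0.15:
        return f"(-{a})"
    if kind < 0.3:
        return f"({a})"
    op = rng.choice(["+", "-", "*", "/"])
    if rng.random() < 0.1:
        op = "^"
        b = f"{rng.uniform(0.5, 2):.3f}"
    return f"{a} {op} {b}"


def test_evaluate_matches_shunting_yard():
    rng = random.Random(20240901)
    checked = 0
    for _ in range(1000):
        text = _random_expr_text(rng, 4)
        try:
            expected = _shunting_yard_eval(text)
        except (ArithmeticError, OverflowError):
            continue
        if isinstance(expected, complex) or not math.isfinite(expected):
            continue  # e.g. (-x)^0.5; engine raises, oracle goes complex
        got = ex.evaluate(ex.parse(text))
        assert got == pytest.approx(expected, rel=1e-12)
        checked += 1
    assert checked > 900


def test_to_string_minimal_parens():
    assert ex.to_string(ex.parse("2*k1@P + 4*k2@G")) == "2*k1@P + 4*k2@G"
    assert ex.to_string(ex.parse("(1+2)*3")) == "(1 + 2)*3"
    assert ex.to_string(ex.parse("1+(2*3)")) == "1 + 2*3"
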