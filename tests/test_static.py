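"""Static update-function properties against exhaustive table filters."""

import itertools

import pytest

import bnsketch as bs
from bnsketch import static_properties as sp
from bnsketch.encoding import row_bit
from conftest import make_ctx


def count(ctx, colour_set):
    return ctx.bdd.count(colour_set, ctx.param_levels())


def unary_ctx():
    return make_ctx({"v": "g(u)", "u": "0"}, [("u", "v")], ("u", "v"))


def binary_ctx():
    return make_ctx(
        {"v": "g(u, w)", "u": "0", "w": "0"},
        [("u", "v"), ("w", "v")],
        ("u", "v", "w"),
    )


# -- independent exhaustive filters (the oracle for every count below) ------


def tables(arity):
    return itertools.product((0, 1), repeat=1 << arity)


def essential_in(table, arity, i):
    bit = 1 << (arity - 1 - i)
    return any(
        table[row] != table[row | bit]
        for row in range(1 << arity)
        if not row_bit(row, i, arity)
    )


def monotone_in(table, arity, i, direction="positive"):
    bit = 1 << (arity - 1 - i)
    rows = [r for r in range(1 << arity) if not row_bit(r, i, arity)]
    if direction == "positive":
        return all(table[r] <= table[r | bit] for r in rows)
    return all(table[r] >= table[r | bit] for r in rows)


class TestRegulationProperties:
    def test_essentiality_of_unconstrained_unary_symbol(self):
        ctx = unary_ctx()
        got = count(ctx, sp.essentiality_of_regulation(ctx, "u", "v"))
        expected = sum(essential_in(t, 1, 0) for t in tables(1))
        assert got == expected == 2

    def test_fixed_function_with_essential_input_is_full_space(self):
        ctx = make_ctx(
            {"v": "u | w", "u": "0", "w": "0"},
            [("u", "v"), ("w", "v")],
            ("u", "v", "w"),
        )
        assert sp.essentiality_of_regulation(ctx, "u", "v") == 1  # TRUE

    def test_never_read_regulator_gives_empty_set(self):
        ctx = make_ctx(
            {"v": "w", "u": "0", "w": "0"},
            [("u", "v"), ("w", "v")],
            ("u", "v", "w"),
        )
        assert sp.essentiality_of_regulation(ctx, "u", "v") == 0  # FALSE

    def test_monotonicity_of_unary_symbol(self):
        ctx = unary_ctx()
        got = count(ctx, sp.monotonicity_of_regulation(ctx, "u", "v", "positive"))
        expected = sum(monotone_in(t, 1, 0) for t in tables(1))
        assert got == expected == 3

    def test_monotone_in_both_arguments(self):
        ctx = binary_ctx()
        both = ctx.bdd.and_(
            sp.monotonicity_of_regulation(ctx, "u", "v", "positive"),
            sp.monotonicity_of_regulation(ctx, "w", "v", "positive"),
        )
        expected = sum(
            monotone_in(t, 2, 0) and monotone_in(t, 2, 1) for t in tables(2)
        )
        assert count(ctx, both) == expected == 6

    def test_undeclared_regulation_raises(self):
        ctx = unary_ctx()
        with pytest.raises(ValueError, match="not declared"):
            sp.essentiality_of_regulation(ctx, "v", "u")

    def test_negative_monotonicity_on_compound_expression(self):
        # v := !u & w is negative in u, positive in w, for every colour
        ctx = make_ctx(
            {"v": "!u & w", "u": "0", "w": "0"},
            [("u", "v"), ("w", "v")],
            ("u", "v", "w"),
        )
        assert sp.monotonicity_of_regulation(ctx, "u", "v", "negative") == 1
        assert sp.monotonicity_of_regulation(ctx, "u", "v", "positive") == 0


class TestSymbolProperties:
    def test_essential_both_arguments(self):
        ctx = binary_ctx()
        both = ctx.bdd.and_(
            sp.symbol_arg_essential(ctx, "g", 0),
            sp.symbol_arg_essential(ctx, "g", 1),
        )
        expected = sum(
            essential_in(t, 2, 0) and essential_in(t, 2, 1) for t in tables(2)
        )
        assert count(ctx, both) == expected == 10

    def test_monotone_and_essential_leaves_and_or(self):
        ctx = binary_ctx()
        props = [
            sp.symbol_arg_essential(ctx, "g", 0),
            sp.symbol_arg_essential(ctx, "g", 1),
            sp.symbol_arg_monotone(ctx, "g", 0, "positive"),
            sp.symbol_arg_monotone(ctx, "g", 1, "positive"),
        ]
        assert count(ctx, ctx.bdd.and_many(props)) == 2  # AND and OR

    @pytest.mark.parametrize("arity,expected", [(1, 3), (2, 6), (3, 20), (4, 168)])
    def test_all_argument_monotone_closed_forms(self, arity, expected):
        """Counts of all-argument monotone tables, against the exhaustive filter."""
        variables = tuple(f"u{i}" for i in range(arity)) + ("v",)
        args = ", ".join(sorted(f"u{i}" for i in range(arity)))
        updates = {f"u{i}": "0" for i in range(arity)}
        updates["v"] = f"g({args})" if arity else "g()"
        ctx = make_ctx(updates, [(f"u{i}", "v") for i in range(arity)], variables)
        monotone_all = ctx.bdd.and_many(
            sp.symbol_arg_monotone(ctx, "g", i, "positive") for i in range(arity)
        )
        brute = sum(
            all(monotone_in(t, arity, i) for i in range(arity))
            for t in tables(arity)
        )
        assert count(ctx, monotone_all) == brute == expected

    def test_index_out_of_range(self):
        ctx = unary_ctx()
        with pytest.raises(ValueError, match="out of range"):
            sp.symbol_arg_essential(ctx, "g", 1)

    def test_regulation_and_symbol_views_coincide_for_plain_application(self):
        # update(v) is exactly g(regulators in order), so both definitions agree
        ctx = binary_ctx()
        assert sp.monotonicity_of_regulation(
            ctx, "u", "v", "positive"
        ) == sp.symbol_arg_monotone(ctx, "g", 0, "positive")
        assert sp.essentiality_of_regulation(
            ctx, "w", "v"
        ) == sp.symbol_arg_essential(ctx, "g", 1)


class TestFol:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("forall a: g(a, 1)", 4),       # p[g,01] and p[g,11] forced
            ("forall a: forall b: (g(a, b) <=> g(b, a))", 8),  # symmetric tables
            ("exists a: exists b: g(a, b)", 15),               # not constant-0
        ],
    )
    def test_binary_symbol_formulas(self, text, expected):
        ctx = binary_ctx()
        got = count(ctx, sp.compile_fol(sp.parse_fol(text), ctx))
        assert got == expected

    def test_unary_exists(self):
        ctx = unary_ctx()
        assert count(ctx, sp.compile_fol(sp.parse_fol("exists a: g(a)"), ctx)) == 3

    def test_matches_exhaustive_evaluation(self):
        from bnsketch.reference import _eval_fol

        ctx = binary_ctx()
        ast = sp.parse_fol("exists a: forall b: (g(a, b) => g(b, a)) ^ g(1, b)")
        compiled = sp.compile_fol(ast, ctx)
        for table in tables(2):
            colour = ctx.space.colour_from_tables({"g": table})
            explicit = _eval_fol(ast, {}, {"g": table})
            assert ctx.bdd.evaluate(compiled, ctx.colour_levels(colour)) == explicit

    def test_conjunction_equals_conjoined_formula(self):
        ctx = binary_ctx()
        one = sp.compile_fol(sp.parse_fol("forall a: g(a, 1)"), ctx)
        two = sp.compile_fol(sp.parse_fol("exists a: g(a, 0)"), ctx)
        joint = sp.compile_fol(
            sp.parse_fol("(forall a: g(a, 1)) & (exists a: g(a, 0))"), ctx
        )
        assert ctx.bdd.and_(one, two) == joint

    def test_free_variable_rejected(self):
        ctx = unary_ctx()
        with pytest.raises(ValueError, match="free variable"):
            sp.compile_fol(sp.parse_fol("g(a)"), ctx)

    def test_state_variables_rejected(self):
        ctx = unary_ctx()
        with pytest.raises(ValueError, match="free variable 'u'"):
            sp.compile_fol(sp.parse_fol("forall a: g(a) & u"), ctx)

    def test_arity_mismatch_rejected(self):
        ctx = unary_ctx()
        with pytest.raises(ValueError, match="arity"):
            sp.compile_fol(sp.parse_fol("forall a: forall b: g(a, b)"), ctx)
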