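"""Parameter-space layout, symbolic compilation and instantiation."""

import itertools

import pytest

import bnsketch as bs
from bnsketch import expressions as ex
from bnsketch.encoding import (
    Colour,
    SymbolicContext,
    build_parameter_space,
    instantiate,
)
from conftest import make_ctx


def psbn_of(updates, regulations, variables, symbols=()):
    return bs.build_psbn(bs.InfluenceGraph(variables, regulations), updates, symbols)


class TestParameterSpace:
    @pytest.mark.parametrize(
        "arities,total",
        [((2,), 4), ((1, 3), 10), ((0,), 1), ((0, 0, 2), 6)],
    )
    def test_bit_totals(self, arities, total):
        symbols = tuple(bs.FunctionSymbol(f"g{i}", a) for i, a in enumerate(arities))
        variables = tuple(f"v{i}" for i in range(len(arities)))
        updates = {}
        for i, (v, s) in enumerate(zip(variables, symbols)):
            args = ", ".join(variables[: s.arity])
            updates[v] = f"{s.name}({args})"
        regs = [
            (u, v)
            for v, s in zip(variables, symbols)
            for u in variables[: s.arity]
        ]
        psbn = psbn_of(updates, regs, variables, symbols)
        space = build_parameter_space(psbn)
        assert space.total_bits == total
        assert space.n_interpretations == 1 << total

    def test_blocks_are_disjoint_and_sorted_by_name(self):
        psbn = psbn_of(
            {"a": "z(a)", "b": "f(b)"},
            [("a", "a"), ("b", "b")],
            ("a", "b"),
            (bs.FunctionSymbol("z", 1), bs.FunctionSymbol("f", 1)),
        )
        space = build_parameter_space(psbn)
        assert space.bit_names() == ["f[0]", "f[1]", "z[0]", "z[1]"]

    def test_arity_cap_guard(self):
        psbn = psbn_of(
            {"v": "g(v)"}, [("v", "v")], ("v",), (bs.FunctionSymbol("g", 17),)
        )
        # declared arity disagrees with the use here, but the cap fires first
        with pytest.raises(ValueError, match="cap"):
            build_parameter_space(psbn)


class TestSymbolicUpdate:
    def test_fixed_expression_is_parameter_free(self):
        ctx = make_ctx(
            {"v": "A & !B", "A": "0", "B": "0"},
            [("A", "v"), ("B", "v")],
            ("A", "B", "v"),
        )
        f = ctx.update_function("v")
        assert ctx.bdd.support(f) == {ctx.state_level("A"), ctx.state_level("B")}
        for a, b in itertools.product((0, 1), repeat=2):
            value = ctx.bdd.evaluate(
                f, {ctx.state_level("A"): bool(a), ctx.state_level("B"): bool(b)}
            )
            assert value == (a == 1 and b == 0)

    def test_unary_multiplexer_structure(self, unary_symbol_ctx):
        ctx = unary_symbol_ctx
        b = ctx.bdd
        expected = b.or_(
            b.and_(b.not_(b.var("x")), b.var("g_x[0]")),
            b.and_(b.var("x"), b.var("g_x[1]")),
        )
        assert ctx.update_function("x") == expected

    def test_instantiated_multiplexer_example(self):
        # v := g(A) | B at colour g = !A gives !A | B
        ctx = make_ctx(
            {"v": "g(A) | B", "A": "0", "B": "0"},
            [("A", "v"), ("B", "v")],
            ("A", "B", "v"),
        )
        colour = ctx.space.colour_from_tables({"g": (1, 0)})
        bn = instantiate(ctx.psbn, colour, ctx.space)
        # table over (A, B): !A | B is 1,1,0,1 in row order 00,01,10,11
        assert bn.tables["v"] == (1, 1, 0, 1)

    def test_pure(self, unary_symbol_ctx):
        assert unary_symbol_ctx.compile_expr(
            unary_symbol_ctx.psbn.update["x"]
        ) == unary_symbol_ctx.compile_expr(unary_symbol_ctx.psbn.update["x"])


class TestInstantiate:
    def test_all_zero_colour_gives_constant_false(self, unary_symbol_ctx):
        ctx = unary_symbol_ctx
        bn = instantiate(ctx.psbn, Colour((0, 0)), ctx.space)
        assert bn.tables["x"] == (0, 0)

    def test_round_trip_through_fixed_expressions(self, unary_symbol_ctx):
        from bnsketch.encoding import concrete_to_psbn

        ctx = unary_symbol_ctx
        bn = instantiate(ctx.psbn, Colour((0, 1)), ctx.space)
        fixed = concrete_to_psbn(bn, ctx.psbn.graph)
        assert build_parameter_space(fixed).n_interpretations == 1

    def test_agrees_with_symbolic_update_exhaustively(self):
        # 3 variables, 6 parameter bits: check every (state, colour) pair
        psbn = psbn_of(
            {"a": "g(b)", "b": "h(a, c)", "c": "a & b"},
            [("b", "a"), ("a", "b"), ("c", "b"), ("a", "c"), ("b", "c")],
            ("a", "b", "c"),
        )
        ctx = SymbolicContext(psbn)
        assert ctx.space.total_bits == 6
        for value in range(1 << 6):
            colour = Colour(
                tuple((value >> i) & 1 for i in range(6))
            )
            bn = instantiate(psbn, colour, ctx.space)
            assignment = ctx.colour_levels(colour)
            for bits in itertools.product((0, 1), repeat=3):
                state = dict(zip(("a", "b", "c"), bits))
                full = {**assignment, **ctx.state_levels_assignment(state)}
                for v in ("a", "b", "c"):
                    assert (
                        ctx.bdd.evaluate(ctx.update_function(v), full)
                        == bn.value(v, state)
                    ), (value, bits, v)

    def test_shared_symbol_agrees_across_variables(self):
        psbn = psbn_of(
            {"a": "g(b)", "b": "g(a)"},
            [("b", "a"), ("a", "b")],
            ("a", "b"),
        )
        space = build_parameter_space(psbn)
        assert space.total_bits == 2
        for value in range(4):
            colour = Colour(((value >> 0) & 1, (value >> 1) & 1))
            bn = instantiate(psbn, colour, space)
            table = space.table_of(colour, "g")
            assert bn.tables["a"] == (table[0], table[1])
            assert bn.tables["b"] == (table[0], table[1])

    def test_nested_applications_compose(self):
        psbn = psbn_of(
            {"a": "g(h(a), b)", "b": "0"},
            [("a", "a"), ("b", "a")],
            ("a", "b"),
        )
        space = build_parameter_space(psbn)
        assert space.total_bits == 4 + 2
        colour = space.colour_from_tables({"g": (0, 1, 1, 0), "h": (1, 0)})
        bn = instantiate(psbn, colour, space)
        # g = xor, h = not: a' = xor(!a, b) over rows (a,b) = 00,01,10,11
        assert bn.tables["a"] == (1, 0, 0, 1)
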