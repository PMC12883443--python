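"""HCTL parsing, symbolic checking, templates, and the operator battery."""

import itertools
import random

import pytest

import bnsketch as bs
from bnsketch import hctl
from bnsketch.encoding import Colour, SymbolicContext, instantiate
from bnsketch.reference import build_explicit_stg, explicit_check_hctl
from conftest import make_ctx
from test_dynamics import random_psbn, state_cube, states_of


class TestParser:
    def test_universally_reachable_state_formula(self):
        formula = hctl.parse_hctl("3{x}: @{x}: (AG (EF {x}))")
        assert formula == hctl.Exists(
            "x",
            hctl.Jump(
                "x", hctl.Temporal("AG", hctl.Temporal("EF", hctl.StateVar("x")))
            ),
        )

    def test_unbound_state_variable_is_a_scoping_error(self):
        formula = hctl.parse_hctl("~{x}")
        with pytest.raises(ValueError, match="not bound"):
            hctl.check_scoping(formula)

    def test_rebinding_on_one_path_is_rejected(self):
        formula = hctl.parse_hctl("3{x}: 3{x}: {x}")
        with pytest.raises(ValueError, match="bound twice"):
            hctl.check_scoping(formula)

    def test_closed_ctl_formula(self):
        formula = hctl.parse_hctl("EF (v & !w)".replace("!", "~"))
        assert formula == hctl.Temporal(
            "EF", hctl.HBin("&", hctl.Atom("v", True), hctl.Atom("w", False))
        )
        hctl.check_scoping(formula)  # no state variables: fine

    @pytest.mark.parametrize(
        "text",
        [
            "3{x}: @{x}: (AG (EF {x}))",
            "!{y}: AG EF {y}",
            "(a EU b) & AF c",
            "~a => EX (b AU ~c)",
            "3{x}: @{x}: ((EF {x}) & a)",
        ],
    )
    def test_print_parse_round_trip(self, text):
        formula = hctl.parse_hctl(text)
        assert hctl.parse_hctl(hctl.to_text(formula)) == formula

    @pytest.mark.parametrize("text", ["EF", "{x", "a &", "@{x} a", "(a EU)", "3{x}"])
    def test_syntax_errors(self, text):
        with pytest.raises(ValueError):
            hctl.parse_hctl(text)


class TestCheck:
    def test_true_is_the_full_space(self, unary_symbol_ctx):
        assert hctl.check(hctl.parse_hctl("true"), unary_symbol_ctx) == 1

    def test_attractor_existence_holds_everywhere(self):
        # every finite transition graph has a terminal SCC
        formula = hctl.parse_hctl("3{x}: @{x}: (AG (EF {x}))")
        for updates in ({"x": "x"}, {"x": "~x"}):
            ctx = make_ctx(updates, [("x", "x")], ("x",))
            assert hctl.check(formula, ctx) == 1

    def test_self_attractor_binder_selects_fixed_points(self, identity_ctx):
        ctx = identity_ctx
        result = hctl.check(hctl.parse_hctl("!{x}: AG EF {x}"), ctx)
        assert result == 1  # both states are singleton attractors
        ctx2 = make_ctx({"a": "b", "b": "b"}, [("b", "a"), ("b", "b")], ("a", "b"))
        result2 = hctl.check(hctl.parse_hctl("!{x}: AG EF {x}"), ctx2)
        # a := b, b := b: attractors are the two states with a == b
        assert states_of(ctx2, result2) == {(0, 0), (1, 1)}

    def test_deadlock_conventions(self, identity_ctx):
        ctx = identity_ctx
        # no successors: EX true is false, AX false is (vacuously) true
        assert hctl.check(hctl.parse_hctl("EX true"), ctx) == 0
        assert hctl.check(hctl.parse_hctl("AX false"), ctx) == 1


class TestSatisfyingColours:
    def test_true_gives_full_colour_space(self, unary_symbol_ctx):
        assert hctl.satisfying_colours(hctl.parse_hctl("true"), unary_symbol_ctx) == 1

    def test_fixed_point_with_observation(self, unary_symbol_ctx):
        ctx = unary_symbol_ctx
        dataset = bs.Dataset("d", (bs.Observation("o", {"x": 1}),), "steady_state")
        formula = hctl.build_template(bs.FixedPointsTemplate("d"), [dataset])
        colours = hctl.satisfying_colours(formula, ctx)
        # exactly the colours with p[g,1] = 1
        assert colours == ctx.bdd.var("g_x[1]")

    def test_state_dependent_formula_warns_and_quantifies_universally(self):
        ctx = make_ctx({"v": "v"}, [("v", "v")], ("v",))
        formula = hctl.parse_hctl("AG (EF v)")
        with pytest.warns(UserWarning, match="depends on state bits"):
            # v=1 is unreachable from v=0, so no colour satisfies it everywhere
            assert hctl.satisfying_colours(formula, ctx) == 0

    def test_free_state_variable_is_an_error(self, unary_symbol_ctx):
        with pytest.raises(ValueError, match="not bound"):
            hctl.satisfying_colours(hctl.parse_hctl("EF {x}"), unary_symbol_ctx)


class TestTemplates:
    def test_fixed_points_on_identity_network(self, identity_ctx):
        dataset = bs.Dataset("d", (bs.Observation("o", {"x": 1}),), "steady_state")
        formula = hctl.build_template(bs.FixedPointsTemplate("d"), [dataset])
        assert hctl.satisfying_colours(formula, identity_ctx) == 1

    def test_time_series_on_toggle(self, toggle_ctx):
        dataset = bs.Dataset(
            "d",
            (bs.Observation("o1", {"x": 0}), bs.Observation("o2", {"x": 1})),
            "time_series",
        )
        formula = hctl.build_template(bs.TimeSeriesTemplate("d"), [dataset])
        assert hctl.satisfying_colours(formula, toggle_ctx) == 1

    def test_attractor_count_exact(self, identity_ctx, toggle_ctx):
        exactly_two = bs.AttractorCountTemplate(2, 2)
        formula = hctl.build_template(exactly_two, [])
        assert hctl.satisfying_colours(formula, identity_ctx) == 1  # two fixed points
        assert hctl.satisfying_colours(formula, toggle_ctx) == 0  # one cycle

        exactly_one = hctl.build_template(bs.AttractorCountTemplate(1, 1), [])
        assert hctl.satisfying_colours(exactly_one, toggle_ctx) == 1

    def test_attractor_count_cap(self):
        with pytest.raises(ValueError, match="exceeds the supported maximum"):
            hctl.build_template(bs.AttractorCountTemplate(9, None), [])

    def test_coverage_separates_oscillation_from_fixed_points(
        self, identity_ctx, toggle_ctx
    ):
        """'Only fixed points, no complex attractors' as attractor coverage
        over the fixed-point observations."""
        fp_dataset = bs.Dataset(
            "fp",
            (bs.Observation("o0", {"x": 0}), bs.Observation("o1", {"x": 1})),
            "steady_state",
        )
        formula = hctl.build_template(bs.AttractorCoverageTemplate("fp"), [fp_dataset])
        assert hctl.satisfying_colours(formula, identity_ctx) == 1
        empty = bs.Dataset("fp", (), "steady_state")
        formula2 = hctl.build_template(bs.AttractorCoverageTemplate("fp"), [empty])
        assert hctl.satisfying_colours(formula2, toggle_ctx) == 0

    def test_empty_dataset_rejected_where_meaningless(self):
        empty = bs.Dataset("d", (), "steady_state")
        for template in (bs.FixedPointsTemplate("d"), bs.TimeSeriesTemplate("d")):
            with pytest.raises(ValueError, match="empty"):
                hctl.build_template(template, [empty])


# ---------------------------------------------------------------------------
# operator battery: symbolic vs explicit, every operator, nesting <= 3

BATTERY = [
    "EX v0",
    "AX (v0 | v1)",
    "EF (v0 & ~v1)",
    "AF v2",
    "EG (v0 => v1)",
    "AG (EF v3)",
    "(v0 EU (v1 & v2))",
    "((~v0) AU v1)",
    "~(v0 <=> EX v1)",
    "EF (EG v1)",
    "3{x}: @{x}: (AG (EF {x}))",
    "3{x}: @{x}: (v0 & (EF (v1 & {x})))",
    "!{x}: AG EF {x}",
    "!{x}: EX {x}",
    "!{x}: AX (EF {x})",
    "3{x}: ((EF {x}) & @{x}: v2)",
    "3{x}: @{x}: ((~v0) AU (v1 | {x}))",
    "AG (v0 => (3{x}: @{x}: (v1 & EF {x})))",
]


def test_symbolic_and_explicit_checking_agree_on_random_instances():
    """Per-colour agreement of the two model checkers for every operator."""
    rng = random.Random(2024)
    for _ in range(6):
        psbn = random_psbn(rng, n_vars=4, max_param_bits=4)
        ctx = SymbolicContext(psbn)
        nbits = ctx.space.total_bits
        formulas = [hctl.parse_hctl(text) for text in BATTERY]
        symbolic = [hctl.check(f, ctx) for f in formulas]
        for value in range(1 << nbits):
            colour = Colour(tuple((value >> i) & 1 for i in range(nbits)))
            stg = build_explicit_stg(instantiate(psbn, colour, ctx.space))
            assignment = ctx.colour_levels(colour)
            for text, formula, result in zip(BATTERY, formulas, symbolic):
                explicit = explicit_check_hctl(formula, stg)
                got = {
                    stg.assignment_state(
                        dict(zip(ctx.state_variables, bits))
                    )
                    for bits in states_of(ctx, result, assignment)
                }
                assert got == explicit, (text, colour.bits)
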