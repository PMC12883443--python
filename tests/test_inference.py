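"""Inference orchestration: counts, sampling, summaries, persistence."""

import itertools
import random

import pytest

import bnsketch as bs
from bnsketch import reference
from bnsketch.inference import (
    SketchError,
    count_candidates,
    export_candidate_set,
    import_candidate_set,
    run_inference,
    sample_candidates,
    sample_colour,
    summarize_variants,
)


def unary_sketch(**kwargs):
    psbn = bs.build_psbn(bs.InfluenceGraph(("x",), [("x", "x")]))
    return bs.Sketch(psbn=psbn, **kwargs)


def fixed_point_sketch(value=1, extra_static=()):
    return unary_sketch(
        datasets=(
            bs.Dataset("d", (bs.Observation("o", {"x": value}),), "steady_state"),
        ),
        dynamic_properties=(bs.FixedPointsTemplate("d"),),
        static_properties=tuple(extra_static),
    )


class TestRunInference:
    def test_no_properties_gives_full_space(self):
        candidate_set, report = run_inference(unary_sketch())
        assert count_candidates(candidate_set) == 4
        assert report.n_interpretations == 4 and report.steps == []

    def test_fixed_point_observation(self):
        candidate_set, report = run_inference(fixed_point_sketch())
        assert count_candidates(candidate_set) == 2
        assert report.steps[-1][1] == 2
        # surviving colours are exactly those with p[g,1] = 1
        for bits in itertools.product((0, 1), repeat=2):
            assert candidate_set.contains(bs.Colour(bits)) == (bits[1] == 1)

    def test_contradiction_yields_empty_set_not_an_error(self):
        sketch = fixed_point_sketch(extra_static=(bs.FolFormula("forall a: !g_x(a)"),))
        candidate_set, report = run_inference(sketch)
        assert count_candidates(candidate_set) == 0
        assert report.variant_counts == {"x": 0}

    def test_validation_errors_are_raised(self):
        from bnsketch import expressions as ex

        psbn = bs.PSBN(
            graph=bs.InfluenceGraph(("v",), []),
            symbols=(),
            update={"v": ex.parse_expression("nosuch")},
        )
        with pytest.raises(SketchError, match="nosuch"):
            run_inference(bs.Sketch(psbn=psbn))

    def test_regulation_annotations_are_applied_as_constraints(self):
        graph = bs.InfluenceGraph(
            ("x",), [bs.Regulation("x", "x", sign="positive", essential="true")]
        )
        sketch = bs.Sketch(psbn=bs.build_psbn(graph))
        candidate_set, report = run_inference(sketch)
        # unary tables positive-monotone AND essential: only the identity
        assert count_candidates(candidate_set) == 1
        assert [count for _, count in report.steps] == [3, 1]

    def test_report_counts_decrease_monotonically(self):
        sketch = fixed_point_sketch(
            extra_static=(bs.SymbolArgEssential("g_x", 0),)
        )
        _, report = run_inference(sketch)
        counts = [report.n_interpretations] + [c for _, c in report.steps]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_final_set_is_order_invariant(self):
        rng = random.Random(5)
        spec = bs.SyntheticSpec(n_vars=3, hidden_fraction=1.0, seed=11)
        sketch, _, _ = bs.generate_sketch(spec)
        extra = (
            bs.AttractorCountTemplate(1, 2),
            bs.RawHctl("3{x}: @{x}: (AG (EF {x}))"),
        )
        base = sketch.dynamic_properties + extra
        counts = set()
        for _ in range(3):
            order = list(base)
            rng.shuffle(order)
            shuffled = bs.Sketch(
                psbn=sketch.psbn,
                static_properties=sketch.static_properties,
                datasets=sketch.datasets,
                dynamic_properties=tuple(order),
            )
            candidate_set, _ = run_inference(shuffled, with_variants=False)
            counts.add(count_candidates(candidate_set))
        assert len(counts) == 1


class TestSampling:
    def test_single_model_set_is_deterministic(self):
        graph = bs.InfluenceGraph(
            ("x",), [bs.Regulation("x", "x", sign="positive", essential="true")]
        )
        candidate_set, _ = run_inference(bs.Sketch(psbn=bs.build_psbn(graph)))
        for seed in (0, 1, 99):
            [bn] = sample_candidates(candidate_set, 1, seed)
            assert bn.tables["x"] == (0, 1)  # the identity function

    def test_samples_are_members(self):
        candidate_set, _ = run_inference(fixed_point_sketch())
        rng = random.Random(3)
        for _ in range(20):
            colour = sample_colour(candidate_set, rng)
            assert candidate_set.contains(colour)

    def test_sampled_networks_satisfy_the_sketch(self):
        sketch = fixed_point_sketch()
        candidate_set, _ = run_inference(sketch)
        for bn in sample_candidates(candidate_set, 10, seed=7):
            assert bn.is_fixed_point({"x": 1})

    def test_fixed_seed_reproduces_draws(self):
        candidate_set, _ = run_inference(fixed_point_sketch())
        assert sample_candidates(candidate_set, 5, seed=42) == sample_candidates(
            candidate_set, 5, seed=42
        )

    def test_empty_set_raises(self):
        sketch = fixed_point_sketch(extra_static=(bs.FolFormula("forall a: !g_x(a)"),))
        candidate_set, _ = run_inference(sketch)
        with pytest.raises(ValueError, match="no candidates"):
            sample_candidates(candidate_set, 1, seed=0)


class TestVariants:
    def test_fully_specified_variable_has_one_variant(self):
        psbn = bs.build_psbn(
            bs.InfluenceGraph(("a", "b"), [("b", "a"), ("a", "b")]),
            {"a": "b"},  # b gets a fresh binary... unary symbol over {a}
        )
        candidate_set, _ = run_inference(bs.Sketch(psbn=psbn), with_variants=False)
        variants = summarize_variants(candidate_set)
        assert variants["a"] == 1 and variants["b"] == 4

    def test_constrained_symbol_variant_count(self):
        candidate_set, _ = run_inference(fixed_point_sketch())
        # surviving tables for x: 01 and 11
        assert summarize_variants(candidate_set) == {"x": 2}

    def test_cap_reports_not_computed(self):
        candidate_set, _ = run_inference(fixed_point_sketch())
        assert summarize_variants(candidate_set, cap_bits=1) == {"x": None}

    def test_distinct_tables_not_colours(self):
        # two symbols feeding one variable: colours may repeat tables
        psbn = bs.build_psbn(
            bs.InfluenceGraph(("a", "b"), [("b", "a"), ("a", "b")]),
            {"a": "g(b) | h(b)", "b": "0"},
        )
        candidate_set, _ = run_inference(bs.Sketch(psbn=psbn), with_variants=False)
        variants = summarize_variants(candidate_set)
        # g(b) | h(b) ranges over all 4 unary tables, but 16 colours exist
        assert variants["a"] == 4


class TestPersistence:
    def test_round_trip_preserves_count_and_membership(self, tmp_path):
        candidate_set, _ = run_inference(fixed_point_sketch())
        path = str(tmp_path / "candidates.json")
        export_candidate_set(candidate_set, path)
        loaded = import_candidate_set(path)
        assert count_candidates(loaded) == count_candidates(candidate_set)
        for bits in itertools.product((0, 1), repeat=2):
            colour = bs.Colour(bits)
            assert loaded.contains(colour) == candidate_set.contains(colour)

    def test_empty_set_round_trips(self, tmp_path):
        sketch = fixed_point_sketch(extra_static=(bs.FolFormula("forall a: !g_x(a)"),))
        candidate_set, _ = run_inference(sketch)
        path = str(tmp_path / "empty.json")
        export_candidate_set(candidate_set, path)
        assert count_candidates(import_candidate_set(path)) == 0

    def test_tampered_parameter_order_is_rejected(self, tmp_path):
        import json

        candidate_set, _ = run_inference(fixed_point_sketch())
        path = str(tmp_path / "candidates.json")
        export_candidate_set(candidate_set, path)
        with open(path) as fh:
            payload = json.load(fh)
        payload["parameter_bits"] = list(reversed(payload["parameter_bits"]))
        with open(path, "w") as fh:
            json.dump(payload, fh)
        with pytest.raises(ValueError, match="refusing to reinterpret"):
            import_candidate_set(path)

    def test_unknown_version_is_rejected(self, tmp_path):
        import json

        path = str(tmp_path / "bad.json")
        with open(path, "w") as fh:
            json.dump({"format_version": "something-else"}, fh)
        with pytest.raises(ValueError, match="unsupported"):
            import_candidate_set(path)


def test_symbolic_count_matches_brute_force_on_mixed_sketch():
    sketch = fixed_point_sketch(
        extra_static=(
            bs.SymbolArgMonotone("g_x", 0, "positive"),
        )
    )
    candidate_set, _ = run_inference(sketch)
    n_brute, survivors = reference.brute_force_inference(sketch)
    assert count_candidates(candidate_set) == n_brute
    assert all(candidate_set.contains(c) for c in survivors)
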