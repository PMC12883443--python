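"""Build a sketch in code, validate it, and write it to disk.

The model: a three-gene positive feedback loop where the update of C is
unknown.  A := C and B := A are fixed; C := g(A, B) uses an
uninterpreted Boolean function symbol g.  Regulation arrows carry the
prior knowledge that every edge is an essential activation.
"""

import bnsketch as bs

graph = bs.InfluenceGraph(
    ("A", "B", "C"),
    [
        bs.Regulation("A", "B", sign="positive", essential="true"),
        bs.Regulation("A", "C", sign="positive", essential="true"),
        bs.Regulation("B", "C", sign="positive", essential="true"),
        bs.Regulation("C", "A", sign="positive", essential="true"),
    ],
)
psbn = bs.build_psbn(graph, {"A": "C", "B": "A", "C": "g(A, B)"})

dataset = bs.Dataset(
    "steady",
    (
        bs.Observation("off", {"A": 0, "B": 0, "C": 0}),
        bs.Observation("on", {"A": 1, "B": 1, "C": 1}),
    ),
    "steady_state",
)
sketch = bs.Sketch(
    psbn=psbn,
    datasets=(dataset,),
    dynamic_properties=(
        bs.FixedPointsTemplate("steady", id="observed-fixed-points"),
        bs.AttractorCoverageTemplate("steady", id="no-extra-attractors"),
    ),
    annotations={"C": "unknown gate integrating A and B"},
)

issues = bs.validate_sketch(sketch)
print(f"validation issues: {len(issues)}")
for issue in issues:
    print(" ", issue)
# no issues: the sketch is structurally sound

bs.save_sketch(sketch, "feedback_loop.json")
print("sketch written to feedback_loop.json")

space = bs.build_parameter_space(psbn)
print(f"unknown truth-table bits: {space.total_bits}  "
      f"(=> {space.n_interpretations} candidate networks before constraints)")
# g has arity 2, so 4 table rows: 16 possible gates for C
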