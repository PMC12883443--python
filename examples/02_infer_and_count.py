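"""Run inference on the feedback-loop sketch and read the report.

Constraints shrink the candidate space step by step: 16 possible gates
for C, cut to 2 by the monotonicity/essentiality annotations (only AND
and OR are increasing and essential in both inputs), and confirmed at 2
by the fixed-point and attractor-coverage requirements.
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
)

candidate_set, report = bs.run_inference(sketch)
print(f"interpretations before constraints: {report.n_interpretations}")
for label, count in report.steps:
    print(f"  after {label:<55} {count}")
print(f"consistent candidates: {report.final_count}")

# per-variable summary: how many distinct update functions survive
for variable, variants in sorted(report.variant_counts.items()):
    print(f"update variants for {variable}: {variants}")
# A and B are fully determined (1 variant); C keeps 2 (AND and OR)
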