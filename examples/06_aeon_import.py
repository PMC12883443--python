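"""Import an influence graph in AEON text format and infer.

Arrows carry signs (``->`` activation, ``-|`` inhibition, ``-?``
unknown) and a ``?`` suffix marks essentiality as unknown.  Variables
without a ``$`` update line get a fresh function symbol over all their
regulators, so an imported topology is immediately a sketch.
"""

import bnsketch as bs

AEON_TEXT = """\
# toy repressilator-like motif
A -| B
B -| C
C -| A
$A: ~C
"""

graph, updates, warnings = bs.read_aeon(AEON_TEXT)
for w in warnings:
    print("note:", w)
psbn = bs.build_psbn(graph, updates)
print("symbols created for unspecified updates:",
      [f"{s.name}/{s.arity}" for s in psbn.symbols])

sketch = bs.Sketch(psbn=psbn)
candidate_set, report = bs.run_inference(sketch, with_variants=False)
print(f"candidates: {report.final_count} of {report.n_interpretations}")
# B and C each had 2 possible unary updates before the inhibition
# annotations; the sign+essentiality arrows force both to negation,
# leaving a single consistent network
print(bs.write_aeon(psbn), end="")
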