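"""Write behavioural requirements directly in HCTL.

Three examples on the one-variable network x := g(x), whose four
possible gates are constant 0, constant 1, identity, and negation:

* ``3{x}: @{x}: (AG (EF {x}))`` — "some state belongs to an attractor".
  Every finite transition graph has a terminal SCC, so this is a sanity
  check that must hold for all 4 gates.
* ``3{x}: ~(3{y}: @{y}: (~(EF {x})))`` — "some state is reachable from
  every state" (no y fails to reach x).  The identity gate has two
  separate fixed points, so it is the only gate that fails.
* the attractor-count template "exactly one attractor" — again only the
  identity gate (two attractors) fails.
"""

import bnsketch as bs

psbn = bs.build_psbn(bs.InfluenceGraph(("x",), [("x", "x")]))  # x := g(x)

for name, prop, expected in [
    ("some attractor state exists",
     bs.RawHctl("3{x}: @{x}: (AG (EF {x}))"), 4),
    ("a universally reachable state exists",
     bs.RawHctl("3{x}: ~(3{y}: @{y}: (~(EF {x})))"), 3),
    ("exactly one attractor",
     bs.AttractorCountTemplate(1, 1), 3),
]:
    sketch = bs.Sketch(psbn=psbn, dynamic_properties=(prop,))
    candidate_set, _ = bs.run_inference(sketch, with_variants=False)
    count = bs.count_candidates(candidate_set)
    print(f"{name}: {count} of 4 gates (expected {expected})")
    identity_gate = bs.Colour((0, 1))
    print("   identity gate consistent:", candidate_set.contains(identity_gate))
# the identity gate x := x is excluded exactly by the last two properties
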