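# bnsketch

Inference of Boolean network models from partial specifications
(*Boolean network sketches*), with a fully symbolic candidate set.

## The problem

Boolean networks (BNs) model regulatory and signalling systems as
variables valued 0/1, each updated by a Boolean function of its
regulators. Building such a model from what is actually known — a
plausible interaction topology, qualitative knowledge such as "this
edge is an activation", and binarized measurements of steady states or
trajectories — is the *BN inference problem*. Most of the time this
knowledge does not determine one network; it determines a (possibly
astronomically large) set of admissible networks.

`bnsketch` represents that partial knowledge as a **sketch** and
computes the *complete* set of consistent networks, for systems
biologists who want guarantees about what the data does and does not
pin down:

- **Influence graph** — the possible regulations, each optionally
  annotated as an *essential* regulation (it must have an effect) and/or
  a *monotone* one (activation `->` / inhibition `-|`).
- **Partially specified BN (PSBN)** — one update expression per
  variable, which may contain uninterpreted function symbols
  (`C: g(A, B)`). Substituting a concrete truth table for every symbol
  (an *interpretation*, or *colour*) yields a concrete BN.
- **Static properties** — first-order logic over Booleans constraining
  the update functions themselves, e.g.
  `forall a: g(a, 1)` or monotonicity/essentiality templates.
- **Dynamic properties** — HCTL (hybrid CTL, with state variables,
  the binder `!{x}:`, jump `@{x}:` and quantifier `3{x}:`) over the
  **fully asynchronous** semantics, either written directly or derived
  from observation datasets by templates: required fixed points,
  attractor counts, attractor coverage ("no attractor outside the
  data"), and time-series reachability chains.

## The method

Every symbol `g` of arity `k` is encoded by `2^k` Boolean parameters,
one per truth-table row; an application compiles to the multiplexer
`⋁_w (p[g,w] ∧ ⋀_i (e_i ⇔ w_i))`. All sets — of states, of colours, and
of (state, colour) pairs — are reduced ordered binary decision diagrams,
so the engine model-checks *all interpretations at once* on the coloured
asynchronous transition graph. The candidate set is the intersection of
the colour sets of every property; it supports

- exact big-integer counting,
- true uniform sampling (weighted descent by subtree model counts —
  no enumeration),
- per-variable counts of the distinct update functions that survive,
- lossless export/import of the whole set.

Every symbolic operation is tested against an independent explicit-state
oracle (exhaustive enumeration plus a direct recursive HCTL evaluator)
on randomized instances.

## Worked example

A three-gene positive feedback loop where only the gate of `C` is
unknown (`A := C`, `B := A`, `C := g(A, B)`), all four arrows annotated
as essential activations, and two steady-state observations (all-off,
all-on) required to be fixed points covering all attractors
(`examples/02_infer_and_count.py`):

```text
interpretations before constraints: 16
  after regulation:A->B:RegulationMonotone                      16
  after regulation:A->B:RegulationEssential                     16
  after regulation:A->C:RegulationMonotone                      9
  after regulation:A->C:RegulationEssential                     5
  after regulation:B->C:RegulationMonotone                      3
  after regulation:B->C:RegulationEssential                     2
  after regulation:C->A:RegulationMonotone                      2
  after regulation:C->A:RegulationEssential                     2
  after observed-fixed-points                                   2
  after no-extra-attractors                                     2
consistent candidates: 2
update variants for A: 1
update variants for B: 1
update variants for C: 2
```

Of the 16 possible gates for `C`, monotonicity and essentiality in both
inputs leave exactly AND and OR; both satisfy the dynamic requirements,
so the data cannot distinguish them — and the per-variable summary says
so directly (`C` keeps 2 variants, `A` and `B` are fully determined).

The other scripts in `examples/` each demonstrate one capability:
building and validating sketches, uniform sampling and candidate-set
export, raw HCTL properties, synthetic ground-truth recovery, and AEON
import.

## Command line

```sh
bnsketch check  sketch.json                  # validate, exit 1 on errors
bnsketch infer  sketch.json --out out/       # report.json + candidates.json
bnsketch count  out/candidates.json
bnsketch sample out/candidates.json -n 5 --seed 1 --format bnet
bnsketch summarize out/candidates.json
```

File formats (sketch JSON, the AEON dialect, observations CSV, BoolNet
export) and the exact FOL/HCTL grammars are documented in
`docs/grammars.md`; the model, conventions and design choices in
`docs/methods.md`.

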