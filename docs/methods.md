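# Methods

## The model

A **Boolean network** over variables `V` assigns each `v ∈ V` an update
function `f_v` over its regulators. A **sketch** is a partial
specification of such a network, made of four parts:

1. an **influence graph**: the binary relation of possible regulations,
   with optional per-edge annotations — sign (`positive`/`negative`/
   `unknown`) and essentiality (`true`/`unknown`);
2. a **partially specified Boolean network (PSBN)**: one update
   expression per variable over constants, regulators, the connectives
   `! & | ^ => <=>`, and applications of uninterpreted function symbols
   (nesting and symbol sharing between variables are allowed);
3. **static properties**: closed first-order formulas over Booleans
   about the update functions (with essentiality and monotonicity as
   templates);
4. **dynamic properties**: HCTL formulas about the asynchronous
   dynamics, written directly or produced by observation-based
   templates.

An **interpretation** (*colour*) picks one truth table for every
symbol; it determines one concrete network. The inference problem is to
compute all colours whose network satisfies every property.

## Parameter encoding

Symbol `g` of arity `k` contributes one Boolean parameter per truth-table
row: `p[g,w]` for `w ∈ {0,1}^k`, rows in binary order with the first
argument as the most significant bit. Symbols are laid out sorted by
name; state bits (variables sorted by name) precede parameter bits in
the global decision-diagram order, and dynamically allocated bits
(copies of state bits for HCTL state variables, table bits for variant
summaries) follow them. Everything downstream — enumeration order,
sampling under a fixed seed, exported files — depends only on this one
deterministic layout. The arity cap (default 16) rejects tables that
would not be representable.

An application `g(e_1, …, e_k)` compiles to the row multiplexer
`⋁_w (p[g,w] ∧ ⋀_i (e_i ⇔ w_i))`, so the compiled update `F_v(s, p)`
agrees with every interpretation simultaneously. Candidate counting
counts *interpretations*: two colours that differ only in a table row
the expressions never select count as two candidates. This is the only
well-defined count without semantic de-duplication, and the per-variable
variant summary provides the semantic view where it matters.

## Static properties

Regulation-level essentiality and monotonicity are defined on the
compiled update `F_v`, not on a symbol's raw table — the only definition
that is well formed for compound expressions such as `g(u) | w`:

- essential `u → v`: `∃s. F_v(s[u:=0]) ≠ F_v(s[u:=1])`;
- positive monotone: `∀s. F_v(s[u:=0]) ⇒ F_v(s[u:=1])` (negative:
  reversed).

Symbol-level versions apply the same definitions directly to the
parameter block, quantifying over the other arguments. When
`update(v) = g(regulators in order)` the two views coincide (tested).
Edge annotations in the influence graph are compiled to exactly these
properties; `unknown` annotations produce no constraint, which also
means a regulation may legitimately end up unused in some candidates
(validation flags this as a warning, not an error).

Free-form first-order properties quantify over Boolean scalars only;
quantifiers are expanded exhaustively (bound variables are few in
practice, and the expansion is trivially auditable). Network state
variables may not appear — state-dependent requirements belong to the
dynamic layer. The concrete grammar is ours (documented in
`grammars.md`); no normal form is required, so the compilation of a
conjunction equals the conjunction of the compilations (tested).

## Dynamics and HCTL

The semantics is **fully asynchronous**: a transition flips exactly one
variable `v` with `F_v(s,p) ≠ s_v`. Transitions must change the state,
so fixed points are deadlocks. All operators act on coloured sets
(diagrams over state × parameter × copy bits) and are implemented with
`pre`/`post` images that flip one bit at a time — no primed state
variables are needed.

Deadlock conventions, fixed once and applied identically in the
symbolic checker and the explicit oracle: `EX`/`EG`/`EU`/`AU` are
computed by the standard μ/ν fixpoints over `pre`, which makes
`EX φ` false and `AX φ` vacuously true at deadlocks; `EF` includes its
zero-step case. Templates never detect fixed points through the absence
of transitions — they use the structural predicate
`⋀_v (F_v(s,p) = s_v)` injected as an atomic set, so results are
independent of the self-loop convention.

Hybrid operators use named copies of the state bits: the atom `{x}` is
the diagonal between state bits and `x`-copies; the binder `!{x}:`
intersects with the diagonal and projects the copies; the jump `@{x}:`
substitutes copies for state bits (via conjunction with the diagonal
and projection of the state bits); `3{x}:` projects the copies
existentially. `!{x}: AG EF {x}` characterises attractor states; the
attractor-count template conjoins `m` jump-tagged attractor witnesses
with pairwise non-reachability, with the bound capped at 8 because each
extra witness costs one full set of copies.

A closed formula constrains a colour by holding in **every** state
(`satisfying_colours` universally quantifies the state bits). All
templates produce state-independent results by construction; for raw
formulas that remain state-dependent, a warning states the convention
explicitly.

## Inference, counting, sampling

`run_inference` intersects property colour-sets in a fixed order —
annotation-implied static properties, explicit static properties,
dynamic properties in declaration order — recording the count after
each step; intersection commutes, so the final set is order-independent
(tested). Counting uses exact big-integer model counting over the
parameter bits. Sampling draws colours uniformly by descending the
diagram with branches weighted by exact subtree model counts, then
instantiates; a fixed seed reproduces draws exactly.

Variant summaries introduce, per variable, a fresh block of `2^k` table
bits constrained row-wise to equal `F_v` at that row's regulator
values, conjoin with the candidate set, project out the parameters and
model-count over the table bits. Variables above the cap (default 20
bits) are reported as "not computed" rather than failing.

Candidate-set files store the PSBN, the parameter-bit ordering and the
serialized diagram; imports verify the ordering and fail loudly rather
than reinterpret bits.

## The explicit oracle and the synthetic generator

Every symbolic operation has an independent explicit-state counterpart
(`reference.py`): interpretations are enumerated (guard: ≤ 24 parameter
bits), the asynchronous graph is materialised per colour (guard: ≤ 12
variables), static properties are checked on truth tables, and HCTL is
evaluated by direct recursion with explicit environments for state
variables. The oracle shares only the AST types with the symbolic
route. The central correctness property — equal counts *and*
membership on randomized mixed sketches — is asserted over 200 seeded
sketches with ≤ 5 variables and ≤ 10 parameter bits, alongside an
operator battery (every HCTL operator, nesting ≤ 3) compared per colour
on random 4-variable instances.

The synthetic generator draws a ground-truth network and forgets parts
of it. Its guarantees: declared regulators are genuinely essential
(tables are resampled until they are), sign annotations are emitted
only where the true table is monotone in that input, essentiality
annotations are always genuine, and observations are true fixed points
(steady-state) or states along a genuine asynchronous trajectory
(time-series). Consequently the generating colour always survives
inference, and with nothing hidden the candidate set is exactly the
ground truth. Default study conditions: 4 variables, regulation density
0.4 with at most 3 regulators per variable, half the variables hidden,
sign annotations on half of the monotone edges, one observation. These
are desk-scale conditions chosen so the enumeration oracle stays exact
in seconds; what passing tests show is correctness of the engine, not
robustness to noisy or mis-binarized data — observations are emitted
noise-free by construction, and real datasets' binarization errors are
out of scope (inputs are assumed already binarized).

## Numerical and engineering choices

- The decision-diagram engine is a hash-consed reduced ordered BDD with
  memoised `ite`, quantification, bit-flip substitution, rename (via
  conjunction with an equality cube and projection), exact counting and
  weighted uniform sampling. Canonicity makes fixpoint termination
  checks a pointer comparison.
- Reachability fixpoints use plain chaotic iteration; at desk scale
  (≤ 12 state bits plus parameters) no saturation heuristics are
  needed, and the contract is representation-independent.
- All randomness flows through explicit `random.Random(seed)` instances;
  no global state.
- Problem sizes in the test suite and the acceptance script (≤ 5
  variables, ≤ 10 parameter bits for oracle comparisons; 60–200
  sketches; 6000 sampling draws) were chosen so every comparison against
  the exhaustive oracle is exact while the whole suite runs in about a
  minute.

## Known limitations

- Only the fully asynchronous update semantics is implemented;
  synchronous and most-permissive semantics are out of scope.
- Counting does not quotient by semantic equality of networks (see
  above); the variant summary is the semantic lens.
- The attractor-count template grows one copy-bit block per counted
  attractor (capped at 8).
- SBML-qual import, multi-valued variables, second-order quantification
  and cardinality constraints over clauses are not supported.
- The pure-Python diagram engine targets correctness and desk-scale
  models, not the performance envelope of compiled symbolic engines.
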