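# Concrete grammars and file formats

## Boolean update expressions

Used in `$V:` lines of `.aeon` files and in the `update_expressions`
section of sketch JSON. EBNF (whitespace insignificant):

```ebnf
expr    = iff ;
iff     = imp , { "<=>" , imp } ;              (* right-assoc *)
imp     = or  , [ "=>" , imp ] ;               (* right-assoc *)
or      = xor , { "|" , xor } ;
xor     = and , { "^" , and } ;
and     = unary , { "&" , unary } ;
unary   = ( "!" | "~" ) , unary | primary ;
primary = "(" , expr , ")"
        | "0" | "1" | "true" | "false"
        | ident , [ "(" , [ expr , { "," , expr } ] , ")" ] ;
ident   = ? [A-Za-z_][A-Za-z0-9_]* ? ;
```

`ident(...)` is a function-symbol application (`g()` for arity 0); a
bare `ident` is a variable reference. In update expressions every
referenced variable must be a declared regulator of the updated
variable.

## First-order static properties

The expression grammar plus quantifiers, which bind as far right as
possible:

```ebnf
fol   = "forall" , ident , ":" , fol
      | "exists" , ident , ":" , fol
      | expr ;                        (* expr may contain parenthesised fol *)
```

Names are quantifier-bound Boolean scalars; network variables may not
appear. Applications refer to the sketch's function symbols. Examples:

```text
forall a: g(a, 1)
exists a: forall b: (g(a, b) => g(b, a))
(forall a: g(a, 1)) & (exists a: g(a, 0))
```

## HCTL dynamic properties

```ebnf
hctl    = hybrid | binary ;
hybrid  = ( "3{" x "}:" | "!{" x "}:" | "@{" x "}:" ) , hctl ;   (* reach right *)
binary  = iff ;
iff     = imp , { "<=>" , imp } ;
imp     = or  , [ "=>" , imp ] ;
or      = until , { "|" , until } ;
until   = and , { "&" , and } , [ ( "EU" | "AU" ) , until ] ;
unary   = "~" , unary
        | ( "EX" | "AX" | "EF" | "AF" | "EG" | "AG" ) , unary
        | primary ;
primary = "(" , hctl , ")" | "true" | "false"
        | ident            (* atom: variable = 1 *)
        | "{" x "}" ;      (* bound state variable *)
```

`~ident` abbreviates "variable = 0". `3{x}:` is existential state
quantification, `!{x}:` the binder (remember the current state as `x`),
`@{x}:` the jump (evaluate at the state remembered as `x`), `{x}` the
atom "current state equals `x`". Each state-variable name may be bound
once per AST path. In practice, parenthesise `EU`/`AU` operands:
`(a EU b)`.

Useful idioms:

```text
!{x}: AG EF {x}                     # x is an attractor state
3{x}: @{x}: (AG (EF {x}))           # some attractor state exists (tautology)
3{x}: ~(3{y}: @{y}: (~(EF {x})))    # a universally reachable state exists
```

## Sketch JSON

One object, sections in any order:

```json
{
  "format_version": "bnsketch-1",
  "variables": ["A", "B"],
  "regulations": [
    {"source": "A", "target": "B", "sign": "positive", "essential": "true"}
  ],
  "symbols": [{"name": "g", "arity": 1}],
  "update_expressions": {"A": "g(B)", "B": "A"},
  "static_properties": [
    {"kind": "regulation_essential", "source": "A", "target": "B", "id": ""},
    {"kind": "regulation_monotone", "source": "A", "target": "B",
     "direction": "positive", "id": ""},
    {"kind": "symbol_essential", "symbol": "g", "arg_index": 0, "id": ""},
    {"kind": "symbol_monotone", "symbol": "g", "arg_index": 0,
     "direction": "positive", "id": ""},
    {"kind": "fol", "formula": "exists a: g(a)", "id": ""}
  ],
  "datasets": [
    {"id": "d1", "category": "steady_state",
     "observations": [{"id": "o1", "values": {"A": 1}}]}
  ],
  "dynamic_properties": [
    {"kind": "hctl", "formula": "AG (EF A)", "id": ""},
    {"kind": "fixed_points", "dataset": "d1", "id": ""},
    {"kind": "attractor_count", "min": 1, "max": 2, "id": ""},
    {"kind": "attractor_coverage", "dataset": "d1", "id": ""},
    {"kind": "time_series", "dataset": "d1", "id": ""}
  ],
  "annotations": {"A": "free text"}
}
```

`sign` ∈ `positive|negative|unknown`; `essential` ∈ `true|unknown`
(`unknown` generates no constraint); dataset `category` ∈
`unspecified|steady_state|time_series`; `attractor_count.max` may be
`null` (unbounded). Annotations are inert metadata: stored and
round-tripped, never interpreted.

## AEON dialect

```text
# comment / metadata lines are ignored (with a warning)
A -> B      activation (positive, essential)
A -| B      inhibition (negative, essential)
A -? B      unknown sign, essential
A ->? B     positive, essentiality unknown   (likewise -|? and -??)
$A: ~B      update expression
```

Variables are the union of regulation endpoints and `$`-declared names;
variables without a `$` line receive a fresh symbol over all their
regulators (sorted by name) when the import is completed into a PSBN.

## Observations CSV

Header `id,<var>,<var>,...`; one row per observation; cells `0`, `1` or
blank (= unconstrained); row order is preserved and meaningful for
time series.

```csv
id,A,B
early,1,
late,0,1
```

## Candidate-set file

JSON with `format_version` (`bnsketch-candidates-1`), the PSBN, the
parameter-bit ordering, the provenance (property labels applied, in
order) and the serialized decision diagram. Import verifies the version
and bit ordering and refuses mismatches.

## BoolNet export

`targets, factors` header, one line per variable; factors are the
canonical DNF of the sampled truth table over the variable's regulators
(constants `0`/`1` for degenerate tables).
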