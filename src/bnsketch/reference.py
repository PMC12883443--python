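"""Explicit-state reference implementations.

Everything here recomputes, by enumeration, what the symbolic engine
computes with decision diagrams: interpretations are enumerated one by
one, the asynchronous transition graph is materialised per colour, and
HCTL is evaluated by direct recursion with explicit environments for
state variables.  These routines are deliberately simple and slow —
they are the oracle the symbolic route is tested against, so they share
no code with it beyond the AST types.

Guards keep everything enumerable: at most 24 parameter bits and 12
network variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterator, List, Mapping, Optional, Sequence, Tuple

from . import expressions as ex
from . import hctl
from . import static_properties as sp
from .encoding import (
    Colour,
    ConcreteBN,
    ParameterSpace,
    argument_row,
    build_parameter_space,
    instantiate,
    row_bit,
)
from .model import PSBN, Sketch, has_errors, validate_sketch
from .properties import (
    FolFormula,
    RegulationEssential,
    RegulationMonotone,
    SymbolArgEssential,
    SymbolArgMonotone,
)
from .static_properties import Quant, implied_static_properties

MAX_PARAM_BITS = 24
MAX_VARIABLES = 12


def enumerate_interpretations(
    psbn: PSBN, space: Optional[ParameterSpace] = None
) -> Iterator[Tuple[Colour, ConcreteBN]]:
    """All ``2**total_bits`` interpretations, in parameter binary order.

    Bit 0 (the first symbol's row 0) varies slowest, matching the
    lexicographic order of the bit tuples.
    """
    if space is None:
        space = build_parameter_space(psbn)
    if space.total_bits > MAX_PARAM_BITS:
        raise ValueError(
            f"{space.total_bits} parameter bits exceed the enumeration "
            f"guard of {MAX_PARAM_BITS}"
        )
    for bits in itertools.product((0, 1), repeat=space.total_bits):
        colour = Colour(bits)
        yield colour, instantiate(psbn, colour, space)


# ---------------------------------------------------------------------------
# explicit transition graph


@dataclass(frozen=True)
class ExplicitStg:
    """Adjacency of the asynchronous graph of one concrete network.

    States are integers over the sorted variables, first variable at the
    most significant bit; deadlocks are exactly the fixed points.
    """

    variables: Tuple[str, ...]
    successors: Tuple[Tuple[int, ...], ...]

    @property
    def n_states(self) -> int:
        return 1 << len(self.variables)

    def all_states(self) -> FrozenSet[int]:
        return frozenset(range(self.n_states))

    def predecessors_of(self, targets: FrozenSet[int]) -> FrozenSet[int]:
        return frozenset(
            s
            for s in range(self.n_states)
            if any(t in targets for t in self.successors[s])
        )

    def deadlocks(self) -> FrozenSet[int]:
        return frozenset(s for s in range(self.n_states) if not self.successors[s])

    def state_assignment(self, state: int) -> Dict[str, int]:
        n = len(self.variables)
        return {v: (state >> (n - 1 - i)) & 1 for i, v in enumerate(self.variables)}

    def assignment_state(self, values: Mapping[str, int]) -> int:
        return argument_row([values[v] for v in self.variables])


def build_explicit_stg(bn: ConcreteBN) -> ExplicitStg:
    variables = bn.variables
    n = len(variables)
    if n > MAX_VARIABLES:
        raise ValueError(f"{n} variables exceed the explicit guard of {MAX_VARIABLES}")
    succ: List[Tuple[int, ...]] = []
    for s in range(1 << n):
        assignment = {v: (s >> (n - 1 - i)) & 1 for i, v in enumerate(variables)}
        out = []
        for i, v in enumerate(variables):
            if bn.value(v, assignment) != assignment[v]:
                out.append(s ^ (1 << (n - 1 - i)))
        succ.append(tuple(out))
    return ExplicitStg(variables=variables, successors=tuple(succ))


# ---------------------------------------------------------------------------
# explicit HCTL

_Env = Tuple[Tuple[str, int], ...]


def _free_state_vars(node: hctl.HctlFormula, cache: Dict[int, FrozenSet[str]]) -> FrozenSet[str]:
    key = id(node)
    if key in cache:
        return cache[key]
    if isinstance(node, hctl.StateVar):
        out: FrozenSet[str] = frozenset({node.name})
    elif isinstance(node, (hctl.Bind, hctl.Exists)):
        out = _free_state_vars(node.body, cache) - {node.var}
    elif isinstance(node, hctl.Jump):
        out = _free_state_vars(node.body, cache) | {node.var}
    else:
        out = frozenset()
        for child in hctl._children(node):
            out |= _free_state_vars(child, cache)
    cache[key] = out
    return out


def explicit_check_hctl(
    formula: hctl.HctlFormula,
    stg: ExplicitStg,
    env: Optional[Mapping[str, int]] = None,
) -> FrozenSet[int]:
    """States satisfying the formula under an environment for its free
    state variables (direct recursive evaluation, memoised)."""
    all_states = stg.all_states()
    free_cache: Dict[int, FrozenSet[str]] = {}
    memo: Dict[Tuple[int, _Env], FrozenSet[int]] = {}

    def rec(node: hctl.HctlFormula, env: Mapping[str, int]) -> FrozenSet[int]:
        relevant = _free_state_vars(node, free_cache)
        key = (id(node), tuple(sorted((k, env[k]) for k in relevant)))
        hit = memo.get(key)
        if hit is not None:
            return hit
        result = _eval(node, env)
        memo[key] = result
        return result

    def _eval(node: hctl.HctlFormula, env: Mapping[str, int]) -> FrozenSet[int]:
        if isinstance(node, hctl.HConst):
            return all_states if node.value else frozenset()
        if isinstance(node, hctl.Atom):
            i = stg.variables.index(node.variable)
            bit = len(stg.variables) - 1 - i
            return frozenset(
                s for s in all_states if ((s >> bit) & 1) == int(node.value)
            )
        if isinstance(node, hctl.StateVar):
            return frozenset({env[node.name]})
        if isinstance(node, hctl.FixedPointAtom):
            return stg.deadlocks()
        if isinstance(node, hctl.HNot):
            return all_states - rec(node.arg, env)
        if isinstance(node, hctl.HBin):
            left, right = rec(node.left, env), rec(node.right, env)
            if node.op == "&":
                return left & right
            if node.op == "|":
                return left | right
            if node.op == "=>":
                return (all_states - left) | right
            return (left & right) | (all_states - (left | right))  # <=>
        if isinstance(node, hctl.Temporal):
            if node.op == "EX":
                return stg.predecessors_of(rec(node.arg, env))
            if node.op == "AX":
                return all_states - stg.predecessors_of(all_states - rec(node.arg, env))
            if node.op == "EF":
                return _lfp_ef(rec(node.arg, env))
            if node.op == "AG":
                return all_states - _lfp_ef(all_states - rec(node.arg, env))
            if node.op == "EG":
                return _gfp_eg(rec(node.arg, env))
            if node.op == "AF":
                return all_states - _gfp_eg(all_states - rec(node.arg, env))
            raise ValueError(f"unknown temporal operator {node.op!r}")
        if isinstance(node, hctl.Until):
            hold, target = rec(node.left, env), rec(node.right, env)
            current: FrozenSet[int] = frozenset()
            while True:
                if node.op == "EU":
                    step = stg.predecessors_of(current)
                else:
                    step = all_states - stg.predecessors_of(all_states - current)
                nxt = target | (hold & step)
                if nxt == current:
                    return current
                current = nxt
        if isinstance(node, hctl.Bind):
            return frozenset(
                s for s in all_states if s in rec(node.body, {**env, node.var: s})
            )
        if isinstance(node, hctl.Jump):
            return all_states if env[node.var] in rec(node.body, env) else frozenset()
        if isinstance(node, hctl.Exists):
            out: FrozenSet[int] = frozenset()
            for witness in all_states:
                out |= rec(node.body, {**env, node.var: witness})
                if out == all_states:
                    break
            return out
        raise TypeError(f"not an HCTL formula: {node!r}")

    def _lfp_ef(target: FrozenSet[int]) -> FrozenSet[int]:
        reach = target
        while True:
            nxt = reach | stg.predecessors_of(reach)
            if nxt == reach:
                return reach
            reach = nxt

    def _gfp_eg(inv: FrozenSet[int]) -> FrozenSet[int]:
        current = inv
        while True:
            nxt = current & stg.predecessors_of(current)
            if nxt == current:
                return current
            current = nxt

    return rec(formula, dict(env or {}))


# ---------------------------------------------------------------------------
# explicit static properties


def _regulation_essential_explicit(bn: ConcreteBN, source: str, target: str) -> bool:
    regs = bn.regulators[target]
    if source not in regs:
        return False
    k = len(regs)
    i = regs.index(source)
    table = bn.tables[target]
    for row in range(1 << k):
        if row_bit(row, i, k):
            continue
        if table[row] != table[row | (1 << (k - 1 - i))]:
            return True
    return False


def _regulation_monotone_explicit(
    bn: ConcreteBN, source: str, target: str, direction: str
) -> bool:
    regs = bn.regulators[target]
    if source not in regs:
        return True  # the update never reads the source: vacuously monotone
    k = len(regs)
    i = regs.index(source)
    table = bn.tables[target]
    for row in range(1 << k):
        if row_bit(row, i, k):
            continue
        low, high = table[row], table[row | (1 << (k - 1 - i))]
        if direction == "positive" and low > high:
            return False
        if direction == "negative" and low < high:
            return False
    return True


def _symbol_table(space: ParameterSpace, colour: Colour, symbol: str) -> Tuple[int, ...]:
    return space.table_of(colour, symbol)


def _eval_fol(node: ex.Expr, env: Dict[str, bool], tables: Mapping[str, Tuple[int, ...]]) -> bool:
    if isinstance(node, Quant):
        lo = _eval_fol(node.body, {**env, node.var: False}, tables)
        hi = _eval_fol(node.body, {**env, node.var: True}, tables)
        return (lo and hi) if node.kind == "forall" else (lo or hi)
    if isinstance(node, ex.Const):
        return node.value
    if isinstance(node, ex.Name):
        return env[node.name]
    if isinstance(node, ex.Not):
        return not _eval_fol(node.arg, env, tables)
    if isinstance(node, ex.BinOp):
        a = _eval_fol(node.left, env, tables)
        b = _eval_fol(node.right, env, tables)
        return {
            "&": a and b,
            "|": a or b,
            "^": a != b,
            "=>": (not a) or b,
            "<=>": a == b,
        }[node.op]
    if isinstance(node, ex.App):
        vals = [_eval_fol(a, env, tables) for a in node.args]
        return bool(tables[node.func][argument_row([int(v) for v in vals])])
    raise TypeError(f"not a first-order formula: {node!r}")


def static_property_holds(
    prop, psbn: PSBN, space: ParameterSpace, colour: Colour, bn: ConcreteBN
) -> bool:
    """Truth-table evaluation of one static property at one colour."""
    if isinstance(prop, RegulationEssential):
        return _regulation_essential_explicit(bn, prop.source, prop.target)
    if isinstance(prop, RegulationMonotone):
        return _regulation_monotone_explicit(bn, prop.source, prop.target, prop.direction)
    if isinstance(prop, SymbolArgEssential):
        table = _symbol_table(space, colour, prop.symbol)
        arity = space.arity(prop.symbol)
        i = prop.arg_index
        return any(
            table[row] != table[row | (1 << (arity - 1 - i))]
            for row in range(1 << arity)
            if not row_bit(row, i, arity)
        )
    if isinstance(prop, SymbolArgMonotone):
        table = _symbol_table(space, colour, prop.symbol)
        arity = space.arity(prop.symbol)
        i = prop.arg_index
        for row in range(1 << arity):
            if row_bit(row, i, arity):
                continue
            low, high = table[row], table[row | (1 << (arity - 1 - i))]
            if prop.direction == "positive" and low > high:
                return False
            if prop.direction == "negative" and low < high:
                return False
        return True
    if isinstance(prop, FolFormula):
        ast = sp.parse_fol(prop.text)
        tables = {s.name: _symbol_table(space, colour, s.name) for s in space.symbols}
        return _eval_fol(ast, {}, tables)
    raise TypeError(f"not a static property: {prop!r}")


# ---------------------------------------------------------------------------
# brute-force inference


def brute_force_inference(sketch: Sketch) -> Tuple[int, List[Colour]]:
    """Reference semantics of the whole sketch, by enumeration.

    Every interpretation is instantiated; static properties are checked
    on truth tables, dynamic properties by explicit HCTL evaluation with
    the universal-over-states convention.  Returns the count and the
    surviving colours in parameter binary order.
    """
    issues = validate_sketch(sketch)
    if has_errors(issues):
        raise ValueError("sketch has validation errors: " + "; ".join(map(str, issues)))
    psbn = sketch.psbn
    space = build_parameter_space(psbn)
    static_props = implied_static_properties(psbn) + tuple(sketch.static_properties)
    formulas = [
        hctl.build_template(prop, sketch.datasets)
        for prop in sketch.dynamic_properties
    ]
    survivors: List[Colour] = []
    for colour, bn in enumerate_interpretations(psbn, space):
        if not all(
            static_property_holds(p, psbn, space, colour, bn) for p in static_props
        ):
            continue
        if formulas:
            stg = build_explicit_stg(bn)
            all_states = stg.all_states()
            if not all(
                explicit_check_hctl(f, stg) == all_states for f in formulas
            ):
                continue
        survivors.append(colour)
    return len(survivors), survivors
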