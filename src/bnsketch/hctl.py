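"""HCTL: hybrid CTL over the coloured asynchronous transition graph.

HCTL extends CTL with named *state variables*: the binder ``!{x}:``
remembers the current state as ``x``, the jump ``@{x}:`` re-evaluates
its body at the remembered state, the quantifier ``3{x}:`` asks for the
existence of some witness state, and the atom ``{x}`` is true exactly
in the remembered state.  This is enough to talk about attractors —
``!{x}: AG EF {x}`` holds precisely in attractor states — and about
their number and relationships.

Concrete syntax (loosest to tightest binding)::

    3{x}: φ   @{x}: φ   !{x}: φ        hybrid prefixes, reach as far
                                       right as possible
    <=>   =>   |   &                   Boolean connectives
    (φ EU ψ)  (φ AU ψ)                 until operators (infix)
    ~ φ   EX AX EF AF EG AG φ          unary prefixes
    v   ~v   true   false   {x}        atoms (a bare name means v = 1)

Deadlock convention: fixed points have no successors, so ``EX``/``EG``
and the until operators are false there (beyond their zero-step cases)
while ``AX φ`` is vacuously true.  Templates therefore always identify
fixed points through the structural predicate, never through the
absence of transitions.

Colour extraction treats a closed formula as a requirement on *every*
state: ``satisfying_colours`` universally quantifies the state bits and
warns if the formula was genuinely state-dependent.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Set, Tuple

from . import dynamics
from .bdd import FALSE, TRUE
from .encoding import SymbolicContext
from .model import Dataset, Observation
from .properties import (
    AttractorCountTemplate,
    AttractorCoverageTemplate,
    DynamicProperty,
    FixedPointsTemplate,
    RawHctl,
    TimeSeriesTemplate,
)

#: each extra attractor in the count template costs one set of state-bit copies
MAX_ATTRACTOR_BOUND = 8


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class HctlFormula:
    pass


@dataclass(frozen=True)
class HConst(HctlFormula):
    value: bool


@dataclass(frozen=True)
class Atom(HctlFormula):
    """Proposition ``variable = value``."""

    variable: str
    value: bool


@dataclass(frozen=True)
class StateVar(HctlFormula):
    """``{x}`` — true exactly in the state remembered as ``x``."""

    name: str


@dataclass(frozen=True)
class FixedPointAtom(HctlFormula):
    """Structural fixed-point predicate (injected by templates)."""


@dataclass(frozen=True)
class HNot(HctlFormula):
    arg: HctlFormula


@dataclass(frozen=True)
class HBin(HctlFormula):
    op: str  # & | => <=>
    left: HctlFormula
    right: HctlFormula


@dataclass(frozen=True)
class Temporal(HctlFormula):
    op: str  # EX AX EF AF EG AG
    arg: HctlFormula


@dataclass(frozen=True)
class Until(HctlFormula):
    op: str  # EU AU
    left: HctlFormula
    right: HctlFormula


@dataclass(frozen=True)
class Bind(HctlFormula):
    """``!{x}: φ`` — remember the current state as ``x``."""

    var: str
    body: HctlFormula


@dataclass(frozen=True)
class Jump(HctlFormula):
    """``@{x}: φ`` — evaluate ``φ`` at the state remembered as ``x``."""

    var: str
    body: HctlFormula


@dataclass(frozen=True)
class Exists(HctlFormula):
    """``3{x}: φ`` — some state can be remembered as ``x``."""

    var: str
    body: HctlFormula


def conj(parts: Sequence[HctlFormula]) -> HctlFormula:
    if not parts:
        return HConst(True)
    acc = parts[0]
    for p in parts[1:]:
        acc = HBin("&", acc, p)
    return acc


# ---------------------------------------------------------------------------
# parser


class HctlSyntaxError(ValueError):
    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


_H_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<hybrid>[3!@]\{[A-Za-z_][A-Za-z0-9_]*\}\s*:)"
    r"|(?P<statevar>\{[A-Za-z_][A-Za-z0-9_]*\})"
    r"|(?P<op><=>|=>|[&|()~])"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_]*)"
    r")"
)

_TEMPORAL_UNARY = ("EX", "AX", "EF", "AF", "EG", "AG")
_TEMPORAL_BINARY = ("EU", "AU")


def _h_tokenize(text: str) -> List[Tuple[str, str, int]]:
    out: List[Tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _H_TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise HctlSyntaxError(f"unexpected character {stripped[0]!r}", pos)
        for kind in ("hybrid", "statevar", "op", "word"):
            val = m.group(kind)
            if val:
                out.append((kind, val, m.start(kind)))
                break
        pos = m.end()
    out.append(("end", "", len(text)))
    return out


_H_PRECEDENCE = {"<=>": 1, "=>": 2, "|": 3, "&": 4}
_UNTIL_PRECEDENCE = 5


class _HctlParser:
    def __init__(self, text: str) -> None:
        self.tokens = _h_tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> HctlFormula:
        formula = self.parse_binary(1)
        kind, val, pos = self.peek()
        if kind != "end":
            raise HctlSyntaxError(f"unexpected trailing {val!r}", pos)
        return formula

    def parse_binary(self, min_prec: int) -> HctlFormula:
        kind, val, _ = self.peek()
        if kind == "hybrid":
            self.advance()
            head, name = val[0], val[val.index("{") + 1 : val.index("}")]
            body = self.parse_binary(1)  # hybrid heads reach as far right as possible
            if head == "3":
                return Exists(name, body)
            if head == "!":
                return Bind(name, body)
            return Jump(name, body)
        left = self.parse_unary()
        while True:
            kind, val, _ = self.peek()
            if kind == "word" and val in _TEMPORAL_BINARY:
                if _UNTIL_PRECEDENCE < min_prec:
                    return left
                self.advance()
                right = self.parse_binary(_UNTIL_PRECEDENCE)
                left = Until(val, left, right)
                continue
            if kind != "op" or val not in _H_PRECEDENCE or _H_PRECEDENCE[val] < min_prec:
                return left
            self.advance()
            next_prec = _H_PRECEDENCE[val] + (0 if val in ("=>", "<=>") else 1)
            right = self.parse_binary(next_prec)
            left = HBin(val, left, right)

    def parse_unary(self) -> HctlFormula:
        kind, val, pos = self.peek()
        if kind == "op" and val == "~":
            self.advance()
            inner = self.parse_unary()
            if isinstance(inner, Atom):
                return Atom(inner.variable, not inner.value)
            return HNot(inner)
        if kind == "word" and val in _TEMPORAL_UNARY:
            self.advance()
            return Temporal(val, self.parse_unary())
        return self.parse_primary()

    def parse_primary(self) -> HctlFormula:
        kind, val, pos = self.advance()
        if kind == "op" and val == "(":
            inner = self.parse_binary(1)
            k2, v2, p2 = self.advance()
            if not (k2 == "op" and v2 == ")"):
                raise HctlSyntaxError(f"expected ')', found {v2 or 'end of input'!r}", p2)
            return inner
        if kind == "statevar":
            return StateVar(val[1:-1])
        if kind == "word":
            if val == "true":
                return HConst(True)
            if val == "false":
                return HConst(False)
            return Atom(val, True)
        if kind == "hybrid":
            # a hybrid head inside a unary chain, e.g. "EF 3{x}: ..." —
            # rewind and let parse_binary handle it
            self.i -= 1
            return self.parse_binary(1)
        raise HctlSyntaxError(f"expected a formula, found {val or 'end of input'!r}", pos)


def parse_hctl(text: str) -> HctlFormula:
    """Parse the concrete syntax above into an :class:`HctlFormula`."""
    return _HctlParser(text).parse()


def to_text(formula: HctlFormula) -> str:
    """Fully parenthesised rendering; ``parse_hctl`` inverts it."""
    if isinstance(formula, HConst):
        return "true" if formula.value else "false"
    if isinstance(formula, Atom):
        return formula.variable if formula.value else f"~{formula.variable}"
    if isinstance(formula, StateVar):
        return "{" + formula.name + "}"
    if isinstance(formula, FixedPointAtom):
        raise ValueError("the structural fixed-point atom has no concrete syntax")
    if isinstance(formula, HNot):
        return f"~({to_text(formula.arg)})"
    if isinstance(formula, HBin):
        return f"({to_text(formula.left)} {formula.op} {to_text(formula.right)})"
    if isinstance(formula, Temporal):
        return f"{formula.op} ({to_text(formula.arg)})"
    if isinstance(formula, Until):
        return f"({to_text(formula.left)} {formula.op} {to_text(formula.right)})"
    if isinstance(formula, Bind):
        return f"!{{{formula.var}}}: ({to_text(formula.body)})"
    if isinstance(formula, Jump):
        return f"@{{{formula.var}}}: ({to_text(formula.body)})"
    if isinstance(formula, Exists):
        return f"3{{{formula.var}}}: ({to_text(formula.body)})"
    raise TypeError(f"not an HCTL formula: {formula!r}")


# ---------------------------------------------------------------------------
# structural checks


def check_scoping(formula: HctlFormula, scope: FrozenSet[str] = frozenset()) -> None:
    """Every ``{x}`` and ``@{x}:`` must be under a binder/quantifier for
    ``x``; rebinding a name on one AST path is rejected."""
    if isinstance(formula, StateVar):
        if formula.name not in scope:
            raise ValueError(f"state variable {{{formula.name}}} is not bound")
    elif isinstance(formula, (Bind, Exists)):
        if formula.var in scope:
            raise ValueError(f"state variable {{{formula.var}}} bound twice")
        check_scoping(formula.body, scope | {formula.var})
    elif isinstance(formula, Jump):
        if formula.var not in scope:
            raise ValueError(f"state variable {{{formula.var}}} is not bound")
        check_scoping(formula.body, scope)
    elif isinstance(formula, HNot):
        check_scoping(formula.arg, scope)
    elif isinstance(formula, Temporal):
        check_scoping(formula.arg, scope)
    elif isinstance(formula, (HBin, Until)):
        check_scoping(formula.left, scope)
        check_scoping(formula.right, scope)


def check_atoms(formula: HctlFormula, variables: Sequence[str]) -> None:
    known = set(variables)

    def rec(node: HctlFormula) -> None:
        if isinstance(node, Atom) and node.variable not in known:
            raise ValueError(f"unknown variable {node.variable!r} in formula")
        for child in _children(node):
            rec(child)

    rec(formula)


def state_var_names(formula: HctlFormula) -> Set[str]:
    out: Set[str] = set()

    def rec(node: HctlFormula) -> None:
        if isinstance(node, (Bind, Exists, Jump)):
            out.add(node.var)
        if isinstance(node, StateVar):
            out.add(node.name)
        for child in _children(node):
            rec(child)

    rec(formula)
    return out


def _children(node: HctlFormula) -> Tuple[HctlFormula, ...]:
    if isinstance(node, HNot):
        return (node.arg,)
    if isinstance(node, Temporal):
        return (node.arg,)
    if isinstance(node, (HBin, Until)):
        return (node.left, node.right)
    if isinstance(node, (Bind, Jump, Exists)):
        return (node.body,)
    return ()


# ---------------------------------------------------------------------------
# symbolic model checking


def check(formula: HctlFormula, ctx: SymbolicContext) -> int:
    """Coloured set of (state, colour) pairs satisfying the formula.

    For formulas with free state variables the result additionally
    ranges over their copy bits.
    """
    check_atoms(formula, ctx.psbn.graph.variables)
    b = ctx.bdd

    def diagonal(var: str) -> int:
        copies = ctx.copy_levels(var)
        acc = TRUE
        for v in ctx.state_variables:
            state_bit = b.var(v)
            copy_bit = b._mk(copies[v], FALSE, TRUE)
            acc = b.and_(acc, b.iff(state_bit, copy_bit))
        return acc

    def rec(node: HctlFormula) -> int:
        if isinstance(node, HConst):
            return TRUE if node.value else FALSE
        if isinstance(node, Atom):
            return b.literal(node.variable, node.value)
        if isinstance(node, StateVar):
            return diagonal(node.name)
        if isinstance(node, FixedPointAtom):
            return dynamics.fixed_points(ctx)
        if isinstance(node, HNot):
            return b.not_(rec(node.arg))
        if isinstance(node, HBin):
            left, right = rec(node.left), rec(node.right)
            op = {"&": b.and_, "|": b.or_, "=>": b.imp, "<=>": b.iff}
            return op[node.op](left, right)
        if isinstance(node, Temporal):
            if node.op == "EX":
                return dynamics.pre_image(ctx, rec(node.arg))
            if node.op == "AX":
                return b.not_(dynamics.pre_image(ctx, b.not_(rec(node.arg))))
            if node.op == "EF":
                return _lfp_ef(rec(node.arg))
            if node.op == "AG":
                return b.not_(_lfp_ef(b.not_(rec(node.arg))))
            if node.op == "EG":
                return _gfp_eg(rec(node.arg))
            if node.op == "AF":
                return b.not_(_gfp_eg(b.not_(rec(node.arg))))
            raise ValueError(f"unknown temporal operator {node.op!r}")
        if isinstance(node, Until):
            left, right = rec(node.left), rec(node.right)
            if node.op == "EU":
                return _lfp_until(left, right, existential=True)
            return _lfp_until(left, right, existential=False)
        if isinstance(node, Bind):
            inner = b.and_(rec(node.body), diagonal(node.var))
            return b.exists(inner, ctx.copy_levels(node.var).values())
        if isinstance(node, Jump):
            inner = b.and_(rec(node.body), diagonal(node.var))
            return b.exists(inner, ctx.state_levels())
        if isinstance(node, Exists):
            return b.exists(rec(node.body), ctx.copy_levels(node.var).values())
        raise TypeError(f"not an HCTL formula: {node!r}")

    def _lfp_ef(target: int) -> int:
        reach = target
        while True:
            nxt = b.or_(reach, dynamics.pre_image(ctx, reach))
            if nxt == reach:
                return reach
            reach = nxt

    def _gfp_eg(inv: int) -> int:
        current = inv
        while True:
            nxt = b.and_(current, dynamics.pre_image(ctx, current))
            if nxt == current:
                return current
            current = nxt

    def _lfp_until(hold: int, target: int, existential: bool) -> int:
        current = FALSE
        while True:
            if existential:
                step = dynamics.pre_image(ctx, current)
            else:
                step = b.not_(dynamics.pre_image(ctx, b.not_(current)))
            nxt = b.or_(target, b.and_(hold, step))
            if nxt == current:
                return current
            current = nxt

    return rec(formula)


def satisfying_colours(formula: HctlFormula, ctx: SymbolicContext) -> int:
    """Colours under which *every* state satisfies the closed formula."""
    check_scoping(formula)  # raises on free state variables
    result = check(formula, ctx)
    b = ctx.bdd
    state_support = set(b.support(result)) & set(ctx.state_levels())
    if state_support:
        names = ", ".join(sorted(b.name_of(l) for l in state_support))
        warnings.warn(
            f"formula result depends on state bits ({names}); colours are "
            "required to satisfy it in every state",
            stacklevel=2,
        )
    return b.forall(result, ctx.state_levels())


# ---------------------------------------------------------------------------
# templates


def observation_atom(observation: Observation) -> HctlFormula:
    """Conjunction of literals fixed by the observation."""
    parts = [
        Atom(v, bool(observation.values[v])) for v in sorted(observation.values)
    ]
    return conj(parts)


def attractor_formula(var: str = "y") -> HctlFormula:
    """``!{y}: AG EF {y}`` — true exactly in attractor states."""
    return Bind(var, Temporal("AG", Temporal("EF", StateVar(var))))


def _at_least_attractors(m: int) -> HctlFormula:
    names = [f"x{i + 1}" for i in range(m)]
    parts: List[HctlFormula] = [
        Jump(x, attractor_formula()) for x in names
    ]
    for i in range(m):
        for j in range(i + 1, m):
            parts.append(
                Jump(names[i], HNot(Temporal("EF", StateVar(names[j]))))
            )
    body = conj(parts)
    for x in reversed(names):
        body = Exists(x, body)
    return body


def build_template(
    prop: DynamicProperty, datasets: Sequence[Dataset]
) -> HctlFormula:
    """Expand a dynamic-property template into a closed HCTL formula."""
    by_id = {d.id: d for d in datasets}

    def dataset_of(dataset_id: str) -> Dataset:
        if dataset_id not in by_id:
            raise ValueError(f"unknown dataset {dataset_id!r}")
        return by_id[dataset_id]

    if isinstance(prop, RawHctl):
        formula = parse_hctl(prop.text)
        check_scoping(formula)
        return formula

    if isinstance(prop, FixedPointsTemplate):
        dataset = dataset_of(prop.dataset_id)
        if not dataset.observations:
            raise ValueError(f"dataset {prop.dataset_id!r} is empty")
        parts = [
            Exists("x", Jump("x", HBin("&", observation_atom(o), FixedPointAtom())))
            for o in dataset.observations
        ]
        return conj(parts)

    if isinstance(prop, AttractorCountTemplate):
        m, upper = prop.min_count, prop.max_count
        if m < 1 or (upper is not None and upper < m):
            raise ValueError(f"invalid attractor count bounds [{m}, {upper}]")
        cap = max(m, (upper + 1) if upper is not None else m)
        if cap > MAX_ATTRACTOR_BOUND:
            raise ValueError(
                f"attractor count bound {cap} exceeds the supported maximum "
                f"of {MAX_ATTRACTOR_BOUND} (each attractor costs one full "
                "set of state-variable copies)"
            )
        formula: HctlFormula = _at_least_attractors(m)
        if upper is not None:
            formula = HBin("&", formula, HNot(_at_least_attractors(upper + 1)))
        return formula

    if isinstance(prop, AttractorCoverageTemplate):
        dataset = dataset_of(prop.dataset_id)
        outside = conj(
            [HNot(observation_atom(o)) for o in dataset.observations]
        )
        stray = Exists("x", Jump("x", HBin("&", attractor_formula(), outside)))
        return HNot(stray)

    if isinstance(prop, TimeSeriesTemplate):
        dataset = dataset_of(prop.dataset_id)
        if not dataset.observations:
            raise ValueError(f"dataset {prop.dataset_id!r} is empty")
        chain = observation_atom(dataset.observations[-1])
        for o in reversed(dataset.observations[:-1]):
            chain = HBin("&", observation_atom(o), Temporal("EF", chain))
        return Exists("x", Jump("x", chain))

    raise TypeError(f"not a dynamic property: {prop!r}")
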