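"""Static (update-function) properties and their symbolic compilation.

Each property compiles to a *colour set*: a decision diagram over the
parameter bits that is true exactly for the interpretations satisfying
the property.

Two families exist.  Regulation-level properties (essentiality and
monotonicity of an edge ``u -> v``) are defined on the fully compiled
update function ``F_v(s, p)`` — the only definition that is well formed
when update expressions are compound, e.g. ``g(u) | w``:

* essential:  some state ``s`` has ``F_v(s[u:=0]) != F_v(s[u:=1])``;
* monotone positive: for all ``s``, ``F_v(s[u:=0]) => F_v(s[u:=1])``
  (negative: the reversed implication).

Symbol-level properties apply the same definitions to the raw truth
table of a function symbol, quantifying over the remaining arguments.

Free-form properties are closed first-order formulas over Booleans:
quantifiers range over ``{0,1}`` and are expanded exhaustively, atoms
are bound variables, constants, and symbol applications.  Network state
variables may not appear — state-dependent requirements belong to the
dynamic (HCTL) properties.  Surface syntax adds ``forall a: ...`` and
``exists a: ...`` (binding as far right as possible) on top of the
expression syntax of :mod:`bnsketch.expressions`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

from . import expressions as ex
from .bdd import FALSE, TRUE
from .encoding import SymbolicContext, row_bit
from .model import PSBN
from .properties import (
    FolFormula,
    RegulationEssential,
    RegulationMonotone,
    StaticProperty,
    SymbolArgEssential,
    SymbolArgMonotone,
)


# ---------------------------------------------------------------------------
# first-order AST and parser


@dataclass(frozen=True)
class Quant(ex.Expr):
    """``forall``/``exists`` over one Boolean-valued bound variable."""

    kind: str  # "forall" | "exists"
    var: str
    body: ex.Expr


class _FolParser(ex._Parser):
    def parse_unary(self) -> ex.Expr:
        kind, val, pos = self.peek()
        if kind == "ident" and val in ("forall", "exists"):
            self.advance()
            vkind, vname, vpos = self.advance()
            if vkind != "ident":
                raise ex.ExprSyntaxError("expected a bound-variable name", vpos)
            self.expect(":")
            return Quant(val, vname, self.parse_binary(1))
        return super().parse_unary()


def parse_fol(text: str) -> ex.Expr:
    """Parse a first-order property; returns an AST with :class:`Quant` nodes."""
    return _FolParser(text).parse()


def fol_to_text(node: ex.Expr) -> str:
    if isinstance(node, Quant):
        return f"{node.kind} {node.var}: ({fol_to_text(node.body)})"
    if isinstance(node, ex.Not):
        return "!" + _wrap(node.arg)
    if isinstance(node, ex.BinOp):
        return f"{_wrap(node.left)} {node.op} {_wrap(node.right)}"
    if isinstance(node, ex.App):
        return f"{node.func}({', '.join(fol_to_text(a) for a in node.args)})"
    return ex.to_text(node)


def _wrap(node: ex.Expr) -> str:
    text = fol_to_text(node)
    if isinstance(node, (ex.BinOp, Quant)):
        return f"({text})"
    return text


def check_fol(ast: ex.Expr, psbn: PSBN, bound: frozenset = frozenset()) -> None:
    """Raise ``ValueError`` on free variables or bad symbol applications."""
    if isinstance(ast, Quant):
        if ast.kind not in ("forall", "exists"):
            raise ValueError(f"unknown quantifier {ast.kind!r}")
        check_fol(ast.body, psbn, bound | {ast.var})
    elif isinstance(ast, ex.Name):
        if ast.name not in bound:
            raise ValueError(
                f"free variable {ast.name!r}: first-order properties may only "
                "mention quantified Booleans, constants and function symbols"
            )
    elif isinstance(ast, ex.Not):
        check_fol(ast.arg, psbn, bound)
    elif isinstance(ast, ex.BinOp):
        check_fol(ast.left, psbn, bound)
        check_fol(ast.right, psbn, bound)
    elif isinstance(ast, ex.App):
        symbol = psbn.symbol(ast.func)
        if symbol is None:
            raise ValueError(f"unknown symbol {ast.func!r}")
        if symbol.arity != len(ast.args):
            raise ValueError(
                f"symbol {ast.func!r} has arity {symbol.arity}, applied to "
                f"{len(ast.args)} arguments"
            )
        for a in ast.args:
            check_fol(a, psbn, bound)
    elif not isinstance(ast, ex.Const):
        raise TypeError(f"not a first-order formula: {ast!r}")


# ---------------------------------------------------------------------------
# compilation to colour sets


def compile_fol(ast: ex.Expr, ctx: SymbolicContext) -> int:
    """Colour set of a closed first-order formula.

    Quantifiers are expanded over the finite Boolean domain; the result
    depends only on parameter bits.
    """
    check_fol(ast, ctx.psbn)
    b = ctx.bdd

    def comp(node: ex.Expr, env: Mapping[str, int]) -> int:
        if isinstance(node, Quant):
            lo = comp(node.body, {**env, node.var: FALSE})
            hi = comp(node.body, {**env, node.var: TRUE})
            return b.and_(lo, hi) if node.kind == "forall" else b.or_(lo, hi)
        if isinstance(node, ex.Const):
            return TRUE if node.value else FALSE
        if isinstance(node, ex.Name):
            return env[node.name]
        if isinstance(node, ex.Not):
            return b.not_(comp(node.arg, env))
        if isinstance(node, ex.BinOp):
            left = comp(node.left, env)
            right = comp(node.right, env)
            op = {"&": b.and_, "|": b.or_, "^": b.xor, "=>": b.imp, "<=>": b.iff}
            return op[node.op](left, right)
        if isinstance(node, ex.App):
            return ctx.apply_symbol(node.func, [comp(a, env) for a in node.args])
        raise TypeError(f"not a first-order formula: {node!r}")

    return comp(ast, {})


def essentiality_of_regulation(ctx: SymbolicContext, source: str, target: str) -> int:
    """Colours under which flipping ``source`` can change ``F_target``."""
    _require_regulation(ctx.psbn, source, target)
    b = ctx.bdd
    f = ctx.update_function(target)
    lvl = ctx.state_level(source)
    low = b.restrict(f, {lvl: False})
    high = b.restrict(f, {lvl: True})
    return b.exists(b.xor(low, high), ctx.state_levels())


def monotonicity_of_regulation(
    ctx: SymbolicContext, source: str, target: str, direction: str
) -> int:
    """Colours under which ``F_target`` is monotone in ``source``."""
    _require_regulation(ctx.psbn, source, target)
    _require_direction(direction)
    b = ctx.bdd
    f = ctx.update_function(target)
    lvl = ctx.state_level(source)
    low = b.restrict(f, {lvl: False})
    high = b.restrict(f, {lvl: True})
    if direction == "positive":
        body = b.imp(low, high)
    else:
        body = b.imp(high, low)
    return b.forall(body, ctx.state_levels())


def symbol_arg_essential(ctx: SymbolicContext, symbol: str, arg_index: int) -> int:
    """Colours whose table for ``symbol`` depends on argument ``arg_index``."""
    arity = _require_arg(ctx, symbol, arg_index)
    b = ctx.bdd
    terms = []
    for row in range(1 << arity):
        if row_bit(row, arg_index, arity):
            continue
        partner = row | (1 << (arity - 1 - arg_index))
        terms.append(b.xor(ctx.param_var(symbol, row), ctx.param_var(symbol, partner)))
    return b.or_many(terms)


def symbol_arg_monotone(
    ctx: SymbolicContext, symbol: str, arg_index: int, direction: str
) -> int:
    """Colours whose table for ``symbol`` is monotone in one argument."""
    arity = _require_arg(ctx, symbol, arg_index)
    _require_direction(direction)
    b = ctx.bdd
    acc = TRUE
    for row in range(1 << arity):
        if row_bit(row, arg_index, arity):
            continue
        partner = row | (1 << (arity - 1 - arg_index))
        low = ctx.param_var(symbol, row)
        high = ctx.param_var(symbol, partner)
        clause = b.imp(low, high) if direction == "positive" else b.imp(high, low)
        acc = b.and_(acc, clause)
    return acc


def compile_static(ctx: SymbolicContext, prop: StaticProperty) -> int:
    """Dispatch one static property to its colour-set compiler."""
    if isinstance(prop, RegulationEssential):
        return essentiality_of_regulation(ctx, prop.source, prop.target)
    if isinstance(prop, RegulationMonotone):
        return monotonicity_of_regulation(ctx, prop.source, prop.target, prop.direction)
    if isinstance(prop, SymbolArgEssential):
        return symbol_arg_essential(ctx, prop.symbol, prop.arg_index)
    if isinstance(prop, SymbolArgMonotone):
        return symbol_arg_monotone(ctx, prop.symbol, prop.arg_index, prop.direction)
    if isinstance(prop, FolFormula):
        return compile_fol(parse_fol(prop.text), ctx)
    raise TypeError(f"not a static property: {prop!r}")


def implied_static_properties(psbn: PSBN) -> Tuple[StaticProperty, ...]:
    """Properties implied by regulation annotations in the influence graph.

    ``sign`` other than ``unknown`` yields a monotonicity property;
    ``essential == "true"`` yields an essentiality property.  ``unknown``
    flags yield nothing.
    """
    out = []
    for r in psbn.graph.regulations:
        if r.sign in ("positive", "negative"):
            out.append(RegulationMonotone(r.source, r.target, r.sign))
        if r.essential == "true":
            out.append(RegulationEssential(r.source, r.target))
    return tuple(out)


# ---------------------------------------------------------------------------


def _require_regulation(psbn: PSBN, source: str, target: str) -> None:
    if psbn.graph.regulation(source, target) is None:
        raise ValueError(f"regulation {source}->{target} is not declared")


def _require_direction(direction: str) -> None:
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be positive or negative, got {direction!r}")


def _require_arg(ctx: SymbolicContext, symbol: str, arg_index: int) -> int:
    sym = ctx.psbn.symbol(symbol)
    if sym is None:
        raise ValueError(f"unknown symbol {symbol!r}")
    if not 0 <= arg_index < sym.arity:
        raise ValueError(
            f"argument index {arg_index} out of range for {symbol!r} "
            f"(arity {sym.arity})"
        )
    return sym.arity
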