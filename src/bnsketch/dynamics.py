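"""Symbolic operators of the coloured asynchronous transition graph.

The semantics is fully asynchronous: a transition picks one variable
``v`` whose update function disagrees with its current value and flips
it.  Because a transition must change the state, fixed points have no
outgoing transitions (no self-loops); they are the deadlocks of the
graph.

All operators act on *coloured* sets — decision diagrams over state
bits and parameter bits (plus any HCTL copy bits, which the operators
leave untouched) — so one call covers every interpretation at once.
Slicing the operators at a single colour reproduces the explicit
transition graph of the instantiated network.
"""

from __future__ import annotations

from typing import List

from .bdd import FALSE, TRUE
from .encoding import SymbolicContext


def flip_enabled(ctx: SymbolicContext, variable: str) -> int:
    """States/colours where ``variable`` can fire: ``F_v(s,p) != s_v``."""
    b = ctx.bdd
    return b.xor(ctx.update_function(variable), ctx.state_var(variable))


def post_image(ctx: SymbolicContext, states: int) -> int:
    """All single-step asynchronous successors of a coloured set."""
    b = ctx.bdd
    out = FALSE
    for v in ctx.state_variables:
        firing = b.and_(states, flip_enabled(ctx, v))
        out = b.or_(out, b.flip(firing, ctx.state_level(v)))
    return out


def pre_image(ctx: SymbolicContext, states: int) -> int:
    """All single-step asynchronous predecessors of a coloured set."""
    b = ctx.bdd
    out = FALSE
    for v in ctx.state_variables:
        reaches = b.flip(states, ctx.state_level(v))
        out = b.or_(out, b.and_(reaches, flip_enabled(ctx, v)))
    return out


def fixed_points(ctx: SymbolicContext) -> int:
    """Structural fixed points: ``F_v(s,p) = s_v`` for every variable.

    These coincide with the deadlock states of the transition graph.
    """
    b = ctx.bdd
    acc = TRUE
    for v in ctx.state_variables:
        acc = b.and_(acc, b.iff(ctx.update_function(v), ctx.state_var(v)))
    return acc


def reach_fwd(ctx: SymbolicContext, seed: int) -> int:
    """States reachable from the seed set (reflexive-transitive closure)."""
    b = ctx.bdd
    reach = seed
    while True:
        nxt = b.or_(reach, post_image(ctx, reach))
        if nxt == reach:
            return reach
        reach = nxt


def reach_bwd(ctx: SymbolicContext, seed: int) -> int:
    """States that can reach the seed set."""
    b = ctx.bdd
    reach = seed
    while True:
        nxt = b.or_(reach, pre_image(ctx, reach))
        if nxt == reach:
            return reach
        reach = nxt
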