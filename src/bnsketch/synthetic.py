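"""Synthetic sketch generation from a hidden ground-truth network.

The generator draws a random concrete Boolean network, then *forgets*
parts of it to produce a sketch whose candidate set provably contains
the ground truth:

* regulators are drawn per variable and the update table is resampled
  until every declared regulator is essential, so the emitted influence
  graph is truthful;
* regulation signs are annotated only where the true table really is
  monotone (each with a stated probability), and essentiality
  annotations are always genuine;
* a chosen fraction of variables have their update expression replaced
  by a fresh function symbol applied to all regulators — these are the
  unknowns the inference must recover;
* observations are either true fixed points of the ground truth (with a
  fixed-points property) or states along a genuine asynchronous
  trajectory (with a time-series property).

Because every emitted constraint holds for the ground truth by
construction, the generating colour is always a member of the inferred
candidate set, and with nothing hidden the candidate count is exactly 1.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .encoding import (
    Colour,
    ConcreteBN,
    build_parameter_space,
    row_bit,
    table_to_expr,
)
from .model import (
    PSBN,
    Dataset,
    FunctionSymbol,
    InfluenceGraph,
    Observation,
    Regulation,
    Sketch,
    default_update_expr,
)
from .properties import FixedPointsTemplate, TimeSeriesTemplate

_MAX_TABLE_RETRIES = 200
_MAX_FIXED_POINT_RETRIES = 50


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic sketch.

    ``density`` is the probability that any given variable regulates
    another (regulator counts are clamped to ``[1, max_regulators]``);
    ``hidden_fraction`` the fraction of variables whose update is
    replaced by an uninterpreted symbol; ``sign_probability`` the chance
    that a genuinely monotone regulation is annotated with its sign;
    ``category`` selects fixed-point (``steady_state``) or trajectory
    (``time_series``) observations.
    """

    n_vars: int = 4
    density: float = 0.4
    hidden_fraction: float = 0.5
    sign_probability: float = 0.5
    n_observations: int = 1
    category: str = "steady_state"
    max_regulators: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vars < 1:
            raise ValueError("n_vars must be at least 1")
        for name in ("density", "hidden_fraction", "sign_probability"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.category not in ("steady_state", "time_series"):
            raise ValueError(f"unknown observation category {self.category!r}")


def _draw_regulators(
    rng: random.Random, variables: Sequence[str], spec: SyntheticSpec
) -> Dict[str, Tuple[str, ...]]:
    out: Dict[str, Tuple[str, ...]] = {}
    for v in variables:
        chosen = [u for u in variables if rng.random() < spec.density]
        if not chosen:
            chosen = [rng.choice(list(variables))]
        if len(chosen) > spec.max_regulators:
            chosen = rng.sample(chosen, spec.max_regulators)
        out[v] = tuple(sorted(chosen))
    return out


def _all_essential(table: Sequence[int], arity: int) -> bool:
    for i in range(arity):
        bit = 1 << (arity - 1 - i)
        if all(
            table[row] == table[row | bit]
            for row in range(1 << arity)
            if not row_bit(row, i, arity)
        ):
            return False
    return True


def _draw_table(rng: random.Random, arity: int) -> Tuple[int, ...]:
    for _ in range(_MAX_TABLE_RETRIES):
        table = tuple(rng.randrange(2) for _ in range(1 << arity))
        if _all_essential(table, arity):
            return table
    raise RuntimeError(f"could not draw an all-essential table of arity {arity}")

def _monotone_direction(table: Sequence[int], arity: int, i: int) -> Optional[str]:
    bit = 1 << (arity - 1 - i)
    rows = [row for row in range(1 << arity) if not row_bit(row, i, arity)]
    if all(table[row] <= table[row | bit] for row in rows):
        return "positive"
    if all(table[row] >= table[row | bit] for row in rows):
        return "negative"
    return None


def _fixed_points(bn: ConcreteBN) -> List[Dict[str, int]]:
    n = len(bn.variables)
    out = []
    for s in range(1 << n):
        state = {v: (s >> (n - 1 - i)) & 1 for i, v in enumerate(bn.variables)}
        if bn.is_fixed_point(state):
            out.append(state)
    return out


def _trajectory(
    rng: random.Random, bn: ConcreteBN, length: int
) -> List[Dict[str, int]]:
    n = len(bn.variables)
    state = {v: rng.randrange(2) for v in bn.variables}
    states = [dict(state)]
    while len(states) < length:
        enabled = [v for v in bn.variables if bn.value(v, state) != state[v]]
        if not enabled:
            states.append(dict(state))  # stuck in a fixed point; EF is reflexive
            continue
        v = rng.choice(enabled)
        state[v] = 1 - state[v]
        states.append(dict(state))
    return states


def generate_sketch(spec: SyntheticSpec) -> Tuple[Sketch, ConcreteBN, Colour]:
    """Draw ``(sketch, ground_truth, ground_colour)`` under the given conditions.

    ``ground_colour`` is the interpretation of the sketch's symbols that
    reproduces the ground truth; it satisfies every emitted property.
    """
    rng = random.Random(spec.seed)
    variables = tuple(f"v{i}" for i in range(spec.n_vars))
    last_error: Optional[str] = None
    for _ in range(_MAX_FIXED_POINT_RETRIES):
        regulators = _draw_regulators(rng, variables, spec)
        tables = {v: _draw_table(rng, len(regulators[v])) for v in variables}
        bn = ConcreteBN(
            variables=tuple(sorted(variables)),
            regulators=regulators,
            tables=tables,
        )
        if spec.category == "steady_state":
            points = _fixed_points(bn)
            if len(points) < spec.n_observations:
                last_error = (
                    f"ground truth has {len(points)} fixed points, "
                    f"{spec.n_observations} observations requested"
                )
                continue
            observed = rng.sample(points, spec.n_observations)
        else:
            observed = _trajectory(rng, bn, max(2, spec.n_observations))
        sketch = _assemble(rng, spec, bn, observed)
        return sketch, bn, ground_colour(sketch, bn)
    raise RuntimeError(f"could not generate a suitable ground truth: {last_error}")


def _assemble(
    rng: random.Random,
    spec: SyntheticSpec,
    bn: ConcreteBN,
    observed: List[Dict[str, int]],
) -> Sketch:
    regulations = []
    for v in bn.variables:
        regs = bn.regulators[v]
        k = len(regs)
        for i, u in enumerate(regs):
            sign = "unknown"
            direction = _monotone_direction(bn.tables[v], k, i)
            if direction is not None and rng.random() < spec.sign_probability:
                sign = direction
            essential = "true" if rng.random() < spec.sign_probability else "unknown"
            regulations.append(Regulation(u, v, sign=sign, essential=essential))
    graph = InfluenceGraph(bn.variables, regulations)

    hidden = [v for v in bn.variables if rng.random() < spec.hidden_fraction]
    symbols: List[FunctionSymbol] = []
    update = {}
    used = set(bn.variables)
    for v in bn.variables:
        if v in hidden:
            symbol, expr = default_update_expr(v, graph, used)
            symbols.append(symbol)
            used.add(symbol.name)
            update[v] = expr
        else:
            update[v] = table_to_expr(bn.regulators[v], bn.tables[v])
    psbn = PSBN(graph=graph, symbols=tuple(symbols), update=update)

    category = spec.category
    observations = tuple(
        Observation(id=f"o{i}", values=dict(state)) for i, state in enumerate(observed)
    )
    dataset = Dataset(id="data", observations=observations, category=category)
    if category == "steady_state":
        prop = FixedPointsTemplate(dataset_id="data", id="fixed_points")
    else:
        prop = TimeSeriesTemplate(dataset_id="data", id="time_series")
    return Sketch(
        psbn=psbn,
        datasets=(dataset,),
        dynamic_properties=(prop,),
    )


def ground_colour(sketch: Sketch, bn: ConcreteBN) -> Colour:
    """Interpretation of the sketch's symbols matching the ground truth."""
    space = build_parameter_space(sketch.psbn)
    tables = {}
    for s in space.symbols:
        variable = s.name[len("g_"):]
        tables[s.name] = bn.tables[variable]
    return space.colour_from_tables(tables)
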