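"""Domain model for Boolean network sketches.

A sketch is a partial specification of a Boolean network: an influence
graph of possible regulations, a partially specified Boolean network
(PSBN) whose update expressions may contain uninterpreted function
symbols, first-order properties of the update functions, datasets of
binarized observations, and HCTL properties of the asynchronous
dynamics.  This module holds the data types, structural validation and
the defaulting rule that gives a variable without an explicit update
expression a fresh symbol applied to all of its regulators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from . import expressions as ex
from .properties import (
    AttractorCountTemplate,
    AttractorCoverageTemplate,
    DynamicProperty,
    FixedPointsTemplate,
    FolFormula,
    RawHctl,
    RegulationEssential,
    RegulationMonotone,
    StaticProperty,
    SymbolArgEssential,
    SymbolArgMonotone,
    TimeSeriesTemplate,
    property_label,
)

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

SIGNS = ("positive", "negative", "unknown")
ESSENTIAL = ("true", "unknown")
DATASET_CATEGORIES = ("unspecified", "steady_state", "time_series")


def is_identifier(name: str) -> bool:
    return bool(_IDENT_RE.match(name))


@dataclass(frozen=True)
class Regulation:
    """A possible regulation (edge of the influence graph).

    ``sign`` records monotonicity knowledge (``positive`` = activation,
    ``negative`` = inhibition, ``unknown`` = unconstrained) and
    ``essential`` whether the regulation must have an effect in every
    candidate (``true``) or may be vacuous (``unknown``).  ``unknown``
    flags generate no constraint at all.
    """

    source: str
    target: str
    sign: str = "unknown"
    essential: str = "unknown"


@dataclass(frozen=True)
class InfluenceGraph:
    """Variables plus the binary relation of possible regulations."""

    variables: Tuple[str, ...]
    regulations: Tuple[Regulation, ...] = ()

    def __init__(
        self,
        variables: Iterable[str],
        regulations: Iterable[Union[Regulation, Tuple[str, str]]] = (),
    ) -> None:
        regs = tuple(
            r if isinstance(r, Regulation) else Regulation(r[0], r[1])
            for r in regulations
        )
        object.__setattr__(self, "variables", tuple(variables))
        object.__setattr__(self, "regulations", regs)

    def regulators_of(self, target: str) -> Tuple[str, ...]:
        """Regulators of ``target`` in the canonical (lexicographic) order."""
        return tuple(sorted(r.source for r in self.regulations if r.target == target))

    def regulation(self, source: str, target: str) -> Optional[Regulation]:
        for r in self.regulations:
            if r.source == source and r.target == target:
                return r
        return None


@dataclass(frozen=True)
class FunctionSymbol:
    """An uninterpreted Boolean function symbol of fixed arity."""

    name: str
    arity: int


@dataclass(frozen=True)
class PSBN:
    """A partially specified Boolean network.

    Every variable has exactly one update expression; expressions may
    apply the declared function symbols to sub-expressions.  Substituting
    a concrete truth table for every symbol (an interpretation, also
    called a colour) yields a concrete Boolean network.
    """

    graph: InfluenceGraph
    symbols: Tuple[FunctionSymbol, ...]
    update: Mapping[str, ex.Expr]

    def symbol(self, name: str) -> Optional[FunctionSymbol]:
        for s in self.symbols:
            if s.name == name:
                return s
        return None

    @property
    def variables(self) -> Tuple[str, ...]:
        return self.graph.variables


@dataclass(frozen=True)
class Observation:
    """One binarized measurement: a partial 0/1 assignment of variables.

    Variables absent from ``values`` are unconstrained (blank cells in
    the CSV form).
    """

    id: str
    values: Mapping[str, int]


@dataclass(frozen=True)
class Dataset:
    """An ordered list of observations; order matters for time series."""

    id: str
    observations: Tuple[Observation, ...]
    category: str = "unspecified"

    def observation(self, obs_id: str) -> Optional[Observation]:
        for o in self.observations:
            if o.id == obs_id:
                return o
        return None


@dataclass(frozen=True)
class Sketch:
    """The full partial specification handed to the inference engine."""

    psbn: PSBN
    static_properties: Tuple[StaticProperty, ...] = ()
    datasets: Tuple[Dataset, ...] = ()
    dynamic_properties: Tuple[DynamicProperty, ...] = ()
    annotations: Mapping[str, str] = field(default_factory=dict)

    def dataset(self, dataset_id: str) -> Optional[Dataset]:
        for d in self.datasets:
            if d.id == dataset_id:
                return d
        return None


@dataclass(frozen=True)
class Issue:
    """One validation finding; ``severity`` is ``error`` or ``warning``."""

    severity: str
    element: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.element}: {self.message}"


# ---------------------------------------------------------------------------
# defaulting


def default_update_expr(
    variable: str, graph: InfluenceGraph, used_names: Set[str]
) -> Tuple[FunctionSymbol, ex.Expr]:
    """Fresh symbol applied to all regulators of ``variable``.

    The symbol is named ``g_<variable>`` (suffixed ``_1``, ``_2``, ... on
    collision with ``used_names``); regulators appear in lexicographic
    order, so the construction is deterministic.
    """
    if variable not in graph.variables:
        raise ValueError(f"unknown variable {variable!r}")
    regulators = graph.regulators_of(variable)
    name = f"g_{variable}"
    if name in used_names:
        k = 1
        while f"{name}_{k}" in used_names:
            k += 1
        name = f"{name}_{k}"
    symbol = FunctionSymbol(name, len(regulators))
    expr = ex.App(name, tuple(ex.Name(r) for r in regulators))
    return symbol, expr


def build_psbn(
    graph: InfluenceGraph,
    updates: Optional[Mapping[str, Union[str, ex.Expr]]] = None,
    symbols: Iterable[FunctionSymbol] = (),
) -> PSBN:
    """Assemble a PSBN, defaulting missing update expressions.

    ``updates`` may give expressions as text or ASTs; variables without
    an entry receive a fresh symbol applied to their regulators.  Symbols
    used in explicit expressions but not declared in ``symbols`` are
    declared implicitly with the arity of their first use.
    """
    updates = dict(updates or {})
    declared: Dict[str, FunctionSymbol] = {s.name: s for s in symbols}
    update_map: Dict[str, ex.Expr] = {}
    for v in graph.variables:
        if v in updates:
            raw = updates[v]
            expr = ex.parse_expression(raw) if isinstance(raw, str) else raw
            update_map[v] = expr
            for fname, arity in sorted(ex.applications(expr)):
                declared.setdefault(fname, FunctionSymbol(fname, arity))
    unknown = set(updates) - set(graph.variables)
    if unknown:
        raise ValueError(f"updates given for undeclared variables: {sorted(unknown)}")
    used = set(graph.variables) | set(declared)
    for v in graph.variables:
        if v not in update_map:
            symbol, expr = default_update_expr(v, graph, used)
            declared[symbol.name] = symbol
            used.add(symbol.name)
            update_map[v] = expr
    ordered = tuple(sorted(declared.values(), key=lambda s: s.name))
    return PSBN(graph=graph, symbols=ordered, update=update_map)


# ---------------------------------------------------------------------------
# validation

_ERROR = "error"
_WARNING = "warning"


def _check_graph(graph: InfluenceGraph, issues: List[Issue]) -> None:
    seen: Set[str] = set()
    for v in graph.variables:
        if not is_identifier(v):
            issues.append(Issue(_ERROR, v, f"invalid variable name {v!r}"))
        if v in seen:
            issues.append(Issue(_ERROR, v, f"duplicate variable {v!r}"))
        seen.add(v)
    pairs: Set[Tuple[str, str]] = set()
    for r in graph.regulations:
        elem = f"{r.source}->{r.target}"
        for endpoint in (r.source, r.target):
            if endpoint not in seen:
                issues.append(Issue(_ERROR, elem, f"undeclared variable {endpoint!r}"))
        if (r.source, r.target) in pairs:
            issues.append(Issue(_ERROR, elem, "duplicate regulation"))
        pairs.add((r.source, r.target))
        if r.sign not in SIGNS:
            issues.append(Issue(_ERROR, elem, f"invalid sign {r.sign!r}"))
        if r.essential not in ESSENTIAL:
            issues.append(Issue(_ERROR, elem, f"invalid essentiality {r.essential!r}"))


def _check_psbn(psbn: PSBN, issues: List[Issue]) -> None:
    graph = psbn.graph
    variables = set(graph.variables)
    symbol_names: Set[str] = set()
    for s in psbn.symbols:
        if not is_identifier(s.name):
            issues.append(Issue(_ERROR, s.name, f"invalid symbol name {s.name!r}"))
        if s.name in symbol_names:
            issues.append(Issue(_ERROR, s.name, f"duplicate symbol {s.name!r}"))
        if s.name in variables:
            issues.append(
                Issue(_ERROR, s.name, f"symbol {s.name!r} collides with a variable")
            )
        if s.arity < 0:
            issues.append(Issue(_ERROR, s.name, "negative arity"))
        symbol_names.add(s.name)
    arity = {s.name: s.arity for s in psbn.symbols}
    for v in graph.variables:
        if v not in psbn.update:
            issues.append(Issue(_ERROR, v, "missing update expression"))
            continue
        expr = psbn.update[v]
        regulators = set(graph.regulators_of(v))
        for name in sorted(ex.free_names(expr)):
            if name not in variables:
                issues.append(
                    Issue(_ERROR, v, f"unknown variable {name!r} in update expression")
                )
            elif name not in regulators:
                issues.append(Issue(_ERROR, v, f"{name} is not a regulator of {v}"))
        for fname, used_arity in sorted(ex.applications(expr)):
            if fname not in arity:
                issues.append(Issue(_ERROR, v, f"undeclared symbol {fname!r}"))
            elif arity[fname] != used_arity:
                issues.append(
                    Issue(
                        _ERROR,
                        v,
                        f"symbol {fname!r} has arity {arity[fname]}, applied to "
                        f"{used_arity} arguments",
                    )
                )
    extra = set(psbn.update) - variables
    for v in sorted(extra):
        issues.append(Issue(_ERROR, v, f"update expression for undeclared variable {v!r}"))


def _essentiality_requested(sketch: Sketch, source: str, target: str) -> bool:
    reg = sketch.psbn.graph.regulation(source, target)
    if reg is not None and reg.essential == "true":
        return True
    return any(
        isinstance(p, RegulationEssential) and p.source == source and p.target == target
        for p in sketch.static_properties
    )


def _check_unused_regulators(sketch: Sketch, issues: List[Issue]) -> None:
    psbn = sketch.psbn
    for r in psbn.graph.regulations:
        expr = psbn.update.get(r.target)
        if expr is None:
            continue
        if r.source not in ex.free_names(expr) and not _essentiality_requested(
            sketch, r.source, r.target
        ):
            issues.append(
                Issue(
                    _WARNING,
                    f"{r.source}->{r.target}",
                    f"regulator {r.source} is never used by the update expression "
                    f"of {r.target} and no essentiality is required",
                )
            )


def _check_datasets(sketch: Sketch, issues: List[Issue]) -> None:
    variables = set(sketch.psbn.graph.variables)
    seen_ids: Set[str] = set()
    for d in sketch.datasets:
        if d.id in seen_ids:
            issues.append(Issue(_ERROR, d.id, f"duplicate dataset id {d.id!r}"))
        seen_ids.add(d.id)
        if d.category not in DATASET_CATEGORIES:
            issues.append(Issue(_ERROR, d.id, f"invalid dataset category {d.category!r}"))
        if d.category == "time_series" and len(d.observations) < 2:
            issues.append(
                Issue(_ERROR, d.id, "a time-series dataset needs at least 2 observations")
            )
        obs_ids: Set[str] = set()
        for o in d.observations:
            elem = f"{d.id}/{o.id}"
            if o.id in obs_ids:
                issues.append(Issue(_ERROR, elem, f"duplicate observation id {o.id!r}"))
            obs_ids.add(o.id)
            for name, value in o.values.items():
                if name not in variables:
                    issues.append(Issue(_ERROR, elem, f"unknown variable {name!r}"))
                if value not in (0, 1):
                    issues.append(Issue(_ERROR, elem, f"non-binary value {value!r}"))


def _check_static_properties(sketch: Sketch, issues: List[Issue]) -> None:
    from . import static_properties as sp  # deferred: avoids an import cycle

    psbn = sketch.psbn
    for i, prop in enumerate(sketch.static_properties):
        label = property_label(prop, i)
        if isinstance(prop, (RegulationEssential, RegulationMonotone)):
            if psbn.graph.regulation(prop.source, prop.target) is None:
                issues.append(
                    Issue(
                        _ERROR,
                        label,
                        f"regulation {prop.source}->{prop.target} is not declared",
                    )
                )
        if isinstance(prop, (SymbolArgEssential, SymbolArgMonotone)):
            symbol = psbn.symbol(prop.symbol)
            if symbol is None:
                issues.append(Issue(_ERROR, label, f"unknown symbol {prop.symbol!r}"))
            elif not 0 <= prop.arg_index < symbol.arity:
                issues.append(
                    Issue(
                        _ERROR,
                        label,
                        f"argument index {prop.arg_index} out of range for "
                        f"{prop.symbol!r} (arity {symbol.arity})",
                    )
                )
        if isinstance(prop, (RegulationMonotone, SymbolArgMonotone)):
            if prop.direction not in ("positive", "negative"):
                issues.append(
                    Issue(_ERROR, label, f"invalid direction {prop.direction!r}")
                )
        if isinstance(prop, FolFormula):
            try:
                ast = sp.parse_fol(prop.text)
                sp.check_fol(ast, psbn)
            except ValueError as err:
                issues.append(Issue(_ERROR, label, str(err)))


def _check_dynamic_properties(sketch: Sketch, issues: List[Issue]) -> None:
    from . import hctl  # deferred: avoids an import cycle

    for i, prop in enumerate(sketch.dynamic_properties):
        label = property_label(prop, i)
        if isinstance(
            prop, (FixedPointsTemplate, AttractorCoverageTemplate, TimeSeriesTemplate)
        ):
            dataset = sketch.dataset(prop.dataset_id)
            if dataset is None:
                issues.append(Issue(_ERROR, label, f"unknown dataset {prop.dataset_id!r}"))
            elif not dataset.observations and not isinstance(
                prop, AttractorCoverageTemplate
            ):
                issues.append(
                    Issue(_ERROR, label, f"dataset {prop.dataset_id!r} is empty")
                )
        if isinstance(prop, AttractorCountTemplate):
            upper = prop.max_count
            if prop.min_count < 1 or (upper is not None and upper < prop.min_count):
                issues.append(
                    Issue(
                        _ERROR,
                        label,
                        f"attractor count bounds [{prop.min_count}, {upper}] invalid",
                    )
                )
        if isinstance(prop, RawHctl):
            try:
                formula = hctl.parse_hctl(prop.text)
                hctl.check_scoping(formula)
                hctl.check_atoms(formula, sketch.psbn.graph.variables)
            except ValueError as err:
                issues.append(Issue(_ERROR, label, str(err)))


def validate_sketch(sketch: Sketch) -> List[Issue]:
    """Structural validation; returns issues instead of raising.

    Errors mark violations of the sketch invariants (unknown names,
    arity mismatches, malformed property text); warnings mark suspicious
    but admissible constructs, e.g. a declared regulation that no
    candidate is required to use.
    """
    issues: List[Issue] = []
    _check_graph(sketch.psbn.graph, issues)
    _check_psbn(sketch.psbn, issues)
    _check_unused_regulators(sketch, issues)
    _check_datasets(sketch, issues)
    _check_static_properties(sketch, issues)
    _check_dynamic_properties(sketch, issues)
    return issues


def has_errors(issues: Sequence[Issue]) -> bool:
    return any(i.severity == _ERROR for i in issues)
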