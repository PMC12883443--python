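"""Candidate-set computation, counting, sampling and summaries.

``run_inference`` intersects, over the full parameter space, the colour
sets of all static properties (cheap, parameter-only) and then of all
dynamic properties in declaration order, recording the candidate count
after every step.  The result is a symbolic candidate set supporting
exact big-integer counting, true uniform sampling of concrete networks,
per-variable update-function variant counts, and a lossless on-disk
round trip.
"""

from __future__ import annotations

import json
import random
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import hctl
from .bdd import TRUE
from .encoding import (
    Colour,
    ConcreteBN,
    SymbolicContext,
    instantiate,
)
from .model import PSBN, Sketch, has_errors, validate_sketch
from .properties import property_label
from .static_properties import compile_static, implied_static_properties

CANDIDATE_FORMAT_VERSION = "bnsketch-candidates-1"

#: per-variable variant summaries are skipped above this many table bits
DEFAULT_VARIANT_CAP_BITS = 20


class SketchError(ValueError):
    """The sketch failed validation; carries the issue list."""

    def __init__(self, issues) -> None:
        super().__init__(
            "sketch has validation errors: " + "; ".join(str(i) for i in issues)
        )
        self.issues = issues


@dataclass
class CandidateSet:
    """Symbolic set of interpretations consistent with a sketch so far."""

    ctx: SymbolicContext
    colours: int  # decision diagram over parameter bits
    provenance: Tuple[str, ...] = ()

    def count(self) -> int:
        return self.ctx.bdd.count(self.colours, self.ctx.param_levels())

    def contains(self, colour: Colour) -> bool:
        return self.ctx.bdd.evaluate(self.colours, self.ctx.colour_levels(colour))

    def is_empty(self) -> bool:
        return self.colours == 0


@dataclass
class InferenceReport:
    """Per-step audit trail of one inference run."""

    n_interpretations: int
    steps: List[Tuple[str, int]] = field(default_factory=list)
    final_count: int = 0
    variant_counts: Optional[Dict[str, Optional[int]]] = None
    elapsed_seconds: float = 0.0

    def to_json(self) -> dict:
        return {
            "interpretations": self.n_interpretations,
            "steps": [{"property": label, "count": count} for label, count in self.steps],
            "final_count": self.final_count,
            "variant_counts": self.variant_counts,
            "elapsed_seconds": round(self.elapsed_seconds, 3),
        }


def run_inference(
    sketch: Sketch, with_variants: bool = True
) -> Tuple[CandidateSet, InferenceReport]:
    """Compute the set of all interpretations consistent with the sketch.

    Counting is over interpretations (parameter valuations): two colours
    that differ only in an unused table row count as two candidates.
    Static properties implied by regulation annotations (sign,
    essentiality) are applied first, then explicit static properties,
    then dynamic properties in declaration order.
    """
    issues = validate_sketch(sketch)
    if has_errors(issues):
        raise SketchError([i for i in issues if i.severity == "error"])
    start = time.monotonic()
    ctx = SymbolicContext(sketch.psbn)
    b = ctx.bdd
    report = InferenceReport(n_interpretations=ctx.space.n_interpretations)
    colours = TRUE
    provenance: List[str] = []

    implied = implied_static_properties(sketch.psbn)
    static_props = [
        (f"regulation:{p.source}->{p.target}:{type(p).__name__}", p) for p in implied
    ] + [
        (property_label(p, i), p) for i, p in enumerate(sketch.static_properties)
    ]
    for label, prop in static_props:
        colours = b.and_(colours, compile_static(ctx, prop))
        provenance.append(label)
        report.steps.append((label, b.count(colours, ctx.param_levels())))

    for i, prop in enumerate(sketch.dynamic_properties):
        label = property_label(prop, i)
        formula = hctl.build_template(prop, sketch.datasets)
        satisfied = hctl.satisfying_colours(formula, ctx)
        colours = b.and_(colours, satisfied)
        provenance.append(label)
        report.steps.append((label, b.count(colours, ctx.param_levels())))

    candidate_set = CandidateSet(ctx=ctx, colours=colours, provenance=tuple(provenance))
    report.final_count = candidate_set.count()
    if with_variants:
        report.variant_counts = summarize_variants(candidate_set)
    report.elapsed_seconds = time.monotonic() - start
    return candidate_set, report


def count_candidates(candidate_set: CandidateSet) -> int:
    """Exact number of consistent interpretations (big-integer safe)."""
    return candidate_set.count()


def sample_candidates(
    candidate_set: CandidateSet, n: int, seed: int
) -> List[ConcreteBN]:
    """Draw ``n`` concrete networks i.i.d. uniformly from the set.

    Uniformity is over interpretations: the diagram is descended with
    branches weighted by their exact model counts, so no enumeration of
    the (possibly astronomically large) set is ever needed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if candidate_set.is_empty():
        raise ValueError("no candidates: the candidate set is empty")
    ctx = candidate_set.ctx
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        out.append(instantiate(ctx.psbn, sample_colour(candidate_set, rng), ctx.space))
    return out


def sample_colour(candidate_set: CandidateSet, rng: random.Random) -> Colour:
    """One uniform draw from the set, as a colour."""
    ctx = candidate_set.ctx
    levels = ctx.param_levels()
    assignment = ctx.bdd.sample(candidate_set.colours, levels, rng)
    return Colour(tuple(int(assignment[lvl]) for lvl in levels))


def summarize_variants(
    candidate_set: CandidateSet, cap_bits: int = DEFAULT_VARIANT_CAP_BITS
) -> Dict[str, Optional[int]]:
    """Distinct update-function variants per variable across the set.

    For each variable the set is projected onto a fresh block of
    truth-table bits constrained row-wise to equal the compiled update
    function, and the projection is model-counted.  Variables whose
    table would exceed ``cap_bits`` bits are reported as ``None``
    (not computed) rather than failing.
    """
    ctx = candidate_set.ctx
    b = ctx.bdd
    out: Dict[str, Optional[int]] = {}
    for v in ctx.state_variables:
        if candidate_set.is_empty():
            out[v] = 0
            continue
        regs = ctx.psbn.graph.regulators_of(v)
        k = len(regs)
        if (1 << k) > cap_bits:
            out[v] = None
            continue
        table_levels = _table_levels(ctx, v, k)
        f = ctx.update_function(v)
        rows = TRUE
        for row in range(1 << k):
            fixed = {
                ctx.state_level(r): bool((row >> (k - 1 - i)) & 1)
                for i, r in enumerate(regs)
            }
            row_fn = b.restrict(f, fixed)
            row_bit_var = b._mk(table_levels[row], 0, 1)
            rows = b.and_(rows, b.iff(row_bit_var, row_fn))
        projected = b.exists(
            b.and_(rows, candidate_set.colours), ctx.param_levels()
        )
        out[v] = b.count(projected, table_levels)
    return out


def _table_levels(ctx: SymbolicContext, variable: str, k: int) -> List[int]:
    """Fresh (cached) bits representing the truth table of one variable."""
    cache = getattr(ctx, "_variant_levels", None)
    if cache is None:
        cache = {}
        ctx._variant_levels = cache  # type: ignore[attr-defined]
    levels = cache.get(variable)
    if levels is None:
        levels = [ctx.bdd.add_var(f"table:{variable}[{row}]") for row in range(1 << k)]
        cache[variable] = levels
    return levels


# ---------------------------------------------------------------------------
# candidate-set files


def export_candidate_set(candidate_set: CandidateSet, path: str) -> None:
    """Serialize the set losslessly (count and membership preserved).

    The file records the format version, the PSBN, and the parameter-bit
    ordering, so an import into a mismatching context fails loudly
    instead of silently reinterpreting bits.
    """
    from .io import psbn_to_json  # deferred: io imports this module

    ctx = candidate_set.ctx
    payload = {
        "format_version": CANDIDATE_FORMAT_VERSION,
        "psbn": psbn_to_json(ctx.psbn),
        "parameter_bits": ctx.space.bit_names(),
        "provenance": list(candidate_set.provenance),
        "colours": ctx.bdd.serialize(candidate_set.colours),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def import_candidate_set(path: str) -> CandidateSet:
    """Rebuild a candidate set exported by :func:`export_candidate_set`."""
    from .io import psbn_from_json  # deferred: io imports this module

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != CANDIDATE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported candidate-set format {version!r} "
            f"(expected {CANDIDATE_FORMAT_VERSION!r})"
        )
    psbn = psbn_from_json(payload["psbn"])
    ctx = SymbolicContext(psbn)
    stored_bits = payload["parameter_bits"]
    if stored_bits != ctx.space.bit_names():
        raise ValueError(
            "parameter-bit ordering in the file does not match the "
            "reconstructed parameter space; refusing to reinterpret"
        )
    colours = ctx.bdd.deserialize(payload["colours"])
    return CandidateSet(
        ctx=ctx, colours=colours, provenance=tuple(payload.get("provenance", ()))
    )
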