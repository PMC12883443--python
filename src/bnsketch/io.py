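"""On-disk formats: sketch JSON, AEON, observations CSV, BoolNet.

The sketch JSON document is the single source of truth for a full
specification; the other formats cover its parts:

* ``.aeon`` (text dialect) — influence graph and update expressions
  only.  Regulation lines are ``A -> B`` (activation), ``A -| B``
  (inhibition), ``A -? B`` (unknown sign), with a ``?`` suffix marking
  essentiality as unknown (``A ->? B``); update lines are
  ``$V: <expression>``; ``#`` lines are ignored (with a warning).
* observations CSV — header row of variable names after an id column,
  cells ``0``/``1``/blank (blank = unconstrained), row order preserved.
* ``.bnet`` (BoolNet) — export of sampled concrete networks, one
  canonical-DNF line per variable under a ``targets, factors`` header.

All readers reject malformed input with a line/cell position rather
than guessing; all writers produce text their reader accepts.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
from typing import Dict, List, Mapping, Optional, Tuple

from . import expressions as ex
from .encoding import ConcreteBN, table_to_expr
from .model import (
    PSBN,
    Dataset,
    FunctionSymbol,
    InfluenceGraph,
    Issue,
    Observation,
    Regulation,
    Sketch,
    build_psbn,
    has_errors,
    validate_sketch,
)
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
)

SKETCH_FORMAT_VERSION = "bnsketch-1"


class FormatError(ValueError):
    """Malformed on-disk input."""


# ---------------------------------------------------------------------------
# sketch JSON


def psbn_to_json(psbn: PSBN) -> dict:
    return {
        "variables": list(psbn.graph.variables),
        "regulations": [
            {
                "source": r.source,
                "target": r.target,
                "sign": r.sign,
                "essential": r.essential,
            }
            for r in psbn.graph.regulations
        ],
        "symbols": [{"name": s.name, "arity": s.arity} for s in psbn.symbols],
        "update_expressions": {
            v: ex.to_text(psbn.update[v]) for v in psbn.graph.variables
        },
    }


def psbn_from_json(data: dict) -> PSBN:
    graph = InfluenceGraph(
        data["variables"],
        [
            Regulation(
                r["source"],
                r["target"],
                sign=r.get("sign", "unknown"),
                essential=r.get("essential", "unknown"),
            )
            for r in data.get("regulations", ())
        ],
    )
    symbols = tuple(
        FunctionSymbol(s["name"], int(s["arity"])) for s in data.get("symbols", ())
    )
    update = {
        v: ex.parse_expression(text)
        for v, text in data.get("update_expressions", {}).items()
    }
    return PSBN(graph=graph, symbols=symbols, update=update)


_STATIC_KINDS = {
    "regulation_essential": RegulationEssential,
    "regulation_monotone": RegulationMonotone,
    "symbol_essential": SymbolArgEssential,
    "symbol_monotone": SymbolArgMonotone,
    "fol": FolFormula,
}


def _static_to_json(prop: StaticProperty) -> dict:
    if isinstance(prop, RegulationEssential):
        return {"kind": "regulation_essential", "source": prop.source,
                "target": prop.target, "id": prop.id}
    if isinstance(prop, RegulationMonotone):
        return {"kind": "regulation_monotone", "source": prop.source,
                "target": prop.target, "direction": prop.direction, "id": prop.id}
    if isinstance(prop, SymbolArgEssential):
        return {"kind": "symbol_essential", "symbol": prop.symbol,
                "arg_index": prop.arg_index, "id": prop.id}
    if isinstance(prop, SymbolArgMonotone):
        return {"kind": "symbol_monotone", "symbol": prop.symbol,
                "arg_index": prop.arg_index, "direction": prop.direction, "id": prop.id}
    if isinstance(prop, FolFormula):
        return {"kind": "fol", "formula": prop.text, "id": prop.id}
    raise TypeError(f"not a static property: {prop!r}")


def _static_from_json(data: dict) -> StaticProperty:
    kind = data.get("kind")
    pid = data.get("id", "")
    if kind == "regulation_essential":
        return RegulationEssential(data["source"], data["target"], id=pid)
    if kind == "regulation_monotone":
        return RegulationMonotone(data["source"], data["target"], data["direction"], id=pid)
    if kind == "symbol_essential":
        return SymbolArgEssential(data["symbol"], int(data["arg_index"]), id=pid)
    if kind == "symbol_monotone":
        return SymbolArgMonotone(
            data["symbol"], int(data["arg_index"]), data["direction"], id=pid
        )
    if kind == "fol":
        return FolFormula(data["formula"], id=pid)
    raise FormatError(f"unknown static property kind {kind!r}")


def _dynamic_to_json(prop: DynamicProperty) -> dict:
    if isinstance(prop, RawHctl):
        return {"kind": "hctl", "formula": prop.text, "id": prop.id}
    if isinstance(prop, FixedPointsTemplate):
        return {"kind": "fixed_points", "dataset": prop.dataset_id, "id": prop.id}
    if isinstance(prop, AttractorCountTemplate):
        return {"kind": "attractor_count", "min": prop.min_count,
                "max": prop.max_count, "id": prop.id}
    if isinstance(prop, AttractorCoverageTemplate):
        return {"kind": "attractor_coverage", "dataset": prop.dataset_id, "id": prop.id}
    if isinstance(prop, TimeSeriesTemplate):
        return {"kind": "time_series", "dataset": prop.dataset_id, "id": prop.id}
    raise TypeError(f"not a dynamic property: {prop!r}")


def _dynamic_from_json(data: dict) -> DynamicProperty:
    kind = data.get("kind")
    pid = data.get("id", "")
    if kind == "hctl":
        return RawHctl(data["formula"], id=pid)
    if kind == "fixed_points":
        return FixedPointsTemplate(data["dataset"], id=pid)
    if kind == "attractor_count":
        upper = data.get("max")
        return AttractorCountTemplate(
            int(data["min"]), None if upper is None else int(upper), id=pid
        )
    if kind == "attractor_coverage":
        return AttractorCoverageTemplate(data["dataset"], id=pid)
    if kind == "time_series":
        return TimeSeriesTemplate(data["dataset"], id=pid)
    raise FormatError(f"unknown dynamic property kind {kind!r}")


def sketch_to_json(sketch: Sketch) -> dict:
    doc = psbn_to_json(sketch.psbn)
    doc["format_version"] = SKETCH_FORMAT_VERSION
    doc["static_properties"] = [_static_to_json(p) for p in sketch.static_properties]
    doc["datasets"] = [
        {
            "id": d.id,
            "category": d.category,
            "observations": [
                {"id": o.id, "values": {k: int(v) for k, v in o.values.items()}}
                for o in d.observations
            ],
        }
        for d in sketch.datasets
    ]
    doc["dynamic_properties"] = [_dynamic_to_json(p) for p in sketch.dynamic_properties]
    doc["annotations"] = dict(sketch.annotations)
    return doc


def sketch_from_json(data: dict) -> Sketch:
    version = data.get("format_version")
    if version != SKETCH_FORMAT_VERSION:
        raise FormatError(
            f"unsupported sketch format {version!r} (expected {SKETCH_FORMAT_VERSION!r})"
        )
    psbn = psbn_from_json(data)
    datasets = tuple(
        Dataset(
            id=d["id"],
            category=d.get("category", "unspecified"),
            observations=tuple(
                Observation(id=o["id"], values={k: int(v) for k, v in o["values"].items()})
                for o in d.get("observations", ())
            ),
        )
        for d in data.get("datasets", ())
    )
    return Sketch(
        psbn=psbn,
        static_properties=tuple(
            _static_from_json(p) for p in data.get("static_properties", ())
        ),
        datasets=datasets,
        dynamic_properties=tuple(
            _dynamic_from_json(p) for p in data.get("dynamic_properties", ())
        ),
        annotations=dict(data.get("annotations", {})),
    )


def sketch_to_text(sketch: Sketch) -> str:
    return json.dumps(sketch_to_json(sketch), indent=2, sort_keys=True) + "\n"


def load_sketch(path: str, strict: bool = True) -> Tuple[Sketch, List[Issue]]:
    """Read and validate a sketch file; raise on errors when ``strict``."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as err:
            raise FormatError(f"{path}: not valid JSON: {err}") from err
    sketch = sketch_from_json(data)
    issues = validate_sketch(sketch)
    if strict and has_errors(issues):
        raise FormatError(
            f"{path}: invalid sketch: " + "; ".join(str(i) for i in issues if i.severity == "error")
        )
    return sketch, issues


def save_sketch(sketch: Sketch, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sketch_to_text(sketch))


# ---------------------------------------------------------------------------
# AEON dialect

_SIGN_BY_ARROW = {"->": "positive", "-|": "negative", "-?": "unknown"}
_ARROW_BY_SIGN = {v: k for k, v in _SIGN_BY_ARROW.items()}


def read_aeon(text: str) -> Tuple[InfluenceGraph, Dict[str, ex.Expr], List[str]]:
    """Parse the AEON dialect; returns (graph, partial updates, warnings).

    Variables are the union of regulation endpoints and ``$``-declared
    names; update expressions are left unset for variables without a
    ``$`` line (to be defaulted into fresh symbols by ``build_psbn``).
    """
    regulations: List[Regulation] = []
    updates: Dict[str, ex.Expr] = {}
    variables: List[str] = []
    warnings_list: List[str] = []
    seen = set()

    def declare(name: str) -> None:
        if name not in seen:
            seen.add(name)
            variables.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            warnings_list.append(f"line {lineno}: ignored metadata/comment line")
            continue
        if line.startswith("$"):
            head, sep, body = line[1:].partition(":")
            if not sep:
                raise FormatError(f"line {lineno}: update line without ':'")
            name = head.strip()
            if name in updates:
                raise FormatError(f"line {lineno}: duplicate update for {name!r}")
            try:
                updates[name] = ex.parse_expression(body.strip())
            except ex.ExprSyntaxError as err:
                raise FormatError(f"line {lineno}: {err}") from err
            declare(name)
            continue
        parsed = _parse_regulation_line(line)
        if parsed is None:
            raise FormatError(f"line {lineno}: malformed line {line!r}")
        source, sign, essential, target = parsed
        declare(source)
        declare(target)
        regulations.append(Regulation(source, target, sign=sign, essential=essential))
    graph = InfluenceGraph(tuple(sorted(variables)), regulations)
    return graph, updates, warnings_list


def _parse_regulation_line(line: str) -> Optional[Tuple[str, str, str, str]]:
    parts = line.split()
    if len(parts) != 3:
        return None
    source, arrow, target = parts
    essential = "true"
    if arrow.endswith("?") and arrow not in ("-?",):
        arrow = arrow[:-1]
        essential = "unknown"
    if arrow not in _SIGN_BY_ARROW:
        return None
    return source, _SIGN_BY_ARROW[arrow], essential, target


def write_aeon(psbn: PSBN) -> str:
    """Inverse of :func:`read_aeon` up to line order."""
    lines = []
    for r in psbn.graph.regulations:
        arrow = _ARROW_BY_SIGN[r.sign]
        if r.essential != "true":
            arrow += "?"
        lines.append(f"{r.source} {arrow} {r.target}")
    for v in psbn.graph.variables:
        if v in psbn.update:
            lines.append(f"${v}: {ex.to_text(psbn.update[v])}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# observations CSV


def read_observations_csv(
    text: str, dataset_id: str = "data", category: str = "unspecified"
) -> Dataset:
    """Header = id column + variable names; cells 0/1/blank."""
    reader = csv.reader(_stdio.StringIO(text))
    rows = [row for row in reader if row]
    if not rows:
        raise FormatError("empty CSV: missing header row")
    header = [c.strip() for c in rows[0]]
    variables = header[1:]
    observations: List[Observation] = []
    seen_ids = set()
    for rowno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"row {rowno}: expected {len(header)} cells, got {len(row)}")
        obs_id = row[0].strip()
        if obs_id in seen_ids:
            raise FormatError(f"row {rowno}: duplicate observation id {obs_id!r}")
        seen_ids.add(obs_id)
        values: Dict[str, int] = {}
        for col, (variable, cell) in enumerate(zip(variables, row[1:]), start=2):
            cell = cell.strip()
            if cell == "":
                continue
            if cell not in ("0", "1"):
                raise FormatError(
                    f"row {rowno}, column {col} ({variable}): non-binary value {cell!r}"
                )
            values[variable] = int(cell)
        observations.append(Observation(id=obs_id, values=values))
    return Dataset(id=dataset_id, observations=tuple(observations), category=category)


def write_observations_csv(dataset: Dataset, variables: Optional[List[str]] = None) -> str:
    if variables is None:
        names = set()
        for o in dataset.observations:
            names |= set(o.values)
        variables = sorted(names)
    buf = _stdio.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["id"] + list(variables))
    for o in dataset.observations:
        writer.writerow(
            [o.id] + ["" if v not in o.values else str(o.values[v]) for v in variables]
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# BoolNet


def write_bnet(bn: ConcreteBN) -> str:
    """BoolNet text: canonical DNF of each truth table."""
    lines = ["targets, factors"]
    for v in bn.variables:
        expr = table_to_expr(bn.regulators[v], bn.tables[v])
        lines.append(f"{v}, {ex.to_text(expr)}")
    return "\n".join(lines) + "\n"
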