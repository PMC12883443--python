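"""Plain data records for static and dynamic sketch properties.

Static properties constrain the update functions themselves (first-order
statements over Booleans); dynamic properties constrain the asynchronous
dynamics (hybrid CTL).  Compilation of static properties lives in
:mod:`bnsketch.static_properties`; template expansion and model checking
of dynamic properties live in :mod:`bnsketch.hctl`.  Keeping the records
here lets the sketch container reference both without import cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union


# ---------------------------------------------------------------------------
# static (update-function) properties


@dataclass(frozen=True)
class RegulationEssential:
    """The regulator must have an effect on its target in every candidate."""

    source: str
    target: str
    id: str = ""


@dataclass(frozen=True)
class RegulationMonotone:
    """The target's update must be monotone in the regulator.

    ``direction`` is ``"positive"`` (activation) or ``"negative"``
    (inhibition).
    """

    source: str
    target: str
    direction: str
    id: str = ""


@dataclass(frozen=True)
class SymbolArgEssential:
    """A function symbol must depend on its ``arg_index``-th argument."""

    symbol: str
    arg_index: int
    id: str = ""


@dataclass(frozen=True)
class SymbolArgMonotone:
    """A function symbol must be monotone in one argument."""

    symbol: str
    arg_index: int
    direction: str
    id: str = ""


@dataclass(frozen=True)
class FolFormula:
    """A free-form first-order property over Booleans (ASCII syntax)."""

    text: str
    id: str = ""


StaticProperty = Union[
    RegulationEssential,
    RegulationMonotone,
    SymbolArgEssential,
    SymbolArgMonotone,
    FolFormula,
]


# ---------------------------------------------------------------------------
# dynamic (behavioural) properties


@dataclass(frozen=True)
class RawHctl:
    """A user-written HCTL formula, required to hold in every state."""

    text: str
    id: str = ""


@dataclass(frozen=True)
class FixedPointsTemplate:
    """Every observation in the dataset is a reachable-free fixed point."""

    dataset_id: str
    id: str = ""


@dataclass(frozen=True)
class AttractorCountTemplate:
    """The number of attractors lies in ``[min_count, max_count]``.

    ``max_count=None`` leaves the count unbounded above.
    """

    min_count: int
    max_count: Optional[int] = None
    id: str = ""


@dataclass(frozen=True)
class AttractorCoverageTemplate:
    """No attractor state may fall outside the dataset's observations."""

    dataset_id: str
    id: str = ""


@dataclass(frozen=True)
class TimeSeriesTemplate:
    """The observations occur, in order, along some trajectory."""

    dataset_id: str
    id: str = ""


DynamicProperty = Union[
    RawHctl,
    FixedPointsTemplate,
    AttractorCountTemplate,
    AttractorCoverageTemplate,
    TimeSeriesTemplate,
]


def property_label(prop, index: int) -> str:
    """Stable display id: the explicit id if set, else kind + position."""
    if getattr(prop, "id", ""):
        return prop.id
    return f"{type(prop).__name__}#{index}"
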