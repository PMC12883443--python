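import hypothesis
import pytest

import bnsketch as bs
from bnsketch.encoding import SymbolicContext

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_ctx(updates, regulations, variables):
    """Symbolic context for a small hand-written network.

    Helper variables should be pinned (e.g. to "0") so that no implicit
    symbols inflate the parameter space.
    """
    psbn = bs.build_psbn(bs.InfluenceGraph(variables, regulations), updates)
    return SymbolicContext(psbn)


@pytest.fixture
def toggle_ctx():
    """One-variable negation network x := ~x (a two-state cycle)."""
    return make_ctx({"x": "~x"}, [("x", "x")], ("x",))


@pytest.fixture
def identity_ctx():
    """One-variable identity network x := x (two fixed points)."""
    return make_ctx({"x": "x"}, [("x", "x")], ("x",))


@pytest.fixture
def unary_symbol_ctx():
    """PSBN x := g(x) with one unary symbol (4 interpretations)."""
    psbn = bs.build_psbn(bs.InfluenceGraph(("x",), [("x", "x")]))
    return SymbolicContext(psbn)
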