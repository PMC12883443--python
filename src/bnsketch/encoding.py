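"""Parameter-space encoding of partially specified Boolean networks.

Every uninterpreted function symbol ``g`` of arity ``k`` is encoded by a
block of ``2**k`` Boolean parameters, one per truth-table row, rows
enumerated in binary order ``00..0`` to ``11..1`` (first argument =
most significant bit).  A full assignment of all parameter bits — a
*colour* — is one interpretation and determines one concrete Boolean
network.  Update expressions compile to decision diagrams over state
bits and parameter bits; an application ``g(e1, .., ek)`` becomes the
multiplexer

    OR_w  p[g,w]  AND  AND_i (e_i <=> w_i)

so the compiled function agrees with every interpretation at once.

Bit order in the shared manager: state bits (variables sorted by name),
then parameter bits (symbols sorted by name, rows in binary order),
then any dynamically allocated bits (HCTL state-variable copies,
truth-table bits for variant summaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import expressions as ex
from .bdd import Bdd, FALSE, TRUE
from .model import PSBN, FunctionSymbol, InfluenceGraph

#: reject symbols whose truth table would not be representable
DEFAULT_ARITY_CAP = 16


@dataclass(frozen=True)
class ParameterSpace:
    """Deterministic layout of all truth-table parameters of a PSBN."""

    symbols: Tuple[FunctionSymbol, ...]  # sorted by name
    offsets: Mapping[str, int]  # symbol -> index of its first bit
    total_bits: int

    def rows(self, symbol: str) -> int:
        return 1 << self.arity(symbol)

    def arity(self, symbol: str) -> int:
        for s in self.symbols:
            if s.name == symbol:
                return s.arity
        raise KeyError(f"unknown symbol {symbol!r}")

    def bit_index(self, symbol: str, row: int) -> int:
        if not 0 <= row < self.rows(symbol):
            raise IndexError(f"row {row} out of range for symbol {symbol!r}")
        return self.offsets[symbol] + row

    def bit_name(self, symbol: str, row: int) -> str:
        self.bit_index(symbol, row)  # bounds check
        return f"{symbol}[{row}]"

    def bit_names(self) -> List[str]:
        names = []
        for s in self.symbols:
            names.extend(f"{s.name}[{row}]" for row in range(1 << s.arity))
        return names

    @property
    def n_interpretations(self) -> int:
        return 1 << self.total_bits

    # -- colours -----------------------------------------------------------

    def colour_from_tables(self, tables: Mapping[str, Sequence[int]]) -> "Colour":
        """Build a colour from one full truth table per symbol."""
        bits: List[int] = []
        for s in self.symbols:
            table = tables[s.name]
            if len(table) != 1 << s.arity:
                raise ValueError(
                    f"table for {s.name!r} has {len(table)} rows, expected {1 << s.arity}"
                )
            bits.extend(int(bool(b)) for b in table)
        return Colour(tuple(bits))

    def colour_from_int(self, value: int) -> "Colour":
        """The colour whose bits spell ``value`` in binary (bit 0 = first bit)."""
        return Colour(tuple((value >> i) & 1 for i in range(self.total_bits)))

    def table_of(self, colour: "Colour", symbol: str) -> Tuple[int, ...]:
        off = self.offsets[symbol]
        return tuple(colour.bits[off : off + self.rows(symbol)])


@dataclass(frozen=True)
class Colour:
    """One interpretation: a total assignment of all parameter bits."""

    bits: Tuple[int, ...]


def build_parameter_space(
    psbn: PSBN, arity_cap: int = DEFAULT_ARITY_CAP
) -> ParameterSpace:
    """One parameter per truth-table row per symbol, in canonical order."""
    symbols = tuple(sorted(psbn.symbols, key=lambda s: s.name))
    offsets: Dict[str, int] = {}
    total = 0
    for s in symbols:
        if s.arity > arity_cap:
            raise ValueError(
                f"symbol {s.name!r} has arity {s.arity}; the 2**{s.arity}-row "
                f"truth table exceeds the cap of arity {arity_cap}"
            )
        offsets[s.name] = total
        total += 1 << s.arity
    return ParameterSpace(symbols=symbols, offsets=offsets, total_bits=total)


def argument_row(values: Sequence[int]) -> int:
    """Truth-table row selected by argument values (first arg = MSB)."""
    row = 0
    for v in values:
        row = (row << 1) | int(bool(v))
    return row


def row_bit(row: int, i: int, arity: int) -> int:
    """Value of argument ``i`` in row ``row`` of an ``arity``-ary table."""
    return (row >> (arity - 1 - i)) & 1


class SymbolicContext:
    """Shared decision-diagram manager for one PSBN.

    Owns the bit layout (state bits, parameter bits, dynamic extras) and
    caches the compiled update functions ``F_v(s, p)``.
    """

    def __init__(self, psbn: PSBN, space: Optional[ParameterSpace] = None) -> None:
        self.psbn = psbn
        self.space = space if space is not None else build_parameter_space(psbn)
        self.bdd = Bdd()
        self.state_variables: Tuple[str, ...] = tuple(sorted(psbn.graph.variables))
        self._state_level: Dict[str, int] = {
            v: self.bdd.add_var(v) for v in self.state_variables
        }
        self._param_level: Dict[str, int] = {
            name: self.bdd.add_var(name) for name in self.space.bit_names()
        }
        self._updates: Dict[str, int] = {}
        self._copies: Dict[str, Dict[str, int]] = {}

    # -- bit lookups -------------------------------------------------------

    def state_level(self, variable: str) -> int:
        return self._state_level[variable]

    def state_levels(self) -> List[int]:
        return [self._state_level[v] for v in self.state_variables]

    def param_level(self, symbol: str, row: int) -> int:
        return self._param_level[self.space.bit_name(symbol, row)]

    def param_levels(self) -> List[int]:
        return [self._param_level[name] for name in self.space.bit_names()]

    def copy_levels(self, hctl_var: str) -> Dict[str, int]:
        """State-bit copies for a named HCTL state variable (lazily made)."""
        copies = self._copies.get(hctl_var)
        if copies is None:
            copies = {
                v: self.bdd.add_var(f"{hctl_var}#{v}") for v in self.state_variables
            }
            self._copies[hctl_var] = copies
        return copies

    # -- compilation -------------------------------------------------------

    def param_var(self, symbol: str, row: int) -> int:
        return self.bdd.var(self.space.bit_name(symbol, row))

    def state_var(self, variable: str) -> int:
        return self.bdd.var(variable)

    def compile_expr(self, expr: ex.Expr, env: Optional[Mapping[str, int]] = None) -> int:
        """Compile an expression to a diagram over state and parameter bits.

        ``env`` overrides the meaning of names (used by the first-order
        property compiler, where names are bound Booleans, not state
        bits).
        """
        b = self.bdd
        if isinstance(expr, ex.Const):
            return TRUE if expr.value else FALSE
        if isinstance(expr, ex.Name):
            if env is not None and expr.name in env:
                return env[expr.name]
            if expr.name not in self._state_level:
                raise ValueError(f"unknown variable {expr.name!r}")
            return b.var(expr.name)
        if isinstance(expr, ex.Not):
            return b.not_(self.compile_expr(expr.arg, env))
        if isinstance(expr, ex.BinOp):
            left = self.compile_expr(expr.left, env)
            right = self.compile_expr(expr.right, env)
            op = {
                "&": b.and_,
                "|": b.or_,
                "^": b.xor,
                "=>": b.imp,
                "<=>": b.iff,
            }[expr.op]
            return op(left, right)
        if isinstance(expr, ex.App):
            symbol = self.psbn.symbol(expr.func)
            if symbol is None:
                raise ValueError(f"unknown symbol {expr.func!r}")
            if symbol.arity != len(expr.args):
                raise ValueError(
                    f"symbol {expr.func!r} has arity {symbol.arity}, applied to "
                    f"{len(expr.args)} arguments"
                )
            args = [self.compile_expr(a, env) for a in expr.args]
            return self.apply_symbol(expr.func, args)
        raise TypeError(f"not an expression: {expr!r}")

    def apply_symbol(self, func: str, args: Sequence[int]) -> int:
        """Truth-table multiplexer for one symbol application.

        ``OR_w p[g,w] AND AND_i (args[i] <=> w_i)`` — selects, per
        interpretation, the table row addressed by the argument values.
        """
        b = self.bdd
        symbol = self.psbn.symbol(func)
        if symbol is None:
            raise ValueError(f"unknown symbol {func!r}")
        if symbol.arity != len(args):
            raise ValueError(
                f"symbol {func!r} has arity {symbol.arity}, applied to "
                f"{len(args)} arguments"
            )
        k = symbol.arity
        terms = []
        for row in range(1 << k):
            term = self.param_var(func, row)
            for i, arg in enumerate(args):
                want = row_bit(row, i, k)
                term = b.and_(term, arg if want else b.not_(arg))
            terms.append(term)
        return b.or_many(terms)

    def update_function(self, variable: str) -> int:
        """``F_v(s, p)``: the compiled update of ``variable`` (cached)."""
        f = self._updates.get(variable)
        if f is None:
            f = self.compile_expr(self.psbn.update[variable])
            self._updates[variable] = f
        return f

    # -- assignments -------------------------------------------------------

    def colour_levels(self, colour: Colour) -> Dict[int, bool]:
        names = self.space.bit_names()
        return {
            self._param_level[name]: bool(bit)
            for name, bit in zip(names, colour.bits)
        }

    def state_levels_assignment(self, state: Mapping[str, int]) -> Dict[int, bool]:
        return {self._state_level[v]: bool(x) for v, x in state.items()}

    def colour_cube(self, colour: Colour) -> int:
        """The singleton colour as a diagram over parameter bits."""
        b = self.bdd
        acc = TRUE
        for name, bit in zip(self.space.bit_names(), colour.bits):
            acc = b.and_(acc, b.literal(name, bool(bit)))
        return acc


# ---------------------------------------------------------------------------
# concrete networks


@dataclass(frozen=True)
class ConcreteBN:
    """A fully specified Boolean network.

    ``tables[v]`` is the truth table of ``v``'s update function over
    ``regulators[v]`` (lexicographic order), rows in binary order with
    the first regulator as the most significant bit.
    """

    variables: Tuple[str, ...]  # sorted
    regulators: Mapping[str, Tuple[str, ...]]
    tables: Mapping[str, Tuple[int, ...]]

    def value(self, variable: str, state: Mapping[str, int]) -> int:
        regs = self.regulators[variable]
        row = argument_row([state[r] for r in regs])
        return self.tables[variable][row]

    def is_fixed_point(self, state: Mapping[str, int]) -> bool:
        return all(self.value(v, state) == state[v] for v in self.variables)


def instantiate(
    psbn: PSBN, colour: Colour, space: Optional[ParameterSpace] = None
) -> ConcreteBN:
    """Substitute a colour into the PSBN, yielding truth tables.

    Evaluation is direct (recursive over the expression AST with symbol
    applications looked up in the colour's tables); it does not go
    through the decision-diagram compiler, so the two routes check each
    other.
    """
    if space is None:
        space = build_parameter_space(psbn)
    sym_tables = {s.name: space.table_of(colour, s.name) for s in space.symbols}

    def apply(func: str, vals: Tuple[bool, ...]) -> bool:
        return bool(sym_tables[func][argument_row([int(v) for v in vals])])

    variables = tuple(sorted(psbn.graph.variables))
    regulators: Dict[str, Tuple[str, ...]] = {}
    tables: Dict[str, Tuple[int, ...]] = {}
    for v in variables:
        regs = psbn.graph.regulators_of(v)
        regulators[v] = regs
        expr = psbn.update[v]
        k = len(regs)
        rows = []
        for row in range(1 << k):
            env = {r: bool(row_bit(row, i, k)) for i, r in enumerate(regs)}
            rows.append(int(ex.evaluate(expr, env, apply)))
        tables[v] = tuple(rows)
    return ConcreteBN(variables=variables, regulators=regulators, tables=tables)


def table_to_expr(regulators: Sequence[str], table: Sequence[int]) -> ex.Expr:
    """Canonical DNF of a truth table (constants for 0-ary / degenerate)."""
    k = len(regulators)
    if all(not t for t in table):
        return ex.FALSE
    if all(table):
        return ex.TRUE
    terms: List[ex.Expr] = []
    for row, bit in enumerate(table):
        if not bit:
            continue
        literals: List[ex.Expr] = []
        for i, r in enumerate(regulators):
            name = ex.Name(r)
            literals.append(name if row_bit(row, i, k) else ex.Not(name))
        term = literals[0]
        for lit in literals[1:]:
            term = ex.BinOp("&", term, lit)
        terms.append(term)
    acc = terms[0]
    for t in terms[1:]:
        acc = ex.BinOp("|", acc, t)
    return acc


def concrete_to_psbn(bn: ConcreteBN, graph: Optional[InfluenceGraph] = None) -> PSBN:
    """Re-encode a concrete network as a PSBN with fixed expressions."""
    if graph is None:
        regs = [
            (r, v)
            for v in bn.variables
            for r in bn.regulators[v]
        ]
        graph = InfluenceGraph(bn.variables, regs)
    update = {
        v: table_to_expr(bn.regulators[v], bn.tables[v]) for v in bn.variables
    }
    return PSBN(graph=graph, symbols=(), update=update)
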