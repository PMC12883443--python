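"""Reduced ordered binary decision diagrams (ROBDDs).

This module is the symbolic carrier for the whole package: Boolean
functions over named bits (network-state bits, truth-table parameter
bits, and copies of state bits used by hybrid temporal operators) are
stored as hash-consed, canonical decision diagrams.  Canonicity gives
constant-time equality, and the diagram structure supports the exact
big-integer model counting and uniform model sampling that candidate-set
analysis needs.

The manager owns a global variable order (the order in which bits were
declared).  All operations are implemented with memoised Shannon
recursion; nothing here is specific to Boolean networks.
"""

from __future__ import annotations

import json
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

#: pseudo-level of the two terminal nodes; larger than any real level
_TERMINAL_LEVEL = 1 << 30

FALSE = 0
TRUE = 1


class Bdd:
    """A BDD manager: a variable order plus a shared node table.

    Nodes are integers; ``0`` and ``1`` are the terminals.  Functions from
    different managers must never be mixed.
    """

    def __init__(self, names: Iterable[str] = ()) -> None:
        self._names: List[str] = []
        self._index: Dict[str, int] = {}
        # parallel arrays indexed by node id; slots 0/1 are terminals
        self._level: List[int] = [_TERMINAL_LEVEL, _TERMINAL_LEVEL]
        self._lo: List[int] = [0, 1]
        self._hi: List[int] = [0, 1]
        self._unique: Dict[Tuple[int, int, int], int] = {}
        self._ite_cache: Dict[Tuple[int, int, int], int] = {}
        for name in names:
            self.add_var(name)

    # ------------------------------------------------------------------
    # variables

    def add_var(self, name: str) -> int:
        """Declare a new bit at the bottom of the order; return its level."""
        if name in self._index:
            raise ValueError(f"bit {name!r} already declared")
        level = len(self._names)
        self._names.append(name)
        self._index[name] = level
        return level

    def level_of(self, name: str) -> int:
        return self._index[name]

    def name_of(self, level: int) -> str:
        return self._names[level]

    @property
    def var_names(self) -> Tuple[str, ...]:
        return tuple(self._names)

    def var(self, name: str) -> int:
        """The function that is true iff the named bit is 1."""
        return self._mk(self._index[name], FALSE, TRUE)

    def nvar(self, name: str) -> int:
        return self._mk(self._index[name], TRUE, FALSE)

    def literal(self, name: str, value: bool) -> int:
        return self.var(name) if value else self.nvar(name)

    # ------------------------------------------------------------------
    # node table

    def _mk(self, level: int, lo: int, hi: int) -> int:
        if lo == hi:
            return lo
        key = (level, lo, hi)
        node = self._unique.get(key)
        if node is None:
            node = len(self._level)
            self._level.append(level)
            self._lo.append(lo)
            self._hi.append(hi)
            self._unique[key] = node
        return node

    def _cofactors(self, u: int, level: int) -> Tuple[int, int]:
        if self._level[u] == level:
            return self._lo[u], self._hi[u]
        return u, u

    # ------------------------------------------------------------------
    # Boolean connectives (all reduce to if-then-else)

    def ite(self, f: int, g: int, h: int) -> int:
        if f == TRUE:
            return g
        if f == FALSE:
            return h
        if g == h:
            return g
        if g == TRUE and h == FALSE:
            return f
        key = (f, g, h)
        cached = self._ite_cache.get(key)
        if cached is not None:
            return cached
        level = min(self._level[f], self._level[g], self._level[h])
        f0, f1 = self._cofactors(f, level)
        g0, g1 = self._cofactors(g, level)
        h0, h1 = self._cofactors(h, level)
        result = self._mk(level, self.ite(f0, g0, h0), self.ite(f1, g1, h1))
        self._ite_cache[key] = result
        return result

    def not_(self, f: int) -> int:
        return self.ite(f, FALSE, TRUE)

    def and_(self, f: int, g: int) -> int:
        return self.ite(f, g, FALSE)

    def or_(self, f: int, g: int) -> int:
        return self.ite(f, TRUE, g)

    def xor(self, f: int, g: int) -> int:
        return self.ite(f, self.not_(g), g)

    def imp(self, f: int, g: int) -> int:
        return self.ite(f, g, TRUE)

    def iff(self, f: int, g: int) -> int:
        return self.ite(f, g, self.not_(g))

    def and_many(self, fs: Iterable[int]) -> int:
        acc = TRUE
        for f in fs:
            acc = self.and_(acc, f)
            if acc == FALSE:
                break
        return acc

    def or_many(self, fs: Iterable[int]) -> int:
        acc = FALSE
        for f in fs:
            acc = self.or_(acc, f)
            if acc == TRUE:
                break
        return acc

    # ------------------------------------------------------------------
    # quantification, substitution, cofactoring

    def exists(self, f: int, levels: Iterable[int]) -> int:
        lvls = frozenset(levels)
        if not lvls:
            return f
        memo: Dict[int, int] = {}

        def rec(u: int) -> int:
            if u < 2 or self._level[u] > max(lvls):
                return u
            r = memo.get(u)
            if r is not None:
                return r
            level, lo, hi = self._level[u], self._lo[u], self._hi[u]
            if level in lvls:
                r = self.or_(rec(lo), rec(hi))
            else:
                r = self._mk(level, rec(lo), rec(hi))
            memo[u] = r
            return r

        return rec(f)

    def forall(self, f: int, levels: Iterable[int]) -> int:
        return self.not_(self.exists(self.not_(f), levels))

    def restrict(self, f: int, assignment: Mapping[int, bool]) -> int:
        """Cofactor: fix the given levels to constants."""
        if not assignment:
            return f
        memo: Dict[int, int] = {}
        top = max(assignment)

        def rec(u: int) -> int:
            if u < 2 or self._level[u] > top:
                return u
            r = memo.get(u)
            if r is not None:
                return r
            level, lo, hi = self._level[u], self._lo[u], self._hi[u]
            if level in assignment:
                r = rec(hi) if assignment[level] else rec(lo)
            else:
                r = self._mk(level, rec(lo), rec(hi))
            memo[u] = r
            return r

        return rec(f)

    def flip(self, f: int, level: int) -> int:
        """Substitute a bit by its own negation: ``f[x := !x]``."""
        memo: Dict[int, int] = {}

        def rec(u: int) -> int:
            if u < 2 or self._level[u] > level:
                return u
            r = memo.get(u)
            if r is not None:
                return r
            lvl, lo, hi = self._level[u], self._lo[u], self._hi[u]
            if lvl == level:
                r = self._mk(lvl, hi, lo)
            else:
                r = self._mk(lvl, rec(lo), rec(hi))
            memo[u] = r
            return r

        return rec(f)

    def rename(self, f: int, mapping: Mapping[int, int]) -> int:
        """Simultaneous substitution of bits by other bits.

        ``f[src := dst]`` computed as ``exists src. f /\\ (src <=> dst)`` —
        valid even when the target bits already occur in ``f``.
        """
        if not mapping:
            return f
        glue = TRUE
        for src, dst in mapping.items():
            eq = self.iff(self._mk(src, FALSE, TRUE), self._mk(dst, FALSE, TRUE))
            glue = self.and_(glue, eq)
        return self.exists(self.and_(f, glue), mapping.keys())

    # ------------------------------------------------------------------
    # evaluation, support, counting, sampling

    def evaluate(self, f: int, assignment: Mapping[int, bool]) -> bool:
        u = f
        while u >= 2:
            u = self._hi[u] if assignment[self._level[u]] else self._lo[u]
        return u == TRUE

    def support(self, f: int) -> Set[int]:
        seen: Set[int] = set()
        levels: Set[int] = set()
        stack = [f]
        while stack:
            u = stack.pop()
            if u < 2 or u in seen:
                continue
            seen.add(u)
            levels.add(self._level[u])
            stack.append(self._lo[u])
            stack.append(self._hi[u])
        return levels

    def count(self, f: int, levels: Sequence[int]) -> int:
        """Exact number of satisfying assignments over the given bits.

        The support of ``f`` must be contained in ``levels``; bits in
        ``levels`` that ``f`` does not mention each double the count.
        """
        lvls = sorted(levels)
        pos = {lvl: i for i, lvl in enumerate(lvls)}
        missing = self.support(f) - set(lvls)
        if missing:
            names = ", ".join(self._names[l] for l in sorted(missing))
            raise ValueError(f"function depends on bits outside the count scope: {names}")
        n = len(lvls)
        memo: Dict[int, int] = {}

        def rec(u: int, i: int) -> int:
            if u == FALSE:
                return 0
            if u == TRUE:
                return 1 << (n - i)
            j = pos[self._level[u]]
            c = memo.get(u)
            if c is None:
                c = rec(self._lo[u], j + 1) + rec(self._hi[u], j + 1)
                memo[u] = c
            return c << (j - i)

        return rec(f, 0)

    def sample(self, f: int, levels: Sequence[int], rng) -> Dict[int, bool]:
        """Draw one satisfying assignment uniformly at random.

        Descends the diagram weighting each branch by its model count, so
        every model over ``levels`` is equally likely.  ``rng`` is a
        ``random.Random`` instance.
        """
        lvls = sorted(levels)
        pos = {lvl: i for i, lvl in enumerate(lvls)}
        if self.count(f, lvls) == 0:
            raise ValueError("cannot sample from an empty set")
        n = len(lvls)
        memo: Dict[int, int] = {}

        def models(u: int, i: int) -> int:
            if u == FALSE:
                return 0
            if u == TRUE:
                return 1 << (n - i)
            j = pos[self._level[u]]
            c = memo.get(u)
            if c is None:
                c = models(self._lo[u], j + 1) + models(self._hi[u], j + 1)
                memo[u] = c
            return c << (j - i)

        assignment: Dict[int, bool] = {}
        u = f
        for i, lvl in enumerate(lvls):
            if u >= 2 and self._level[u] == lvl:
                c0 = models(self._lo[u], i + 1)
                c1 = models(self._hi[u], i + 1)
                take_hi = rng.randrange(c0 + c1) < c1
                assignment[lvl] = take_hi
                u = self._hi[u] if take_hi else self._lo[u]
            else:
                # bit unconstrained at this point: both values equally likely
                assignment[lvl] = bool(rng.getrandbits(1))
        return assignment

    # ------------------------------------------------------------------
    # serialization

    def serialize(self, f: int) -> dict:
        """Portable JSON form: variable order + reachable node table."""
        order: List[int] = []
        index: Dict[int, int] = {FALSE: 0, TRUE: 1}

        def visit(u: int) -> int:
            if u in index:
                return index[u]
            lo = visit(self._lo[u])
            hi = visit(self._hi[u])
            index[u] = len(order) + 2
            order.append(u)
            return index[u]

        root = visit(f)
        nodes = [
            [self._names[self._level[u]], index[self._lo[u]], index[self._hi[u]]]
            for u in order
        ]
        return {"vars": list(self._names), "nodes": nodes, "root": root}

    def deserialize(self, data: dict) -> int:
        """Rebuild a function serialized by :meth:`serialize`.

        Every variable named in the payload must already be declared in
        this manager; the stored order must be a prefix-compatible subset
        of the manager's order (checked node-wise through ``_mk``).
        """
        ids: List[int] = [FALSE, TRUE]
        for name, lo, hi in data["nodes"]:
            if name not in self._index:
                raise ValueError(f"serialized function mentions undeclared bit {name!r}")
            level = self._index[name]
            if level >= min(self._level[ids[lo]], self._level[ids[hi]]):
                raise ValueError(
                    "serialized function is incompatible with this manager's bit order"
                )
            ids.append(self._mk(level, ids[lo], ids[hi]))
        root = data["root"]
        return ids[root]


def dump_json(manager: Bdd, f: int) -> str:
    return json.dumps(manager.serialize(f))


def load_json(manager: Bdd, text: str) -> int:
    return manager.deserialize(json.loads(text))
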