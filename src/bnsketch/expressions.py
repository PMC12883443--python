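"""Boolean expression ASTs and their ASCII concrete syntax.

One expression language serves two roles: update expressions of a
partially specified Boolean network (names are network variables,
applications are uninterpreted function symbols) and quantifier-free
bodies of first-order update-function properties (names are bound
Boolean variables).

Concrete syntax, loosest to tightest binding::

    <=>   =>   |   ^   &   ! (or ~)   atoms

with constants ``0``/``1``/``false``/``true``, identifiers
``[A-Za-z_][A-Za-z0-9_]*`` and applications ``g(e1, ..., ek)`` (``g()``
for arity 0; a bare identifier is always a name, never a call).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Sequence, Set, Tuple


class ExprSyntaxError(ValueError):
    """Malformed expression text; carries the offending position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Expr:
    pass


@dataclass(frozen=True)
class Const(Expr):
    value: bool


@dataclass(frozen=True)
class Name(Expr):
    name: str


@dataclass(frozen=True)
class Not(Expr):
    arg: Expr


@dataclass(frozen=True)
class BinOp(Expr):
    op: str  # one of & | ^ => <=>
    left: Expr
    right: Expr


@dataclass(frozen=True)
class App(Expr):
    func: str
    args: Tuple[Expr, ...]


TRUE = Const(True)
FALSE = Const(False)

_PRECEDENCE = {"<=>": 1, "=>": 2, "|": 3, "^": 4, "&": 5}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<op><=>|=>|[&|^()!,~:])|(?P<const>[01]\b|true\b|false\b)"
    r"|(?P<ident>[A-Za-z_][A-Za-z0-9_]*))"
)


def _tokenize(text: str) -> Iterator[Tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ExprSyntaxError(f"unexpected character {stripped[0]!r}", pos)
        if m.group("op"):
            yield ("op", m.group("op"), m.start("op"))
        elif m.group("const"):
            yield ("const", m.group("const"), m.start("const"))
        else:
            yield ("ident", m.group("ident"), m.start("ident"))
        pos = m.end()
    yield ("end", "", len(text))


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> Tuple[str, str, int]:
        return self.tokens[self.i]

    def advance(self) -> Tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val, pos = self.peek()
        if kind != "op" or val != value:
            raise ExprSyntaxError(f"expected {value!r}, found {val or 'end of input'!r}", pos)
        self.advance()

    def parse(self) -> Expr:
        expr = self.parse_binary(1)
        kind, val, pos = self.peek()
        if kind != "end":
            raise ExprSyntaxError(f"unexpected trailing {val!r}", pos)
        return expr

    def parse_binary(self, min_prec: int) -> Expr:
        left = self.parse_unary()
        while True:
            kind, val, _ = self.peek()
            if kind != "op" or val not in _PRECEDENCE or _PRECEDENCE[val] < min_prec:
                return left
            self.advance()
            # => and <=> associate to the right, the rest are associative
            next_prec = _PRECEDENCE[val] + (0 if val in ("=>", "<=>") else 1)
            right = self.parse_binary(next_prec)
            left = BinOp(val, left, right)

    def parse_unary(self) -> Expr:
        kind, val, pos = self.peek()
        if kind == "op" and val in ("!", "~"):
            self.advance()
            return Not(self.parse_unary())
        return self.parse_primary()

    def parse_primary(self) -> Expr:
        kind, val, pos = self.advance()
        if kind == "op" and val == "(":
            inner = self.parse_binary(1)
            self.expect(")")
            return inner
        if kind == "const":
            return Const(val in ("1", "true"))
        if kind == "ident":
            nkind, nval, _ = self.peek()
            if nkind == "op" and nval == "(":
                self.advance()
                args = []
                fkind, fval, _ = self.peek()
                if not (fkind == "op" and fval == ")"):
                    args.append(self.parse_binary(1))
                    while True:
                        ckind, cval, _ = self.peek()
                        if ckind == "op" and cval == ",":
                            self.advance()
                            args.append(self.parse_binary(1))
                        else:
                            break
                self.expect(")")
                return App(val, tuple(args))
            return Name(val)
        raise ExprSyntaxError(f"expected an expression, found {val or 'end of input'!r}", pos)


def parse_expression(text: str) -> Expr:
    """Parse the ASCII syntax above into an :class:`Expr` tree."""
    return _Parser(text).parse()


def to_text(expr: Expr, parent_prec: int = 0) -> str:
    """Render an expression; inverse of :func:`parse_expression` up to parentheses."""
    if isinstance(expr, Const):
        return "1" if expr.value else "0"
    if isinstance(expr, Name):
        return expr.name
    if isinstance(expr, Not):
        return "!" + to_text(expr.arg, 6)
    if isinstance(expr, App):
        return f"{expr.func}({', '.join(to_text(a) for a in expr.args)})"
    if isinstance(expr, BinOp):
        prec = _PRECEDENCE[expr.op]
        body = f"{to_text(expr.left, prec)} {expr.op} {to_text(expr.right, prec + 1)}"
        return f"({body})" if prec < parent_prec else body
    raise TypeError(f"not an expression: {expr!r}")


def free_names(expr: Expr) -> Set[str]:
    """Names referenced as atoms (function symbols excluded)."""
    if isinstance(expr, Name):
        return {expr.name}
    if isinstance(expr, Not):
        return free_names(expr.arg)
    if isinstance(expr, BinOp):
        return free_names(expr.left) | free_names(expr.right)
    if isinstance(expr, App):
        out: Set[str] = set()
        for a in expr.args:
            out |= free_names(a)
        return out
    return set()


def applications(expr: Expr) -> Set[Tuple[str, int]]:
    """All ``(symbol, arity)`` pairs applied anywhere in the expression."""
    if isinstance(expr, App):
        out = {(expr.func, len(expr.args))}
        for a in expr.args:
            out |= applications(a)
        return out
    if isinstance(expr, Not):
        return applications(expr.arg)
    if isinstance(expr, BinOp):
        return applications(expr.left) | applications(expr.right)
    return set()


def evaluate(
    expr: Expr,
    env: Mapping[str, bool],
    apply: Callable[[str, Tuple[bool, ...]], bool] | None = None,
) -> bool:
    """Evaluate under a total name environment and a symbol interpretation."""
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Name):
        return bool(env[expr.name])
    if isinstance(expr, Not):
        return not evaluate(expr.arg, env, apply)
    if isinstance(expr, BinOp):
        a = evaluate(expr.left, env, apply)
        b = evaluate(expr.right, env, apply)
        if expr.op == "&":
            return a and b
        if expr.op == "|":
            return a or b
        if expr.op == "^":
            return a != b
        if expr.op == "=>":
            return (not a) or b
        return a == b  # <=>
    if isinstance(expr, App):
        if apply is None:
            raise ValueError(f"no interpretation provided for symbol {expr.func!r}")
        vals = tuple(evaluate(a, env, apply) for a in expr.args)
        return apply(expr.func, vals)
    raise TypeError(f"not an expression: {expr!r}")
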