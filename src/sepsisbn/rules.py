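"""Rule language for delay-aware Boolean update functions.

Each node of the network carries one update rule written in a small logical
dialect::

    Bacteria = Infection &! (Bacteria & (THR_MAC[B_CL] | THR_Phagocytosis[B_CL]))

Operators are ``&`` (AND), ``|`` (OR) and ``!`` (NOT); ``&!`` is the
conventional way inhibition is written and simply parses as "AND NOT".
``THR_<node>[<tag>]`` is a *threshold* (time-delay) term: it is true at step
``t`` only if ``<node>`` has been active for the last ``d`` consecutive
committed steps, where ``d`` is the delay attached to ``<tag>``.  Identifiers
may contain letters, digits, underscores and hyphens (``Act-Mon``, ``TNF-a``).

Precedence is the usual NOT > AND > OR, left associative; parentheses
override.  Parsing is whitespace-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "RuleExpr",
    "Var",
    "Not",
    "And",
    "Or",
    "Thr",
    "RuleSyntaxError",
    "parse_rule",
    "parse_expr",
    "serialize",
    "evaluate",
    "referenced_nodes",
    "referenced_tags",
    "flatten_delays",
]


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

class RuleExpr:
    """Base class for rule expression nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class Var(RuleExpr):
    """Plain reference to another node's current/previous state."""

    name: str


@dataclass(frozen=True)
class Not(RuleExpr):
    child: RuleExpr


@dataclass(frozen=True)
class And(RuleExpr):
    children: tuple[RuleExpr, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND requires at least 2 children")


@dataclass(frozen=True)
class Or(RuleExpr):
    children: tuple[RuleExpr, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR requires at least 2 children")


@dataclass(frozen=True)
class Thr(RuleExpr):
    """Threshold term ``THR_<name>[<tag>]``: *name* active for the last
    ``delay(tag)`` consecutive steps."""

    name: str
    tag: str


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries 1-based line and column."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_IDENT_CHARS = set("abcdefghijklmnopqrstuvwxyz"
                   "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "0123456789_-")


@dataclass(frozen=True)
class _Token:
    kind: str  # IDENT THR & | ! ( ) = EOF
    text: str
    line: int
    column: int


def _tokenize(text: str, line: int = 1) -> Iterator[_Token]:
    i, n = 0, len(text)
    col0 = 1
    while i < n:
        c = text[i]
        if c in " \t\r\n":
            i += 1
            continue
        col = col0 + i
        if c in "&|!()=[]":
            yield _Token(c, c, line, col)
            i += 1
            continue
        if c in _IDENT_CHARS:
            j = i
            while j < n and text[j] in _IDENT_CHARS:
                j += 1
            word = text[i:j]
            # THR_<node>[<tag>] — the bracketed tag is tokenized separately
            if word.startswith("THR_"):
                yield _Token("THR", word, line, col)
            else:
                yield _Token("IDENT", word, line, col)
            i = j
            continue
        raise RuleSyntaxError(f"unexpected character {c!r}", line, col)
    yield _Token("EOF", "", line, col0 + n)


class _Parser:
    """Recursive-descent parser: expr := term ('|' term)*, term := factor
    ('&' factor)*, factor := '!' factor | IDENT | THR '[' IDENT ']' |
    '(' expr ')'."""

    def __init__(self, tokens: Sequence[_Token]):
        self.tokens = list(tokens)
        self.pos = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.pos]

    def expect(self, kind: str) -> _Token:
        tok = self.cur
        if tok.kind != kind:
            what = tok.text or "end of input"
            raise RuleSyntaxError(f"expected {kind!r}, found {what!r}",
                                  tok.line, tok.column)
        self.pos += 1
        return tok

    def parse_expr(self) -> RuleExpr:
        terms = [self.parse_term()]
        while self.cur.kind == "|":
            self.pos += 1
            terms.append(self.parse_term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_term(self) -> RuleExpr:
        factors = [self.parse_factor()]
        while self.cur.kind == "&":
            self.pos += 1
            factors.append(self.parse_factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_factor(self) -> RuleExpr:
        tok = self.cur
        if tok.kind == "!":
            self.pos += 1
            return Not(self.parse_factor())
        if tok.kind == "(":
            self.pos += 1
            inner = self.parse_expr()
            self.expect(")")
            return inner
        if tok.kind == "IDENT":
            self.pos += 1
            return Var(tok.text)
        if tok.kind == "THR":
            self.pos += 1
            node = tok.text[len("THR_"):]
            if not node:
                raise RuleSyntaxError("THR_ term lacks a node name",
                                      tok.line, tok.column)
            self.expect("[")
            tag = self.expect("IDENT").text
            self.expect("]")
            return Thr(node, tag)
        what = tok.text or "end of input"
        raise RuleSyntaxError(f"unexpected {what!r}", tok.line, tok.column)


def parse_expr(text: str, line: int = 1) -> RuleExpr:
    """Parse a bare right-hand-side expression."""
    parser = _Parser(list(_tokenize(text, line)))
    expr = parser.parse_expr()
    parser.expect("EOF")
    return expr


def parse_rule(text: str, line: int = 1) -> tuple[str, RuleExpr]:
    """Parse one ``"Node = expression"`` line into ``(node_name, RuleExpr)``.

    Raises :class:`RuleSyntaxError` with line/column on malformed input,
    including an empty right-hand side.
    """
    tokens = list(_tokenize(text, line))
    parser = _Parser(tokens)
    target = parser.expect("IDENT").text
    parser.expect("=")
    if parser.cur.kind == "EOF":
        raise RuleSyntaxError("empty right-hand side",
                              parser.cur.line, parser.cur.column)
    expr = parser.parse_expr()
    parser.expect("EOF")
    return target, expr


# ---------------------------------------------------------------------------
# Serialization (canonical form)
# ---------------------------------------------------------------------------

def _serialize(expr: RuleExpr, parent_prec: int) -> str:
    # precedence levels: OR=1, AND=2, NOT=3, atom=4
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Thr):
        return f"THR_{expr.name}[{expr.tag}]"
    if isinstance(expr, Not):
        return "!" + _serialize(expr.child, 3)
    if isinstance(expr, And):
        body = " & ".join(_serialize(c, 2) for c in expr.children)
        # >= so that an AND nested inside an AND keeps its own parentheses
        # and the tree shape survives a re-parse
        return f"({body})" if parent_prec >= 2 else body
    if isinstance(expr, Or):
        body = " | ".join(_serialize(c, 1) for c in expr.children)
        return f"({body})" if parent_prec >= 1 else body
    raise TypeError(f"not a RuleExpr: {expr!r}")


def serialize(expr: RuleExpr) -> str:
    """Canonical text form; re-parsing it yields an identical tree."""
    return _serialize(expr, 0)


# ---------------------------------------------------------------------------
# Introspection helpers
# ---------------------------------------------------------------------------

def _walk(expr: RuleExpr) -> Iterator[RuleExpr]:
    yield expr
    if isinstance(expr, Not):
        yield from _walk(expr.child)
    elif isinstance(expr, (And, Or)):
        for c in expr.children:
            yield from _walk(c)


def referenced_nodes(expr: RuleExpr) -> set[str]:
    """All node names read by *expr* (through VAR or THR)."""
    out: set[str] = set()
    for e in _walk(expr):
        if isinstance(e, (Var, Thr)):
            out.add(e.name)
    return out


def referenced_tags(expr: RuleExpr) -> set[str]:
    """All threshold-tag names used by *expr*."""
    return {e.tag for e in _walk(expr) if isinstance(e, Thr)}


def flatten_delays(expr: RuleExpr) -> RuleExpr:
    """Replace every THR term by a plain VAR reference (drops the delay)."""
    if isinstance(expr, Thr):
        return Var(expr.name)
    if isinstance(expr, Not):
        return Not(flatten_delays(expr.child))
    if isinstance(expr, And):
        return And(tuple(flatten_delays(c) for c in expr.children))
    if isinstance(expr, Or):
        return Or(tuple(flatten_delays(c) for c in expr.children))
    return expr


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(
    expr: RuleExpr,
    history,
    t: int,
    delays: Mapping[str, int],
    node_index: Mapping[str, int] | None = None,
    initial_state=None,
    snapshot=None,
) -> int:
    """Evaluate *expr* at time step ``t`` against a committed state history.

    Parameters
    ----------
    history:
        Either a 2-D 0/1 array with one row per committed step (row ``k`` =
        state after step ``k``) and one column per node, or an object with
        ``states`` and ``nodes`` attributes (a :class:`~sepsisbn.engine.Trajectory`).
    t:
        Step being computed, ``t >= 1``.  ``history`` must cover rows
        ``0 .. t-1``.
    delays:
        Threshold-tag name -> positive integer delay.
    node_index:
        Node name -> column.  Required when *history* is a bare array.
    initial_state:
        1-D 0/1 vector used for fictitious steps before 0; defaults to row 0
        of the history.
    snapshot:
        Optional 1-D vector of the freshest within-step values.  When given,
        plain VAR terms read from it (the update scheduler's view); THR terms
        always read the committed history.  Without it, VAR reads row ``t-1``.

    Returns the bit value (0 or 1).  Evaluation is pure.
    """
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if node_index is None:
        nodes = getattr(history, "nodes", None)
        if nodes is None:
            raise ValueError("node_index required for a bare state array")
        node_index = {name: i for i, name in enumerate(nodes)}
    states = np.asarray(getattr(history, "states", history))
    if states.ndim != 2:
        raise ValueError("history must be 2-D (steps x nodes)")
    if states.shape[0] < t:
        raise ValueError(f"history has {states.shape[0]} rows, needs {t}")
    init = states[0] if initial_state is None else np.asarray(initial_state)
    var_row = states[t - 1] if snapshot is None else np.asarray(snapshot)

    def col(name: str) -> int:
        try:
            return node_index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r} in rule expression") from None

    def rec(e: RuleExpr) -> int:
        if isinstance(e, Var):
            return int(var_row[col(e.name)])
        if isinstance(e, Thr):
            try:
                d = delays[e.tag]
            except KeyError:
                raise KeyError(f"unknown threshold tag {e.tag!r}") from None
            c = col(e.name)
            for k in range(1, d + 1):
                step = t - k
                bit = init[c] if step < 0 else states[step, c]
                if not bit:
                    return 0
            return 1
        if isinstance(e, Not):
            return 1 - rec(e.child)
        if isinstance(e, And):
            for ch in e.children:
                if not rec(ch):
                    return 0
            return 1
        if isinstance(e, Or):
            for ch in e.children:
                if rec(ch):
                    return 1
            return 0
        raise TypeError(f"not a RuleExpr: {e!r}")

    return rec(expr)
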