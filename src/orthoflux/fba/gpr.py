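"""Boolean gene-protein-reaction (GPR) rules.

Grammar (case-insensitive keywords)::

    expr   := term (OR term)*
    term   := factor (AND factor)*
    factor := GENE | '(' expr ')'

AND joins subunits of one enzyme complex (all genes required); OR joins
isozymes (any gene suffices). The empty rule means the reaction needs no
gene product and is always active.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Union


class GPRSyntaxError(ValueError):
    """Malformed GPR; the message carries the character position."""


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    operands: tuple["Node", ...]


@dataclass(frozen=True)
class Or:
    operands: tuple["Node", ...]


Node = Union[Gene, And, Or]

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        match = _TOKEN_RE.match(expr, pos)
        if match is None:
            break
        tokens.append((match.group(1), match.start(1)))
        pos = match.end()
    return tokens


class _Parser:
    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.index = 0

    def _peek(self) -> Optional[tuple[str, int]]:
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        token = self._peek()
        if token is None:
            raise GPRSyntaxError(
                f"unexpected end of expression at position {len(self.expr)}"
            )
        self.index += 1
        return token

    def parse(self) -> Node:
        node = self._expr()
        leftover = self._peek()
        if leftover is not None:
            raise GPRSyntaxError(
                f"unexpected token {leftover[0]!r} at position {leftover[1]}"
            )
        return node

    def _expr(self) -> Node:
        operands = [self._term()]
        while True:
            token = self._peek()
            if token is not None and token[0].upper() == "OR":
                self._next()
                operands.append(self._term())
            else:
                break
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def _term(self) -> Node:
        operands = [self._factor()]
        while True:
            token = self._peek()
            if token is not None and token[0].upper() == "AND":
                self._next()
                operands.append(self._factor())
            else:
                break
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def _factor(self) -> Node:
        token, pos = self._next()
        if token == "(":
            node = self._expr()
            closing = self._next()
            if closing[0] != ")":
                raise GPRSyntaxError(
                    f"expected ')' at position {closing[1]}, got {closing[0]!r}"
                )
            return node
        if token == ")" or token.upper() in ("AND", "OR"):
            raise GPRSyntaxError(
                f"unexpected token {token!r} at position {pos}"
            )
        return Gene(token)


def parse_gpr(expr: str) -> Optional[Node]:
    """Parse a GPR string into an AST; empty/whitespace rules give None."""
    if not expr or not expr.strip():
        return None
    return _Parser(expr).parse()


def _eval(node: Node, deleted: frozenset[str]) -> bool:
    if isinstance(node, Gene):
        return node.name not in deleted
    if isinstance(node, And):
        return all(_eval(op, deleted) for op in node.operands)
    return any(_eval(op, deleted) for op in node.operands)


def evaluate_gpr(expr: Union[str, Node, None], deleted_genes: Iterable[str]) -> bool:
    """True when the reaction remains catalysable after deleting genes.

    Deleted genes evaluate to false, all others to true; standard boolean
    semantics. An empty rule is always active.
    """
    node = parse_gpr(expr) if isinstance(expr, str) or expr is None else expr
    if node is None:
        return True
    return _eval(node, frozenset(deleted_genes))


def gpr_genes(expr: Union[str, Node, None]) -> frozenset[str]:
    """All gene identifiers referenced by a rule."""
    node = parse_gpr(expr) if isinstance(expr, str) or expr is None else expr
    if node is None:
        return frozenset()
    if isinstance(node, Gene):
        return frozenset([node.name])
    return frozenset().union(*(gpr_genes(op) for op in node.operands))
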