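"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links a reaction to the genes whose products catalyse it:
``and`` combines obligate complex subunits, ``or`` combines isozymes.
The grammar accepted here is the common SBML-FBC textual convention:

    rule   := orexpr
    orexpr := andexpr ("or" andexpr)*
    andexpr:= atom ("and" atom)*
    atom   := "(" orexpr ")" | GENE

``and`` binds tighter than ``or``; operators are case-insensitive; gene
identifiers are any run of word characters plus ``.``, ``:`` and ``-``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Optional

__all__ = ["GPRNode", "Gene", "And", "Or", "GPRParseError", "parse_gpr",
           "serialize_gpr", "gpr_genes", "evaluate_gpr"]


class GPRParseError(ValueError):
    """Raised for a malformed GPR rule; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class GPRNode:
    """Base class for nodes of a parsed GPR tree."""

    __slots__ = ()


@dataclass(frozen=True)
class Gene(GPRNode):
    gene: str


@dataclass(frozen=True)
class And(GPRNode):
    children: tuple[GPRNode, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND node requires >= 2 children")


@dataclass(frozen=True)
class Or(GPRNode):
    children: tuple[GPRNode, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR node requires >= 2 children")


_TOKEN = re.compile(r"\s*(\(|\)|[\w.:-]+)")


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise GPRParseError(f"unexpected character {text.strip()[0]!r}", pos)
            return
        yield m.group(1), m.start(1)
        pos = m.end()


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> GPRNode:
        if not self.tokens:
            raise GPRParseError("empty rule", 0)
        node = self.or_expr()
        if self.peek() is not None:
            raise GPRParseError(f"unexpected token {self.peek()!r}", self.pos())
        return node

    def or_expr(self) -> GPRNode:
        children = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def and_expr(self) -> GPRNode:
        children = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            children.append(self.atom())
        return children[0] if len(children) == 1 else And(tuple(children))

    def atom(self) -> GPRNode:
        pos = self.pos()
        tok = self.next()
        if tok == "(":
            node = self.or_expr()
            if self.peek() != ")":
                raise GPRParseError("unbalanced parentheses", self.pos())
            self.next()
            return node
        if tok == ")":
            raise GPRParseError("unexpected ')'", pos)
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"operator {tok!r} used where an operand is required", pos)
        return Gene(tok)


def parse_gpr(text: str) -> GPRNode:
    """Parse a textual GPR rule into a tree of :class:`Gene`/:class:`And`/:class:`Or`."""
    return _Parser(text).parse()


def serialize_gpr(node: GPRNode) -> str:
    """Render a GPR tree back to rule text.

    Same-operator children are parenthesised so the printed rule parses back
    to a structurally identical tree (nesting is preserved, not flattened).
    """
    if isinstance(node, Gene):
        return node.gene
    op = "and" if isinstance(node, And) else "or"
    parts = []
    for child in node.children:
        text = serialize_gpr(child)
        needs_parens = type(child) is type(node) or (isinstance(node, And) and isinstance(child, Or))
        parts.append(f"({text})" if needs_parens else text)
    return f" {op} ".join(parts)


def gpr_genes(node: GPRNode) -> set[str]:
    """All gene ids appearing in the rule."""
    if isinstance(node, Gene):
        return {node.gene}
    out: set[str] = set()
    for child in node.children:
        out |= gpr_genes(child)
    return out


def evaluate_gpr(
    node: GPRNode,
    values: Mapping[str, float],
    and_op: Callable[[list[float]], float] = min,
    or_op: Callable[[list[float]], float] = max,
) -> Optional[float]:
    """Collapse a GPR tree over per-gene values (e.g. expression fold changes).

    Genes absent from ``values`` are dropped from their operator's operand
    list; a node whose operands are all missing evaluates to ``None``, and a
    rule whose leaves are all missing yields ``None`` overall (the reaction
    is treated as unperturbed downstream).
    """
    if isinstance(node, Gene):
        return values.get(node.gene)
    op = and_op if isinstance(node, And) else or_op
    operands = [v for v in (evaluate_gpr(c, values, and_op, or_op) for c in node.children)
                if v is not None]
    if not operands:
        return None
    return float(op(operands))
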