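"""Gene-protein-reaction (GPR) rule parsing and evaluation.

A GPR rule is a boolean expression over gene identifiers in which ``and``
joins subunits of an enzyme complex (all required) and ``or`` joins
isozymes (any sufficient).  Rules are evaluated under two semantics:

* discrete — gene categories in {+1 expressed, 0 unknown, -1 unexpressed};
  ``and`` takes the minimum of its children, ``or`` the maximum, so a
  complex is only as expressed as its least-expressed subunit while one
  expressed isozyme suffices.
* continuous — non-negative expression levels; ``and`` -> min and ``or``
  -> max or sum.  The sum mode models isozymes adding catalytic capacity
  and is the default when translating expression into flux bound caps.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Union


class GprParseError(ValueError):
    """Raised when a rule string cannot be parsed; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Gene:
    id: str

    def genes(self) -> set:
        return {self.id}


@dataclass(frozen=True)
class And:
    children: tuple

    def genes(self) -> set:
        return set().union(*(c.genes() for c in self.children))


@dataclass(frozen=True)
class Or:
    children: tuple

    def genes(self) -> set:
        return set().union(*(c.genes() for c in self.children))


GprNode = Union[Gene, And, Or]


@dataclass
class GprExpression:
    """Parsed GPR rule: an AST plus the original source text."""

    root: GprNode
    source_text: str = ""

    def genes(self) -> set:
        return self.root.genes()

    def serialize(self) -> str:
        return _serialize(self.root)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> List[tuple]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


class _Parser:
    # grammar: expr := term ('or' term)* ; term := factor ('and' factor)* ;
    # factor := GENE | '(' expr ')'   -- 'and' binds tighter than 'or'
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.text))

    def parse(self) -> GprNode:
        node = self._expr()
        tok, at = self._peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok!r}", at)
        return node

    def _expr(self) -> GprNode:
        parts = [self._term()]
        while True:
            tok, _ = self._peek()
            if tok is not None and tok.lower() == "or":
                self.pos += 1
                parts.append(self._term())
            else:
                break
        if len(parts) == 1:
            return parts[0]
        # flatten nested same-operator nodes: 'a or (b or c)' == 'a or b or c'
        flat = []
        for p in parts:
            flat.extend(p.children if isinstance(p, Or) else (p,))
        return Or(tuple(flat))

    def _term(self) -> GprNode:
        parts = [self._factor()]
        while True:
            tok, _ = self._peek()
            if tok is not None and tok.lower() == "and":
                self.pos += 1
                parts.append(self._factor())
            else:
                break
        if len(parts) == 1:
            return parts[0]
        flat = []
        for p in parts:
            flat.extend(p.children if isinstance(p, And) else (p,))
        return And(tuple(flat))

    def _factor(self) -> GprNode:
        tok, at = self._peek()
        if tok is None:
            raise GprParseError("unexpected end of rule", at)
        if tok == "(":
            self.pos += 1
            node = self._expr()
            tok2, at2 = self._peek()
            if tok2 != ")":
                raise GprParseError("unbalanced parenthesis", at2)
            self.pos += 1
            return node
        if tok == ")":
            raise GprParseError("unbalanced parenthesis", at)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"dangling operator {tok!r}", at)
        self.pos += 1
        return Gene(tok)


def parse_gpr(rule_text: str) -> GprExpression:
    """Parse a GPR rule string into an AST.

    ``and``/``or`` are case-insensitive; ``and`` binds tighter than ``or``;
    parentheses override precedence.  Raises :class:`GprParseError` with
    the offending position on malformed input.
    """
    text = rule_text.strip()
    if not text:
        raise GprParseError("empty rule", 0)
    return GprExpression(root=_Parser(text).parse(), source_text=rule_text)


def _serialize(node: GprNode, parent: str = "") -> str:
    if isinstance(node, Gene):
        return node.id
    if isinstance(node, And):
        inner = " and ".join(_serialize(c, "and") for c in node.children)
        return inner
    inner = " or ".join(_serialize(c, "or") for c in node.children)
    # 'or' under an 'and' parent needs parentheses to survive re-parsing
    return f"({inner})" if parent == "and" else inner


def evaluate_discrete(
    expr: GprExpression,
    categories: Mapping[str, int],
    default_missing: int = 0,
) -> int:
    """Evaluate a rule over gene categories in {+1, 0, -1}.

    Genes absent from ``categories`` take ``default_missing``.
    """

    def rec(node: GprNode) -> int:
        if isinstance(node, Gene):
            return int(categories.get(node.id, default_missing))
        if isinstance(node, And):
            return min(rec(c) for c in node.children)
        return max(rec(c) for c in node.children)

    return rec(expr.root)


def evaluate_continuous(
    expr: GprExpression,
    levels: Mapping[str, float],
    or_mode: str = "max",
    default_missing: float = 0.0,
) -> float:
    """Evaluate a rule over non-negative expression levels.

    ``and`` -> min; ``or`` -> max or sum depending on ``or_mode``.
    """
    if or_mode not in ("max", "sum"):
        raise ValueError(f"or_mode must be 'max' or 'sum', got {or_mode!r}")

    def rec(node: GprNode) -> float:
        if isinstance(node, Gene):
            level = float(levels.get(node.id, default_missing))
            if level < 0:
                raise ValueError(f"negative expression level for gene {node.id!r}")
            return level
        if isinstance(node, And):
            return min(rec(c) for c in node.children)
        vals = [rec(c) for c in node.children]
        return max(vals) if or_mode == "max" else sum(vals)

    return rec(expr.root)
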