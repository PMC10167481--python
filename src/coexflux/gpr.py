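"""Boolean gene-protein-reaction (GPR) rules.

A GPR states which gene combinations enable a reaction: AND joins obligate
complex subunits, OR joins interchangeable isozymes.  The grammar accepts
``&``/``|`` as well as the words ``and``/``or`` (case-insensitive), with AND
binding tighter than OR, and both round ``()`` and square ``[]`` grouping, so
rules as printed in model annotations — e.g. ``[(sdha-1 | sdha-2) & sdhb-1]``
— parse directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator


class GPRParseError(ValueError):
    """Raised on malformed GPR text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GPRExpression:
    """A parsed GPR: a tree whose leaves are gene ids.

    ``op`` is ``"GENE"`` for a leaf (with ``gene`` set), else ``"AND"`` or
    ``"OR"`` with ``children``.
    """

    op: str
    children: tuple["GPRExpression", ...] = ()
    gene: str | None = None

    def genes(self) -> frozenset[str]:
        if self.op == "GENE":
            return frozenset([self.gene])
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def serialize(self) -> str:
        """Canonical text form; ``parse_gpr(serialize())`` round-trips."""
        if self.op == "GENE":
            return self.gene
        sep = " & " if self.op == "AND" else " | "
        parts = []
        for c in self.children:
            s = c.serialize()
            # parenthesize an OR under an AND to preserve precedence
            if self.op == "AND" and c.op == "OR":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def minimal_gene_sets(self) -> list[frozenset[str]]:
        """Minimal satisfying gene assignments (simplified DNF conjuncts).

        Each returned set is a minimal combination of genes that enables the
        reaction; supersets of another conjunct are dropped.
        """
        if self.op == "GENE":
            return [frozenset([self.gene])]
        if self.op == "OR":
            combined: list[frozenset[str]] = []
            for c in self.children:
                combined.extend(c.minimal_gene_sets())
        else:  # AND: cartesian conjunction of child DNFs
            combined = [frozenset()]
            for c in self.children:
                combined = [a | b for a in combined for b in c.minimal_gene_sets()]
        # absorption: drop conjuncts that contain another conjunct
        combined = sorted(set(combined), key=lambda s: (len(s), sorted(s)))
        kept: list[frozenset[str]] = []
        for s in combined:
            if not any(k <= s for k in kept):
                kept.append(s)
        return kept


_OPEN = {"(": ")", "[": "]"}


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "([":
            yield ("OPEN", ch, i)
            i += 1
        elif ch in ")]":
            yield ("CLOSE", ch, i)
            i += 1
        elif ch == "&":
            yield ("AND", ch, i)
            i += 1
        elif ch == "|":
            yield ("OR", ch, i)
            i += 1
        else:
            j = i
            while j < n and (text[j].isalnum() or text[j] in "_-.'"):
                j += 1
            if j == i:
                raise GPRParseError(f"unexpected character {ch!r}", i)
            word = text[i:j]
            low = word.lower()
            if low == "and":
                yield ("AND", word, i)
            elif low == "or":
                yield ("OR", word, i)
            else:
                yield ("ID", word, i)
            i = j


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of input", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> GPRExpression:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    @staticmethod
    def _combine(op: str, parts: list[GPRExpression]) -> GPRExpression:
        if len(parts) == 1:
            return parts[0]
        # flatten nested same-op nodes so equivalent texts parse identically
        flat: list[GPRExpression] = []
        for p in parts:
            flat.extend(p.children if p.op == op else (p,))
        return GPRExpression(op, tuple(flat))

    def parse_or(self) -> GPRExpression:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek()[0] == "OR":
            self.next()
            terms.append(self.parse_and())
        return self._combine("OR", terms)

    def parse_and(self) -> GPRExpression:
        factors = [self.parse_atom()]
        while self.peek() is not None and self.peek()[0] == "AND":
            self.next()
            factors.append(self.parse_atom())
        return self._combine("AND", factors)

    def parse_atom(self) -> GPRExpression:
        tok = self.next()
        kind, value, position = tok
        if kind == "ID":
            return GPRExpression("GENE", gene=value)
        if kind == "OPEN":
            inner = self.parse_or()
            closing = self.next()
            if closing[0] != "CLOSE" or closing[1] != _OPEN[value]:
                raise GPRParseError(
                    f"expected {_OPEN[value]!r} to close {value!r}", closing[2]
                )
            return inner
        raise GPRParseError(f"unexpected token {value!r}", position)


def parse_gpr(text: str) -> GPRExpression:
    """Parse GPR ``text`` into a :class:`GPRExpression`.

    Raises :class:`GPRParseError` (with position) on empty input, unbalanced
    brackets or stray tokens.
    """
    if not text or not text.strip():
        raise GPRParseError("empty GPR", 0)
    return _Parser(text).parse()


def and_or_pairs(
    expr: GPRExpression,
) -> tuple[set[frozenset[str]], set[frozenset[str]]]:
    """Extract AND pairs and OR pairs from one reaction's GPR.

    AND pairs co-occur in at least one minimal satisfying gene set (complex
    partners); OR pairs appear only in alternative conjuncts, never jointly
    (isozyme alternatives).  Returned as unordered 2-element frozensets.
    """
    conjuncts = expr.minimal_gene_sets()
    and_pairs: set[frozenset[str]] = set()
    for conj in conjuncts:
        genes = sorted(conj)
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                and_pairs.add(frozenset([a, b]))
    all_genes = sorted(expr.genes())
    or_pairs: set[frozenset[str]] = set()
    for i, a in enumerate(all_genes):
        for b in all_genes[i + 1 :]:
            pair = frozenset([a, b])
            if pair not in and_pairs:
                or_pairs.add(pair)
    return and_pairs, or_pairs
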