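"""Atom selection mini-language.

Grammar (case-sensitive values, lowercase keywords)::

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := "not" factor | "(" expr ")" | primary
    primary := FIELD value+          FIELD in {name, resname, resid, chain, element}

A primary with several values matches any of them, e.g. ``name C1 C2``.
``resid`` accepts integers and ``lo:hi`` inclusive ranges. Examples::

    resname GlcUA and resid 1178 and name C2
    not (name CA) or chain B
"""

from __future__ import annotations

import re

import numpy as np

from .errors import SelectionError
from .io import Topology

FIELDS = ("name", "resname", "resid", "chain", "element")
KEYWORDS = ("and", "or", "not")

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(query: str):
    tokens = []
    for m in _TOKEN.finditer(query):
        tokens.append((m.group(0), m.start()))
    return tokens


class _Parser:
    def __init__(self, query: str, topology: Topology):
        self.query = query
        self.tokens = _tokenize(query)
        self.pos = 0
        self.top = topology
        self.n = topology.n_atoms

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, message):
        where = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.query)
        raise SelectionError(f"{message} (at position {where} in {self.query!r})", position=where)

    def parse(self) -> np.ndarray:
        if not self.tokens:
            self.fail("empty selection")
        mask = self.expr()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self):
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self):
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self):
        tok = self.peek()
        if tok is None:
            self.fail("expected expression")
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.next()
            return mask
        return self.primary()

    def primary(self):
        tok, _ = self.next()
        if tok not in FIELDS:
            self.pos -= 1
            self.fail(f"expected a field ({', '.join(FIELDS)}), got {tok!r}")
        values = []
        while self.peek() is not None and self.peek() not in KEYWORDS + ("(", ")"):
            nxt = self.peek()
            if nxt in FIELDS and values:
                break
            values.append(self.next()[0])
        if not values:
            self.fail(f"field {tok!r} requires at least one value")
        column = self.top.column(tok)
        if tok == "resid":
            mask = np.zeros(self.n, dtype=bool)
            resid = column.astype(int)
            for v in values:
                if ":" in v:
                    lo, _, hi = v.partition(":")
                    try:
                        mask |= (resid >= int(lo)) & (resid <= int(hi))
                    except ValueError:
                        self.fail(f"bad resid range {v!r}")
                else:
                    try:
                        mask |= resid == int(v)
                    except ValueError:
                        self.fail(f"bad resid {v!r}")
            return mask
        return np.isin(column.astype(str), values)


def selection_mask(topology: Topology, query: str) -> np.ndarray:
    """Boolean mask over topology atoms for a selection expression."""
    return _Parser(query, topology).parse()


def select_atoms(topology: Topology, query: str) -> np.ndarray:
    """Ascending atom indices (0-based) matching the selection expression."""
    return np.flatnonzero(selection_mask(topology, query))
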