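"""A small atom-selection language.

Grammar (keywords are case-insensitive; ``and`` binds tighter than ``or``,
``not`` tighter than both; parentheses group)::

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := unary ("and" unary)*
    unary    := "not" unary | "(" expr ")" | term
    term     := "name" WORD+ | "element" WORD+ | "resname" WORD+
              | "chain" WORD+ | "resid" RANGE+          # RANGE: 3 or 2-7
              | "protein" | "hetatm" | "backbone" | "calpha" | "all"

Examples: ``"name CA"``, ``"resid 1-2 and name CA"``, ``"not chain A"``.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

from .core import SelectionMask, StructureModel

__all__ = ["select", "SelectionSyntaxError"]

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
_KEYWORDS = {"and", "or", "not", "name", "element", "resname", "chain",
             "resid", "protein", "hetatm", "backbone", "calpha", "all",
             "(", ")"}


class SelectionSyntaxError(ValueError):
    """Selection grammar violation; carries the character position."""

    def __init__(self, position: int, message: str):
        super().__init__(f"at position {position}: {message}")
        self.position = position


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]


class _Parser:
    def __init__(self, model: StructureModel, expression: str):
        self.model = model
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError(0, "empty selection expression")
        mask = self.or_expr()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionSyntaxError(at, f"unexpected token {tok!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek()[0] and self.peek()[0].lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek()[0] and self.peek()[0].lower() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok, at = self.peek()
        if tok is None:
            raise SelectionSyntaxError(at, "unexpected end of expression")
        low = tok.lower()
        if low == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            tok2, at2 = self.next()
            if tok2 != ")":
                raise SelectionSyntaxError(at2, "expected ')'")
            return mask
        return self.term()

    def _values(self, at: int) -> list[str]:
        vals = []
        while True:
            tok, _ = self.peek()
            if tok is None or tok.lower() in _KEYWORDS:
                break
            vals.append(self.next()[0])
        if not vals:
            raise SelectionSyntaxError(at, "keyword needs at least one value")
        return vals

    def term(self) -> np.ndarray:
        m = self.model
        tok, at = self.next()
        low = tok.lower()
        if low == "all":
            return np.ones(m.n_atoms, dtype=bool)
        if low == "protein":
            return ~m.is_hetatm
        if low == "hetatm":
            return m.is_hetatm.copy()
        if low == "backbone":
            return np.isin(m.atom_names, sorted(_BACKBONE_NAMES)) & ~m.is_hetatm
        if low == "calpha":
            return (m.atom_names == "CA") & ~m.is_hetatm
        if low == "name":
            return np.isin(m.atom_names, self._values(at))
        if low == "element":
            return np.isin(np.char.upper(m.elements),
                           [v.upper() for v in self._values(at)])
        if low == "resname":
            return np.isin(np.char.upper(m.resnames),
                           [v.upper() for v in self._values(at)])
        if low == "chain":
            return np.isin(m.chain_ids, self._values(at))
        if low == "resid":
            mask = np.zeros(m.n_atoms, dtype=bool)
            for val in self._values(at):
                rm = re.fullmatch(r"(-?\d+)(?:[-:](-?\d+))?", val)
                if rm is None:
                    raise SelectionSyntaxError(at, f"bad residue range {val!r}")
                lo = int(rm.group(1))
                hi = int(rm.group(2)) if rm.group(2) else lo
                mask |= (m.resids >= lo) & (m.resids <= hi)
            return mask
        raise SelectionSyntaxError(at, f"unknown keyword {tok!r}")


def select(model: StructureModel, expression: str) -> SelectionMask:
    """Evaluate a selection expression against a model.

    Deterministic; an empty result is allowed but reported with a warning.
    """
    mask = _Parser(model, expression).parse()
    if not mask.any():
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return SelectionMask.from_bool(mask)
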