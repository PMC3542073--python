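"""Condensed linear-code glycan formulas.

Glycan structures are written as strings in a condensed linear code: each
residue is a one- or two-letter sugar symbol (``M`` mannose, ``GN`` GlcNAc,
``A`` galactose, ``AN`` GalNAc, ``F`` fucose, ``NN`` NeuAc, ``G`` glucose)
followed by its anomeric configuration (``a``/``b``) and the carbon locant of
its attachment to the parent residue.  The reducing-end residue carries no
linkage suffix.  A residue's substituents are written to its left: the
lowest-locant branch continues the unparenthesized chain, higher-locant
branches are parenthesized immediately before the parent and ordered by
ascending locant, e.g. ``Ma3(Ma6)Mb4GNb4GN`` for the trimannosyl-chitobiose
N-glycan core.

Canonical form is exactly that ascending-locant branch ordering; parsing
followed by serialization canonicalizes any valid permutation of branch
order.  Two branches attached to one residue at the same locant are rejected.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "SYMBOLS",
    "FormulaError",
    "Residue",
    "GlycanFormula",
    "parse_formula",
    "canonicalize",
    "count_residues",
]

#: Closed residue alphabet: Glc, Gal, GlcNAc, GalNAc, Man, Fuc, NeuAc.
SYMBOLS = ("GN", "AN", "NN", "G", "A", "M", "F")

_LINKED_RE = re.compile(r"(GN|AN|NN|[GAMF])([ab])([2-6])$")
_ROOT_RE = re.compile(r"(GN|AN|NN|[GAMF])$")


class FormulaError(ValueError):
    """Raised when a linear-code string cannot be parsed."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class Residue:
    """One monosaccharide node of a glycan tree.

    ``anomeric`` and ``locant`` describe the bond to the parent residue and
    are ``None`` for the reducing-end root.
    """

    symbol: str
    anomeric: str | None
    locant: int | None
    children: tuple["Residue", ...] = ()

    def walk(self):
        for child in self.children:
            yield from child.walk()
        yield self


def _parse_node(text: str, offset: int, is_root: bool) -> Residue:
    """Parse one subtree.  ``offset`` is the absolute start of ``text`` in
    the original string, used only for error positions."""
    if not text:
        raise FormulaError("empty residue expression", offset)
    if is_root:
        m = _ROOT_RE.search(text)
        if m is None:
            if _LINKED_RE.search(text):
                raise FormulaError(
                    "reducing-end residue must not carry a linkage suffix",
                    offset + len(text),
                )
            raise FormulaError("unknown residue symbol", offset + len(text))
        symbol, anomeric, locant = m.group(1), None, None
    else:
        m = _LINKED_RE.search(text)
        if m is None:
            if _ROOT_RE.search(text):
                raise FormulaError(
                    "missing linkage on non-root residue", offset + len(text)
                )
            raise FormulaError("unknown residue symbol", offset + len(text))
        symbol, anomeric, locant = m.group(1), m.group(2), int(m.group(3))
    rest = text[: m.start()]

    branches: list[Residue] = []
    while rest.endswith(")"):
        depth = 0
        start = None
        for i in range(len(rest) - 1, -1, -1):
            ch = rest[i]
            if ch == ")":
                depth += 1
            elif ch == "(":
                depth -= 1
                if depth == 0:
                    start = i
                    break
        if start is None:
            raise FormulaError("unbalanced parenthesis", offset + len(rest) - 1)
        inner = rest[start + 1 : -1]
        branches.insert(0, _parse_node(inner, offset + start + 1, False))
        rest = rest[:start]
    children: list[Residue] = []
    if rest:
        children.append(_parse_node(rest, offset, False))
    children.extend(branches)

    locants = [c.locant for c in children]
    if len(set(locants)) != len(locants):
        raise FormulaError(
            f"duplicate branch locant on residue {symbol!r}", offset
        )
    return Residue(symbol, anomeric, locant, tuple(children))


def _serialize(node: Residue) -> str:
    kids = sorted(node.children, key=lambda c: c.locant)
    parts = []
    if kids:
        parts.append(_serialize(kids[0]))
        for k in kids[1:]:
            parts.append("(" + _serialize(k) + ")")
    suffix = "" if node.anomeric is None else f"{node.anomeric}{node.locant}"
    parts.append(node.symbol + suffix)
    return "".join(parts)


class GlycanFormula:
    """A parsed, canonicalized glycan structure."""

    __slots__ = ("text", "root", "_composition")

    def __init__(self, root: Residue):
        self.root = root
        self.text = _serialize(root)
        self._composition: Counter | None = None

    @property
    def residue_count(self) -> int:
        return sum(self.composition.values())

    @property
    def composition(self) -> Counter:
        if self._composition is None:
            self._composition = Counter(r.symbol for r in self.root.walk())
        return self._composition

    def count(self, symbol: str) -> int:
        if symbol not in SYMBOLS:
            raise FormulaError(f"unknown residue symbol {symbol!r}")
        return self.composition.get(symbol, 0)

    def __str__(self) -> str:
        return self.text

    def __repr__(self) -> str:
        return f"GlycanFormula({self.text!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, GlycanFormula) and self.text == other.text

    def __hash__(self) -> int:
        return hash(self.text)


@lru_cache(maxsize=200_000)
def parse_formula(text: str) -> GlycanFormula:
    """Parse a linear-code string into a canonical :class:`GlycanFormula`.

    Round-trips: ``parse_formula(s).text`` equals ``s`` with branches at each
    branch point reordered by ascending locant.
    """
    if not text:
        raise FormulaError("empty formula")
    if text.count("(") != text.count(")"):
        raise FormulaError("unbalanced parenthesis", len(text))
    return GlycanFormula(_parse_node(text, 0, True))


def canonicalize(text: str) -> str:
    """Canonical serialization of a linear-code string (idempotent)."""
    return parse_formula(text).text


def count_residues(formula: GlycanFormula | str, symbol: str) -> int:
    """Number of residues with the given symbol, ignoring linkage."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return formula.count(symbol)
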