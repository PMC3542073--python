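"""Pattern language and reaction rules for glycan string rewriting.

Enzyme specificities are expressed as substring-rewrite rules on the
canonical linear code.  Before searching, the whole formula is wrapped in
parentheses so a leading ``(`` in a pattern anchors a non-reducing terminus.
The pattern metacharacters are:

``…``  (ligand) any possibly-empty substring with all parentheses matched;
``_``  (continuation) any possibly-empty substring where every ``(`` is
       matched by a following ``)`` (surplus ``)`` closing outer scopes are
       allowed);
``|``  (possible branch point) the empty string or one parenthesized group;
``*``  the reaction site: the position of the first difference between the
       substrate and product pattern strings, used to anchor constraint
       subpatterns at the residue being modified;
``Gnbis`` shorthand for the bisecting-GlcNAc motif ``Ma3(GNb4)(…Ma6)Mb4``;
``#X cmp n`` residue-count comparison, cmp in ``= < >``.

Constraints combine subpatterns with ``∼`` (not), ``&`` (and) and ``or``.
Parameter adjustment rules attach multiplicative factors to the base
kinetic parameters of a rule whenever their condition matches the substrate
at the reaction site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .formula import GlycanFormula, parse_formula, count_residues

__all__ = [
    "Pattern",
    "MatchSite",
    "ReactionRule",
    "AdjustmentRule",
    "PatternError",
    "find_sites",
    "eval_constraint",
    "apply_rule",
    "apply_rule_detailed",
    "adjusted_params",
    "load_rule_table",
    "load_adjustments",
    "DONOR_BY_ENZYME",
    "GNBIS",
]

GNBIS = "Ma3(GNb4)(…Ma6)Mb4"

#: Nucleotide-sugar donor for each enzyme (mannosidases release mannose and
#: consume no donor).
DONOR_BY_ENZYME = {
    "ManI": None,
    "ManII": None,
    "a6FucT": "GDP-Fuc",
    "FucTLe": "GDP-Fuc",
    "a3FucT": "GDP-Fuc",
    "FucTH": "GDP-Fuc",
    "GnTI": "UDP-GlcNAc",
    "GnTII": "UDP-GlcNAc",
    "GnTIII": "UDP-GlcNAc",
    "GnTIV": "UDP-GlcNAc",
    "GnTV": "UDP-GlcNAc",
    "iGnT": "UDP-GlcNAc",
    "IGnT": "UDP-GlcNAc",
    "b4GalT": "UDP-Gal",
    "b3GalT": "UDP-Gal",
    "GalT-B": "UDP-Gal",
    "a3SiaT": "CMP-NeuAc",
    "a6SiaT": "CMP-NeuAc",
    "GalNAcT-A": "UDP-GalNAc",
}

SPENT_DONOR = {"GDP-Fuc": "GDP", "UDP-GlcNAc": "UDP", "UDP-Gal": "UDP",
               "UDP-GalNAc": "UDP", "CMP-NeuAc": "CMP"}


class PatternError(ValueError):
    pass


# token kinds
_LIT, _LIG, _CONT, _BRANCH = "lit", "lig", "cont", "branch"


class Pattern:
    """A compiled pattern: a sequence of literal and metacharacter tokens."""

    __slots__ = ("raw", "tokens", "spans", "first_lit")

    def __init__(self, raw: str):
        self.raw = raw
        text = raw.replace("...", "…").replace("Gnbis", GNBIS)
        tokens: list[tuple] = []
        spans: list[tuple[int, int]] = []  # spans in the normalized text
        i = 0
        lit_start = None

        def flush(end):
            nonlocal lit_start
            if lit_start is not None:
                tokens.append((_LIT, text[lit_start:end]))
                spans.append((lit_start, end))
                lit_start = None

        while i < len(text):
            ch = text[i]
            if ch == "…":
                flush(i)
                tokens.append((_LIG,))
                spans.append((i, i + 1))
            elif ch == "_":
                flush(i)
                tokens.append((_CONT,))
                spans.append((i, i + 1))
            elif ch == "|":
                flush(i)
                tokens.append((_BRANCH,))
                spans.append((i, i + 1))
            elif ch == "*":
                raise PatternError("'*' must be handled by constraint splitting")
            else:
                if lit_start is None:
                    lit_start = i
            i += 1
        flush(len(text))
        self.tokens = tokens
        self.spans = spans
        self.first_lit = tokens[0][1] if tokens and tokens[0][0] == _LIT else None

    @property
    def norm(self) -> str:
        return self.raw.replace("...", "…").replace("Gnbis", GNBIS)

    def __repr__(self):
        return f"Pattern({self.raw!r})"


def _lig_ends(s: str, pos: int):
    """End positions of balanced (all-parens-matched) substrings from pos."""
    depth = 0
    yield pos
    for j in range(pos, len(s)):
        ch = s[j]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return
        if depth == 0:
            yield j + 1


def _cont_ends(s: str, pos: int):
    """End positions of continuation substrings (every '(' matched by a
    following ')', surplus ')' allowed) from pos."""
    open_ = 0
    yield pos
    for j in range(pos, len(s)):
        ch = s[j]
        if ch == "(":
            open_ += 1
        elif ch == ")" and open_ > 0:
            open_ -= 1
        if open_ == 0:
            yield j + 1


def _branch_ends(s: str, pos: int):
    yield pos
    if pos < len(s) and s[pos] == "(":
        depth = 0
        for j in range(pos, len(s)):
            if s[j] == "(":
                depth += 1
            elif s[j] == ")":
                depth -= 1
                if depth == 0:
                    yield j + 1
                    return
                if depth < 0:
                    return


def _enumerate_matches(pattern: Pattern, s: str, start: int):
    """Yield (end, binds, token_positions) for every match of ``pattern``
    beginning exactly at ``start``.  ``binds`` is a tuple of (kind, text)
    captures for the metacharacter tokens in order; ``token_positions`` maps
    token index -> string position of the token start (plus final end)."""
    tokens = pattern.tokens
    n = len(tokens)
    binds: list[tuple[str, str]] = []
    positions: list[int] = []

    def rec(ti: int, pos: int):
        if ti == n:
            yield (pos, tuple(binds), tuple(positions) + (pos,))
            return
        kind = tokens[ti][0]
        positions.append(pos)
        if kind == _LIT:
            lit = tokens[ti][1]
            if s.startswith(lit, pos):
                yield from rec(ti + 1, pos + len(lit))
        else:
            if kind == _LIG:
                ends = _lig_ends(s, pos)
            elif kind == _CONT:
                ends = _cont_ends(s, pos)
            else:
                ends = _branch_ends(s, pos)
            for end in ends:
                binds.append((kind, s[pos:end]))
                yield from rec(ti + 1, end)
                binds.pop()
        positions.pop()

    yield from rec(0, start)


@dataclass(frozen=True)
class MatchSite:
    """One occurrence of a substrate pattern in a wrapped formula string."""

    start: int
    end: int
    site: int  # reaction-site position (first substrate/product difference)
    binds: tuple[tuple[str, str], ...] = ()
    token_positions: tuple[int, ...] = ()


def _candidate_starts(pattern: Pattern, s: str):
    lit = pattern.first_lit
    if lit:
        i = s.find(lit)
        while i != -1:
            yield i
            i = s.find(lit, i + 1)
    else:
        yield from range(len(s) + 1)


def _all_matches(pattern: Pattern, s: str):
    for start in _candidate_starts(pattern, s):
        yield from ((start,) + m for m in _enumerate_matches(pattern, s, start))


def _site_index(sub: Pattern, diff: int, start: int, end: int,
                token_positions: tuple[int, ...]) -> int:
    """Map a raw-pattern index (first substrate/product difference) to a
    position in the matched string."""
    if diff >= (sub.spans[-1][1] if sub.spans else 0):
        return end
    for ti, (a, b) in enumerate(sub.spans):
        if a <= diff < b:
            pos = token_positions[ti]
            if sub.tokens[ti][0] == _LIT:
                return pos + (diff - a)
            return pos
    return end


def wrap(formula: GlycanFormula | str) -> str:
    text = formula.text if isinstance(formula, GlycanFormula) else formula
    return "(" + text + ")"


def find_sites(formula: GlycanFormula | str, pattern: Pattern | str,
               site_diff: int | None = None) -> list[MatchSite]:
    """All distinct sites where ``pattern`` matches the wrapped formula.

    ``site_diff`` is the raw-pattern index of the reaction site (first
    substrate/product difference); when omitted the site is the match start.
    """
    if isinstance(pattern, str):
        pattern = Pattern(pattern)
    w = wrap(formula)
    seen = set()
    out = []
    for start, end, binds, tps in _all_matches(pattern, w):
        key = (start, end, binds)
        if key in seen:
            continue
        seen.add(key)
        site = start if site_diff is None else _site_index(
            pattern, site_diff, start, end, tps)
        out.append(MatchSite(start, end, site, binds, tps))
    return out


# ---------------------------------------------------------------------------
# Constraint expressions

_COUNT_RE = re.compile(r"^#\s*(GN|AN|NN|[GAMF])\s*([=<>])\s*(\d+)$")


def _parse_primary(text: str):
    text = text.strip()
    m = _COUNT_RE.match(text)
    if m:
        return ("count", m.group(1), m.group(2), int(m.group(3)))
    if "*" in text:
        left, _, right = text.partition("*")
        return ("sitepat",
                Pattern(left) if left else None,
                Pattern(right) if right else None)
    return ("pat", Pattern(text))


@lru_cache(maxsize=4096)
def parse_constraint(text: str):
    """Parse a boolean constraint expression ('' means always true)."""
    text = text.replace("~", "∼").strip()
    if not text:
        return ("true",)
    ors = []
    for term in text.split(" or "):
        ands = []
        for factor in term.split("&"):
            factor = factor.strip()
            neg = factor.startswith("∼")
            if neg:
                factor = factor[1:].strip()
            prim = _parse_primary(factor)
            ands.append(("not", prim) if neg else prim)
        ors.append(("and", ands))
    return ("or", ors)


def _match_ending_at(pattern: Pattern, s: str, end: int) -> bool:
    """True if some match of ``pattern`` ends exactly at position ``end``."""
    for start in range(end, -1, -1):
        for e, _, _ in _enumerate_matches(pattern, s, start):
            if e == end:
                return True
    return False


def _eval_node(node, w: str, formula: GlycanFormula, site: int | None) -> bool:
    kind = node[0]
    if kind == "true":
        return True
    if kind == "or":
        return any(_eval_node(t, w, formula, site) for t in node[1])
    if kind == "and":
        return all(_eval_node(t, w, formula, site) for t in node[1])
    if kind == "not":
        return not _eval_node(node[1], w, formula, site)
    if kind == "count":
        _, sym, cmp_, val = node
        c = count_residues(formula, sym)
        return c == val if cmp_ == "=" else c > val if cmp_ == ">" else c < val
    if kind == "pat":
        pattern = node[1]
        return next(iter(_all_matches(pattern, w)), None) is not None
    if kind == "sitepat":
        _, left, right = node
        if site is None:
            raise PatternError("'*'-anchored constraint evaluated without a site")
        ok = True
        if right is not None:
            ok = next(iter(_enumerate_matches(right, w, site)), None) is not None
        if ok and left is not None:
            ok = _match_ending_at(left, w, site)
        return ok
    raise PatternError(f"unknown constraint node {node!r}")


def eval_constraint(formula: GlycanFormula | str, site: MatchSite | int | None,
                    constraint) -> bool:
    """Evaluate a constraint against a formula, with ``site`` anchoring any
    '*'-subpatterns at the reaction site."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if isinstance(constraint, str):
        constraint = parse_constraint(constraint)
    pos = site.site if isinstance(site, MatchSite) else site
    return _eval_node(constraint, wrap(formula), formula, pos)


# ---------------------------------------------------------------------------
# Reaction rules

@dataclass(frozen=True)
class ReactionRule:
    index: int
    enzyme: str
    substrate: Pattern
    product: Pattern
    constraint: tuple
    donor: str | None
    kf: float
    Km: float
    Kmd: float
    site_diff: int = field(default=0)

    @property
    def coproduct(self) -> str | None:
        return SPENT_DONOR.get(self.donor) if self.donor else None


@dataclass(frozen=True)
class AdjustmentRule:
    adjust_id: int
    rule_index: int
    condition: tuple
    kf_mult: float
    Km_mult: float
    Kmd_mult: float


def _first_diff(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _read_table(name: str) -> list[dict]:
    text = resources.files("glycosim.data").joinpath(name).read_text("utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


@lru_cache(maxsize=None)
def load_rule_table() -> tuple[ReactionRule, ...]:
    """The packaged enzyme reaction-rule table with base kinetic parameters."""
    params = {int(r["index"]): (float(r["kf"]), float(r["Km"]), float(r["Kmd"]))
              for r in _read_table("base_params.tsv")}
    rules = []
    for row in _read_table("reaction_rules.tsv"):
        idx = int(row["index"])
        sub = Pattern(row["substrate"])
        prod = Pattern(row["product"])
        kf, Km, Kmd = params[idx]
        rules.append(ReactionRule(
            index=idx,
            enzyme=row["enzyme"],
            substrate=sub,
            product=prod,
            constraint=parse_constraint(row.get("constraint", "") or ""),
            donor=DONOR_BY_ENZYME[row["enzyme"]],
            kf=kf, Km=Km, Kmd=Kmd,
            site_diff=_first_diff(sub.norm, prod.norm),
        ))
    return tuple(rules)


@lru_cache(maxsize=None)
def load_adjustments() -> tuple[AdjustmentRule, ...]:
    """The packaged structure-dependent parameter adjustment table."""
    out = []
    for row in _read_table("adjustments.tsv"):
        out.append(AdjustmentRule(
            adjust_id=int(row["adjust"]),
            rule_index=int(row["index"]),
            condition=parse_constraint(row["condition"]),
            kf_mult=float(row["kf"]),
            Km_mult=float(row["Km"]),
            Kmd_mult=float(row["Kmd"]),
        ))
    return tuple(out)


def _substitute(product: Pattern, binds) -> str:
    """Render the product pattern, re-inserting substrate captures for the
    metacharacters in order of appearance."""
    queues: dict[str, list[str]] = {}
    for kind, text in binds:
        queues.setdefault(kind, []).append(text)
    parts = []
    for tok in product.tokens:
        if tok[0] == _LIT:
            parts.append(tok[1])
        else:
            q = queues.get(tok[0])
            if not q:
                raise PatternError(
                    "product pattern has an unmatched metacharacter")
            parts.append(q.pop(0))
    return "".join(parts)


def apply_rule_detailed(formula: GlycanFormula | str, rule: ReactionRule):
    """Apply one rule at every satisfying site.

    Returns a list of ``(product GlycanFormula, MatchSite)`` pairs; products
    are re-canonicalized.  Identical (product, site) duplicates are removed
    but distinct sites yielding the same product are all reported.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    w = wrap(formula)
    results = []
    seen = set()
    for start in _candidate_starts(rule.substrate, w):
        for end, binds, tps in _enumerate_matches(rule.substrate, w, start):
            site = _site_index(rule.substrate, rule.site_diff, start, end, tps)
            key = (start, end, binds)
            if key in seen:
                continue
            seen.add(key)
            if not _eval_node(rule.constraint, w, formula, site):
                continue
            new_w = w[:start] + _substitute(rule.product, binds) + w[end:]
            if not (new_w.startswith("(") and new_w.endswith(")")):
                raise PatternError(
                    f"rule {rule.index} produced an unwrapped string: {new_w!r}")
            try:
                prod = parse_formula(new_w[1:-1])
            except Exception as exc:  # rule-table corruption
                raise PatternError(
                    f"rule {rule.index} produced an unparseable product "
                    f"{new_w[1:-1]!r}: {exc}") from exc
            ms = MatchSite(start, end, site, binds, tps)
            results.append((prod, ms))
    return results


def apply_rule(formula: GlycanFormula | str, rule: ReactionRule) -> set[GlycanFormula]:
    """Set of canonical products of one rule applied to one structure."""
    return {prod for prod, _ in apply_rule_detailed(formula, rule)}


def adjusted_params(rule: ReactionRule | int,
                    substrate: GlycanFormula | str,
                    site: MatchSite | int | None = None,
                    adjustments: tuple[AdjustmentRule, ...] | None = None,
                    ) -> tuple[float, float, float]:
    """Base (kf, Km, Kmd) of a rule multiplied by every adjustment whose
    condition matches the substrate (at the reaction site for '*'-anchored
    conditions).  A zero Kmd marks the donor term as saturated."""
    if isinstance(rule, int):
        table = {r.index: r for r in load_rule_table()}
        if rule not in table:
            raise KeyError(f"unknown rule index {rule}")
        rule = table[rule]
    if adjustments is None:
        adjustments = load_adjustments()
    if isinstance(substrate, str):
        substrate = parse_formula(substrate)
    kf, Km, Kmd = rule.kf, rule.Km, rule.Kmd
    pos = site.site if isinstance(site, MatchSite) else site
    w = wrap(substrate)
    for adj in adjustments:
        if adj.rule_index != rule.index:
            continue
        if _eval_node(adj.condition, w, substrate, pos):
            kf *= adj.kf_mult
            Km *= adj.Km_mult
            Kmd *= adj.Kmd_mult
    return kf, Km, Kmd
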