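"""Glycan classification and abundance-weighted profile summaries.

Structures are classified into the three N-glycan families: high-mannose
(no antennary GlcNAc, five or more mannoses), complex (GlcNAc-initiated
antennae on both core arms) and hybrid (antennae on the a3 arm only, with
untrimmed mannose on the a6 arm).  Antenna units are counted as terminal
epitopes with most-derivatized-wins exclusivity so each Gal-GlcNAc unit is
tallied exactly once: a type II (Gal-b4-GlcNAc) unit may mature into H(II)
(+Fuc-a2 on Gal), Lewis x (+Fuc-a3 on GlcNAc), Lewis y (both), or the A/B
blood-group epitopes (GalNAc/Gal-a3 on an H unit); type I (Gal-b3-GlcNAc)
correspondingly into H(I), Lewis a, Lewis b, A and B.  Sialylated units
are counted as sialylated rather than free LacNAc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formula import GlycanFormula, Residue, parse_formula

__all__ = ["GlycanClass", "MoietyCounts", "classify_structure",
           "count_moieties", "profile_summary", "annotate_peaks"]


@dataclass(frozen=True)
class GlycanClass:
    family: str                  # 'high-mannose' | 'hybrid' | 'complex'
    antennae: int                # GlcNAc-initiated branches on the core arms
    core_fucosylated: bool
    bisected: bool
    lacnac_repeats: int          # extra type II units beyond one per antenna
    sialyl_a3: int
    sialyl_a6: int


@dataclass
class MoietyCounts:
    type2: int = 0               # plain Gal-b4-GlcNAc
    type1: int = 0               # plain Gal-b3-GlcNAc
    h2: int = 0                  # Fuc-a2-Gal-b4-GlcNAc
    h1: int = 0
    lewis_x: int = 0
    lewis_y: int = 0
    lewis_a: int = 0
    lewis_b: int = 0
    epitope_a: int = 0
    epitope_b: int = 0
    sialyl: int = 0

    def total_type2_units(self) -> int:
        # every category except type1-family counts a type II unit
        return (self.type2 + self.h2 + self.lewis_x + self.lewis_y
                + self._a2 + self._b2 + self._s2)

    # bookkeeping split of A/B/sialyl between chain types
    _a2: int = 0
    _b2: int = 0
    _s2: int = 0


def _child(node: Residue, symbol: str, anomeric: str, locant: int):
    for c in node.children:
        if c.symbol == symbol and c.anomeric == anomeric and c.locant == locant:
            return c
    return None


def _core(formula: GlycanFormula):
    """Locate the chitobiose + beta-mannose core; returns (root GN, inner
    GN, Mb4, Ma3 arm, Ma6 arm) with arms possibly None."""
    root = formula.root
    if root.symbol != "GN":
        raise ValueError("structure lacks the reducing-end GlcNAc")
    gn2 = _child(root, "GN", "b", 4)
    if gn2 is None:
        raise ValueError("structure lacks the chitobiose core")
    mb4 = _child(gn2, "M", "b", 4)
    if mb4 is None:
        raise ValueError("structure lacks the core beta-mannose")
    return root, gn2, mb4, _child(mb4, "M", "a", 3), _child(mb4, "M", "a", 6)


def classify_structure(formula: GlycanFormula | str) -> GlycanClass:
    if isinstance(formula, str):
        formula = parse_formula(formula)
    root, gn2, mb4, ma3, ma6 = _core(formula)
    bisected = _child(mb4, "GN", "b", 4) is not None
    core_fuc = _child(root, "F", "a", 6) is not None

    def antenna_gns(arm):
        if arm is None:
            return []
        return [c for c in arm.children if c.symbol == "GN"
                and c.locant in (2, 4, 6)]

    a3_ant = antenna_gns(ma3)
    a6_ant = antenna_gns(ma6)
    antennae = len(a3_ant) + len(a6_ant)
    n_man = formula.count("M")

    if antennae == 0 and n_man >= 5:
        family = "high-mannose"
    elif a3_ant and (a6_ant or ma6 is None):
        family = "complex"
    else:
        family = "hybrid"

    sialyl_a3 = sialyl_a6 = 0
    type2_units = 0
    for node in formula.root.walk():
        if node.symbol == "A" and node.anomeric == "b" and node.locant == 4:
            type2_units += 1
            for c in node.children:
                if c.symbol == "NN" and c.locant == 3:
                    sialyl_a3 += 1
                if c.symbol == "NN" and c.locant == 6:
                    sialyl_a6 += 1
    lacnac_repeats = max(0, type2_units - antennae) if antennae else 0

    return GlycanClass(family, antennae if family == "complex" else antennae,
                       core_fuc, bisected, lacnac_repeats,
                       sialyl_a3, sialyl_a6)


def count_moieties(formula: GlycanFormula | str) -> MoietyCounts:
    """Hierarchically exclusive epitope counts over all Gal-GlcNAc units."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mc = MoietyCounts()
    for gn in formula.root.walk():
        if gn.symbol != "GN":
            continue
        for locant, is_type2 in ((4, True), (3, False)):
            gal = _child(gn, "A", "b", locant)
            if gal is None:
                continue
            fuc_on_gal = _child(gal, "F", "a", 2) is not None
            fuc_on_gn = (_child(gn, "F", "a", 3) is not None if is_type2
                         else _child(gn, "F", "a", 4) is not None)
            a_cap = _child(gal, "AN", "a", 3) is not None
            b_cap = _child(gal, "A", "a", 3) is not None
            sialyl = any(c.symbol == "NN" for c in gal.children)
            if sialyl:
                mc.sialyl += 1
                if is_type2:
                    mc._s2 += 1
            elif fuc_on_gal and a_cap:
                mc.epitope_a += 1
                if is_type2:
                    mc._a2 += 1
            elif fuc_on_gal and b_cap:
                mc.epitope_b += 1
                if is_type2:
                    mc._b2 += 1
            elif fuc_on_gal and fuc_on_gn:
                if is_type2:
                    mc.lewis_y += 1
                else:
                    mc.lewis_b += 1
            elif fuc_on_gal:
                if is_type2:
                    mc.h2 += 1
                else:
                    mc.h1 += 1
            elif fuc_on_gn:
                if is_type2:
                    mc.lewis_x += 1
                else:
                    mc.lewis_a += 1
            else:
                if is_type2:
                    mc.type2 += 1
                else:
                    mc.type1 += 1
    return mc


_FAMILIES = ("high-mannose", "hybrid", "complex")
_MOIETY_FIELDS = ("type2", "type1", "h2", "h1", "lewis_x", "lewis_y",
                  "lewis_a", "lewis_b", "epitope_a", "epitope_b", "sialyl")


def profile_summary(abundances: dict[str, float]) -> dict[str, float]:
    """Abundance-weighted profile percentages.

    Family percentages partition 100%; antennary percentages are reported
    both over all glycans and over complex glycans; moiety percentages are
    the weighted mean count x 100 and may exceed 100 when glycans carry
    multiple copies; core fucosylation is reported on the hybrid+complex
    subset.
    """
    total = sum(abundances.values())
    if total <= 0:
        raise ValueError("empty profile")
    out = {f"family_{f}_pct": 0.0 for f in _FAMILIES}
    for k in (2, 3, 4):
        out[f"antennae_{k}_pct_total"] = 0.0
        out[f"antennae_{k}_pct_complex"] = 0.0
    for f in _MOIETY_FIELDS:
        out[f"moiety_{f}_pct"] = 0.0
    out["core_fucosylated_pct_hybrid_complex"] = 0.0
    out["bisected_pct"] = 0.0
    complex_total = 0.0
    hybrid_complex_total = 0.0
    corefuc = 0.0
    for text, ab in abundances.items():
        w = ab / total
        cls = classify_structure(text)
        out[f"family_{cls.family}_pct"] += 100.0 * w
        if cls.family == "complex":
            complex_total += w
            k = min(max(cls.antennae, 2), 4)
            out[f"antennae_{k}_pct_total"] += 100.0 * w
        if cls.family in ("hybrid", "complex"):
            hybrid_complex_total += w
            if cls.core_fucosylated:
                corefuc += w
        if cls.bisected:
            out["bisected_pct"] += 100.0 * w
        mc = count_moieties(text)
        for f in _MOIETY_FIELDS:
            out[f"moiety_{f}_pct"] += 100.0 * w * getattr(mc, f)
    if complex_total > 0:
        for k in (2, 3, 4):
            out[f"antennae_{k}_pct_complex"] = (
                out[f"antennae_{k}_pct_total"] / complex_total)
    if hybrid_complex_total > 0:
        out["core_fucosylated_pct_hybrid_complex"] = (
            100.0 * corefuc / hybrid_complex_total)
    return out


def annotate_peaks(spectrum, abundances: dict[str, float] | None = None):
    """Per-peak contributor lists of a synthetic spectrum.

    Returns a list of (m/z, %area, ((formula, share), ...)) sorted by m/z;
    the spectrum's contributor shares are computed during synthesis (isomer
    groups share each envelope).
    """
    rows = []
    for mz, pct, contrib in zip(spectrum.mz, spectrum.area_pct,
                                spectrum.contributors):
        rows.append((float(mz), float(pct), contrib))
    return rows
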