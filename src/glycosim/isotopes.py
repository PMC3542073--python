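"""Permethylated-glycan elemental compositions, masses and isotope envelopes.

MALDI sample preparation is modeled as full permethylation of the released,
free-reducing-end glycan (every hydroxyl OH -> OCH3, every acetamido NH ->
NCH3, the NeuAc carboxyl methyl-esterified) followed by single sodiation.
Masses are monoisotopic; isotope envelopes follow the multinomial
distribution implied by the natural isotope abundances of C, H, N, O
pinned in a packaged table so results do not drift with library versions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .formula import GlycanFormula, parse_formula

__all__ = [
    "ElementalComposition",
    "IsotopePattern",
    "SyntheticSpectrum",
    "permethylated_composition",
    "permethylated_mass",
    "monoisotopic_mass",
    "isotope_pattern",
    "synthesize_spectrum",
]

_ELECTRON = 0.00054858

#: residue class for each linear-code symbol
RESIDUE_CLASS = {"G": "Hex", "A": "Hex", "M": "Hex",
                 "GN": "HexNAc", "AN": "HexNAc",
                 "F": "dHex", "NN": "NeuAc"}

#: free-monosaccharide elemental composition and number of methylatable
#: positions (hydroxyls + amide NH + carboxyl) per residue class
_RESIDUE_ATOMS = {
    "Hex":    ({"C": 6, "H": 12, "O": 6}, 5),
    "HexNAc": ({"C": 8, "H": 15, "N": 1, "O": 6}, 5),
    "dHex":   ({"C": 6, "H": 12, "O": 5}, 4),
    "NeuAc":  ({"C": 11, "H": 19, "N": 1, "O": 9}, 7),
}


@lru_cache(maxsize=None)
def _isotope_table() -> dict[str, tuple[tuple[float, float], ...]]:
    text = resources.files("glycosim.data").joinpath("isotopes.tsv").read_text()
    table: dict[str, list[tuple[float, float]]] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        el, mass, ab = line.split("\t")
        table.setdefault(el, []).append((float(mass), float(ab)))
    return {el: tuple(sorted(v)) for el, v in table.items()}


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a permethylated, sodiated glycan species."""

    counts: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def monoisotopic_mass(self) -> float:
        table = _isotope_table()
        m = sum(table[el][0][0] * n for el, n in self.counts)
        return m - _ELECTRON  # singly charged [M+Na]+

    def __getitem__(self, el: str) -> int:
        return self.as_dict().get(el, 0)


def _class_counts(formula: GlycanFormula | str | Counter) -> Counter:
    if isinstance(formula, Counter):
        return formula
    if isinstance(formula, str):
        formula = parse_formula(formula)
    out: Counter = Counter()
    for sym, n in formula.composition.items():
        out[RESIDUE_CLASS[sym]] += n
    return out


def permethylated_composition(formula: GlycanFormula | str | Counter,
                              ) -> ElementalComposition:
    """Elemental composition of the fully permethylated, sodiated glycan.

    Accepts a structure or a residue-class Counter (e.g. ``{'Hex': 5,
    'HexNAc': 4, 'dHex': 2}``); isomers share one composition.  The molecule
    is the sum of free-monosaccharide formulas minus one water per
    glycosidic bond; each bond also removes two methylation sites (the
    anomeric hydroxyl of the child and the acceptor hydroxyl of the parent).
    """
    classes = _class_counts(formula)
    n = sum(classes.values())
    if n == 0:
        raise ValueError("empty composition")
    bonds = n - 1
    atoms: Counter = Counter()
    sites = 0
    for cls, count in classes.items():
        res_atoms, res_sites = _RESIDUE_ATOMS[cls]
        for el, k in res_atoms.items():
            atoms[el] += k * count
        sites += res_sites * count
    atoms["H"] -= 2 * bonds
    atoms["O"] -= bonds
    sites -= 2 * bonds
    # each methylation replaces one H with CH3: net +CH2
    atoms["C"] += sites
    atoms["H"] += 2 * sites
    atoms["Na"] += 1
    return ElementalComposition(tuple(sorted(atoms.items())))


def permethylated_mass(formula: GlycanFormula | str | Counter) -> float:
    """Monoisotopic m/z of the permethylated, singly sodiated glycan."""
    return permethylated_composition(formula).monoisotopic_mass


monoisotopic_mass = permethylated_mass


@dataclass(frozen=True)
class IsotopePattern:
    """Isotope envelope: (mass, relative abundance) pairs, mass ascending,
    first peak monoisotopic, abundances summing to <= 1."""

    peaks: tuple[tuple[float, float], ...]
    threshold: float = 1e-6

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks])


def _convolve(a: list[tuple[float, float]], b: list[tuple[float, float]],
              ) -> list[tuple[float, float]]:
    """Convolve two (abundance, mean-mass-shift) distributions indexed by
    nucleon-number shift."""
    out_ab = [0.0] * (len(a) + len(b) - 1)
    out_ms = [0.0] * (len(a) + len(b) - 1)
    for i, (ai, mi) in enumerate(a):
        if ai == 0.0:
            continue
        for j, (bj, mj) in enumerate(b):
            if bj == 0.0:
                continue
            p = ai * bj
            out_ab[i + j] += p
            out_ms[i + j] += p * (mi + mj)
    return [(ab, ms / ab if ab > 0 else 0.0)
            for ab, ms in zip(out_ab, out_ms)]


def _element_dist(el: str) -> list[tuple[float, float]]:
    isos = _isotope_table()[el]
    base = isos[0][0]
    dist: list[tuple[float, float]] = []
    for mass, ab in isos:
        shift = round(mass - base)
        while len(dist) <= shift:
            dist.append((0.0, 0.0))
        dist[shift] = (ab, mass - base)
    return dist


def isotope_pattern(comp: ElementalComposition | Counter | str,
                    threshold: float = 1e-6) -> IsotopePattern:
    """Isotope envelope of a species, truncated at ``threshold`` of the
    total abundance of the species.

    The satellite-peak abundances are the multinomial distribution over
    isotopologues, computed by per-element convolution and aggregated by
    nucleon-number shift (unresolved fine structure is mass-averaged).
    """
    if not isinstance(comp, ElementalComposition):
        comp = permethylated_composition(comp)
    mono = comp.monoisotopic_mass
    dist = [(1.0, 0.0)]
    for el, n in comp.counts:
        if n == 0:
            continue
        base = _element_dist(el)
        if len(base) == 1:
            continue
        # n-fold convolution by binary powering
        power = base
        k = n
        while k:
            if k & 1:
                dist = _convolve(dist, power)
            k >>= 1
            if k:
                power = _convolve(power, power)
            # drop negligible tail to bound the polynomial degree
            while len(dist) > 1 and dist[-1][0] < threshold * 1e-3:
                dist.pop()
            while len(power) > 1 and power[-1][0] < threshold * 1e-3:
                power.pop()
    peaks = [(mono + ms, ab) for ab, ms in dist if ab >= threshold]
    return IsotopePattern(tuple(peaks), threshold)


def envelope_table(structures, threshold: float = 1e-6,
                   ) -> dict[float, IsotopePattern]:
    """Isotope envelope per unique composition among ``structures``, keyed
    by monoisotopic mass (rounded to 1e-6 Da)."""
    out: dict[float, IsotopePattern] = {}
    for s in structures:
        comp = permethylated_composition(
            s.text if isinstance(s, GlycanFormula) else str(s))
        key = round(comp.monoisotopic_mass, 6)
        if key not in out:
            out[key] = isotope_pattern(comp, threshold)
    return out


@dataclass(frozen=True)
class SyntheticSpectrum:
    """Stick spectrum: (m/z, intensity as % of total area in range)."""

    mz: np.ndarray
    area_pct: np.ndarray
    # per-peak contributor lists: tuple of ((formula text, fraction), ...)
    contributors: tuple = ()
    mass_range: tuple[float, float] = (1400.0, 4000.0)


def synthesize_spectrum(abundances, structures=None,
                        mass_range: tuple[float, float] = (1400.0, 4000.0),
                        threshold: float = 1e-6,
                        merge_tol: float = 1e-9) -> SyntheticSpectrum:
    """Merge per-structure isotope envelopes into one synthetic spectrum.

    ``abundances`` is either a mapping {formula text: fraction} or a
    sequence aligned with ``structures``.  Isomers coincide exactly (they
    share an elemental composition); peak areas are normalized to 100% of
    the total within ``mass_range``.
    """
    if structures is not None:
        items = list(zip(structures, abundances))
    else:
        items = list(abundances.items())
    if not items:
        raise ValueError("empty structure list")

    # group structures by elemental composition: isomers are mass-degenerate
    groups: dict[ElementalComposition, list[tuple[str, float]]] = {}
    for struct, ab in items:
        if ab < 0:
            raise ValueError("negative abundance")
        text = struct.text if isinstance(struct, GlycanFormula) else str(struct)
        comp = permethylated_composition(text)
        groups.setdefault(comp, []).append((text, ab))

    mz_list, val_list, contrib_list = [], [], []
    for comp, members in groups.items():
        total = sum(ab for _, ab in members)
        if total == 0:
            continue
        pat = isotope_pattern(comp, threshold)
        shares = tuple(sorted(((t, ab / total) for t, ab in members),
                              key=lambda x: -x[1]))
        for mass, ab in pat.peaks:
            mz_list.append(mass)
            val_list.append(total * ab)
            contrib_list.append(shares)

    order = np.argsort(mz_list)
    mz, val, contrib = [], [], []
    for idx in order:
        m, v = mz_list[idx], val_list[idx]
        if mz and abs(m - mz[-1]) <= merge_tol:
            w = val[-1] + v
            # merge contributor shares abundance-weighted
            merged: dict[str, float] = {}
            for t, fr in contrib[-1]:
                merged[t] = merged.get(t, 0.0) + fr * val[-1]
            for t, fr in contrib_list[idx]:
                merged[t] = merged.get(t, 0.0) + fr * v
            contrib[-1] = tuple(sorted(((t, f / w) for t, f in merged.items()),
                                       key=lambda x: -x[1]))
            val[-1] = w
        else:
            mz.append(m)
            val.append(v)
            contrib.append(contrib_list[idx])

    mz_arr = np.array(mz)
    val_arr = np.array(val)
    in_range = (mz_arr >= mass_range[0]) & (mz_arr <= mass_range[1])
    mz_arr, val_arr = mz_arr[in_range], val_arr[in_range]
    contrib = tuple(c for c, keep in zip(contrib, in_range) if keep)
    total = val_arr.sum()
    if total <= 0:
        raise ValueError("no peaks within the modeled mass range")
    return SyntheticSpectrum(mz_arr, 100.0 * val_arr / total, contrib,
                             mass_range)
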