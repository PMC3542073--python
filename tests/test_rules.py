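"""Pattern language, constraint evaluation, rule application and kinetic
parameter adjustment, cross-checked against a brute-force token-semantics
oracle."""

import itertools

import pytest

from glycosim.formula import parse_formula
from glycosim.isotopes import permethylated_mass
from glycosim.rules import (GNBIS, Pattern, adjusted_params, apply_rule,
                            apply_rule_detailed, eval_constraint, find_sites,
                            load_adjustments, load_rule_table, wrap)

MAN9 = "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN"
MAN5 = "Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN"
GNTI_PRODUCT = "GNb2Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN"


# --- brute-force oracle for the pattern token semantics -------------------

def _is_balanced(x: str) -> bool:
    d = 0
    for ch in x:
        if ch == "(":
            d += 1
        elif ch == ")":
            d -= 1
            if d < 0:
                return False
    return d == 0


def _is_continuation(x: str) -> bool:
    open_ = 0
    for ch in x:
        if ch == "(":
            open_ += 1
        elif ch == ")" and open_ > 0:
            open_ -= 1
    return open_ == 0


def _is_branch(x: str) -> bool:
    if x == "":
        return True
    if not (x.startswith("(") and x.endswith(")") and _is_balanced(x)):
        return False
    d = 0
    for i, ch in enumerate(x):
        d += 1 if ch == "(" else (-1 if ch == ")" else 0)
        if d == 0:
            return i == len(x) - 1
    return False


_PREDICATES = {"lig": _is_balanced, "cont": _is_continuation,
               "branch": _is_branch}


def brute_force_matches(pattern: Pattern, s: str):
    """Enumerate all (start, end, binds) by trying every split of every
    substring across the pattern tokens."""
    tokens = pattern.tokens
    results = set()
    for start in range(len(s) + 1):
        for end in range(start, len(s) + 1):
            segment = s[start:end]
            # all ways to cut the segment into len(tokens) pieces
            n = len(tokens)
            for cuts in itertools.combinations_with_replacement(
                    range(len(segment) + 1), n - 1) if n > 1 else [()]:
                bounds = [0, *cuts, len(segment)]
                ok = True
                binds = []
                for t, (a, b) in zip(tokens, itertools.pairwise(bounds)):
                    piece = segment[a:b]
                    if t[0] == "lit":
                        if piece != t[1]:
                            ok = False
                            break
                    else:
                        if not _PREDICATES[t[0]](piece):
                            ok = False
                            break
                        binds.append((t[0], piece))
                if ok:
                    results.add((start, end, tuple(binds)))
            if not tokens and segment == "":
                results.add((start, end, ()))
    return results


CORPUS = [
    "GN", "GNb4GN", "Mb4GNb4GN", MAN5, GNTI_PRODUCT,
    "GNb2Ma3(GNb2Ma6)Mb4GNb4GN",
    "Ab4GNb2Ma3(Ab4GNb2Ma6)Mb4GNb4(Fa6)GN",
    "GNb2Ma3(GNb4)(GNb2Ma6)Mb4GNb4GN",
    "Fa2Ab4GNb2Ma3(Ab4GNb2Ma6)Mb4GNb4GN",
    "NNa3Ab4GNb2Ma3(GNb2(GNb6)Ma6)Mb4GNb4GN",
    "Ab4GNb3Ab4GNb2Ma3(Ma6)Mb4GNb4GN",
]

PATTERNS = ["(GN", "(Ma2Ma", "(Ab4GN", "GNb2|Ma3", "(…Ab4GNb", "Gnbis",
            "(GNb2|Ma3(Ma6)Mb4", "GNb4GN", "_Ma3|Mb4"]


@pytest.mark.parametrize("pattern_text", PATTERNS)
def test_matcher_agrees_with_brute_force_oracle(pattern_text):
    pattern = Pattern(pattern_text)
    for struct in CORPUS:
        w = wrap(parse_formula(struct).text)
        got = {(m.start, m.end, m.binds) for m in find_sites(struct, pattern)}
        expected = brute_force_matches(pattern, w)
        assert got == expected, f"{pattern_text} on {struct}"


class TestFindSites:
    def test_terminal_anchor(self):
        sites = find_sites("GNb4GN", "(GN")
        assert len(sites) == 1 and sites[0].start == 0

    def test_man9_terminal_ma2(self):
        assert len(find_sites(MAN9, "(Ma2Ma")) == 3

    def test_gnbis_abbreviation(self):
        bisected = "GNb2Ma3(GNb4)(GNb2Ma6)Mb4GNb4GN"
        assert len(find_sites(bisected, "Gnbis")) == 1
        assert Pattern("Gnbis").norm == GNBIS


class TestConstraints:
    def test_not_gnbis_on_man5(self):
        assert eval_constraint(MAN5, None, "∼Gnbis") is True

    def test_count_comparison(self):
        hybrid_with_gal = "Ab4GNb2Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN"
        assert eval_constraint(hybrid_with_gal, None, "#A = 0") is False

    def test_rule7_conjunction_on_gnti_product(self):
        assert eval_constraint(GNTI_PRODUCT, None,
                               "GNb2|Ma3 & #A = 0 & ∼Gnbis") is True

    def test_or_operator(self):
        s = "Ab4GNb2Ma3(GNb6(Ab4GNb2)Ma6)Mb4GNb4GN"
        assert eval_constraint(s, None,
                               "Ab4GNb2|Ma6 or Ab4GNb6)Ma6") is True

    def test_site_anchored(self, rules_by_index):
        # ManI rule 1 blocks the a2-Man on the Ma3-of-Ma6 arm only
        rule = rules_by_index[1]
        results = apply_rule_detailed(MAN9, rule)
        assert len(results) == 2
        sites = find_sites(MAN9, rule.substrate, rule.site_diff)
        assert len(sites) == 3  # one site is excluded by the constraint


class TestApplyRule:
    def test_gnti_on_man5(self, rules_by_index):
        prods = apply_rule(MAN5, rules_by_index[8])
        assert {p.text for p in prods} == {GNTI_PRODUCT}

    def test_gnti_on_man9_empty(self, rules_by_index):
        assert apply_rule(MAN9, rules_by_index[8]) == set()

    def test_man9_trimming_respects_constraint(self, rules_by_index):
        prods = {p.text for p in apply_rule(MAN9, rules_by_index[1])}
        assert prods == {
            "Ma2Ma2Ma3(Ma2Ma3(Ma6)Ma6)Mb4GNb4GN",
            "Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN",
        }

    def test_core_fucosylation(self, rules_by_index):
        prods = apply_rule(GNTI_PRODUCT, rules_by_index[7])
        assert {p.text for p in prods} == {
            "GNb2Ma3(Ma3(Ma6)Ma6)Mb4GNb4(Fa6)GN"}

    @pytest.mark.parametrize("rule_index", [1, 2, 5, 6, 7, 8, 9, 10, 11, 12,
                                            13, 14, 15, 16, 17, 18, 20, 21,
                                            22, 23, 24, 25, 26])
    def test_mass_delta_matches_rule_chemistry(self, rules_by_index,
                                               rule_index, small_network):
        """Every product differs from its substrate by exactly one residue
        of the enzyme's donor (removal for the mannosidases)."""
        # in-chain permethylated residue increments: free monosaccharide
        # minus water plus one CH2 per net methylation site
        deltas = {
            "Hex": 204.09977, "HexNAc": 245.12633,
            "dHex": 174.08921, "NeuAc": 361.17367,
        }
        expected_by_rule = {
            1: -deltas["Hex"], 2: -deltas["Hex"], 5: -deltas["Hex"],
            6: -deltas["Hex"], 7: deltas["dHex"], 8: deltas["HexNAc"],
            9: deltas["HexNAc"], 10: deltas["HexNAc"], 11: deltas["HexNAc"],
            12: deltas["HexNAc"], 13: deltas["HexNAc"], 14: deltas["Hex"],
            15: deltas["NeuAc"], 16: deltas["HexNAc"], 17: deltas["NeuAc"],
            18: deltas["Hex"], 20: deltas["dHex"], 21: deltas["dHex"],
            22: deltas["dHex"], 23: deltas["dHex"], 24: deltas["dHex"],
            25: deltas["HexNAc"], 26: deltas["Hex"],
        }
        rule = rules_by_index[rule_index]
        checked = 0
        for struct in small_network.structures:
            for prod, _site in apply_rule_detailed(struct, rule):
                delta = permethylated_mass(prod) - permethylated_mass(struct)
                assert delta == pytest.approx(expected_by_rule[rule_index],
                                              abs=1e-4)
                checked += 1
            if checked >= 5:
                break


class TestAdjustedParams:
    def test_mani_man9_km(self, rules_by_index):
        kf, Km, Kmd = adjusted_params(1, MAN9, 3)
        assert kf == pytest.approx(1923.75)
        assert Km == pytest.approx(827 * 182.052)
        assert Kmd == 0.0

    def test_b4galt_no_gnb2_ma6(self, rules_by_index):
        # hybrid: terminal GN on the a3 arm, no GNb2 on the a6 arm
        sub = GNTI_PRODUCT
        rule = rules_by_index[14]
        sites = find_sites(sub, rule.substrate, rule.site_diff)
        assert sites
        kf, Km, Kmd = adjusted_params(rule, sub, sites[0])
        assert Km == pytest.approx(150 * 26.6667)

    def test_no_matching_adjustment(self, rules_by_index):
        # GnTI has no adjustment rows: base parameters pass through
        kf, Km, Kmd = adjusted_params(8, MAN5, 1)
        assert (kf, Km, Kmd) == (990.0, 260.0, 170.0)

    def test_order_independence(self, rules_by_index):
        adjustments = load_adjustments()
        reversed_adj = tuple(reversed(adjustments))
        for struct in (MAN9, GNTI_PRODUCT):
            a = adjusted_params(1, struct, 3, adjustments)
            b = adjusted_params(1, struct, 3, reversed_adj)
            assert a == b


def test_rule_table_indices_match_printed_tables():
    indices = sorted(r.index for r in load_rule_table())
    assert indices == [1, 2, *range(5, 19), *range(20, 27)]
    adj_ids = sorted(a.adjust_id for a in load_adjustments())
    assert adj_ids == [*range(1, 21), *range(24, 30)]
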