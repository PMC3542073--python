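"""Reactor-cascade kinetics: rate law, residuals against a dense oracle,
closed-form CSTR limits, conservation, and the full nonlinear solve."""

import numpy as np
import pytest

from glycosim.config import EnzymeProfile, ReactorConfig
from glycosim.golgi import (SolverError, compile_kinetics,
                            linear_abundance_estimate, outlet_abundances,
                            reaction_rate, residuals, solve_steady_state)
from glycosim.network import Reaction, ReactionNetwork


def _reactor(n=4, tau=2.0, c_tot=10.0, inlet=None, donors=None):
    return ReactorConfig(tau=[tau] * n, volumes=[1.0 / n] * n, c_tot=c_tot,
                         inlet=inlet or {"S0": 1.0}, donors=donors or {})


def _chain_network(n_steps, enzyme="b4GalT", kf=100.0, Km=1e6, Kmd=0.0):
    structures = [f"S{i}" for i in range(n_steps + 1)]
    rxns = [Reaction(enzyme, 14, f"S{i}", f"S{i+1}", None, None, kf, Km, Kmd)
            for i in range(n_steps)]
    return ReactionNetwork(structures, rxns, ["S0"])


def _profile(act, enzymes=("b4GalT",), c_tot=10.0, kf_base=None):
    return EnzymeProfile({e: act for e in enzymes},
                         {e: [0.25] * 4 for e in enzymes}, c_tot=c_tot,
                         kf_base=kf_base)


class TestReactionRate:
    def test_zero_enzyme(self):
        assert reaction_rate(0.0, 100.0, 50.0, 10.0, 1.0, 5.0, 1.0) == 0.0

    def test_saturated_donor_convention(self):
        r0 = reaction_rate(1.0, 100.0, 50.0, 0.0, 1.0, 0.0, 1.0)
        r1 = reaction_rate(1.0, 100.0, 50.0, 0.0, 1.0, 12345.0, 1.0)
        assert r0 == r1 == pytest.approx(100.0 / 50.0)

    def test_closed_form_value(self):
        # direct evaluation of Et*kf*(Sd/Kmd)/(1+Sd/Kmd)*(c/Km)/D
        got = reaction_rate(Et=0.5, kf=200.0, Km=40.0, Kmd=20.0,
                            substrate_conc=8.0, donor_conc=60.0,
                            denominator=3.0)
        expected = 0.5 * 200.0 * (3.0 / 4.0) * (8.0 / 40.0) / 3.0
        assert got == pytest.approx(expected, rel=1e-12)

    def test_competition_decreases_rate(self):
        lo = reaction_rate(1.0, 100.0, 50.0, 0.0, 1.0, 0.0, 1.0 + 1.0 / 50.0)
        hi = reaction_rate(1.0, 100.0, 50.0, 0.0, 1.0, 0.0, 1.0 + 2.0 / 50.0)
        assert hi < lo

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            reaction_rate(1.0, 1.0, 1.0, 0.0, -1.0, 0.0, 1.0)


class TestResiduals:
    def test_passthrough_fixed_point(self):
        net = _chain_network(1)
        kin = compile_kinetics(net)
        cfg = _reactor()
        prof = _profile(0.0)
        c = np.zeros((2, 4))
        c[0] = 10.0
        D = 1.0 + c[[0, 0, 0, 0], [0, 1, 2, 3]].reshape(1, 4) / 1e6
        res = residuals(kin, c, D, prof, cfg)
        assert np.abs(res).max() < 1e-12

    def test_perturbation_gives_linear_balance(self):
        net = _chain_network(1)
        kin = compile_kinetics(net)
        cfg = _reactor()
        prof = _profile(0.0)
        c = np.zeros((2, 4))
        c[0] = 10.0
        delta = 0.3
        c[1, 2] += delta                      # perturb one entry
        D = 1.0 + c[0:1, :] / 1e6
        res = residuals(kin, c, D, prof, cfg).reshape(-1)
        # structure residuals are ordered compartment-major
        expected = np.zeros(8)
        expected[2 * 2 + 1] = -delta / cfg.tau[2]   # (i=1, j=2)
        expected[3 * 2 + 1] = +delta / cfg.tau[3]   # flows into j=3
        assert res[:8] == pytest.approx(expected, abs=1e-12)

    def test_dense_oracle_on_toy_network(self):
        """Residuals equal a naive dense re-implementation of the rate law
        and balance equations on a 3-structure, 2-enzyme toy network."""
        structures = ["S0", "S1", "S2"]
        rxns = [
            Reaction("E1", 14, "S0", "S1", "UDP-Gal", "UDP", 50.0, 20.0, 30.0),
            Reaction("E2", 15, "S1", "S2", "CMP-NeuAc", "CMP", 70.0, 35.0, 0.0),
            Reaction("E1", 14, "S1", "S2", "UDP-Gal", "UDP", 20.0, 80.0, 30.0),
        ]
        net = ReactionNetwork(structures, rxns, ["S0"])
        kin = compile_kinetics(net)
        cfg = ReactorConfig(tau=[1.5, 2.5, 2.0, 3.0], volumes=[0.25] * 4,
                            c_tot=9.0, inlet={"S0": 1.0},
                            donors={"UDP-Gal": 120.0, "CMP-NeuAc": 45.0})
        prof = EnzymeProfile({"E1": 1.0, "E2": 2.0},
                             {"E1": [0.4, 0.3, 0.2, 0.1],
                              "E2": [0.1, 0.2, 0.3, 0.4]}, c_tot=9.0,
                             kf_base={"E1": 50.0, "E2": 70.0})
        rng = np.random.default_rng(42)
        c = rng.uniform(0.1, 3.0, size=(3, 4))
        D = rng.uniform(1.0, 2.0, size=(2, 4))
        got = residuals(kin, c, D, prof, cfg)

        # dense, index-free re-derivation
        et = {("E1", j): 1.0 * 9.0 / 50.0 * [0.4, 0.3, 0.2, 0.1][j] / 0.25
              for j in range(4)}
        et.update({("E2", j): 2.0 * 9.0 / 70.0 * [0.1, 0.2, 0.3, 0.4][j] / 0.25
                   for j in range(4)})
        names = {0: "E1", 1: "E2"}
        expected = []
        c0 = np.array([9.0, 0.0, 0.0])
        for j in range(4):
            rates = []
            for r, (enz, sub, prod) in zip(rxns, [("E1", 0, 1), ("E2", 1, 2),
                                                  ("E1", 1, 2)]):
                donor = cfg.donors[r.cosubstrate]
                df = (donor / r.Kmd) / (1 + donor / r.Kmd) if r.Kmd else 1.0
                e_idx = 0 if enz == "E1" else 1
                v = et[(enz, j)] * r.kf * df * (c[sub, j] / r.Km) / D[e_idx, j]
                rates.append((v, sub, prod))
            for i in range(3):
                prev = c0[i] if j == 0 else c[i, j - 1]
                r_net = sum(v for v, s, p in rates if p == i) \
                    - sum(v for v, s, p in rates if s == i)
                expected.append((prev - c[i, j]) / cfg.tau[j] + r_net)
        for j in range(4):
            for e in range(2):
                occ = sum(c[s, j] / r.Km for r, (enz, s, p) in
                          zip(rxns, [("E1", 0, 1), ("E2", 1, 2), ("E1", 1, 2)])
                          if enz == names[e])
                expected.append(D[e, j] - 1.0 - occ)
        # reorder: residuals() returns all structure balances then all D rows
        exp_struct = np.array(expected[:12]).reshape(4, 3).T.ravel(order="F")
        exp_D = np.array(expected[12:]).reshape(4, 2).T.ravel(order="F")
        assert got == pytest.approx(np.concatenate([exp_struct, exp_D]),
                                    rel=1e-12)


class TestSolve:
    def test_zero_enzymes_passthrough(self):
        net = _chain_network(2)
        cfg = _reactor(inlet={"S0": 0.7, "S1": 0.3})
        st = solve_steady_state(net, _profile(0.0), cfg)
        ab = outlet_abundances(st)
        assert ab["S0"] == pytest.approx(0.7, abs=1e-12)
        assert ab["S1"] == pytest.approx(0.3, abs=1e-12)

    def test_cstr_cascade_closed_form(self):
        """Single linear reaction through j compartments: outlet fraction
        (1 + k tau)^-j to 6 digits."""
        net = _chain_network(1, kf=500.0, Km=1e7)
        c_tot, act = 10.0, 2.0
        cfg = _reactor(tau=3.0, c_tot=c_tot)
        prof = _profile(act, c_tot=c_tot, kf_base={"b4GalT": 500.0})
        st = solve_steady_state(net, prof, cfg)
        Et = act * c_tot / 500.0       # per-compartment concentration
        k = Et * 500.0 / 1e7
        expected = (1 + k * 3.0) ** -4
        assert st.c[0, -1] / c_tot == pytest.approx(expected, rel=1e-6)

    def test_conservation_with_strong_kinetics(self, small_network, reference):
        st = solve_steady_state(small_network, reference.enzymes,
                                reference.reactor)
        totals = st.c.sum(axis=0)
        assert totals == pytest.approx(
            np.full(4, reference.reactor.c_tot), rel=1e-9)
        assert (st.c >= 0).all()

    def test_newton_matches_dense_brute_force(self):
        """Sequential sparse Newton equals a dense nonlinear solve of the
        full coupled system on a toy network."""
        from scipy.optimize import fsolve
        structures = ["S0", "S1", "S2", "S3"]
        rxns = [
            Reaction("E1", 14, "S0", "S1", None, None, 60.0, 5.0, 0.0),
            Reaction("E1", 14, "S1", "S2", None, None, 45.0, 8.0, 0.0),
            Reaction("E2", 15, "S1", "S3", None, None, 80.0, 3.0, 0.0),
        ]
        net = ReactionNetwork(structures, rxns, ["S0"])
        kin = compile_kinetics(net)
        cfg = _reactor(tau=1.0, c_tot=10.0)
        prof = EnzymeProfile({"E1": 3.0, "E2": 1.0},
                             {"E1": [0.25] * 4, "E2": [0.25] * 4}, c_tot=10.0,
                             kf_base={"E1": 60.0, "E2": 80.0})
        st = solve_steady_state(kin, prof, cfg)

        n, m = 4, 2
        def full_res(x):
            c = x[: n * 4].reshape(n, 4)
            D = x[n * 4:].reshape(m, 4)
            return residuals(kin, c, D, prof, cfg)
        x0 = np.concatenate([np.tile([10, 0, 0, 0.0], 4).reshape(4, n).T.ravel(),
                             np.ones(m * 4)])
        sol = fsolve(full_res, x0, full_output=False, xtol=1e-13)
        c_dense = sol[: n * 4].reshape(n, 4)
        assert st.c == pytest.approx(c_dense, rel=1e-8, abs=1e-10)

    def test_solution_invariant_under_structure_reordering(self):
        structures = ["S0", "S1", "S2"]
        rxns = [Reaction("E1", 14, "S0", "S1", None, None, 60.0, 5.0, 0.0),
                Reaction("E1", 14, "S1", "S2", None, None, 45.0, 8.0, 0.0)]
        cfg = _reactor(tau=1.0)
        prof = EnzymeProfile({"E1": 3.0}, {"E1": [0.25] * 4}, c_tot=10.0,
                             kf_base={"E1": 60.0})
        st1 = solve_steady_state(
            ReactionNetwork(structures, rxns, ["S0"]), prof, cfg)
        st2 = solve_steady_state(
            ReactionNetwork(structures[::-1], rxns, ["S0"]), prof, cfg)
        ab1, ab2 = outlet_abundances(st1), outlet_abundances(st2)
        for s in structures:
            assert ab1[s] == pytest.approx(ab2[s], rel=1e-10, abs=1e-14)

    def test_enzyme_monotonicity(self):
        """More enzyme, more flux: outlet substrate decreases with Et on an
        acyclic chain."""
        net = _chain_network(2, Km=20.0)
        cfg = _reactor(tau=1.0)
        outs = []
        for act in (0.5, 1.0, 2.0):
            st = solve_steady_state(net, _profile(act), cfg)
            outs.append(st.c[0, -1])
        assert outs[0] > outs[1] > outs[2]

    def test_outlet_fractions_sum_to_one(self, small_network, reference):
        st = solve_steady_state(small_network, reference.enzymes,
                                reference.reactor)
        ab = outlet_abundances(st)
        assert sum(ab.values()) == pytest.approx(1.0, abs=1e-12)


class TestLinearEstimate:
    def test_matches_solver_in_dilute_limit(self):
        net = _chain_network(2, Km=1e8)
        cfg = _reactor(tau=2.0)
        prof = _profile(5.0)
        est = linear_abundance_estimate(net, prof, cfg)
        st = solve_steady_state(net, prof, cfg)
        for i, s in enumerate(["S0", "S1", "S2"]):
            assert est[s] == pytest.approx(
                max(st.c[i].max(), st.c0[i]) / cfg.c_tot, rel=1e-6)
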