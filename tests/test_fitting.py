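"""Enzyme-level estimation: RMS metric, parameter recovery on
forward-simulated targets, and the expression-ratio constrained fit."""

import numpy as np
import pytest

from glycosim.config import load_reference_config
from glycosim.expression import ExpressionConstraint
from glycosim.fitting import (FitProblem, build_peak_grid, envelope_areas,
                              fit_enzyme_levels,
                              fit_with_expression_constraint,
                              model_areas_on_grid, rms_error)
from glycosim.golgi import compile_kinetics, outlet_abundances, \
    solve_steady_state


class TestRms:
    def test_identical_zero(self):
        assert rms_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert rms_error([3.0, 4.0], [0.0, 0.0]) == pytest.approx(3.5355,
                                                                  abs=1e-4)

    def test_permutation_symmetric(self):
        a, b = np.array([1.0, 5.0, 2.0]), np.array([2.0, 3.0, 0.0])
        assert rms_error(a, b) == pytest.approx(rms_error(a[::-1], b[::-1]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms_error([], [])


@pytest.fixture(scope="module")
def fit_setup(small_network, reference):
    kin = compile_kinetics(small_network)
    grid = build_peak_grid(small_network.structures, (1400.0, 2600.0))
    return kin, grid, reference


def _target(kin, grid, reference, profile):
    st = solve_steady_state(kin, profile, reference.reactor)
    return model_areas_on_grid(grid, outlet_abundances(st))


class TestFit:
    def test_fixed_point_at_truth(self, fit_setup):
        kin, grid, ref = fit_setup
        target = _target(kin, grid, ref, ref.enzymes)
        problem = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses,
                             target, ["FucTH", "b4GalT"], (1400, 2600), grid)
        res = fit_enzyme_levels(problem, init={
            "FucTH": ref.enzymes.activity["FucTH"],
            "b4GalT": ref.enzymes.activity["b4GalT"]}, n_restarts=0)
        assert res.rms == pytest.approx(0.0, abs=1e-8)

    def test_single_enzyme_recovery(self, fit_setup):
        kin, grid, ref = fit_setup
        truth = ref.enzymes.with_activity({"FucTH": 0.06})
        target = _target(kin, grid, ref, truth)
        problem = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses,
                             target, ["FucTH"], (1400, 2600), grid)
        res = fit_enzyme_levels(problem, n_restarts=1, seed=0)
        assert res.activities["FucTH"] == pytest.approx(0.06, rel=0.05)
        assert res.converged

    def test_three_enzyme_noiseless_recovery(self, fit_setup):
        kin, grid, ref = fit_setup
        truth = ref.enzymes.with_activity(
            {"FucTH": 0.05, "a6FucT": 1.2, "GnTV": 1.8})
        target = _target(kin, grid, ref, truth)
        problem = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses,
                             target, ["FucTH", "a6FucT", "GnTV"],
                             (1400, 2600), grid)
        res = fit_enzyme_levels(problem, n_restarts=1, seed=0)
        for e, v in (("FucTH", 0.05), ("a6FucT", 1.2), ("GnTV", 1.8)):
            assert res.activities[e] == pytest.approx(v, rel=0.05), e

    def test_unidentifiable_enzyme_flagged(self, fit_setup):
        kin, grid, ref = fit_setup
        # GalT-B requires an H-capped galactose; with FucTH ~ 0 its flux is
        # zero, so its level cannot be inferred from the spectrum
        base = ref.enzymes.with_activity({"FucTH": 0.0})
        target = _target(kin, grid, ref, base)
        problem = FitProblem(kin, ref.reactor, base, grid.masses, target,
                             ["GalT-B"], (1400, 2600), grid)
        res = fit_enzyme_levels(problem, n_restarts=0)
        assert "GalT-B" in res.unidentifiable


class TestConstrainedFit:
    def test_unit_ratios_identical_targets(self, fit_setup):
        kin, grid, ref = fit_setup
        target = _target(kin, grid, ref, ref.enzymes)
        free = ["FucTH", "b4GalT"]
        pa = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses, target,
                        free, (1400, 2600), grid)
        pb = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses, target,
                        free, (1400, 2600), grid)
        constraint = ExpressionConstraint({"FucTH": 1.0, "b4GalT": 1.0},
                                          frozenset())
        ra, rb = fit_with_expression_constraint(pa, pb, constraint)
        for e in free:
            assert ra.activities[e] == pytest.approx(rb.activities[e],
                                                     rel=1e-9)

    def test_missing_ratio_rejected(self, fit_setup):
        kin, grid, ref = fit_setup
        target = _target(kin, grid, ref, ref.enzymes)
        p = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses, target,
                       ["FucTH", "b4GalT"], (1400, 2600), grid)
        with pytest.raises(ValueError, match="missing expression ratio"):
            fit_with_expression_constraint(
                p, p, ExpressionConstraint({"FucTH": 1.0}, frozenset()))

    def test_constrained_recovery_with_true_ratios(self, fit_setup):
        """Fixture pair generated with b4GalT doubled in condition B; the
        constrained fit with the true ratio recovers condition A."""
        kin, grid, ref = fit_setup
        truth_a = ref.enzymes
        truth_b = ref.enzymes.with_activity(
            {"b4GalT": 2.0 * ref.enzymes.activity["b4GalT"]})
        ta = _target(kin, grid, ref, truth_a)
        tb = _target(kin, grid, ref, truth_b)
        free = ["b4GalT", "FucTH"]
        pa = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses, ta,
                        free, (1400, 2600), grid)
        pb = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses, tb,
                        free, (1400, 2600), grid)
        constraint = ExpressionConstraint({"b4GalT": 2.0, "FucTH": 1.0},
                                          frozenset())
        init = {"b4GalT": 0.6 * truth_a.activity["b4GalT"],
                "FucTH": 2.0 * truth_a.activity["FucTH"]}
        ra, rb = fit_with_expression_constraint(pa, pb, constraint, init=init)
        assert ra.activities["b4GalT"] == pytest.approx(
            truth_a.activity["b4GalT"], rel=0.05)
        assert rb.activities["b4GalT"] == pytest.approx(
            2.0 * ra.activities["b4GalT"], rel=1e-9)

    def test_wrong_ratio_cannot_beat_unconstrained(self, fit_setup):
        """Forcing an incorrect between-condition ratio can only worsen the
        fit relative to fitting each condition freely."""
        kin, grid, ref = fit_setup
        truth_b = ref.enzymes.with_activity(
            {"b4GalT": 2.0 * ref.enzymes.activity["b4GalT"]})
        ta = _target(kin, grid, ref, ref.enzymes)
        tb = _target(kin, grid, ref, truth_b)
        free = ["b4GalT"]
        pb = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses, tb,
                        free, (1400, 2600), grid)
        free_fit = fit_enzyme_levels(pb, n_restarts=0)
        pa = FitProblem(kin, ref.reactor, ref.enzymes, grid.masses, ta,
                        free, (1400, 2600), grid)
        constraint = ExpressionConstraint({"b4GalT": 1.0}, frozenset())
        _ra, rb = fit_with_expression_constraint(pa, pb, constraint)
        assert rb.rms >= free_fit.rms - 1e-9


def test_envelope_areas_normalized(small_network, reference):
    kin = compile_kinetics(small_network)
    st = solve_steady_state(kin, reference.enzymes, reference.reactor)
    masses, areas = envelope_areas(kin, outlet_abundances(st), (1400, 2600))
    assert areas.sum() == pytest.approx(100.0, abs=1e-9)
    assert (np.diff(masses) > 0).all()
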