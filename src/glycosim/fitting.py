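"""Enzyme-level estimation against processed MALDI spectra.

Free parameters are per-enzyme activity levels (fitted in log-space to
enforce positivity).  For a trial profile the model is solved to steady
state, the outlet glycan distribution converted to envelope %-areas at the
theoretical peak masses, and the residual is the difference to the target
%-areas; the Levenberg-Marquardt method minimizes the sum of squares.  A
two-condition variant ties the second condition's activities to the first
through transcript-expression ratios (exempt enzymes float freely in both
conditions), minimizing the joint sum of both conditions' squared
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .config import EnzymeProfile, ReactorConfig
from .expression import ExpressionConstraint
from .golgi import SolverError, compile_kinetics, outlet_abundances, \
    solve_steady_state
from .isotopes import envelope_table, permethylated_composition

__all__ = ["FitProblem", "FitResult", "PeakGrid", "rms_error",
           "envelope_areas", "build_peak_grid", "model_areas_on_grid",
           "observe_on_grid", "fit_enzyme_levels",
           "fit_with_expression_constraint"]


def rms_error(a, b) -> float:
    """Root-mean-square difference of two %-area vectors on a shared grid."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("area vectors must be nonempty and aligned")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def envelope_areas(network, state_abundances: dict[str, float],
                   mass_range=(1400.0, 4000.0)) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate outlet abundances into envelope %-areas keyed by
    monoisotopic mass (isomers merge; envelopes normalized to 100% total)."""
    groups: dict[float, float] = {}
    for text, ab in state_abundances.items():
        m = round(permethylated_composition(text).monoisotopic_mass, 6)
        groups[m] = groups.get(m, 0.0) + ab
    masses = np.array(sorted(groups))
    areas = np.array([groups[m] for m in masses])
    keep = (masses >= mass_range[0]) & (masses <= mass_range[1])
    masses, areas = masses[keep], areas[keep]
    total = areas.sum()
    if total <= 0:
        raise ValueError("no model mass falls inside the fit range")
    return masses, 100.0 * areas / total


@dataclass
class PeakGrid:
    """Fixed grid of model isotope-peak masses with envelope membership.

    ``masses`` are all isotope-peak m/z of the network's envelopes whose
    monoisotopic mass lies in range; ``envelope_masses`` labels the
    envelopes (monoisotopic m/z); ``matrix[i, e]`` is envelope e's relative
    abundance at grid mass i, so a glycan distribution maps to peak areas
    by one matrix product and an observed area vector NNLS-projects onto
    the model's explainable subspace.
    """

    masses: np.ndarray
    envelope_masses: np.ndarray
    matrix: np.ndarray


def build_peak_grid(structures, mass_range=(1400.0, 4000.0),
                    threshold: float = 1e-4,
                    merge_tol: float = 0.3) -> PeakGrid:
    """Grid masses closer than ``merge_tol`` Da (unresolvable by the peak
    integrator) are merged into one entry."""
    env = envelope_table(structures, threshold)
    monos = sorted(m for m in env if mass_range[0] <= m <= mass_range[1])
    entries = []
    for e_idx, mono in enumerate(monos):
        for m, ab in env[mono].peaks:
            entries.append((m, e_idx, ab))
    entries.sort()
    groups: list[list[tuple[float, int, float]]] = []
    for m, e_idx, ab in entries:
        if groups and m - groups[-1][-1][0] <= merge_tol:
            groups[-1].append((m, e_idx, ab))
        else:
            groups.append([(m, e_idx, ab)])
    masses = np.array([np.mean([g[0] for g in grp]) for grp in groups])
    A = np.zeros((len(groups), len(monos)))
    for i, grp in enumerate(groups):
        for _m, e_idx, ab in grp:
            A[i, e_idx] += ab
    return PeakGrid(masses, np.array(monos), A)


def model_areas_on_grid(grid: PeakGrid, abundances: dict[str, float],
                        ) -> np.ndarray:
    """Peak %-areas of a glycan distribution on the grid (sum 100)."""
    env_ab = np.zeros(grid.envelope_masses.size)
    lookup = {round(m, 6): i for i, m in enumerate(grid.envelope_masses)}
    for text, ab in abundances.items():
        key = round(permethylated_composition(text).monoisotopic_mass, 6)
        if key in lookup:
            env_ab[lookup[key]] += ab
    areas = grid.matrix @ env_ab
    total = areas.sum()
    if total <= 0:
        raise ValueError("distribution has no mass on the peak grid")
    return 100.0 * areas / total


def observe_on_grid(raw, grid: PeakGrid, baseline_window: float = 20.0,
                    calibrate: bool = True):
    """Preprocess a raw spectrum and put it on the model peak grid.

    Returns (areas_pct, projected_pct): integrated peak %-areas at the
    grid masses, and their nonnegative projection onto the model
    envelopes (both normalized to 100)."""
    from .preprocess import apply_calibration, calibrate_mass, \
        correct_baseline, integrate_peaks, project_spectrum
    spec = correct_baseline(raw, window=baseline_window)
    if calibrate:
        fit = calibrate_mass(spec, grid.masses)
        spec = apply_calibration(spec, fit)
    table = integrate_peaks(spec, grid.masses)
    areas = table.area_pct
    proj = project_spectrum(table.areas, grid.matrix)
    fitted = proj.fitted
    total = fitted.sum()
    projected = 100.0 * fitted / total if total > 0 else fitted
    return areas, projected


@dataclass
class FitProblem:
    network: object
    reactor: ReactorConfig
    base_profile: EnzymeProfile
    target_masses: np.ndarray           # theoretical envelope masses
    target_areas: np.ndarray            # observed %-areas at those masses
    free_enzymes: list[str]
    mass_range: tuple[float, float] = (1400.0, 4000.0)
    grid: PeakGrid | None = None        # peak-level comparison when set

    def __post_init__(self):
        self.target_masses = np.asarray(self.target_masses, dtype=float)
        self.target_areas = np.asarray(self.target_areas, dtype=float)


@dataclass
class FitResult:
    activities: dict[str, float]
    rms: float
    iterations: int
    converged: bool
    unidentifiable: list[str] = field(default_factory=list)
    profile: EnzymeProfile | None = None


_LOG_FLOOR = 1e-8


def _model_areas(problem: FitProblem, profile: EnzymeProfile) -> np.ndarray:
    kin = problem.network if hasattr(problem.network, "sub_idx") \
        else compile_kinetics(problem.network)
    state = solve_steady_state(kin, profile, problem.reactor)
    ab = outlet_abundances(state)
    if problem.grid is not None:
        return model_areas_on_grid(problem.grid, ab)
    masses, areas = envelope_areas(kin, ab, problem.mass_range)
    lookup = {round(m, 4): a for m, a in zip(masses, areas)}
    return np.array([lookup.get(round(m, 4), 0.0)
                     for m in problem.target_masses])


def _profile_from_theta(problem: FitProblem, theta: np.ndarray) -> EnzymeProfile:
    updates = {e: float(np.exp(t)) for e, t in zip(problem.free_enzymes, theta)}
    return problem.base_profile.with_activity(updates)


def fit_enzyme_levels(problem: FitProblem, init: dict[str, float] | None = None,
                      n_restarts: int = 3, seed: int = 0,
                      xtol: float = 1e-8, max_nfev: int = 200) -> FitResult:
    """Levenberg-Marquardt fit of the free enzymes' activities.

    Runs a deterministic multi-start (the supplied init plus ``n_restarts``
    perturbed copies) and returns the best local optimum.  Enzymes whose
    reactions carry zero flux at the optimum cannot influence the spectrum
    and are reported as unidentifiable rather than trusted as estimates.
    """
    kin = problem.network if hasattr(problem.network, "sub_idx") \
        else compile_kinetics(problem.network)
    problem = FitProblem(kin, problem.reactor, problem.base_profile,
                         problem.target_masses, problem.target_areas,
                         problem.free_enzymes, problem.mass_range,
                         problem.grid)
    base_act = problem.base_profile.activity
    if init is None:
        init = {e: max(base_act.get(e, 0.0), _LOG_FLOOR)
                for e in problem.free_enzymes}
    theta0 = np.log([max(init[e], _LOG_FLOOR) for e in problem.free_enzymes])

    def residual(theta):
        try:
            model = _model_areas(problem, _profile_from_theta(problem, theta))
        except SolverError:
            return np.full(problem.target_areas.size, 1e3)
        return model - problem.target_areas

    rng = np.random.default_rng(seed)
    starts = [theta0] + [theta0 + rng.normal(0, 0.5, theta0.size)
                         for _ in range(n_restarts)]
    best = None
    total_nfev = 0
    for t0 in starts:
        sol = least_squares(residual, t0, method="lm", xtol=xtol,
                            max_nfev=max_nfev)
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    theta = best.x
    profile = _profile_from_theta(problem, theta)
    model = _model_areas(problem, profile)
    rms = rms_error(model, problem.target_areas)

    # identifiability: zero-flux enzymes at the optimum
    state = solve_steady_state(kin, profile, problem.reactor)
    flux_by_enzyme = _enzyme_flux(kin, state, profile, problem.reactor)
    unident = [e for e in problem.free_enzymes
               if flux_by_enzyme.get(e, 0.0) <= 1e-12 * problem.reactor.c_tot]
    activities = {e: float(np.exp(t))
                  for e, t in zip(problem.free_enzymes, theta)}
    return FitResult(activities, rms, total_nfev, bool(best.status > 0),
                     unident, profile)


def _enzyme_flux(kin, state, profile, reactor) -> dict[str, float]:
    from .golgi import _rate_coef
    coef = _rate_coef(kin, profile, reactor)
    out: dict[str, float] = {}
    for j in range(reactor.n_compartments):
        v = coef[:, j] * state.c[kin.sub_idx, j] / (
            kin.Km * state.D[kin.enz_idx, j])
        for e_idx, enz in enumerate(kin.enzymes):
            out[enz] = out.get(enz, 0.0) + float(v[kin.enz_idx == e_idx].sum())
    return out


def fit_with_expression_constraint(problem_a: FitProblem, problem_b: FitProblem,
                                   constraint: ExpressionConstraint,
                                   init: dict[str, float] | None = None,
                                   seed: int = 0, xtol: float = 1e-8,
                                   max_nfev: int = 300,
                                   ) -> tuple[FitResult, FitResult]:
    """Joint two-condition fit with activity ratios tied to expression.

    Condition-A activities of all free enzymes are fitted; non-exempt
    enzymes in condition B are fixed at ratio x condition A, exempt enzymes
    get their own free condition-B level.  The joint objective is the sum
    of both conditions' squared residuals.
    """
    free = problem_a.free_enzymes
    if problem_b.free_enzymes != free:
        raise ValueError("both problems must share the free enzyme list")
    exempt = [e for e in free if e in constraint.exempt]
    for e in free:
        if e not in constraint.exempt and e not in constraint.ratios:
            raise ValueError(f"missing expression ratio for enzyme {e}")
    kin_a = problem_a.network if hasattr(problem_a.network, "sub_idx") \
        else compile_kinetics(problem_a.network)
    kin_b = problem_b.network if hasattr(problem_b.network, "sub_idx") \
        else compile_kinetics(problem_b.network)
    problem_a = FitProblem(kin_a, problem_a.reactor, problem_a.base_profile,
                           problem_a.target_masses, problem_a.target_areas,
                           free, problem_a.mass_range, problem_a.grid)
    problem_b = FitProblem(kin_b, problem_b.reactor, problem_b.base_profile,
                           problem_b.target_masses, problem_b.target_areas,
                           free, problem_b.mass_range, problem_b.grid)

    base_act = problem_a.base_profile.activity
    if init is None:
        init = {e: max(base_act.get(e, 0.0), _LOG_FLOOR) for e in free}
    theta0 = np.log([max(init[e], _LOG_FLOOR) for e in free]
                    + [max(init[e], _LOG_FLOOR) for e in exempt])

    def split(theta):
        act_a = {e: float(np.exp(t)) for e, t in zip(free, theta[: len(free)])}
        act_b = {}
        for e in free:
            if e in constraint.exempt:
                act_b[e] = float(np.exp(
                    theta[len(free) + exempt.index(e)]))
            else:
                act_b[e] = act_a[e] * constraint.ratios[e]
        return act_a, act_b

    def residual(theta):
        act_a, act_b = split(theta)
        try:
            ma = _model_areas(problem_a,
                              problem_a.base_profile.with_activity(act_a))
            mb = _model_areas(problem_b,
                              problem_b.base_profile.with_activity(act_b))
        except SolverError:
            return np.full(problem_a.target_areas.size
                           + problem_b.target_areas.size, 1e3)
        return np.concatenate([ma - problem_a.target_areas,
                               mb - problem_b.target_areas])

    sol = least_squares(residual, theta0, method="lm", xtol=xtol,
                        max_nfev=max_nfev)
    act_a, act_b = split(sol.x)
    prof_a = problem_a.base_profile.with_activity(act_a)
    prof_b = problem_b.base_profile.with_activity(act_b)
    rms_a = rms_error(_model_areas(problem_a, prof_a), problem_a.target_areas)
    rms_b = rms_error(_model_areas(problem_b, prof_b), problem_b.target_areas)
    ra = FitResult(act_a, rms_a, sol.nfev, bool(sol.status > 0), [], prof_a)
    rb = FitResult(act_b, rms_b, sol.nfev, bool(sol.status > 0), [], prof_b)
    return ra, rb
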