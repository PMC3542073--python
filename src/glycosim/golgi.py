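"""Steady-state Golgi reactor cascade with competitive Michaelis-Menten
kinetics.

The Golgi is modeled as four well-mixed compartments in series: glycans
flow from compartment j-1 into j with residence time tau_j while enzymes
stay put.  At steady state each structure i in compartment j satisfies

    (c_{i,j-1} - c_{i,j}) / tau_j + r_{i,j} = 0,

with c_{i,0} the inlet fraction times the (conserved) total glycan
concentration c_tot.  Each glycosylation reaction proceeds at

    v = [E_t] * kf * donor_factor * ([P_i]/Km_i) / D_e,
    donor_factor = ([S_d]/Kmd) / (1 + [S_d]/Kmd)   (1 when Kmd = 0),
    D_e = 1 + sum_k [P_k]/Km_k  over substrates competing for enzyme e,

the random-order rapid-equilibrium two-site form with reversibility off by
default (no reverse-rate constants are parameterized in the base tables);
a nonzero ``kr`` per reaction enables the reverse term.  The competitive
denominators D_e are carried as separate unknowns so the Jacobian stays
sparse; because coupling between compartments is strictly feed-forward the
Newton solve proceeds compartment by compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import EnzymeProfile, ReactorConfig

__all__ = ["CompiledKinetics", "GolgiState", "SolverError", "reaction_rate",
           "compile_kinetics", "residuals", "solve_steady_state",
           "linear_abundance_estimate", "outlet_abundances"]


class SolverError(RuntimeError):
    pass


def reaction_rate(Et: float, kf: float, Km: float, Kmd: float,
                  substrate_conc: float, donor_conc: float,
                  denominator: float) -> float:
    """Rate (uM/min) of one glycosylation reaction.

    ``denominator`` is the shared competitive term D_e of the catalyzing
    enzyme; ``Kmd = 0`` means the donor site is saturated.
    """
    if substrate_conc < 0 or donor_conc < 0:
        raise ValueError("negative concentration")
    if Kmd > 0:
        x = donor_conc / Kmd
        donor_factor = x / (1.0 + x)
    else:
        donor_factor = 1.0
    return Et * kf * donor_factor * (substrate_conc / Km) / denominator


@dataclass
class CompiledKinetics:
    """Numeric view of a reaction network for the reactor solver."""

    structures: list[str]
    enzymes: list[str]
    sub_idx: np.ndarray      # per reaction
    prod_idx: np.ndarray
    enz_idx: np.ndarray
    kf: np.ndarray
    Km: np.ndarray
    Kmd: np.ndarray
    donor: list[str | None]

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    @property
    def n_enzymes(self) -> int:
        return len(self.enzymes)

    @property
    def n_reactions(self) -> int:
        return len(self.sub_idx)


def compile_kinetics(network) -> CompiledKinetics:
    """Index a ReactionNetwork (or any object with .structures / .reactions)
    into flat arrays."""
    structures = [s if isinstance(s, str) else s.text for s in network.structures]
    index = {s: i for i, s in enumerate(structures)}
    enzymes: dict[str, int] = {}
    sub, prod, enz, kf, Km, Kmd, donor = [], [], [], [], [], [], []
    for r in network.reactions:
        e = enzymes.setdefault(r.enzyme, len(enzymes))
        sub.append(index[r.substrate])
        prod.append(index[r.product])
        enz.append(e)
        kf.append(r.kf)
        Km.append(r.Km)
        Kmd.append(r.Kmd)
        donor.append(r.cosubstrate)
    return CompiledKinetics(
        structures=structures,
        enzymes=list(enzymes),
        sub_idx=np.asarray(sub, dtype=np.int64),
        prod_idx=np.asarray(prod, dtype=np.int64),
        enz_idx=np.asarray(enz, dtype=np.int64),
        kf=np.asarray(kf, dtype=float),
        Km=np.asarray(Km, dtype=float),
        Kmd=np.asarray(Kmd, dtype=float),
        donor=donor,
    )


@dataclass
class GolgiState:
    """Solution of the reactor cascade: concentrations (uM) per structure
    and compartment plus the enzyme denominator auxiliaries."""

    kin: CompiledKinetics
    c: np.ndarray            # (n_structures, n_compartments)
    D: np.ndarray            # (n_enzymes, n_compartments)
    c0: np.ndarray           # inlet concentrations
    config: ReactorConfig
    residual_norm: float = 0.0
    converged: bool = True


def _donor_factor(kin: CompiledKinetics, config: ReactorConfig) -> np.ndarray:
    """Per-reaction donor saturation factor (donors uniform across
    compartments)."""
    df = np.ones(kin.n_reactions)
    for k in range(kin.n_reactions):
        if kin.Kmd[k] > 0:
            d = kin.donor[k]
            conc = config.donors.get(d, 0.0) if d else 0.0
            x = conc / kin.Kmd[k]
            df[k] = x / (1.0 + x)
    return df


def _rate_coef(kin: CompiledKinetics, enzymes: EnzymeProfile,
               config: ReactorConfig) -> np.ndarray:
    """coef[k, j] = Et[e_k, j] * kf_k * donor_factor_k; rate = coef * c_s /
    (Km_k * D_e)."""
    Et = enzymes.et_matrix(kin.enzymes, config.volumes)
    df = _donor_factor(kin, config)
    return Et[kin.enz_idx, :] * (kin.kf * df)[:, None]


def inlet_vector(kin: CompiledKinetics, config: ReactorConfig) -> np.ndarray:
    c0 = np.zeros(kin.n_structures)
    index = {s: i for i, s in enumerate(kin.structures)}
    for s, frac in config.inlet.items():
        if s in index:
            c0[index[s]] = frac * config.c_tot
    return c0


def residuals(kin: CompiledKinetics, c: np.ndarray, D: np.ndarray,
              enzymes: EnzymeProfile, config: ReactorConfig) -> np.ndarray:
    """Full-system residual vector: the structure balances for every
    compartment followed by the denominator-definition equations."""
    n, m = kin.n_structures, kin.n_enzymes
    n_c = config.n_compartments
    if c.shape != (n, n_c) or D.shape != (m, n_c):
        raise ValueError("dimension mismatch")
    coef = _rate_coef(kin, enzymes, config)
    c0 = inlet_vector(kin, config)
    Fc = np.zeros((n, n_c))
    FD = np.zeros((m, n_c))
    for j in range(n_c):
        prev = c0 if j == 0 else c[:, j - 1]
        v = coef[:, j] * c[kin.sub_idx, j] / (kin.Km * D[kin.enz_idx, j])
        r = np.zeros(n)
        np.subtract.at(r, kin.sub_idx, v)
        np.add.at(r, kin.prod_idx, v)
        Fc[:, j] = (prev - c[:, j]) / config.tau[j] + r
        occ = np.zeros(m)
        np.add.at(occ, kin.enz_idx, c[kin.sub_idx, j] / kin.Km)
        FD[:, j] = D[:, j] - 1.0 - occ
    return np.concatenate([Fc.ravel(order="F"), FD.ravel(order="F")])


def _solve_compartment(kin: CompiledKinetics, coef_j: np.ndarray,
                       c_prev: np.ndarray, tau: float, tol: float,
                       max_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve of one compartment's balances + denominator equations."""
    n, m = kin.n_structures, kin.n_enzymes
    sub, prod, enz = kin.sub_idx, kin.prod_idx, kin.enz_idx
    Km = kin.Km

    n_arange = np.arange(n)

    def linear_c(D):
        """Concentrations solving the balances with denominators frozen."""
        k_lin = coef_j / (Km * D[enz])
        rows = np.concatenate([prod, sub, n_arange])
        cols = np.concatenate([sub, sub, n_arange])
        vals = np.concatenate([-k_lin, k_lin, np.full(n, 1.0 / tau)])
        M = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        return np.maximum(spla.spsolve(M, c_prev / tau), 0.0)

    # phase 1: damped successive substitution on the denominators —
    # globally robust, loose tolerance (Newton polishes below)
    occ = np.zeros(m)
    np.add.at(occ, enz, c_prev[sub] / Km)
    D = 1.0 + occ
    for _ in range(60):
        c = linear_c(D)
        occ = np.zeros(m)
        np.add.at(occ, enz, c[sub] / Km)
        D_new = 1.0 + occ
        if np.abs(D_new - D).max() <= 1e-4 * max(1.0, np.abs(D).max()):
            D = D_new
            break
        D = 0.5 * D + 0.5 * D_new
    c = linear_c(D)
    occ = np.zeros(m)
    np.add.at(occ, enz, c[sub] / Km)
    D = 1.0 + occ

    # phase 2: Newton polish on the coupled system

    def F(c, D):
        v = coef_j * c[sub] / (Km * D[enz])
        r = np.zeros(n)
        np.subtract.at(r, sub, v)
        np.add.at(r, prod, v)
        Fc = (c_prev - c) / tau + r
        occ = np.zeros(m)
        np.add.at(occ, enz, c[sub] / Km)
        FD = D - 1.0 - occ
        return np.concatenate([Fc, FD])

    f = F(c, D)
    norm = np.abs(f).max()
    for _ in range(max_iter):
        if norm <= tol:
            break
        dv_dc = coef_j / (Km * D[enz])              # d v / d c_sub
        v = dv_dc * c[sub]
        dv_dD = -v / D[enz]                          # d v / d D_e
        rows = np.concatenate([
            sub, prod,                    # d r / d c_sub
            sub, prod,                    # d r / d D
            np.arange(n),                 # -1/tau diagonal
            n + enz,                      # FD rows wrt c_sub
            n + np.arange(m),             # FD diagonal
        ])
        cols = np.concatenate([
            sub, sub,
            n + enz, n + enz,
            np.arange(n),
            sub,
            n + np.arange(m),
        ])
        vals = np.concatenate([
            -dv_dc, dv_dc,
            -dv_dD, dv_dD,
            -np.full(n, 1.0 / tau),
            -1.0 / Km,
            np.ones(m),
        ])
        J = sp.csc_matrix((vals, (rows, cols)), shape=(n + m, n + m))
        try:
            dx = spla.splu(J).solve(-f)
        except RuntimeError as exc:
            raise SolverError(f"singular Jacobian: {exc}") from exc
        alpha = 1.0
        for _ls in range(30):
            c_new = np.maximum(c + alpha * dx[:n], 0.0)
            D_new = np.maximum(D + alpha * dx[n:], 1.0)
            f_new = F(c_new, D_new)
            norm_new = np.abs(f_new).max()
            if norm_new < norm:
                break
            alpha *= 0.5
        else:
            break  # stalled; accept best so far
        c, D, f, norm = c_new, D_new, f_new, norm_new
    return c, D


def solve_steady_state(network, enzymes: EnzymeProfile, config: ReactorConfig,
                       init: GolgiState | None = None,
                       tol_factor: float = 1e-9, max_iter: int = 200,
                       ) -> GolgiState:
    """Solve the steady-state cascade for all structure concentrations.

    Compartments are solved in sequence (coupling is feed-forward); each
    compartment is a damped Newton iteration on its balances plus the
    denominator auxiliaries, with concentrations clipped at zero.
    Convergence requires max-residual <= ``tol_factor * c_tot``.
    """
    kin = network if isinstance(network, CompiledKinetics) \
        else compile_kinetics(network)
    n_c = config.n_compartments
    coef = _rate_coef(kin, enzymes, config)
    c0 = inlet_vector(kin, config)
    tol = tol_factor * config.c_tot
    c = np.zeros((kin.n_structures, n_c))
    D = np.ones((kin.n_enzymes, n_c))
    prev = c0
    for j in range(n_c):
        cj, Dj = _solve_compartment(kin, coef[:, j], prev, config.tau[j],
                                    tol, max_iter)
        c[:, j], D[:, j] = cj, Dj
        prev = cj
    res = residuals(kin, c, D, enzymes, config)
    norm = np.abs(res).max()
    state = GolgiState(kin, c, D, c0, config, residual_norm=norm,
                       converged=norm <= tol * 10)
    if not state.converged:
        raise SolverError(
            f"steady-state solve did not converge: max residual {norm:.3e}")
    return state


def linear_abundance_estimate(network, enzymes: EnzymeProfile,
                              config: ReactorConfig) -> dict[str, float]:
    """Rough relative abundances from linearized (far-below-Km) kinetics.

    With denominators fixed at 1 the balances are linear per compartment;
    the estimate for a structure is its maximum concentration across
    compartments relative to c_tot.  Used by abundance-based pruning.
    """
    kin = network if isinstance(network, CompiledKinetics) \
        else compile_kinetics(network)
    n = kin.n_structures
    coef = _rate_coef(kin, enzymes, config)
    c0 = inlet_vector(kin, config)
    best = c0.copy()
    prev = c0
    for j in range(config.n_compartments):
        k_lin = coef[:, j] / kin.Km
        rows = np.concatenate([kin.prod_idx, kin.sub_idx, np.arange(n)])
        cols = np.concatenate([kin.sub_idx, kin.sub_idx, np.arange(n)])
        vals = np.concatenate([-k_lin, k_lin,
                               np.full(n, 1.0 / config.tau[j])])
        M = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        cj = spla.spsolve(M, prev / config.tau[j])
        cj = np.maximum(cj, 0.0)
        best = np.maximum(best, cj)
        prev = cj
    return {s: best[i] / config.c_tot for i, s in enumerate(kin.structures)}


def outlet_abundances(state: GolgiState) -> dict[str, float]:
    """Final-compartment concentrations normalized to sum 1."""
    out = state.c[:, -1]
    total = out.sum()
    if total <= 0:
        raise ValueError("unsolved or empty state")
    return {s: out[i] / total for i, s in enumerate(state.kin.structures)}
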