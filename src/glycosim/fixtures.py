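"""Synthetic experimental-data generator.

Emulates the two experimental inputs end to end so the whole pipeline is
testable without downloads: (1) a raw MALDI spectrum obtained by
forward-simulating a known enzyme profile, convolving each isotope peak
with a Gaussian whose width grows linearly with mass (mass-spectrometer
peak broadening), adding a smooth baseline drift and multiplicative noise;
and (2) a per-enzyme multi-probe microarray-style signal table with chosen
between-condition ratios.  The generating truth is stored alongside so
recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EnzymeProfile, ReactorConfig, load_reference_config
from .golgi import compile_kinetics, outlet_abundances, solve_steady_state
from .isotopes import SyntheticSpectrum, synthesize_spectrum
from .network import GenerationConfig, ReactionNetwork, generate_network, \
    reference_generation_config
from .preprocess import RawSpectrum

__all__ = ["Fixture", "fixture_network", "render_spectrum",
           "generate_fixture", "microarray_fixture"]


def fixture_network(mass_cutoff: float = 2600.0,
                    prune_threshold: float = 1e-4) -> ReactionNetwork:
    """A small reference-rule network (reduced mass cutoff, aggressive
    pruning) sized for tests and fixtures."""
    cfg = reference_generation_config(mass_cutoff=mass_cutoff,
                                      prune_threshold=prune_threshold)
    return generate_network(cfg)


@dataclass
class Fixture:
    profile: EnzymeProfile              # generating truth
    abundances: dict[str, float]        # outlet distribution
    spectrum: SyntheticSpectrum         # noiseless stick spectrum
    raw: RawSpectrum                    # rendered raw spectrum
    microarray: pd.DataFrame | None = None
    seed: int = 0
    network: ReactionNetwork | None = None
    reactor: ReactorConfig | None = None


def render_spectrum(spectrum: SyntheticSpectrum, noise: float = 0.0,
                    baseline: float = 0.0, seed: int = 0,
                    resolution: float = 8000.0, grid_step: float = 0.05,
                    pad: float = 15.0) -> RawSpectrum:
    """Render a stick spectrum to a profile-mode raw spectrum.

    Peaks become Gaussians of FWHM m/resolution (width linear in mass);
    ``baseline`` adds a smooth drift of that fraction of the tallest peak;
    ``noise`` applies multiplicative lognormal-ish noise of that relative
    s.d. per point.  Deterministic for a given seed.
    """
    lo = spectrum.mz.min() - pad
    hi = spectrum.mz.max() + pad
    grid = np.arange(lo, hi, grid_step)
    y = np.zeros_like(grid)
    sigmas = spectrum.mz / (resolution * 2.354820045)
    for mz, area, sigma in zip(spectrum.mz, spectrum.area_pct, sigmas):
        sel = slice(np.searchsorted(grid, mz - 6 * sigma),
                    np.searchsorted(grid, mz + 6 * sigma))
        y[sel] += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -((grid[sel] - mz) ** 2) / (2 * sigma ** 2))
    if baseline > 0:
        amp = baseline * y.max()
        y = y + amp * (0.55 + 0.45 * np.sin(2 * np.pi * (grid - lo) / 617.0))
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y * np.exp(rng.normal(0.0, noise, y.size))
    return RawSpectrum(grid, y)


def generate_fixture(profile: EnzymeProfile | dict[str, float] | None = None,
                     noise: float = 0.0, seed: int = 0,
                     baseline: float = 0.0,
                     network: ReactionNetwork | None = None,
                     reactor: ReactorConfig | None = None,
                     mass_range: tuple[float, float] = (1400.0, 2600.0),
                     microarray_ratios: dict[str, float] | None = None,
                     ) -> Fixture:
    """Forward-simulate a known enzyme profile into a raw spectrum fixture."""
    ref = load_reference_config()
    if reactor is None:
        reactor = ref.reactor
    if profile is None:
        profile = ref.enzymes
    elif isinstance(profile, dict):
        profile = ref.enzymes.with_activity(profile)
    if noise < 0:
        raise ValueError("noise must be nonnegative")
    if network is None:
        network = fixture_network(mass_cutoff=mass_range[1])
    kin = compile_kinetics(network)
    state = solve_steady_state(kin, profile, reactor)
    abundances = outlet_abundances(state)
    spectrum = synthesize_spectrum(abundances, mass_range=mass_range)
    raw = render_spectrum(spectrum, noise=noise, baseline=baseline, seed=seed)
    micro = None
    if microarray_ratios is not None:
        micro = microarray_fixture(microarray_ratios, seed=seed)
    return Fixture(profile, abundances, spectrum, raw, micro, seed,
                   network, reactor)


def microarray_fixture(ratios: dict[str, float], base_signal: float = 100.0,
                       n_probes: int = 3, rel_spread: float = 0.3,
                       seed: int = 0) -> pd.DataFrame:
    """Per-enzyme multi-probe signal table with exact condition ratios.

    Probe base signals are spread deterministically around ``base_signal``;
    condition B signals are exactly ratio x condition A so the computed
    per-enzyme mean ratio equals the requested ratio.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for enzyme, ratio in sorted(ratios.items()):
        if ratio <= 0:
            raise ValueError(f"ratio for {enzyme} must be positive")
        for k in range(n_probes):
            a = base_signal * (1.0 + rel_spread * rng.uniform(-1, 1))
            rows.append({
                "probe_id": f"{enzyme}_p{k}",
                "gene": f"{enzyme.upper()}_GENE{k}",
                "signal_low": round(a, 3),
                "signal_high": round(a * ratio, 3),
                "call_low": "P",
                "call_high": "P",
            })
    return pd.DataFrame(rows)
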