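"""Processing of raw experimental MALDI spectra.

Four stages bring a raw two-column (m/z, intensity) spectrum onto the
model's theoretical mass grid: baseline correction (iterative rolling
minimum plus moving-average smoothing), linear mass calibration (maximize
the summed intensity interpolated at the theoretical peak masses), peak
integration (height at the nearest local maximum; width measured at
exp(-pi/4) ~= 45.6% of height for the largest peaks, then regressed
linearly on mass so every peak gets a width; area = width x height,
normalized to 100%), and nonnegative projection of the observed areas onto
the model isotope envelopes, which discards signal at masses the model
cannot produce.

The exp(-pi/4) fraction is chosen so that width x height equals the exact
area of a Gaussian peak: a Gaussian of s.d. sigma falls to exp(-pi/4) of
its height at half-width w/2 with (w/2)^2/(2 sigma^2) = pi/4, i.e.
w = sigma*sqrt(2*pi), and w * height = area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.optimize import minimize, nnls

__all__ = ["RawSpectrum", "PeakTable", "CalibrationFit", "ProjectedSpectrum",
           "WIDTH_FRACTION", "read_spectrum", "correct_baseline",
           "calibrate_mass", "integrate_peaks", "project_spectrum",
           "filter_isolated_spikes"]

#: fractional height at which peak width is measured
WIDTH_FRACTION = float(np.exp(-np.pi / 4.0))  # 0.4559


@dataclass
class RawSpectrum:
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.mz)))


def read_spectrum(path) -> RawSpectrum:
    """Read whitespace- or comma-delimited two-column (m/z, intensity) text."""
    data = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
    order = np.argsort(data[:, 0])
    return RawSpectrum(data[order, 0], data[order, 1])


def _is_whitespace(path) -> bool:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                return "," not in line
    return True


@dataclass
class CalibrationFit:
    slope: float
    offset: float
    objective: float
    objective_identity: float


@dataclass
class PeakTable:
    masses: np.ndarray          # theoretical masses
    heights: np.ndarray
    widths: np.ndarray
    areas: np.ndarray
    area_pct: np.ndarray        # normalized to 100


@dataclass
class ProjectedSpectrum:
    masses: np.ndarray          # envelope labels (monoisotopic mass each)
    coefficients: np.ndarray    # nonnegative scale per envelope
    fitted: np.ndarray          # fitted observation vector
    residual_norm: float


def correct_baseline(raw: RawSpectrum, window: float = 20.0,
                     iterations: int = 2) -> RawSpectrum:
    """Subtract a slowly varying baseline.

    The baseline is an iterated rolling minimum of width ``window`` (Da)
    smoothed with a moving average of the same width; corrected intensities
    are clipped at zero.
    """
    step = raw.spacing
    size = max(3, int(round(window / step)))
    if window < step:
        raise ValueError("baseline window smaller than the m/z spacing")
    base = raw.intensity.copy()
    for _ in range(iterations):
        base = minimum_filter1d(base, size=size, mode="nearest")
        base = uniform_filter1d(base, size=size, mode="nearest")
    base = np.minimum(base, raw.intensity)
    return RawSpectrum(raw.mz, np.maximum(raw.intensity - base, 0.0))


def calibrate_mass(spectrum: RawSpectrum, theoretical_masses,
                   slope_range: tuple[float, float] = (0.999, 1.001),
                   offset_range: tuple[float, float] = (-2.0, 2.0),
                   grid: int = 21) -> CalibrationFit:
    """Linear mass adjustment m' = a*m + b maximizing the summed intensity
    interpolated at the theoretical masses (coarse grid + Nelder-Mead)."""
    theo = np.asarray(theoretical_masses, dtype=float)
    theo = theo[(theo >= spectrum.mz[0]) & (theo <= spectrum.mz[-1])]
    if theo.size == 0:
        raise ValueError("no theoretical mass inside the spectrum range")

    def objective(params):
        a, b = params
        return -float(np.interp(theo, a * spectrum.mz + b,
                                spectrum.intensity).sum())

    best = (1.0, 0.0)
    best_val = objective(best)
    for a in np.linspace(*slope_range, grid):
        for b in np.linspace(*offset_range, 4 * grid + 1):
            v = objective((a, b))
            if v < best_val:
                best, best_val = (a, b), v
    res = minimize(objective, best, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-12})
    a, b = (res.x if res.fun <= best_val else best)
    obj = -objective((a, b))
    obj0 = -objective((1.0, 0.0))
    if obj < obj0:
        a, b, obj = 1.0, 0.0, obj0
    return CalibrationFit(float(a), float(b), obj, obj0)


def apply_calibration(spectrum: RawSpectrum, fit: CalibrationFit) -> RawSpectrum:
    return RawSpectrum(fit.slope * spectrum.mz + fit.offset,
                       spectrum.intensity)


def _local_max_index(y: np.ndarray, idx: int, lo: int, hi: int) -> int:
    """Index of the local maximum nearest to idx within [lo, hi)."""
    seg = y[lo:hi]
    if seg.size == 0:
        return idx
    candidates = [lo + k for k in range(seg.size)
                  if (k == 0 or seg[k] >= seg[k - 1])
                  and (k == seg.size - 1 or seg[k] >= seg[k + 1])]
    interior = [c for c in candidates if lo < c < hi - 1]
    pool = interior or candidates
    return min(pool, key=lambda c: (abs(c - idx), c))


def _width_at_fraction(spectrum: RawSpectrum, peak_idx: int,
                       fraction: float) -> float | None:
    """Full width of the peak at ``fraction`` of its height, interpolated."""
    y, x = spectrum.intensity, spectrum.mz
    target = y[peak_idx] * fraction
    left = None
    for i in range(peak_idx - 1, -1, -1):
        if y[i] <= target:
            left = np.interp(target, [y[i], y[i + 1]], [x[i], x[i + 1]])
            break
    right = None
    for i in range(peak_idx + 1, len(y)):
        if y[i] <= target:
            right = np.interp(target, [y[i], y[i - 1]], [x[i], x[i - 1]])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def integrate_peaks(spectrum: RawSpectrum, theoretical_masses,
                    search_window: float = 0.4,
                    n_width_peaks: int = 50) -> PeakTable:
    """Estimate areas at the theoretical masses.

    Heights come from the nearest local maximum within ``search_window``
    Da of each theoretical mass; widths are measured at exp(-pi/4) of the
    height for the ``n_width_peaks`` largest peaks and regressed linearly
    on mass to assign a width (hence an area = width x height) to every
    peak.  Areas are normalized to sum to 100%.
    """
    theo = np.asarray(theoretical_masses, dtype=float)
    y, x = spectrum.intensity, spectrum.mz
    heights = np.zeros(theo.size)
    peak_idx = np.full(theo.size, -1)
    for i, m in enumerate(theo):
        lo = int(np.searchsorted(x, m - search_window))
        hi = int(np.searchsorted(x, m + search_window))
        if hi <= lo:
            continue
        idx = int(np.searchsorted(x, m))
        idx = min(max(idx, lo), hi - 1)
        j = _local_max_index(y, idx, lo, hi)
        peak_idx[i] = j
        h = y[j]
        if 0 < j < y.size - 1:
            # parabolic apex refinement removes grid discretization bias
            a, b, c = y[j - 1], y[j], y[j + 1]
            denom = a - 2 * b + c
            if denom < 0:
                h = b - (a - c) ** 2 / (8 * denom)
        heights[i] = h

    order = np.argsort(heights)[::-1]
    w_masses, w_widths = [], []
    for i in order[:n_width_peaks]:
        if heights[i] <= 0 or peak_idx[i] < 0:
            continue
        w = _width_at_fraction(spectrum, int(peak_idx[i]), WIDTH_FRACTION)
        if w is not None and w > 0:
            w_masses.append(theo[i])
            w_widths.append(w)
    if len(w_widths) >= 2 and np.ptp(w_masses) > 0:
        slope, intercept = np.polyfit(w_masses, w_widths, 1)
    elif w_widths:
        slope, intercept = 0.0, float(np.mean(w_widths))
    else:
        slope, intercept = 0.0, spectrum.spacing
    widths = np.maximum(slope * theo + intercept, spectrum.spacing)
    areas = widths * heights
    total = areas.sum()
    pct = 100.0 * areas / total if total > 0 else np.zeros_like(areas)
    return PeakTable(theo, heights, widths, areas, pct)


def filter_isolated_spikes(spectrum: RawSpectrum, isotope_spacing: float = 1.2,
                           min_neighbor_fraction: float = 0.05,
                           height_fraction: float = 0.05) -> RawSpectrum:
    """Drop isolated spikes: points carrying a local peak with no
    neighboring peak within ``isotope_spacing`` Da at >=
    ``min_neighbor_fraction`` of their intensity (real glycan signals have
    isotopic satellites)."""
    y, x = spectrum.intensity.copy(), spectrum.mz
    if y.size < 3:
        return spectrum
    thresh = y.max() * height_fraction
    is_peak = np.r_[False, (y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:]),
                    False] & (y > thresh)
    peak_pos = np.flatnonzero(is_peak)
    for j in peak_pos:
        lo = np.searchsorted(x, x[j] - isotope_spacing)
        hi = np.searchsorted(x, x[j] + isotope_spacing)
        neighborhood = np.r_[y[lo:j], y[j + 1:hi]]
        if neighborhood.size == 0 or neighborhood.max() < y[j] * min_neighbor_fraction:
            y[max(j - 1, 0): j + 2] = 0.0
    return RawSpectrum(x, y)


def project_spectrum(peak_areas, model_envelopes) -> ProjectedSpectrum:
    """Nonnegative least-squares projection of observed peak areas onto the
    model isotope envelopes.

    ``peak_areas`` is a vector of observed areas on a shared mass grid;
    ``model_envelopes`` is a matrix with one column per envelope giving its
    relative abundance at each grid mass (or a dict label -> column).
    Signal at masses in no envelope contributes only to the residual.
    """
    if isinstance(model_envelopes, dict):
        labels = np.array(sorted(model_envelopes))
        A = np.column_stack([model_envelopes[k] for k in labels])
    else:
        A = np.asarray(model_envelopes, dtype=float)
        labels = np.arange(A.shape[1])
    if A.size == 0 or A.shape[1] == 0:
        raise ValueError("empty envelope set")
    b = np.asarray(peak_areas, dtype=float)
    coef, rnorm = nnls(A, b)
    return ProjectedSpectrum(labels, coef, A @ coef, float(rnorm))
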