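"""Gaussian band-fitting estimates of secondary structure.

Two classical baselines against which reference-set fitting is compared:

* *direct fitting* — baseline the Amide I band with a straight 1600-1700
  cm^-1 line, then least-squares fit a sum of Gaussians whose initial centres
  come from minima of the second-derivative spectrum;
* *second-derivative fitting* — fit Gaussians to minus the second derivative
  (negative parts clipped to zero) instead of the absorbance itself.

Either way, structure is quantified by normalising the total fitted band area
to 1 and summing areas of bands falling in the consensus windows:
1620-1640 cm^-1 sheet, 1650-1656 cm^-1 helix; 1640-1650 cm^-1 and the
1670-1685 cm^-1 turn region (and anything unassigned) count as "other".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, savgol_filter

from .spectra import Spectrum, StructureFractions

__all__ = [
    "GaussianBand",
    "StructureWindows",
    "second_derivative",
    "pick_band_centers",
    "fit_gaussians",
    "structure_from_bands",
    "fit_direct_method",
    "fit_second_derivative_method",
    "FitError",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class FitError(RuntimeError):
    """Band fit failed to converge or had nothing to fit."""


@dataclass(frozen=True)
class GaussianBand:
    """One fitted component band, parameterised by sigma (not FWHM)."""

    center: float      # cm^-1
    amplitude: float   # absorbance (or -d2 units)
    sigma: float       # cm^-1
    degenerate: bool = False   # amplitude pinned at the zero bound

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma

    def evaluate(self, wn: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wn - self.center) / self.sigma) ** 2)


@dataclass(frozen=True)
class StructureWindows:
    """Band-centre windows assigning fitted bands to structure classes.

    Windows are closed intervals; centres outside every window, in the
    turn region, or in the 1640-1650 cm^-1 gap count as "other".
    """

    sheet: tuple[float, float] = (1620.0, 1640.0)
    helix: tuple[float, float] = (1650.0, 1656.0)
    turns: tuple[float, float] = (1670.0, 1685.0)   # counted into other

    def classify(self, center: float) -> str:
        if self.sheet[0] <= center <= self.sheet[1]:
            return "sheet"
        if self.helix[0] <= center <= self.helix[1]:
            return "helix"
        return "other"


def _uniform_spacing(s: Spectrum) -> float:
    d = np.diff(s.wavenumbers)
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValueError("second derivative requires a uniform wavenumber grid")
    return float(d[0])


def second_derivative(s: Spectrum, window_pts: int = 9, polyorder: int = 3
                      ) -> Spectrum:
    """Savitzky-Golay second derivative d2A/dv2 on a uniform grid."""
    if window_pts % 2 == 0 or window_pts <= polyorder:
        raise ValueError("window_pts must be odd and > polyorder")
    delta = _uniform_spacing(s)
    d2 = savgol_filter(s.absorbance, window_pts, polyorder, deriv=2, delta=delta)
    return s.with_absorbance(d2)


def pick_band_centers(d2: Spectrum, min_prominence: float = 0.0
                      ) -> list[float]:
    """Local minima of the second derivative below -min_prominence.

    These are the classical initial band-centre candidates (absorption
    maxima appear as negative d2 lobes). Returned ascending; empty when the
    spectrum has no qualifying minima.
    """
    peaks, _ = find_peaks(-d2.absorbance, height=min_prominence
                          if min_prominence > 0 else 1e-300)
    return sorted(float(d2.wavenumbers[i]) for i in peaks)


def _pack(bands):
    return np.concatenate([[b.center for b in bands],
                           [b.amplitude for b in bands],
                           [b.sigma for b in bands]])


def fit_gaussians(
    s: Spectrum,
    centers,
    center_bound: float = 8.0,
    sigma_bounds: tuple[float, float] = (2.0, 20.0),
    max_nfev: int = 2000,
    ftol: float = 1e-10,
) -> tuple[list[GaussianBand], float, list[float]]:
    """Least-squares fit of a sum of Gaussians to a baselined band.

    Centres are bounded to +-center_bound of their initial guesses, sigmas to
    sigma_bounds and amplitudes to >= 0 (a band pinned at zero amplitude is
    flagged degenerate). Returns (bands sorted by centre, residual sum of
    squares, per-iteration residual trace).
    """
    centers = [float(c) for c in centers]
    if not centers:
        raise FitError("no initial band centres supplied")
    wn, ab = s.wavenumbers, s.absorbance
    n = len(centers)
    amp0 = np.maximum(np.interp(centers, wn, ab), 1e-12)
    sig0 = np.full(n, np.clip(6.0, *sigma_bounds))
    x0 = np.concatenate([centers, amp0, sig0])
    lb = np.concatenate([np.array(centers) - center_bound,
                         np.zeros(n), np.full(n, sigma_bounds[0])])
    ub = np.concatenate([np.array(centers) + center_bound,
                         np.full(n, np.inf), np.full(n, sigma_bounds[1])])

    def model(x):
        c, a, sg = x[:n], x[n:2 * n], x[2 * n:]
        return (a[:, None] * np.exp(
            -0.5 * ((wn[None, :] - c[:, None]) / sg[:, None]) ** 2)).sum(axis=0)

    def resid(x):
        return model(x) - ab

    trace: list[float] = []

    def _log(intermediate_result):
        trace.append(2.0 * float(intermediate_result.cost))  # cost = RSS/2

    res = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                        max_nfev=max_nfev, ftol=ftol, xtol=1e-12, gtol=1e-12,
                        callback=_log)
    if not res.success and res.status == 0:
        raise FitError(f"band fit did not converge; residual trace: {trace}")
    c, a, sg = res.x[:n], res.x[n:2 * n], res.x[2 * n:]
    bands = [GaussianBand(float(ci), float(ai), float(si),
                          degenerate=bool(ai <= 1e-12))
             for ci, ai, si in zip(c, a, sg)]
    bands.sort(key=lambda b: b.center)
    rss = 2.0 * float(res.cost)
    trace.append(rss)
    return bands, rss, trace


def structure_from_bands(bands, windows: StructureWindows | None = None
                         ) -> StructureFractions:
    """Fractions = window area sums / total area over all fitted bands."""
    windows = windows if windows is not None else StructureWindows()
    areas = {"helix": 0.0, "sheet": 0.0, "other": 0.0}
    total = 0.0
    for b in bands:
        a = b.area
        if a < 0:
            raise ValueError("negative band area")
        areas[windows.classify(b.center)] += a
        total += a
    if total <= 0:
        raise ValueError("zero total band area; nothing to quantify")
    return StructureFractions(areas["helix"] / total, areas["sheet"] / total,
                              areas["other"] / total)


def fit_direct_method(s: Spectrum, windows: StructureWindows | None = None,
                      min_prominence: float = 0.0, window_pts: int = 9,
                      polyorder: int = 3):
    """Direct Gaussian fit of the baselined Amide I band.

    Returns (fractions, bands, rss). The input must already be baselined on
    1600-1700 cm^-1 (see :func:`irsom.preprocess.baseline_linear`).
    """
    d2 = second_derivative(s, window_pts, polyorder)
    centers = pick_band_centers(d2, min_prominence)
    if not centers:
        raise FitError("no band centres found in the second derivative")
    bands, rss, _ = fit_gaussians(s, centers)
    return structure_from_bands(bands, windows), bands, rss


def fit_second_derivative_method(
    s: Spectrum, windows: StructureWindows | None = None,
    min_prominence: float = 0.0, window_pts: int = 9, polyorder: int = 3,
):
    """Gaussian fit of minus the second derivative (negatives clipped).

    Returns (fractions, bands, rss). For equal-width bands this preserves
    the area ratios of the underlying absorbance bands, since the negative
    lobe of a Gaussian's second derivative scales as amplitude/sigma^2.
    """
    d2 = second_derivative(s, window_pts, polyorder)
    target = d2.with_absorbance(np.clip(-d2.absorbance, 0.0, None))
    centers = pick_band_centers(d2, min_prominence)
    if not centers:
        raise FitError("no band centres found in the second derivative")
    bands, rss, _ = fit_gaussians(target, centers)
    return structure_from_bands(bands, windows), bands, rss
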