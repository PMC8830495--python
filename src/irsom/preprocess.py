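"""Spectral conditioning ahead of structure fitting.

The pipeline mirrors standard aqueous-protein FTIR practice: interpolate to a
common grid, subtract a scaled solvent reference (the scale chosen so the
difference is flat in the ~2,100 cm^-1 water libration region), check the
water-vapour diagnostic integrals, draw a straight baseline across the Amide I
band, and normalise to 1 at the Amide I maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, SpectrumError

__all__ = [
    "PreprocessReport",
    "interpolate_to_grid",
    "baseline_linear",
    "normalize_amide1",
    "subtract_scaled_reference",
    "vapour_integral",
    "AMIDE1_WINDOW",
    "FLAT_WINDOW",
    "VAPOUR_REGIONS",
]

AMIDE1_WINDOW = (1600.0, 1700.0)
FLAT_WINDOW = (2050.0, 2150.0)
VAPOUR_REGIONS = ((1717.0, 1772.0), (3800.0, 3900.0))


@dataclass
class PreprocessReport:
    """Diagnostics logged by the preprocessing steps (fields filled as used)."""

    water_scale: float | None = None          # reference subtraction factor k
    flatness_residual: float | None = None    # RSS about best line, flat window
    vapour_integral: float | None = None      # absorbance * cm^-1
    normalisation_factor: float | None = None
    baseline_endpoints: tuple | None = None   # ((lo, A_lo), (hi, A_hi))


def _check_in_span(s: Spectrum, lo: float, hi: float, what: str) -> None:
    s_lo, s_hi = s.span
    if lo < s_lo or hi > s_hi:
        raise SpectrumError(
            f"{what} [{lo}, {hi}] outside spectrum span [{s_lo}, {s_hi}]"
        )


def interpolate_to_grid(s: Spectrum, grid) -> Spectrum:
    """Linearly resample onto ``grid``; no extrapolation allowed."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
        grid = np.sort(np.atleast_1d(grid).ravel())
    _check_in_span(s, float(grid[0]), float(grid[-1]), "target grid")
    return Spectrum(grid, np.interp(grid, s.wavenumbers, s.absorbance), s.label)


def _value_at(s: Spectrum, wn: float) -> float:
    return float(np.interp(wn, s.wavenumbers, s.absorbance))


def baseline_linear(
    s: Spectrum, lo: float = 1600.0, hi: float = 1700.0
) -> tuple[Spectrum, PreprocessReport]:
    """Subtract the straight line through the spectrum at lo and hi.

    The output is restricted to [lo, hi] and vanishes at both anchors.
    """
    if lo >= hi:
        raise ValueError(f"baseline anchors must satisfy lo < hi (got {lo}, {hi})")
    _check_in_span(s, lo, hi, "baseline window")
    a_lo, a_hi = _value_at(s, lo), _value_at(s, hi)
    w = s.window(lo, hi)
    line = a_lo + (a_hi - a_lo) * (w.wavenumbers - lo) / (hi - lo)
    rep = PreprocessReport(baseline_endpoints=((lo, a_lo), (hi, a_hi)))
    return w.with_absorbance(w.absorbance - line), rep


def normalize_amide1(
    s: Spectrum, window: tuple[float, float] = AMIDE1_WINDOW
) -> tuple[Spectrum, float]:
    """Divide by the maximum absorbance in the Amide I window.

    Returns the normalised spectrum and the divisor, so the original can be
    recovered. The window maximum of the output is exactly 1.
    """
    lo, hi = window
    _check_in_span(s, lo, hi, "Amide I window")
    m = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    peak = float(s.absorbance[m].max())
    if peak <= 0:
        raise ValueError(f"non-positive Amide I maximum ({peak}); cannot normalise")
    return s.with_absorbance(s.absorbance / peak), peak


def _detrend_projector(wn: np.ndarray) -> np.ndarray:
    """Projector onto the orthogonal complement of span{1, wavenumber}."""
    x = np.column_stack([np.ones_like(wn), wn])
    q, _ = np.linalg.qr(x)
    return np.eye(wn.size) - q @ q.T


def subtract_scaled_reference(
    s: Spectrum,
    ref: Spectrum,
    flat_window: tuple[float, float] = FLAT_WINDOW,
) -> tuple[Spectrum, PreprocessReport]:
    """Subtract k * ref, with k chosen so the result is flat near 2,100 cm^-1.

    "Flat" means minimal residual sum of squares about the best straight line
    inside ``flat_window``; k has the closed form of a least-squares
    projection, so the solution is deterministic.
    """
    lo, hi = flat_window
    _check_in_span(s, lo, hi, "flat window")
    _check_in_span(ref, lo, hi, "flat window (reference)")
    sw = s.window(lo, hi)
    rw_ab = np.interp(sw.wavenumbers, ref.wavenumbers, ref.absorbance)
    proj = _detrend_projector(sw.wavenumbers)
    ps, pr = proj @ sw.absorbance, proj @ rw_ab
    denom = float(pr @ pr)
    # relative threshold: a reference that is (numerically) a straight line in
    # the window carries no flatness information
    if denom <= 1e-12 * max(float(rw_ab @ rw_ab), 1e-300):
        raise ValueError(
            "reference has no non-linear structure in the flat window; "
            "cannot determine a subtraction scale"
        )
    k = float(ps @ pr) / denom
    resid = ps - k * pr
    ref_on_s = np.interp(s.wavenumbers, ref.wavenumbers, ref.absorbance)
    out = s.with_absorbance(s.absorbance - k * ref_on_s)
    rep = PreprocessReport(water_scale=k, flatness_residual=float(resid @ resid))
    return out, rep


def vapour_integral(
    s: Spectrum, region: tuple[float, float] = VAPOUR_REGIONS[0]
) -> float:
    """Trapezoidal integral of |absorbance| over a water-vapour region.

    Diagnostic only — large values flag inadequate vapour subtraction; no
    automatic correction is applied.
    """
    lo, hi = region
    _check_in_span(s, lo, hi, "vapour region")
    m = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    wn = s.wavenumbers[m]
    ab = s.absorbance[m]
    # include interpolated endpoint values so the integral covers exactly [lo, hi]
    if wn.size == 0 or wn[0] > lo:
        wn = np.insert(wn, 0, lo)
        ab = np.insert(ab, 0, _value_at(s, lo))
    if wn[-1] < hi:
        wn = np.append(wn, hi)
        ab = np.append(ab, _value_at(s, hi))
    return float(np.trapezoid(np.abs(ab), wn))
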