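"""ATR <-> transmission conversion for aqueous protein spectra.

ATR band intensities are weighted by the wavenumber-dependent penetration
depth of the evanescent wave,

    d_p(v) = 1 / (2*pi*v*n1*sqrt(sin^2(theta) - (n2/n1)^2)),

so a measured ATR absorbance relates to the transmission-equivalent one (path
length l) through

    A_ATR = A_T * (d_p*f / l) * (1 - ln(10)*d_p*f*(eC)_water),

where f is a light-intensity factor and (eC)_water = A_water/l is the
water absorbance per unit path (the dominant absorber, so its d_p*f governs
the correction term). The forward and inverse conversions are exact pointwise
inverses of each other, and since both are linear in the protein absorbance,
spectra that are subsequently normalised at the Amide I maximum need no
knowledge of concentration, extinction coefficient or path length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import normalize_amide1
from .spectra import Spectrum

__all__ = [
    "ATRGeometry",
    "WaterAbsorbanceModel",
    "penetration_depth",
    "atr_to_transmission",
    "transmission_to_atr",
    "normalised_conversion",
    "GeometryError",
    "SaturationError",
]

LN10 = math.log(10.0)


class GeometryError(ValueError):
    """No total internal reflection for the given indices/angle."""


class SaturationError(ValueError):
    """Water absorption saturates the conversion denominator."""


@dataclass(frozen=True)
class ATRGeometry:
    """Single-bounce ATR geometry (defaults: ZnSe crystal, aqueous sample, 45 deg).

    intensity_factor multiplies the penetration depth wherever d_p appears
    (the combination d_p*f is what the conversion equations use);
    path_length_cm is the transmission-equivalent path l.
    """

    crystal_index: float = 2.43      # n1, ZnSe
    sample_index: float = 1.33       # n2, water
    incidence_angle_deg: float = 45.0
    intensity_factor: float = 1.0    # f
    path_length_cm: float = 1.0      # l

    def __post_init__(self) -> None:
        if not (self.crystal_index > self.sample_index > 0):
            raise GeometryError("need n1 > n2 > 0")
        if self.intensity_factor <= 0 or self.path_length_cm <= 0:
            raise ValueError("intensity_factor and path_length_cm must be > 0")
        if math.sin(math.radians(self.incidence_angle_deg)) <= (
            self.sample_index / self.crystal_index
        ):
            raise GeometryError(
                "incidence angle at or below the critical angle: "
                "no total internal reflection"
            )


@dataclass(frozen=True)
class WaterAbsorbanceModel:
    """(eC)_water = A_water / l on a wavenumber grid, interpolated as needed."""

    grid: np.ndarray
    epsilonC: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        e = np.asarray(self.epsilonC, dtype=float)
        if g.shape != e.shape or g.ndim != 1:
            raise ValueError("grid and epsilonC must be 1-D and equal length")
        if np.any(e < 0):
            raise ValueError("epsilonC must be non-negative")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "epsilonC", e)

    def on_grid(self, wavenumbers: np.ndarray) -> np.ndarray:
        if (wavenumbers.min() < self.grid.min()
                or wavenumbers.max() > self.grid.max()):
            raise ValueError("water model does not cover the conversion window")
        return np.interp(wavenumbers, self.grid, self.epsilonC)

    @classmethod
    def zero(cls, lo: float = 900.0, hi: float = 4000.0) -> "WaterAbsorbanceModel":
        """Water-free limit (useful for dry films and algebraic checks)."""
        g = np.array([lo, hi])
        return cls(g, np.zeros_like(g))

    @classmethod
    def flat(cls, value: float, lo: float = 900.0, hi: float = 4000.0
             ) -> "WaterAbsorbanceModel":
        """SYNTHETIC constant-(eC) placeholder for testing only; real water
        absorbance is strongly wavenumber dependent."""
        g = np.array([lo, hi])
        return cls(g, np.full_like(g, float(value)))


def penetration_depth(wavenumber, g: ATRGeometry) -> np.ndarray | float:
    """Evanescent-wave penetration depth d_p in cm (wavenumber in cm^-1)."""
    v = np.asarray(wavenumber, dtype=float)
    if np.any(v <= 0):
        raise ValueError("wavenumber must be positive")
    theta = math.radians(g.incidence_angle_deg)
    root = math.sin(theta) ** 2 - (g.sample_index / g.crystal_index) ** 2
    if root <= 0:
        raise GeometryError("at or below the critical angle")
    dp = 1.0 / (2.0 * math.pi * v * g.crystal_index * math.sqrt(root))
    return float(dp) if np.isscalar(wavenumber) else dp


def _denominator(wn: np.ndarray, water: WaterAbsorbanceModel, g: ATRGeometry
                 ) -> tuple[np.ndarray, np.ndarray]:
    dpf = penetration_depth(wn, g) * g.intensity_factor
    denom = 1.0 - LN10 * dpf * water.on_grid(wn)
    if np.any(denom <= 0):
        bad = wn[denom <= 0]
        raise SaturationError(
            "conversion denominator non-positive (water absorption saturates "
            f"the evanescent field) at wavenumbers {bad[:5].tolist()}"
            + ("..." if bad.size > 5 else "")
        )
    return dpf, denom


def atr_to_transmission(atr: Spectrum, water: WaterAbsorbanceModel,
                        g: ATRGeometry) -> Spectrum:
    """A_T(v) = A_ATR(v) * l / (d_p(v)*f * (1 - ln10*d_p(v)*f*(eC)_water(v)))."""
    dpf, denom = _denominator(atr.wavenumbers, water, g)
    out = atr.absorbance * g.path_length_cm / (dpf * denom)
    return atr.with_absorbance(out)


def transmission_to_atr(trans: Spectrum, water: WaterAbsorbanceModel,
                        g: ATRGeometry) -> Spectrum:
    """Exact pointwise inverse of :func:`atr_to_transmission`."""
    dpf, denom = _denominator(trans.wavenumbers, water, g)
    out = trans.absorbance * dpf * denom / g.path_length_cm
    return trans.with_absorbance(out)


def normalised_conversion(s: Spectrum, water: WaterAbsorbanceModel,
                          g: ATRGeometry, direction: str,
                          window: tuple[float, float] = (1600.0, 1700.0)
                          ) -> Spectrum:
    """Convert and renormalise to 1 at the Amide I maximum.

    The result is independent of the path length and of any overall scaling
    of the input, so concentration/extinction knowledge is unnecessary.
    """
    if direction == "atr2trans":
        conv = atr_to_transmission(s, water, g)
    elif direction == "trans2atr":
        conv = transmission_to_atr(s, water, g)
    else:
        raise ValueError(f"direction must be 'atr2trans' or 'trans2atr', "
                         f"got {direction!r}")
    out, _ = normalize_amide1(conv, window)
    return out
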