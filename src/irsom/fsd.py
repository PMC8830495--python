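"""Fourier self-deconvolution (FSD) band narrowing.

The spectrum is taken to the conjugate (retardation) domain, multiplied by
the inverse transform of an assumed Lorentzian line shape of half-width gamma
— exp(2*pi*gamma*|x|), which boosts high retardation and thus narrows bands —
and by a triangular-squared apodization that tapers to zero at a fraction
``smoothing`` of the maximum retardation to keep noise amplification in
check. smoothing = 1 disables the apodization entirely, so gamma = 0 with
smoothing = 1 is the identity. A deconvolved spectrum is conventionally
re-zeroed (minimum to 0) and re-normalised (maximum to 1) before further use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

__all__ = ["FSDParams", "fsd", "rezero_renormalize", "FSDParameterError"]

_EXP_GUARD = 700.0  # beyond this, exp overflows double precision


class FSDParameterError(ValueError):
    """gamma/smoothing combination would overflow the deconvolution filter."""


@dataclass(frozen=True)
class FSDParams:
    """gamma: Lorentzian HWHM to deconvolve (cm^-1); smoothing in (0, 1]."""

    gamma: float = 10.0
    smoothing: float = 0.25

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.smoothing <= 1):
            raise ValueError("smoothing must be in (0, 1]")


def _uniform_spacing(wn: np.ndarray) -> float:
    d = np.diff(wn)
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValueError("FSD requires a uniform wavenumber grid")
    return float(d[0])


def fsd(s: Spectrum, p: FSDParams) -> Spectrum:
    """Self-deconvolve a spectrum; output on the original grid.

    The spectrum is mean-padded to a power of two at least twice its length
    before the transform to suppress wrap-around, and the padding is removed
    afterwards. The operation is linear in the input.
    """
    if not np.all(np.isfinite(s.absorbance)):
        raise ValueError("spectrum must be finite for FSD")
    delta = _uniform_spacing(s.wavenumbers)
    n = s.absorbance.size
    n_pad = 1 << max(1, math.ceil(math.log2(2 * n)))
    padded = np.full(n_pad, float(s.absorbance.mean()))
    padded[:n] = s.absorbance

    # retardation axis of the real FFT: x_k = k / (n_pad * delta), in cm
    x = np.fft.rfftfreq(n_pad, d=delta)
    x_max = x[-1]

    boost_arg = 2.0 * math.pi * p.gamma * min(p.smoothing * x_max, x_max)
    if boost_arg > _EXP_GUARD:
        raise FSDParameterError(
            f"gamma={p.gamma} with smoothing={p.smoothing} amplifies the "
            "highest retained retardation beyond the overflow guard; "
            "reduce gamma or the smoothing factor"
        )
    if p.smoothing < 1.0:
        cutoff = p.smoothing * x_max
        apod = np.clip(1.0 - x / cutoff, 0.0, None) ** 2
        # evaluate the boost only where the apodization is non-zero, so a
        # large gamma outside the retained band cannot overflow
        filt = np.where(apod > 0.0,
                        np.exp(2.0 * math.pi * p.gamma * np.minimum(x, cutoff)),
                        0.0) * apod
    else:
        filt = np.exp(2.0 * math.pi * p.gamma * x)

    spec = np.fft.rfft(padded)
    out = np.fft.irfft(spec * filt, n=n_pad)[:n]
    return s.with_absorbance(out)


def rezero_renormalize(s: Spectrum) -> Spectrum:
    """Shift the minimum to 0 and scale the maximum to 1.

    Affine-invariant: any a + b*spectrum (b > 0) maps to the same output.
    """
    lo = float(s.absorbance.min())
    hi = float(s.absorbance.max())
    if hi - lo <= 0:
        raise ValueError("constant spectrum cannot be re-normalised")
    return s.with_absorbance((s.absorbance - lo) / (hi - lo))
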