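"""Synthetic Amide I spectra with known secondary-structure fractions.

Spectra are structure-weighted mixtures of class basis bands at the consensus
Amide I positions: helix at ~1654 cm^-1, sheet as a major ~1631 plus minor
~1678 cm^-1 pair (4:1 area ratio), and a broad ~1645 cm^-1 band for "other"
(turn bands fold into "other", matching three-class reporting). Each class
basis is normalised to unit area so a fraction mixture is area-faithful.
Per-spectrum band-centre jitter and additive Gaussian noise emulate
sample-to-sample and instrument variation; every spectrum is normalised to 1
at its Amide I maximum, as measured spectra are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import ReferenceSet, Spectrum, StructureFractions

__all__ = ["SyntheticModel", "sample_fractions", "synth_spectrum",
           "make_reference_set", "default_grid"]


def default_grid(lo: float = 1600.0, hi: float = 1700.0,
                 step: float = 2.0) -> np.ndarray:
    """Amide I wavenumber grid, 2 cm^-1 spacing by default (51 points)."""
    return np.arange(lo, hi + step / 2, step)


@dataclass(frozen=True)
class SyntheticModel:
    """Band model for synthetic Amide I spectra.

    Centers (cm^-1) follow the consensus assignments; widths are Gaussian
    sigmas chosen to give realistically broad, overlapping solution bands.
    noise_sd is additive absorbance noise (relative to a unit-peak spectrum);
    center_jitter_sd shifts each band's centre per spectrum.
    """

    helix_center: float = 1654.0
    helix_sigma: float = 7.0
    sheet_major_center: float = 1631.0
    sheet_major_sigma: float = 6.0
    sheet_minor_center: float = 1678.0
    sheet_minor_sigma: float = 5.0
    sheet_minor_weight: float = 0.2      # 4:1 major:minor area ratio
    other_center: float = 1645.0
    other_sigma: float = 12.0
    center_jitter_sd: float = 1.0
    noise_sd: float = 0.005
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        for s in (self.helix_sigma, self.sheet_major_sigma,
                  self.sheet_minor_sigma, self.other_sigma):
            if s <= 0:
                raise ValueError("band sigmas must be positive")


def _unit_area_gaussian(grid: np.ndarray, center: float, sigma: float
                        ) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2) / (
        sigma * np.sqrt(2 * np.pi)
    )


def _class_bases(m: SyntheticModel, jitter: np.ndarray) -> np.ndarray:
    """(3, n_pts) unit-area basis bands with per-band centre offsets."""
    g = m.grid
    helix = _unit_area_gaussian(g, m.helix_center + jitter[0], m.helix_sigma)
    sheet = ((1 - m.sheet_minor_weight)
             * _unit_area_gaussian(g, m.sheet_major_center + jitter[1],
                                   m.sheet_major_sigma)
             + m.sheet_minor_weight
             * _unit_area_gaussian(g, m.sheet_minor_center + jitter[2],
                                   m.sheet_minor_sigma))
    other = _unit_area_gaussian(g, m.other_center + jitter[3], m.other_sigma)
    return np.stack([helix, sheet, other])


def sample_fractions(n: int, seed: int | None = None) -> list[StructureFractions]:
    """n fractions drawn uniformly on the 2-simplex (ordered-spacings)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = np.sort(rng.uniform(size=(n, 2)), axis=1)
    out = []
    for a, b in u:
        out.append(StructureFractions(float(a), float(b - a), float(1.0 - b)))
    return out


def synth_spectrum(f: StructureFractions, m: SyntheticModel | None = None,
                   seed: int | None = None, label: str = "synthetic"
                   ) -> Spectrum:
    """One synthetic Amide I spectrum for given structure fractions.

    absorbance = f.helix*B_helix + f.sheet*B_sheet + f.other*B_other with
    per-spectrum centre jitter and additive noise, normalised to max 1.
    """
    m = m if m is not None else SyntheticModel()
    rng = np.random.default_rng(seed)
    jitter = (rng.normal(0.0, m.center_jitter_sd, size=4)
              if m.center_jitter_sd > 0 else np.zeros(4))
    bases = _class_bases(m, jitter)
    ab = f.as_array() @ bases
    if m.noise_sd > 0:
        # noise is specified relative to a unit-peak spectrum
        ab = ab + rng.normal(0.0, m.noise_sd * ab.max(), size=ab.size)
    peak = ab.max()
    if peak <= 0:
        raise ValueError("degenerate synthetic spectrum (non-positive peak)")
    return Spectrum(m.grid, ab / peak, label)


def make_reference_set(n: int, m: SyntheticModel | None = None,
                       seed: int | None = None) -> ReferenceSet:
    """n synthetic members with their true fractions on the shared grid."""
    if n < 2:
        raise ValueError("a reference set needs n >= 2")
    m = m if m is not None else SyntheticModel()
    ss = np.random.SeedSequence(seed)
    frac_seed, *member_seeds = ss.spawn(n + 1)
    fractions = sample_fractions(n, seed=frac_seed)
    members = []
    for i, (f, mseed) in enumerate(zip(fractions, member_seeds)):
        s = synth_spectrum(f, m, seed=mseed, label=f"S{i + 1:03d}")
        members.append((s.label, s.absorbance, f))
    return ReferenceSet(m.grid.copy(), members)
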