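"""Core containers: spectra, secondary-structure fractions, reference sets.

A :class:`Spectrum` is absorbance on a strictly monotonic wavenumber grid
(cm^-1); wavenumbers are stored ascending regardless of input order.
:class:`StructureFractions` is a point on the 2-simplex over (helix, sheet,
other), where helix counts alpha- plus 3_10-helix and "other" is everything
else, so other = 1 - helix - sheet by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "StructureFractions",
    "ReferenceSet",
    "SpectrumError",
    "ValidationError",
]

#: Tolerance for the simplex-sum invariant of StructureFractions.
FRACTION_SUM_TOL = 1e-6


class SpectrumError(ValueError):
    """Malformed spectrum (grid/absorbance mismatch, non-monotonic grid...)."""


class ValidationError(ValueError):
    """Domain invariant violated (fractions off the simplex, bad set...)."""


@dataclass(frozen=True)
class Spectrum:
    """Absorbance values on a wavenumber grid.

    Parameters
    ----------
    wavenumbers : array-like
        Strictly monotonic grid in cm^-1 (either direction; stored ascending).
    absorbance : array-like
        Dimensionless absorbance, same length as the grid.
    label : str
        Free-text identifier.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise SpectrumError("wavenumbers and absorbance must be 1-D")
        if wn.size != ab.size:
            raise SpectrumError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbances"
            )
        if wn.size < 3:
            raise SpectrumError("a spectrum needs at least 3 points")
        d = np.diff(wn)
        if np.all(d < 0):  # descending input: flip to ascending
            wn, ab = wn[::-1], ab[::-1]
        elif not np.all(d > 0):
            raise SpectrumError("wavenumber grid must be strictly monotonic")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def window(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to grid points with lo <= wavenumber <= hi."""
        m = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if m.sum() < 3:
            raise SpectrumError(f"window [{lo}, {hi}] contains <3 grid points")
        return Spectrum(self.wavenumbers[m], self.absorbance[m], self.label)

    def with_absorbance(self, ab: np.ndarray, label: str | None = None) -> "Spectrum":
        return Spectrum(self.wavenumbers, ab, self.label if label is None else label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.label == other.label
            and np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.absorbance, other.absorbance)
        )


@dataclass(frozen=True)
class StructureFractions:
    """Per-residue fractions of helix (alpha + 3_10), beta-sheet and other.

    The three fractions live on the unit simplex; "other" is always
    1 - helix - sheet and the constructor enforces the sum within 1e-6.
    """

    helix: float
    sheet: float
    other: float

    def __post_init__(self) -> None:
        vals = (self.helix, self.sheet, self.other)
        for name, v in zip(("helix", "sheet", "other"), vals):
            if not np.isfinite(v) or v < -FRACTION_SUM_TOL or v > 1 + FRACTION_SUM_TOL:
                raise ValidationError(f"{name} fraction {v!r} outside [0, 1]")
        s = sum(vals)
        if abs(s - 1.0) > FRACTION_SUM_TOL:
            raise ValidationError(f"fractions sum to {s}, not 1")

    @classmethod
    def from_helix_sheet(cls, helix: float, sheet: float) -> "StructureFractions":
        return cls(helix, sheet, 1.0 - helix - sheet)

    @classmethod
    def from_array(cls, a) -> "StructureFractions":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.helix, self.sheet, self.other], dtype=float)


@dataclass
class ReferenceSet:
    """Reference spectra with known structure fractions on a shared grid.

    members are (label, absorbance vector, StructureFractions) triples; every
    absorbance vector lies on ``grid``.
    """

    grid: np.ndarray
    members: list[tuple[str, np.ndarray, StructureFractions]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 3:
            raise ValidationError("grid must be 1-D with >= 3 points")
        if not np.all(np.diff(self.grid) > 0):
            raise ValidationError("grid must be strictly ascending")
        if len(self.members) < 2:
            raise ValidationError("a reference set needs at least 2 members")
        norm = []
        for label, ab, f in self.members:
            ab = np.asarray(ab, dtype=float)
            if ab.shape != self.grid.shape:
                raise ValidationError(
                    f"member {label!r}: {ab.size} values on a {self.grid.size}-point grid"
                )
            if not isinstance(f, StructureFractions):
                f = StructureFractions.from_array(f)
            norm.append((str(label), ab, f))
        self.members = norm

    def __len__(self) -> int:
        return len(self.members)

    @property
    def labels(self) -> list[str]:
        return [m[0] for m in self.members]

    def spectra_matrix(self) -> np.ndarray:
        """(N, n_points) matrix of member absorbances."""
        return np.stack([m[1] for m in self.members])

    def fractions_matrix(self) -> np.ndarray:
        """(N, 3) matrix of (helix, sheet, other)."""
        return np.stack([m[2].as_array() for m in self.members])

    def spectrum(self, i: int) -> Spectrum:
        label, ab, _ = self.members[i]
        return Spectrum(self.grid, ab, label)

    def drop(self, i: int) -> "ReferenceSet":
        """Copy of the set without member i (for leave-one-out folds)."""
        kept = [m for j, m in enumerate(self.members) if j != i]
        return ReferenceSet(self.grid, kept)
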