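"""Reading and writing the columnar training/test text format.

A training file holds an N-member reference set as N vertical comma-separated
columns of spectral data with the corresponding structure rows (helix, sheet,
other) placed below the spectral block. Two dialects are supported:

* ``grid="embedded"`` (default on write): spectral rows carry the wavenumber
  as an extra first field, so spectral rows have N+1 fields and structure rows
  have N — the blocks are self-delimiting.
* ``grid=<array>``: plain N-column files; the last 3 rows are the structure
  block and the caller supplies the grid.

Test files are the same minus the structure block. Generic single-spectrum
I/O uses two-column (wavenumber, absorbance) delimited text with ``#``
comments. Numbers are written with 9 significant digits, dot decimal
separator only.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .spectra import ReferenceSet, Spectrum, StructureFractions, ValidationError

__all__ = [
    "read_training_file",
    "write_training_file",
    "read_test_file",
    "write_test_file",
    "read_spectrum",
    "write_spectrum",
    "write_predictions_csv",
    "FormatError",
]

_FMT = "%.9g"


class FormatError(ValueError):
    """File does not conform to the columnar text dialect."""


def _parse_cell(tok: str, where: str) -> float:
    tok = tok.strip()
    try:
        return float(tok)
    except ValueError:
        raise FormatError(f"{where}: cannot parse {tok!r} as a number "
                          "(dot decimal separator required)") from None


def _read_rows(path) -> tuple[list[list[float]], list[str]]:
    rows: list[list[float]] = []
    labels: list[str] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if stripped[1:].strip().lower().startswith("labels:"):
                    labels = [t.strip() for t in
                              stripped.split(":", 1)[1].split(",")]
                continue
            toks = stripped.split(",")
            rows.append([_parse_cell(t, f"line {lineno}") for t in toks])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return rows, labels


def read_training_file(path, grid=None) -> ReferenceSet:
    """Parse a columnar training file into a :class:`ReferenceSet`.

    Parameters
    ----------
    path : path-like
    grid : array-like, optional
        Wavenumber grid for the plain N-column dialect. When omitted the
        file must embed the grid as the first field of each spectral row.
    """
    rows, labels = _read_rows(path)
    widths = {len(r) for r in rows}
    if grid is None:
        if len(widths) != 2:
            raise FormatError(
                f"{path}: embedded-grid dialect needs spectral rows of N+1 "
                f"fields and structure rows of N; found row widths {sorted(widths)}"
            )
        wide, narrow = max(widths), min(widths)
        if wide != narrow + 1:
            raise FormatError(f"{path}: ragged columns (widths {sorted(widths)})")
        spectral = [r for r in rows if len(r) == wide]
        structure = [r for r in rows if len(r) == narrow]
        if structure != rows[-3:] or len(structure) != 3:
            raise FormatError(
                f"{path}: expected exactly 3 trailing structure rows, "
                f"found {len(structure)} narrow rows"
            )
        g = np.array([r[0] for r in spectral])
        data = np.array([r[1:] for r in spectral])
        n = narrow
    else:
        if len(widths) != 1:
            raise FormatError(f"{path}: ragged columns (widths {sorted(widths)})")
        if len(rows) < 4:
            raise FormatError(f"{path}: too few rows for spectra + 3 structure rows")
        g = np.asarray(grid, dtype=float)
        spectral, structure = rows[:-3], rows[-3:]
        if len(spectral) != g.size:
            raise FormatError(
                f"{path}: {len(spectral)} spectral rows on a {g.size}-point grid"
            )
        data = np.array(spectral)
        n = len(rows[0])

    frac_rows = np.array(structure)  # 3 rows x N columns: helix, sheet, other
    if labels and len(labels) != n:
        raise FormatError(f"{path}: {len(labels)} labels for {n} columns")
    if not labels:
        labels = [f"P{j + 1:02d}" for j in range(n)]

    members = []
    for j in range(n):
        h, s, o = frac_rows[:, j]
        try:
            f = StructureFractions(h, s, o)
        except ValidationError as e:
            raise ValidationError(f"{path}: column {labels[j]!r}: {e}") from None
        members.append((labels[j], data[:, j], f))
    return ReferenceSet(g, members)


def write_training_file(refset: ReferenceSet, path) -> None:
    """Write a reference set in the embedded-grid columnar dialect."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# columnar training file: wavenumber + N absorbance columns,\n")
        fh.write("# then 3 structure rows (helix, sheet, other)\n")
        fh.write("# labels: " + ",".join(refset.labels) + "\n")
        mat = refset.spectra_matrix()  # (N, n_pts)
        for i, wn in enumerate(refset.grid):
            fields = [_FMT % wn] + [_FMT % v for v in mat[:, i]]
            fh.write(",".join(fields) + "\n")
        fr = refset.fractions_matrix()  # (N, 3)
        for k in range(3):
            fh.write(",".join(_FMT % v for v in fr[:, k]) + "\n")


def read_test_file(path, grid=None) -> list[Spectrum]:
    """Read test spectra (one per column, no structure block)."""
    rows, labels = _read_rows(path)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged columns (widths {sorted(widths)})")
    data = np.array(rows)
    if grid is None:
        g = data[:, 0]
        data = data[:, 1:]
        if data.shape[1] == 0:
            raise FormatError(f"{path}: embedded-grid test file needs >= 2 columns")
    else:
        g = np.asarray(grid, dtype=float)
        if data.shape[0] != g.size:
            raise FormatError(
                f"{path}: {data.shape[0]} values per column on a "
                f"{g.size}-point grid"
            )
    n = data.shape[1]
    if not labels:
        labels = [f"T{j + 1:02d}" for j in range(n)]
    return [Spectrum(g, data[:, j], labels[j]) for j in range(n)]


def write_test_file(spectra: list[Spectrum], path) -> None:
    """Write test spectra in the embedded-grid dialect (shared grid required)."""
    g = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, g):
            raise FormatError("test spectra must share a grid")
    with open(path, "w", newline="") as fh:
        fh.write("# labels: " + ",".join(s.label for s in spectra) + "\n")
        for i, wn in enumerate(g):
            fields = [_FMT % wn] + [_FMT % s.absorbance[i] for s in spectra]
            fh.write(",".join(fields) + "\n")


def read_spectrum(path, label: str | None = None) -> Spectrum:
    """Read a generic two-column (wavenumber, absorbance) text spectrum.

    Comma, tab or whitespace delimited; '#' starts a comment.
    """
    wn, ab = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            toks = stripped.replace(",", " ").replace("\t", " ").split()
            if len(toks) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            wn.append(_parse_cell(toks[0], f"line {lineno}"))
            ab.append(_parse_cell(toks[1], f"line {lineno}"))
    return Spectrum(np.array(wn), np.array(ab),
                    label if label is not None else Path(path).stem)


def write_spectrum(s: Spectrum, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {s.label}\n# wavenumber_cm-1, absorbance\n")
        for wn, ab in zip(s.wavenumbers, s.absorbance):
            fh.write(f"{_FMT % wn},{_FMT % ab}\n")


def write_predictions_csv(results, path) -> None:
    """Export PredictionResults as CSV: label, fractions, NRMSD, BMU list."""
    results = list(results)
    k = max(len(r.bmus) for r in results)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["label", "helix", "sheet", "other", "nrmsd"]
        header += [f"bmu{i + 1}" for i in range(k)] + [f"d{i + 1}" for i in range(k)]
        w.writerow(header)
        for r in results:
            row = [r.label, _FMT % r.fractions.helix, _FMT % r.fractions.sheet,
                   _FMT % r.fractions.other, _FMT % r.nrmsd]
            coords = [f"({n[0]};{n[1]})" for n, _ in r.bmus]
            dists = [_FMT % d for _, d in r.bmus]
            row += coords + [""] * (k - len(coords)) + dists + [""] * (k - len(dists))
            w.writerow(row)
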