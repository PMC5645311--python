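"""Core data types and delimited-text readers/writers.

Conventions
-----------
* Wavelengths are nanometres (float, strictly ascending). Magnetic fields use
  the same container with a millitesla axis; the axis label records which.
* Times always carry a unit tag, one of ``"s"``, ``"us"``, ``"ns"``; mixing
  seconds-scale steady-state data with microsecond transient-absorption data
  is the main foot-gun of this analysis, so units are explicit everywhere and
  never converted silently.
* File dialect: delimited text (comma or tab, auto-detected). For a 2-D
  matrix the first column holds the wavelength (or field) axis and the header
  row the time axis, each time cell prefixed with its unit tag, e.g.
  ``t_us=12.5``. Files are self-describing and human-readable.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from lovspec.errors import ParseError, SpectralRangeError, ValidationError

TIME_UNITS = ("s", "us", "ns")

#: aliases accepted on input (the canonical tag is always ASCII)
_UNIT_ALIASES = {"µs": "us", "μs": "us", "usec": "us", "nsec": "ns", "sec": "s"}


def _canon_unit(unit: str) -> str:
    unit = _UNIT_ALIASES.get(unit, unit)
    if unit not in TIME_UNITS:
        raise ValidationError(
            f"unknown time unit {unit!r}; expected one of {TIME_UNITS}"
        )
    return unit


def _as_float_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")
    return arr


def _check_strictly_increasing(arr: np.ndarray, name: str) -> None:
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class Spectrum:
    """An absorbance (or ΔA) spectrum on a strictly ascending wavelength grid.

    ``wavelengths`` are nm for optical spectra; EPR field-swept spectra reuse
    the container with a mT axis and ``axis_label="B_mT"``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    label: str = ""
    axis_label: str = "wavelength_nm"

    def __post_init__(self):
        wl = _as_float_1d(self.wavelengths, "wavelengths")
        vals = _as_float_1d(self.values, "values")
        if wl.size != vals.size:
            raise ValidationError(
                f"wavelengths ({wl.size}) and values ({vals.size}) differ in length"
            )
        if wl.size == 0:
            raise ValidationError("empty spectrum")
        _check_strictly_increasing(wl, "wavelengths")
        wl.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values, label: str | None = None) -> "Spectrum":
        return Spectrum(
            self.wavelengths,
            values,
            self.label if label is None else label,
            self.axis_label,
        )


@dataclass(frozen=True)
class TimeTrace:
    """A signal sampled on a strictly increasing time axis with a unit tag."""

    times: np.ndarray
    values: np.ndarray
    unit: str
    label: str = ""

    def __post_init__(self):
        t = _as_float_1d(self.times, "times")
        vals = _as_float_1d(self.values, "values")
        if t.size != vals.size:
            raise ValidationError(
                f"times ({t.size}) and values ({vals.size}) differ in length"
            )
        if t.size == 0:
            raise ValidationError("empty trace")
        _check_strictly_increasing(t, "times")
        unit = _canon_unit(self.unit)
        t.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "unit", unit)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SpectralMatrix:
    """A 2-D dataset A(λ, t): rows are wavelengths, columns are times."""

    wavelengths: np.ndarray
    times: np.ndarray
    values: np.ndarray
    time_unit: str
    label: str = ""
    axis_label: str = "wavelength_nm"

    def __post_init__(self):
        wl = _as_float_1d(self.wavelengths, "wavelengths")
        t = _as_float_1d(self.times, "times")
        if wl.size == 0 or t.size == 0:
            raise ValidationError("matrix must have at least one row and one column")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (wl.size, t.size):
            raise ValidationError(
                f"values shape {vals.shape} != (len(wavelengths), len(times)) "
                f"= ({wl.size}, {t.size})"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("matrix contains non-finite entries")
        _check_strictly_increasing(wl, "wavelengths")
        _check_strictly_increasing(t, "times")
        unit = _canon_unit(self.time_unit)
        for a in (wl, t, vals):
            a.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "time_unit", unit)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, index: int, label: str = "") -> Spectrum:
        """The spectrum at time index ``index``."""
        return Spectrum(self.wavelengths, self.values[:, index], label, self.axis_label)

    def row(self, index: int, label: str = "") -> TimeTrace:
        """The time trace at wavelength index ``index``."""
        return TimeTrace(self.times, self.values[index, :], self.time_unit, label)


@dataclass
class SpeciesBasis:
    """Named reference spectra on one shared wavelength grid.

    Canonical names used across the package: ``FMNox``, ``FMNHrad``,
    ``TrpRad``, ``TyrORad``, ``Triplet``. User-defined names are allowed.
    """

    spectra: dict[str, Spectrum] = field(default_factory=dict)

    def __post_init__(self):
        grid = None
        for name, spec in self.spectra.items():
            if grid is None:
                grid = spec.wavelengths
            elif not np.array_equal(spec.wavelengths, grid):
                raise ValidationError(
                    f"reference {name!r} is not on the shared wavelength grid"
                )

    @property
    def grid(self) -> np.ndarray:
        if not self.spectra:
            raise ValidationError("empty basis")
        return next(iter(self.spectra.values())).wavelengths

    @property
    def names(self) -> list[str]:
        return list(self.spectra)

    def __getitem__(self, name: str) -> Spectrum:
        return self.spectra[name]

    def __contains__(self, name: str) -> bool:
        return name in self.spectra

    def add(self, name: str, spectrum: Spectrum) -> None:
        if name in self.spectra:
            raise ValidationError(f"duplicate reference name {name!r}")
        if self.spectra and not np.array_equal(spectrum.wavelengths, self.grid):
            raise ValidationError(
                f"reference {name!r} is not on the shared wavelength grid"
            )
        self.spectra[name] = spectrum

    def subset(self, names: Iterable[str]) -> "SpeciesBasis":
        return SpeciesBasis({n: self.spectra[n] for n in names})

    def matrix(self) -> np.ndarray:
        """References stacked as columns, shape (n_wavelengths, n_species)."""
        return np.column_stack([s.values for s in self.spectra.values()])


# ---------------------------------------------------------------------------
# delimited-text I/O


def _sniff_delimiter(sample: str) -> str:
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def _parse_time_header(cell: str, col: int) -> tuple[float, str]:
    cell = cell.strip()
    if "=" not in cell or not cell.startswith("t_"):
        raise ParseError(
            f"column {col}: time header {cell!r} must look like 't_<unit>=<value>'"
        )
    tag, _, value = cell.partition("=")
    unit = _canon_unit(tag[2:])
    try:
        return float(value), unit
    except ValueError as exc:
        raise ParseError(f"column {col}: non-numeric time {value!r}") from exc


def _parse_cell(cell: str, row: int, col: int) -> float:
    try:
        val = float(cell)
    except ValueError as exc:
        raise ParseError(f"row {row}, column {col}: non-numeric cell {cell!r}") from exc
    if not np.isfinite(val):
        raise ParseError(f"row {row}, column {col}: non-finite cell {cell!r}")
    return val


def read_spectral_matrix(path: str | Path) -> SpectralMatrix:
    """Read a 2-D wavelength × time matrix from delimited text.

    Rows/columns may appear in any order; both axes are sorted ascending and
    the data re-ordered accordingly. Duplicate wavelengths or times are an
    error (fail loudly rather than average).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    reader = csv.reader(_stdio.StringIO(text), delimiter=delim)
    rows = [r for r in reader if r and any(c.strip() for c in r)]
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")

    header = rows[0]
    axis_label = header[0].strip() or "wavelength_nm"
    times, units = [], set()
    for j, cell in enumerate(header[1:], start=1):
        t, unit = _parse_time_header(cell, j)
        times.append(t)
        units.add(unit)
    if len(units) != 1:
        raise ParseError(f"{path}: mixed time units in header: {sorted(units)}")
    unit = units.pop()

    wavelengths, data = [], []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: row {i} has {len(row)} cells, expected {len(header)}"
            )
        wavelengths.append(_parse_cell(row[0], i, 0))
        data.append([_parse_cell(c, i, j) for j, c in enumerate(row[1:], start=1)])

    wl = np.asarray(wavelengths)
    t = np.asarray(times)
    vals = np.asarray(data)

    order_wl = np.argsort(wl, kind="stable")
    order_t = np.argsort(t, kind="stable")
    wl, t = wl[order_wl], t[order_t]
    vals = vals[np.ix_(order_wl, order_t)]
    if np.any(np.diff(wl) == 0):
        dup = wl[np.flatnonzero(np.diff(wl) == 0)[0]]
        raise ValidationError(f"{path}: duplicate wavelength row {dup}")
    if np.any(np.diff(t) == 0):
        dup = t[np.flatnonzero(np.diff(t) == 0)[0]]
        raise ValidationError(f"{path}: duplicate time column {dup}")

    return SpectralMatrix(wl, t, vals, unit, label=path.stem, axis_label=axis_label)


def write_spectral_matrix(
    matrix: SpectralMatrix, path: str | Path, delimiter: str = ","
) -> None:
    """Write a matrix in the self-describing dialect read by
    :func:`read_spectral_matrix`; round-trips values to ≤1e-9 relative."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        header = [matrix.axis_label] + [
            f"t_{matrix.time_unit}={float(t)!r}" for t in matrix.times
        ]
        writer.writerow(header)
        for wl, row in zip(matrix.wavelengths, matrix.values):
            writer.writerow([repr(float(wl))] + [repr(float(v)) for v in row])


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column (axis, value) delimited file; header row optional."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    rows = [
        r
        for r in csv.reader(_stdio.StringIO(text), delimiter=delim)
        if r and any(c.strip() for c in r)
    ]
    axis_label = "wavelength_nm"
    start = 0
    try:
        float(rows[0][0])
    except ValueError:
        axis_label = rows[0][0].strip() or axis_label
        start = 1
    wl, vals = [], []
    for i, row in enumerate(rows[start:], start=start):
        if len(row) < 2:
            raise ParseError(f"{path}: row {i} needs two columns")
        wl.append(_parse_cell(row[0], i, 0))
        vals.append(_parse_cell(row[1], i, 1))
    order = np.argsort(wl, kind="stable")
    wl = np.asarray(wl)[order]
    if np.any(np.diff(wl) == 0):
        raise ValidationError(f"{path}: duplicate axis value")
    return Spectrum(wl, np.asarray(vals)[order], label=path.stem, axis_label=axis_label)


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = ",") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([spectrum.axis_label, spectrum.label or "value"])
        for wl, v in zip(spectrum.wavelengths, spectrum.values):
            writer.writerow([repr(float(wl)), repr(float(v))])


def read_trace(path: str | Path) -> TimeTrace:
    """Read a two-column trace; the header's first cell must be ``t_<unit>``."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    rows = [
        r
        for r in csv.reader(_stdio.StringIO(text), delimiter=delim)
        if r and any(c.strip() for c in r)
    ]
    head = rows[0][0].strip()
    if not head.startswith("t_"):
        raise ParseError(f"{path}: trace header must start with 't_<unit>', got {head!r}")
    unit = _canon_unit(head[2:])
    times, vals = [], []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) < 2:
            raise ParseError(f"{path}: row {i} needs two columns")
        times.append(_parse_cell(row[0], i, 0))
        vals.append(_parse_cell(row[1], i, 1))
    order = np.argsort(times, kind="stable")
    t = np.asarray(times)[order]
    if np.any(np.diff(t) == 0):
        raise ValidationError(f"{path}: duplicate time value")
    return TimeTrace(t, np.asarray(vals)[order], unit, label=path.stem)


def write_trace(trace: TimeTrace, path: str | Path, delimiter: str = ",") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([f"t_{trace.unit}", trace.label or "value"])
        for t, v in zip(trace.times, trace.values):
            writer.writerow([repr(float(t)), repr(float(v))])


def interpolate_to_grid(spectrum: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (nm).

    Extrapolation is refused: the grid must lie within the source range.
    Exact at shared grid points; exact for affine spectra.
    """
    grid = _as_float_1d(grid, "grid")
    _check_strictly_increasing(grid, "grid")
    if grid.size == 0:
        raise ValidationError("empty target grid")
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise SpectralRangeError(
            f"grid [{grid[0]}, {grid[-1]}] nm extends beyond data range "
            f"[{lo}, {hi}] nm; extrapolation is not supported"
        )
    values = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return Spectrum(grid, values, spectrum.label, spectrum.axis_label)


def basis_on_grid(basis: SpeciesBasis, grid) -> SpeciesBasis:
    """Interpolate every member of a basis onto a common grid."""
    return SpeciesBasis(
        {name: interpolate_to_grid(s, grid) for name, s in basis.spectra.items()}
    )
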