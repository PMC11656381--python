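"""Core spectrum container and two-column text I/O.

A spectrum is a pair of equal-length vectors: an abscissa ``x`` in
technique-specific units (wavenumber cm^-1 for Raman/IR, wavelength nm for
UV-vis, diffraction angle 2-theta degrees for XRD) and an intensity ``y``
in arbitrary units.  Every processing stage in this package consumes and
produces :class:`Spectrum` objects, so the invariants enforced here
(strictly increasing x, finite values, length >= 2) hold throughout a
pipeline.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "normalize",
    "crop",
    "write_peak_table",
    "read_peak_table",
]

PEAK_TABLE_COLUMNS = ("center", "amplitude", "width1", "width2", "family")


class SpectrumFormatError(ValueError):
    """Raised when a file or array cannot form a valid spectrum."""


@dataclass(frozen=True)
class Spectrum:
    """Paired x / intensity vectors with axis metadata.

    Parameters
    ----------
    x : ndarray
        Strictly increasing abscissa, length >= 2, all finite.
    y : ndarray
        Intensity at each ``x``, same length, all finite.
    x_label, y_label : str
        Axis annotations carried through the pipeline (not interpreted).
    """

    x: np.ndarray
    y: np.ndarray
    x_label: str = "x"
    y_label: str = "intensity"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1:
            raise SpectrumFormatError("x and y must be one-dimensional")
        if x.size != y.size:
            raise SpectrumFormatError(
                f"length mismatch: {x.size} x-values vs {y.size} intensities"
            )
        if x.size < 2:
            raise SpectrumFormatError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise SpectrumFormatError("non-finite values in spectrum")
        dx = np.diff(x)
        if np.any(dx == 0):
            bad = x[1:][dx == 0][0]
            # duplicates are rejected (not averaged) so finite-difference
            # operators downstream stay well-defined
            raise SpectrumFormatError(
                f"duplicate x value {bad!r}: duplicate abscissa points make "
                "derivative-based stages ill-defined; merge or drop them first"
            )
        if np.any(dx < 0):
            raise SpectrumFormatError("x must be strictly increasing")

    def __len__(self) -> int:
        return self.x.size

    @property
    def span(self) -> float:
        return float(self.x[-1] - self.x[0])

    def grid_step(self) -> float:
        """Mean grid spacing (exact step for uniform grids)."""
        return self.span / (len(self) - 1)

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        dx = np.diff(self.x)
        return bool(np.all(np.abs(dx - dx.mean()) <= rtol * abs(dx.mean())))

    def with_y(self, y: np.ndarray) -> "Spectrum":
        return replace(self, y=np.asarray(y, dtype=float))


def _sorted_spectrum(x: np.ndarray, y: np.ndarray, **kw) -> Spectrum:
    order = np.argsort(x, kind="stable")
    return Spectrum(x[order], y[order], **kw)


def read_spectrum(path, delimiter: str | None = None) -> Spectrum:
    """Read a two-column (x, intensity) text file.

    The first column is the x-axis.  Lines starting with ``#`` and blank
    lines are skipped.  When ``delimiter`` is None the separator is
    auto-detected among whitespace, comma, and tab.  Rows are sorted by x;
    exact duplicate x values raise :class:`SpectrumFormatError`.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise IOError(f"cannot read spectrum file {path!r}: {exc}") from exc

    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delimiter is not None:
            parts = [p for p in line.split(delimiter) if p.strip()]
        elif "," in line:
            parts = [p for p in line.split(",") if p.strip()]
        else:
            parts = line.split()  # handles spaces and tabs alike
        if len(parts) < 2:
            raise SpectrumFormatError(
                f"{path}:{lineno}: expected two columns, got {line!r}"
            )
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(
                f"{path}:{lineno}: non-numeric row {line!r}"
            ) from exc

    if len(xs) < 2:
        raise SpectrumFormatError(
            f"{path}: fewer than 2 parseable data rows"
        )
    return _sorted_spectrum(np.array(xs), np.array(ys))


def write_spectrum(s: Spectrum, path) -> None:
    """Write a spectrum as two-column text, round-trippable by
    :func:`read_spectrum` to within 1e-9 relative."""
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {s.x_label}\t{s.y_label}\n")
            for xi, yi in zip(s.x, s.y):
                fh.write(f"{xi:.12g}\t{yi:.12g}\n")
    except OSError as exc:
        raise IOError(f"cannot write spectrum to {path!r}: {exc}") from exc


def normalize(s: Spectrum) -> Spectrum:
    """Scale intensities so that max(y) == 1; x is unchanged.

    Raises ValueError for an all-zero signal (no scale is defined).
    """
    m = float(np.max(s.y))
    if m <= 0.0:
        raise ValueError(
            "cannot normalize: maximum intensity is not positive"
        )
    return s.with_y(s.y / m)


def crop(s: Spectrum, x_min: float, x_max: float) -> Spectrum:
    """Restrict to the closed interval [x_min, x_max], order preserved."""
    if not x_min < x_max:
        raise ValueError(f"x_min ({x_min}) must be < x_max ({x_max})")
    mask = (s.x >= x_min) & (s.x <= x_max)
    if int(mask.sum()) < 2:
        raise ValueError(
            f"crop [{x_min}, {x_max}] leaves fewer than 2 points of the "
            f"spectrum spanning [{s.x[0]}, {s.x[-1]}]"
        )
    return replace(s, x=s.x[mask], y=s.y[mask])


def write_peak_table(decomposition, path) -> None:
    """Write fitted components as a TSV peak table.

    Columns: center, amplitude, width1 (Gaussian sigma), width2
    (Lorentzian gamma), family.  Widths not used by a family are blank.
    An empty decomposition yields a header-only file.
    """
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(PEAK_TABLE_COLUMNS) + "\n")
            for comp in decomposition.components:
                w1 = "" if comp.sigma is None else f"{comp.sigma:.9g}"
                w2 = "" if comp.gamma is None else f"{comp.gamma:.9g}"
                fh.write(
                    f"{comp.center:.9g}\t{comp.amplitude:.9g}\t{w1}\t{w2}\t"
                    f"{comp.family}\n"
                )
    except OSError as exc:
        raise IOError(f"cannot write peak table to {path!r}: {exc}") from exc


def read_peak_table(path) -> list[dict]:
    """Read a TSV peak table back into a list of row dicts."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for raw in fh:
            if not raw.strip():
                continue
            vals = raw.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            for key in ("center", "amplitude", "width1", "width2"):
                row[key] = float(row[key]) if row.get(key) else None
            rows.append(row)
    return rows
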