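"""Spectrum container, CSV I/O and absorption-band detection.

A :class:`Spectrum` is a wavelength grid (nm, strictly ascending) with an
absorbance trace (AU).  Band maxima are located with a prominence filter and
refined to sub-grid precision by a three-point parabolic fit, which is the
standard treatment for smooth electronic absorption bands sampled on a
nanometre grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Spectrum",
    "SpectrumFormatError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "find_band_maxima",
    "ct_band_shift_check",
]

#: default peak prominence as a fraction of the global maximum; resolves the
#: three UV bands of the bundled donor scenario without picking up noise.
DEFAULT_PROMINENCE_FRAC = 0.05


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file or array pair is malformed."""


@dataclass
class Spectrum:
    """Absorbance trace on a strictly ascending wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly ascending, length >= 2.
    absorbance : array of float
        Absorbance in AU, same length as ``wavelengths``.
    metadata : dict
        Free-form label map (sample id, scenario name, flags).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.absorbance.ndim != 1:
            raise SpectrumFormatError("wavelengths and absorbance must be 1-D")
        if self.wavelengths.size != self.absorbance.size:
            raise SpectrumFormatError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.absorbance.size} absorbances"
            )
        if self.wavelengths.size < 2:
            raise SpectrumFormatError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(self.wavelengths)) and np.all(np.isfinite(self.absorbance))):
            raise SpectrumFormatError("spectrum contains non-finite values")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectrumFormatError("wavelengths must be strictly ascending")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a two-column ``wavelength_nm,absorbance`` CSV.

    Lines starting with ``#`` are comments.  Rows in descending wavelength
    order are sorted (a warning is issued and ``metadata['sorted']`` set);
    duplicate wavelengths or non-numeric entries raise
    :class:`SpectrumFormatError` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SpectrumFormatError(f"{path}: file is empty") from exc
    if df.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: expected 2 columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: one for the header row, one for 1-based line numbering
        line = int(numeric.index[bad][0]) + 2
        raise SpectrumFormatError(f"{path}: non-numeric value at line {line}")
    wl = numeric.iloc[:, 0].to_numpy()
    ab = numeric.iloc[:, 1].to_numpy()
    dup = pd.Index(wl).duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise SpectrumFormatError(f"{path}: duplicate wavelength at line {line}")
    meta = {"source": str(path)}
    if np.any(np.diff(wl) < 0):
        order = np.argsort(wl)
        wl, ab = wl[order], ab[order]
        meta["sorted"] = True
        warnings.warn(f"{path}: wavelengths were not ascending; sorted", stacklevel=2)
    return Spectrum(wl, ab, meta)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write the fixed two-column dialect ``wavelength_nm,absorbance``."""
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbance}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine the maximum at grid index ``i`` with a parabola through its
    two neighbours; falls back to the grid point for degenerate curvature.
    Ties break toward the shorter wavelength."""
    xs, ys = x[i - 1 : i + 2], y[i - 1 : i + 2]
    a, b, c = np.polyfit(xs, ys, 2)
    if a >= 0:  # flat or upward curvature: keep the grid point
        return float(x[i]), float(y[i])
    xv = -b / (2.0 * a)
    if not (xs[0] <= xv <= xs[2]):
        return float(x[i]), float(y[i])
    return float(xv), float(a * xv * xv + b * xv + c)


def find_band_maxima(
    s: Spectrum, prominence_frac: float = DEFAULT_PROMINENCE_FRAC
) -> list[tuple[float, float]]:
    """Locate absorption-band maxima.

    Local maxima with prominence >= ``prominence_frac`` x the global maximum
    absorbance are kept and refined by three-point parabolic interpolation.
    Returns ``(wavelength_nm, absorbance)`` pairs sorted by wavelength; an
    all-flat spectrum yields an empty list.
    """
    if prominence_frac < 0:
        raise ValueError("prominence_frac must be non-negative")
    y = s.absorbance
    ymax = float(np.max(y))
    if ymax <= 0 or np.allclose(y, y[0]):
        return []
    peaks, _ = find_peaks(y, prominence=prominence_frac * ymax)
    out = [_parabolic_refine(s.wavelengths, y, int(i)) for i in peaks]
    out.sort(key=lambda t: t[0])
    return out


def ct_band_shift_check(
    reaction: Spectrum,
    donor: Spectrum,
    acceptor: Spectrum,
    min_shift_nm: float = 10.0,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> list[tuple[float, float]]:
    """Report new bands in a reaction spectrum.

    A maximum of the reaction spectrum counts as *new* when no maximum of
    either reactant spectrum lies within ``min_shift_nm`` of it.  The
    appearance of such a band in the visible region is the classic signature
    of charge-transfer complex formation.

    Raises ``ValueError`` if the reactant grids do not overlap the reaction
    grid.
    """
    lo = max(s.wavelengths[0] for s in (reaction, donor, acceptor))
    hi = min(s.wavelengths[-1] for s in (reaction, donor, acceptor))
    if lo >= hi:
        raise ValueError("spectra wavelength grids do not overlap")
    rx = find_band_maxima(reaction, prominence_frac)
    known = [w for s in (donor, acceptor) for w, _ in find_band_maxima(s, prominence_frac)]
    new = [
        (w, a)
        for w, a in rx
        if all(abs(w - k) >= min_shift_nm for k in known)
    ]
    return new
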