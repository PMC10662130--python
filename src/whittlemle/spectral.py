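"""Standardization and one-sided periodogram estimation.

The periodogram used throughout the package is the raw squared-modulus
DFT of the z-scored series on the bounded Fourier-frequency grid

    omega_j = 2*pi*j / N,   j = 1, ..., m,   m = floor((N - 1) / 2),

with the power doubled so that the one-sided spectrum conserves total
power over (0, pi).  The DC term is excluded (it vanishes after
centering) and, for even N, so is the Nyquist frequency.  No
zero-padding, tapering or segment averaging is applied: the transform
length equals the series length, so the grid is exact for any N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LengthError, ZeroVarianceError

__all__ = [
    "Periodogram",
    "standardize",
    "fourier_bound",
    "periodogram",
    "read_series",
    "write_periodogram",
]

#: Minimum series length accepted by the estimation pipeline.
MIN_LENGTH = 8


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values (NaN/inf); "
                         "missing data are not imputed")
    return x


def standardize(x) -> np.ndarray:
    """Z-score a series: mean 0, sample standard deviation 1 (ddof=1).

    Parameters
    ----------
    x : array-like
        Univariate real series of length >= 2.

    Returns
    -------
    numpy.ndarray
        Standardized copy of ``x``.

    Raises
    ------
    LengthError
        If the series has fewer than 2 points.
    ZeroVarianceError
        If the series is constant.
    """
    x = _as_series(x)
    if x.size < 2:
        raise LengthError(f"need at least 2 points to standardize, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ZeroVarianceError("series is constant; cannot standardize")
    return (x - x.mean()) / sd


def fourier_bound(n: int) -> int:
    """Upper index m = floor((n - 1) / 2) of the retained frequency grid.

    For a power-of-2 length this excludes the Nyquist frequency; e.g.
    ``fourier_bound(1024) == 511``.
    """
    n = int(n)
    if n < 3:
        raise LengthError(f"need n >= 3 for a non-empty frequency grid, got {n}")
    return (n - 1) // 2


@dataclass(frozen=True)
class Periodogram:
    """One-sided periodogram on the bounded Fourier grid.

    Attributes
    ----------
    omega : numpy.ndarray
        Angular frequencies 2*pi*j/n_source, j = 1..m (radians/sample).
    power : numpy.ndarray
        Doubled one-sided power at each frequency; strictly positive for
        non-degenerate inputs.
    n_source : int
        Length of the series the periodogram was computed from.
    """

    omega: np.ndarray
    power: np.ndarray
    n_source: int

    @property
    def m(self) -> int:
        return self.omega.size

    def __post_init__(self):
        if self.omega.size != self.power.size:
            raise ValueError("omega and power must have equal length")
        if self.omega.size != fourier_bound(self.n_source):
            raise ValueError("grid length does not match floor((n_source-1)/2)")


def periodogram(x, *, assume_standardized: bool = False) -> Periodogram:
    """Estimate the one-sided periodogram of a series.

    The series is z-scored first (unless ``assume_standardized``), then

        P(omega_j) = (1 / (pi * N)) * |FFT(x)_j|^2,   j = 1..m,

    which equals the doubled two-sided value 2*(1/(2*pi*N))*|DFT|^2.

    Parameters
    ----------
    x : array-like
        Series of length >= 8.
    assume_standardized : bool
        Skip the internal z-scoring (caller guarantees mean 0, sd 1).

    Returns
    -------
    Periodogram
    """
    x = _as_series(x)
    n = x.size
    if n < MIN_LENGTH:
        raise LengthError(f"need at least {MIN_LENGTH} points, got {n}")
    if not assume_standardized:
        x = standardize(x)
    m = fourier_bound(n)
    y = np.fft.rfft(x)  # length-n transform, bins 0..floor(n/2)
    power = np.abs(y[1 : m + 1]) ** 2 / (np.pi * n)
    omega = 2.0 * np.pi * np.arange(1, m + 1) / n
    return Periodogram(omega=omega, power=power, n_source=n)


def read_series(path, column: str | None = None) -> np.ndarray:
    """Read a univariate series from plain text or CSV.

    Plain text is one float per line. For CSV, ``column`` selects a named
    column; without it the first (or only) column is used, and a
    non-numeric first row is treated as a header.
    """
    path = Path(path)
    if column is not None:
        return _as_series(pd.read_csv(path)[column].to_numpy())
    try:
        return _as_series(np.loadtxt(path, delimiter=None, ndmin=1))
    except ValueError:
        pass
    frame = pd.read_csv(path)
    return _as_series(frame.iloc[:, 0].to_numpy())


def write_periodogram(pg: Periodogram, path) -> None:
    """Write a periodogram as two-column CSV (omega, power)."""
    pd.DataFrame({"omega": pg.omega, "power": pg.power}).to_csv(path, index=False)
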