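"""Closed-form model power spectral densities.

Two stationary long-memory families share the same low-frequency decay
``omega**(-2*d)`` with ``d = H - 1/2``:

* fractional Gaussian noise (fGn), parameterized by the Hurst exponent
  ``H`` in (0, 1):   ``sin(H*pi) * Gamma(2H+1) * omega**(1-2H)``;
* ARFIMA(0, d, 0), parameterized by ``d`` in (-1/2, 1/2):
  ``(1/(2*pi)) * (2*sin(omega/2))**(-2d)``.

Both are normalized for unit-variance (z-scored) processes; any global
scale mismatch is absorbed by the proportionality constant fitted in the
Whittle objective.  The three-parameter ARFIMA(p, d, q) spectrum adds
the squared moduli of AR and MA transfer polynomials and is provided for
evaluation and surrogate generation only (its parameters are not
estimated here).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

from .errors import DomainError

__all__ = [
    "Family",
    "SpectralModel",
    "fgn_psd",
    "arfima_psd",
    "arfima_pdq_psd",
    "h_to_d",
    "d_to_h",
]


class Family(str, enum.Enum):
    """Spectral model family."""

    FGN = "fgn"
    ARFIMA0D0 = "arfima"
    ARFIMAPDQ = "arfimapdq"


def h_to_d(H: float) -> float:
    """Convert a Hurst exponent to the fractional-integration order d = H - 1/2."""
    return H - 0.5


def d_to_h(d: float) -> float:
    """Convert a fractional-integration order to the Hurst exponent H = d + 1/2."""
    return d + 0.5


def _check_omega(omega) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if omega.size and (np.min(omega) <= 0.0 or np.max(omega) > np.pi + 1e-12):
        raise DomainError("frequencies must lie in (0, pi]")
    return omega


def fgn_psd(H: float, omega) -> np.ndarray:
    """Theoretical fGn spectral density sin(H*pi)*Gamma(2H+1)*|omega|**(1-2H).

    Parameters
    ----------
    H : float
        Hurst exponent, strictly inside (0, 1).
    omega : array-like
        Angular frequencies in (0, pi].
    """
    if not 0.0 < H < 1.0:
        raise DomainError(f"H must lie in (0, 1), got {H}")
    omega = _check_omega(omega)
    return np.sin(np.pi * H) * _gamma(2.0 * H + 1.0) * np.abs(omega) ** (1.0 - 2.0 * H)


def arfima_psd(d: float, omega) -> np.ndarray:
    """Theoretical ARFIMA(0,d,0) spectral density (1/(2*pi))*(2*sin(omega/2))**(-2d)."""
    if not -0.5 < d < 0.5:
        raise DomainError(f"d must lie in (-0.5, 0.5), got {d}")
    omega = _check_omega(omega)
    return (2.0 * np.sin(omega / 2.0)) ** (-2.0 * d) / (2.0 * np.pi)


def arfima_pdq_psd(d: float, omega, ar=(), ma=()) -> np.ndarray:
    """Theoretical ARFIMA(p,d,q) spectral density.

    The fractional term of ARFIMA(0,d,0) multiplied by
    ``|theta(e^{-i*omega})|**2 / |phi(e^{-i*omega})|**2`` where
    ``phi(z) = 1 - sum_j phi_j z**j`` and ``theta(z) = 1 + sum_j theta_j z**j``
    (leading MA coefficient fixed to 1).

    Parameters
    ----------
    d : float
        Fractional-integration order in (-0.5, 0.5).
    omega : array-like
        Angular frequencies in (0, pi].
    ar, ma : sequence of float
        AR coefficients phi_1..phi_p and MA coefficients theta_1..theta_q.
    """
    omega = _check_omega(omega)
    base = arfima_psd(d, omega)
    z = np.exp(-1j * omega)
    ar = np.asarray(ar, dtype=float)
    ma = np.asarray(ma, dtype=float)
    theta = np.ones_like(z)
    for j, coef in enumerate(ma, start=1):
        theta = theta + coef * z**j
    phi = np.ones_like(z)
    for j, coef in enumerate(ar, start=1):
        phi = phi - coef * z**j
    phi_mod2 = np.abs(phi) ** 2
    if np.any(phi_mod2 < 1e-12):
        raise DomainError("AR polynomial vanishes at an evaluation frequency "
                          "(root on the unit circle)")
    return base * np.abs(theta) ** 2 / phi_mod2


@dataclass(frozen=True)
class SpectralModel:
    """Parametric spectral model: family plus its parameters.

    For FGN the parameter is ``hurst``; for the ARFIMA families it is
    ``d`` (with optional ``ar``/``ma`` coefficient tuples for
    ARFIMAPDQ).  ``hurst`` and ``d`` are linked by d = H - 1/2; either
    may be given and the other is derived.
    """

    family: Family
    hurst: float | None = None
    d: float | None = None
    ar: tuple = field(default=())
    ma: tuple = field(default=())

    def __post_init__(self):
        if self.hurst is None and self.d is None:
            raise DomainError("one of hurst or d must be given")
        if self.hurst is None:
            object.__setattr__(self, "hurst", d_to_h(self.d))
        elif self.d is None:
            object.__setattr__(self, "d", h_to_d(self.hurst))
        elif abs(self.d - h_to_d(self.hurst)) > 1e-12:
            raise DomainError("hurst and d are inconsistent (d must equal H - 1/2)")

    def psd(self, omega) -> np.ndarray:
        """Evaluate the model spectral density on a frequency grid."""
        if self.family is Family.FGN:
            return fgn_psd(self.hurst, omega)
        if self.family is Family.ARFIMA0D0:
            return arfima_psd(self.d, omega)
        return arfima_pdq_psd(self.d, omega, ar=self.ar, ma=self.ma)
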