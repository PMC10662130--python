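"""Surrogate signal generators spanning the noise-motion continuum alpha in (0, 2).

Two routes produce signals with a known fractal exponent:

* ``cholesky_fgn`` — exact fractional Gaussian noise: the Toeplitz
  autocovariance of unit-variance fGn is Cholesky-factorized and applied
  to i.i.d. Gaussian draws.  Exact in distribution, O(n^2) memory.
* ``arfima_filter`` — ARFIMA(0, d, 0) filtering: the MA(infinity)
  expansion of the fractional-integration operator (psi_0 = 1,
  psi_j = psi_{j-1} * (j - 1 + d) / j) is truncated and convolved with
  Gaussian innovations, with a burn-in discarded.

For alpha > 1 (non-stationary, motion-like targets) both routes build
the stationary surrogate at the exponent shifted down by 1 and return
its cumulative sum.  ``arfima_pdq_generate`` adds short-memory AR/MA
components around the fractional filter, producing mixed (possibly
non-monotone) spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import cholesky as _cholesky, toeplitz
from scipy.signal import fftconvolve, lfilter

from .errors import DomainError, NonStationaryError, NotPositiveDefiniteError, SizeError

__all__ = [
    "GeneratorSpec",
    "alpha_grid",
    "fgn_autocovariance",
    "cholesky_fgn",
    "arfima_psi",
    "arfima_filter",
    "arfima_pdq_generate",
    "generate",
]

#: Hard cap on the Cholesky route (n x n covariance is materialized).
CHOLESKY_MAX_N = 4096


def alpha_grid() -> np.ndarray:
    """The 42-level grid of target exponents used by the benchmark.

    {0.01, 0.05, 0.10, ..., 0.95, 0.99, 1.01, 1.05, ..., 1.95, 1.99}:
    21 noise levels in (0, 1) and their mirror images in (1, 2); the
    model-breaking values 0, 1 and 2 are excluded.
    """
    lo = np.concatenate(([0.01], np.round(np.arange(1, 20) * 0.05, 2), [0.99]))
    return np.concatenate((lo, (2.0 - lo)[::-1]))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _split_alpha(alpha: float) -> tuple[float, bool]:
    """Map alpha in (0,1)u(1,2) to (stationary exponent, integrate flag)."""
    if not (0.0 < alpha < 2.0) or alpha == 1.0:
        raise DomainError(f"alpha must lie in (0, 1) or (1, 2), got {alpha}")
    if alpha > 1.0:
        return alpha - 1.0, True
    return alpha, False


def fgn_autocovariance(H: float, n: int) -> np.ndarray:
    """Autocovariance gamma(k), k = 0..n-1, of unit-variance fGn.

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}); gamma(0) = 1,
    and gamma(k >= 1) = 0 at H = 0.5 (white noise).
    """
    if not 0.0 < H < 1.0:
        raise DomainError(f"H must lie in (0, 1), got {H}")
    k = np.arange(n, dtype=float)
    two_h = 2.0 * H
    return 0.5 * (np.abs(k + 1) ** two_h - 2 * np.abs(k) ** two_h
                  + np.abs(k - 1) ** two_h)


@lru_cache(maxsize=64)
def _cholesky_factor(H: float, n: int) -> np.ndarray:
    gamma = fgn_autocovariance(H, n)
    try:
        return _cholesky(toeplitz(gamma), lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numerical guard
        raise NotPositiveDefiniteError(
            f"fGn covariance not positive definite for H={H}, n={n}") from exc


def cholesky_fgn(alpha: float, n: int, seed=None) -> np.ndarray:
    """Exact fGn (alpha < 1) or fBm-like cumulative sum (alpha > 1).

    Parameters
    ----------
    alpha : float
        Target exponent in (0, 1) or (1, 2); H = alpha or alpha - 1.
    n : int
        Output length, at most 4096 (the n x n covariance is dense).
    seed : int, numpy.random.Generator or None
    """
    if n > CHOLESKY_MAX_N:
        raise SizeError(f"n={n} exceeds the Cholesky cap of {CHOLESKY_MAX_N}")
    H, integrate = _split_alpha(alpha)
    L = _cholesky_factor(float(H), int(n))
    x = L @ _rng(seed).standard_normal(n)
    return np.cumsum(x) if integrate else x


def arfima_psi(d: float, n_terms: int) -> np.ndarray:
    """First ``n_terms`` MA(infinity) weights of (1 - B)^(-d).

    psi_0 = 1, psi_j = psi_{j-1} * (j - 1 + d) / j
    (equivalently Gamma(j + d) / (Gamma(j + 1) * Gamma(d))).
    """
    if not -0.5 < d < 0.5:
        raise DomainError(f"d must lie in (-0.5, 0.5), got {d}")
    j = np.arange(1, n_terms, dtype=float)
    psi = np.empty(n_terms)
    psi[0] = 1.0
    psi[1:] = np.cumprod((j - 1.0 + d) / j)
    return psi


def _fractional_noise(d: float, n: int, burn_in: int, eps: np.ndarray) -> np.ndarray:
    psi = arfima_psi(d, n + burn_in)
    return fftconvolve(psi, eps)[burn_in : burn_in + n]


def arfima_filter(alpha: float, n: int, seed=None, burn_in: int | None = None) -> np.ndarray:
    """ARFIMA(0, d, 0) surrogate with target exponent alpha.

    d = alpha - 0.5 for alpha < 1; for alpha > 1 a d = alpha - 1.5 series
    is generated and cumulatively summed.  The truncated MA(infinity)
    filter runs over ``n + burn_in`` innovations and the first ``burn_in``
    outputs (default: n) are discarded.
    """
    stat_alpha, integrate = _split_alpha(alpha)
    d = stat_alpha - 0.5
    if burn_in is None:
        burn_in = n
    eps = _rng(seed).standard_normal(n + burn_in)
    x = _fractional_noise(d, n, burn_in, eps)
    return np.cumsum(x) if integrate else x


def _check_stationary(ar) -> np.ndarray:
    ar = np.asarray(ar, dtype=float)
    if ar.size:
        poles = np.roots(np.concatenate(([1.0], -ar)))
        if np.any(np.abs(poles) >= 1.0 - 1e-10):
            raise NonStationaryError(
                f"AR polynomial has a pole of modulus >= 1 (coefficients {ar})")
    return ar


def arfima_pdq_generate(d: float, n: int, ar=(), ma=(), seed=None,
                        burn_in: int | None = None) -> np.ndarray:
    """ARFIMA(p, d, q) surrogate: MA filter, fractional filter, AR recursion.

    Reduces exactly to ``arfima_filter`` output (stationary case) when
    p = q = 0 and the same seed is used.
    """
    ar = _check_stationary(ar)
    ma = np.asarray(ma, dtype=float)
    if burn_in is None:
        burn_in = n
    eps = _rng(seed).standard_normal(n + burn_in)
    if ma.size:
        eps = np.convolve(eps, np.concatenate(([1.0], ma)))[: n + burn_in]
    psi = arfima_psi(d, n + burn_in)
    x = fftconvolve(psi, eps[: n + burn_in])[: n + burn_in]
    if ar.size:
        x = lfilter([1.0], np.concatenate(([1.0], -ar)), x)
    return x[burn_in : burn_in + n]


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one surrogate signal."""

    kind: str  # "cholesky" | "arfima" | "arfimapdq"
    n: int
    seed: int
    alpha: float | None = None       # cholesky / arfima kinds
    d: float | None = None           # arfimapdq kind
    ar: tuple = ()
    ma: tuple = ()
    burn_in: int | None = None


def generate(spec: GeneratorSpec) -> np.ndarray:
    """Generate the signal a :class:`GeneratorSpec` describes."""
    if spec.kind == "cholesky":
        return cholesky_fgn(spec.alpha, spec.n, spec.seed)
    if spec.kind == "arfima":
        return arfima_filter(spec.alpha, spec.n, spec.seed, spec.burn_in)
    if spec.kind == "arfimapdq":
        return arfima_pdq_generate(spec.d, spec.n, spec.ar, spec.ma,
                                   spec.seed, spec.burn_in)
    raise DomainError(f"unknown generator kind {spec.kind!r}")
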