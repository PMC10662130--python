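"""Deterministic synthetic demonstration signals.

Four named 1024-point series, regenerated bit-identically from packaged
seeds, stand in for the kinds of inputs the estimator is designed for:

* ``cholesky_like``   — exact fGn with alpha = 0.8 (persistent noise);
* ``arfima_like``     — ARFIMA(0, 0.3, 0), the spectrally equivalent
  long-memory process (alpha = d + 1/2 = 0.8);
* ``whitenoise_like`` — i.i.d. N(0, 1) (alpha = 0.5);
* ``empirical_like``  — a synthetic ARFIMA(2, -0.35, 1) surrogate with an
  anti-persistent low-frequency trend and a persistent high-frequency
  band, emulating the mixed spectral behavior seen in constrained human
  gait.  It is a stand-in, not a reproduction of any recorded series.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .generators import arfima_filter, arfima_pdq_generate, cholesky_fgn

__all__ = ["DEFAULT_SEED", "FIXTURE_NAMES", "make_fixtures", "write_fixtures"]

DEFAULT_SEED = 1724
FIXTURE_N = 1024
FIXTURE_NAMES = ("cholesky_like", "arfima_like", "whitenoise_like",
                 "empirical_like")

# AR(2) poles at 0.8*exp(+/-2.5i): a spectral peak near omega = 2.5 that,
# against d = -0.35, makes the log-spectrum non-monotone.
_EMPIRICAL_AR = (2 * 0.8 * np.cos(2.5), -0.64)
_EMPIRICAL_MA = (0.3,)
_EMPIRICAL_D = -0.35


def make_fixtures(seed: int = DEFAULT_SEED) -> dict[str, np.ndarray]:
    """Build the four named series; identical seed gives identical output."""
    child = np.random.SeedSequence(seed).spawn(4)
    return {
        "cholesky_like": cholesky_fgn(0.8, FIXTURE_N,
                                      np.random.default_rng(child[0])),
        "arfima_like": arfima_filter(0.8, FIXTURE_N,
                                     np.random.default_rng(child[1])),
        "whitenoise_like": np.random.default_rng(child[2])
                              .standard_normal(FIXTURE_N),
        "empirical_like": arfima_pdq_generate(
            _EMPIRICAL_D, FIXTURE_N, ar=_EMPIRICAL_AR, ma=_EMPIRICAL_MA,
            seed=np.random.default_rng(child[3])),
    }


def write_fixtures(out_dir, seed: int = DEFAULT_SEED) -> list[Path]:
    """Write each fixture as a one-column CSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, values in make_fixtures(seed).items():
        path = out_dir / f"{name}.csv"
        pd.DataFrame({"value": values}).to_csv(path, index=False)
        paths.append(path)
    return paths
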