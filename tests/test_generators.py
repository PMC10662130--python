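"""Surrogate generators: exactness, filter recursions, seed determinism."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import factorial, poch

from whittlemle import (
    DomainError,
    GeneratorSpec,
    SizeError,
    alpha_grid,
    arfima_filter,
    arfima_pdq_generate,
    arfima_psi,
    cholesky_fgn,
    fgn_autocovariance,
    generate,
)
from whittlemle.errors import NonStationaryError

FGN_GAMMA1_H08 = 0.5157165665103981  # 0.5*(2**1.6 - 2), frozen at 25 digits


def _lag1(x):
    # Non-centered estimator: the generators produce zero-mean processes,
    # and subtracting the sample mean would bias long-memory series.
    return np.sum(x[:-1] * x[1:]) / np.sum(x * x)


class TestAlphaGrid:
    def test_structure(self):
        grid = alpha_grid()
        assert len(grid) == 42
        assert grid[0] == 0.01
        assert grid[20] == 0.99
        assert grid[21] == 1.01
        assert grid[41] == 1.99
        assert np.all(np.diff(grid) > 0)

    def test_symmetry_about_one(self):
        grid = alpha_grid()
        np.testing.assert_allclose(grid + grid[::-1], 2.0, atol=1e-12)


class TestFgnAutocovariance:
    def test_unit_variance_and_white_limit(self):
        gamma = fgn_autocovariance(0.5, 64)
        assert gamma[0] == 1.0
        np.testing.assert_allclose(gamma[1:], 0.0, atol=1e-12)

    def test_lag_one_frozen_value(self):
        assert fgn_autocovariance(0.8, 4)[1] == pytest.approx(
            FGN_GAMMA1_H08, rel=1e-12)

    def test_persistent_vs_antipersistent_sign(self):
        assert fgn_autocovariance(0.8, 4)[1] > 0
        assert fgn_autocovariance(0.2, 4)[1] < 0


class TestCholeskyFgn:
    def test_half_is_iid_gaussian(self):
        pooled = np.concatenate(
            [cholesky_fgn(0.5, 256, seed=s) for s in range(20)])
        assert stats.kstest(pooled, "norm").pvalue > 0.01

    def test_lag1_autocorrelation_matches_gamma(self):
        r1 = [_lag1(cholesky_fgn(0.8, 1024, seed=s)) for s in range(200)]
        assert np.mean(r1) == pytest.approx(FGN_GAMMA1_H08, abs=0.02)

    def test_motion_differences_to_white_noise(self):
        r1 = [_lag1(np.diff(cholesky_fgn(1.5, 1024, seed=s)))
              for s in range(200)]
        assert np.mean(r1) == pytest.approx(0.0, abs=0.02)

    def test_size_cap_and_alpha_domain(self):
        with pytest.raises(SizeError):
            cholesky_fgn(0.5, 5000)
        with pytest.raises(DomainError):
            cholesky_fgn(1.0, 64)


class TestArfimaFilter:
    def test_psi_recursion_closed_form(self):
        for d in (-0.3, 0.1, 0.45):
            psi = arfima_psi(d, 50)
            assert psi[0] == 1.0
            assert psi[1] == pytest.approx(d, rel=1e-14)
            assert psi[2] == pytest.approx(d * (d + 1) / 2, rel=1e-14)
            # Gamma(j+d) / (Gamma(j+1) Gamma(d)) = poch(d, j) / j!
            for j in (5, 17, 49):
                expected = poch(d, j) / factorial(j)
                assert psi[j] == pytest.approx(expected, rel=1e-10)

    def test_d_zero_returns_innovations(self):
        n = 128
        x = arfima_filter(0.5, n, seed=9)  # alpha=0.5 -> d=0
        eps = np.random.default_rng(9).standard_normal(2 * n)
        np.testing.assert_allclose(x, eps[n:], atol=1e-10)

    def test_mean_periodogram_proportional_to_model(self):
        from whittlemle import arfima_psd, periodogram

        P = np.zeros(511)
        for s in range(150):
            P += periodogram(arfima_filter(0.8, 1024, seed=1000 + s)).power
        P /= 150
        omega = 2 * np.pi * np.arange(1, 512) / 1024
        slope = np.polyfit(np.log(arfima_psd(0.3, omega)), np.log(P), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_domain(self):
        with pytest.raises(DomainError):
            arfima_filter(2.3, 64)


class TestArfimaPdq:
    def test_reduces_to_plain_filter(self):
        # alpha = d + 0.5 with both exactly representable in binary
        a = arfima_pdq_generate(0.25, 256, seed=4)
        b = arfima_filter(0.75, 256, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_ar1_lag1_autocorrelation(self):
        r1 = [_lag1(arfima_pdq_generate(0.0, 512, ar=(0.6,), seed=s))
              for s in range(300)]
        assert np.mean(r1) == pytest.approx(0.6, abs=0.02)

    def test_mixed_spectrum_periodogram_non_monotone(self):
        """Anti-persistent d with a high-frequency AR peak: the averaged
        periodogram rises to an interior maximum instead of decaying."""
        from whittlemle import periodogram

        P = np.zeros(511)
        for s in range(60):
            P += periodogram(arfima_pdq_generate(
                -0.35, 1024, ar=(2 * 0.8 * np.cos(2.5), -0.64), ma=(0.3,),
                seed=s)).power
        smooth = np.convolve(P / 60, np.ones(31) / 31, mode="valid")
        peak = np.argmax(smooth)
        assert 0 < peak < smooth.size - 1

    def test_nonstationary_ar_rejected(self):
        with pytest.raises(NonStationaryError):
            arfima_pdq_generate(0.0, 64, ar=(1.01,))


class TestDeterminismAndDispatch:
    @pytest.mark.parametrize("spec", [
        GeneratorSpec(kind="cholesky", n=128, seed=11, alpha=0.7),
        GeneratorSpec(kind="arfima", n=128, seed=11, alpha=1.3),
        GeneratorSpec(kind="arfimapdq", n=128, seed=11, d=-0.2,
                      ar=(0.4,), ma=(0.1,)),
    ])
    def test_identical_spec_bit_identical_output(self, spec):
        np.testing.assert_array_equal(generate(spec), generate(spec))

    def test_outputs_finite_and_non_constant(self):
        for alpha in (0.01, 0.5, 0.99, 1.01, 1.5, 1.99):
            for fn in (cholesky_fgn, arfima_filter):
                x = fn(alpha, 128, seed=3)
                assert np.all(np.isfinite(x))
                assert x.std() > 0

    def test_unknown_kind(self):
        with pytest.raises(DomainError):
            generate(GeneratorSpec(kind="wavelet", n=64, seed=0, alpha=0.5))


def test_cholesky_generator_biased_near_unity():
    """Integrated-fGn surrogates are biased around alpha = 1 while ARFIMA
    surrogates stay close to the identity line (mean deviation ratio > 1.5)."""
    from whittlemle import estimate

    dev = {}
    for gen, fn in (("cholesky", cholesky_fgn), ("arfima", arfima_filter)):
        errs = []
        for ai, a in enumerate((0.99, 1.01, 1.05, 1.1, 1.15, 1.2)):
            for rep in range(15):
                x = fn(a, 1024, seed=1000 * ai + rep)
                errs.append(abs(estimate(x, "arfima").alpha - a))
        dev[gen] = np.mean(errs)
    assert dev["cholesky"] / dev["arfima"] > 1.5
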