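"""Welch estimation and periodic/aperiodic decomposition."""

import numpy as np
import pytest

from gpalpha.io import Recording
from gpalpha.simulate import generate_lfp
from gpalpha.spectral import (PowerSpectrum, SpecparamSettings, aperiodic_model,
                              average_session_psd, classify_knee, fit_specparam,
                              model_psd, periodic_spectrum, relative_spectrum,
                              welch_psd)

FREQS = np.arange(0.0, 125.01, 0.5)


def _rec(samples, **kw):
    defaults = dict(patient_id="P01", hemisphere="L", session_index=1, pair=(0, 1))
    defaults.update(kw)
    return Recording(samples=np.asarray(samples, float), fs=250.0, **defaults)


class TestWelchPSD:
    def test_zero_signal_gives_zero_spectrum(self):
        psd = welch_psd(_rec(np.zeros(5000)))
        assert np.all(psd.power == 0)

    def test_grid_is_half_hz(self):
        psd = welch_psd(_rec(np.zeros(5000)))
        assert psd.df == 0.5 and psd.freqs[0] == 0.0 and psd.freqs[-1] == 125.0

    def test_tone_peaks_at_its_frequency(self):
        t = np.arange(5000) / 250.0
        psd = welch_psd(_rec(np.sin(2 * np.pi * 10.0 * t)))
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(10.0)

    def test_parseval_against_direct_periodogram(self, rng):
        x = rng.standard_normal(5000)
        psd = welch_psd(_rec(x))
        total = psd.power.sum() * psd.df
        # oracle: direct (boxcar, unpadded) periodogram integrates to the variance
        spec = np.abs(np.fft.rfft(x - x.mean())) ** 2 / (250.0 * x.size)
        spec[1:-1] *= 2
        direct = spec.sum() * (250.0 / x.size)
        assert total == pytest.approx(direct, rel=0.10)
        assert total == pytest.approx(1.0, rel=0.10)

    def test_gapped_windows_are_skipped(self, rng):
        x = rng.standard_normal(5000)
        mask = np.zeros(5000, bool)
        mask[1000:1010] = True
        x_spiked = x.copy()
        x_spiked[1000:1010] = 1e6  # wild values inside gapped windows only
        psd = welch_psd(_rec(x_spiked, gap_mask=mask))
        clean = welch_psd(_rec(x))
        assert psd.power.max() < 10 * clean.power.max()

    def test_circular_shift_invariance_in_expectation(self, rng):
        base = [welch_psd(_rec(np.roll(rng.standard_normal(5000), 0))).power
                for _ in range(10)]
        rng2 = np.random.default_rng(1234)
        rolled = [welch_psd(_rec(np.roll(rng2.standard_normal(5000), 777))).power
                  for _ in range(10)]
        assert np.mean(base) == pytest.approx(np.mean(rolled), rel=0.05)

    def test_insufficient_clean_data_errors(self):
        with pytest.raises(ValueError, match="insufficient clean data"):
            welch_psd(_rec(np.zeros(600), gap_mask=np.ones(600, bool)))


class TestAverageAndRelative:
    def test_single_spectrum_is_itself(self):
        p = PowerSpectrum(FREQS, np.ones_like(FREQS))
        out = average_session_psd([p])
        np.testing.assert_array_equal(out.power, p.power)

    def test_linearity(self):
        p = PowerSpectrum(FREQS, np.linspace(1, 2, FREQS.size))
        p3 = PowerSpectrum(FREQS, 3 * p.power)
        out = average_session_psd([p, p3])
        np.testing.assert_allclose(out.power, 2 * p.power)

    def test_mismatched_grids_error(self):
        p = PowerSpectrum(FREQS, np.ones_like(FREQS))
        q = PowerSpectrum(FREQS[:-2], np.ones(FREQS.size - 2))
        with pytest.raises(ValueError, match="grid"):
            average_session_psd([p, q])

    def test_flat_relative_sums_to_100(self):
        rel = relative_spectrum(PowerSpectrum(FREQS, np.ones_like(FREQS)))
        m = (rel.freqs >= 3) & (rel.freqs <= 100)
        assert rel.power[m].sum() == pytest.approx(100.0, abs=1e-6)
        assert np.ptp(rel.power) == 0

    def test_scale_invariance(self):
        p = np.linspace(1, 5, FREQS.size)
        a = relative_spectrum(PowerSpectrum(FREQS, p))
        b = relative_spectrum(PowerSpectrum(FREQS, 2 * p))
        np.testing.assert_allclose(a.power, b.power)

    def test_single_nonzero_bin(self):
        p = np.zeros(FREQS.size)
        p[FREQS == 10.0] = 7.0
        rel = relative_spectrum(PowerSpectrum(FREQS, p))
        assert rel.power[FREQS == 10.0] == pytest.approx(100.0)
        assert rel.power.sum() == pytest.approx(100.0)

    def test_zero_total_power_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            relative_spectrum(PowerSpectrum(FREQS, np.zeros(FREQS.size)))


class TestAperiodicModel:
    def test_offset_is_power_at_fmin(self):
        for a, fk, chi in [(3.0, 0.5, 1.5), (10.0, 20.0, 2.5), (1.0, 5.0, -0.5)]:
            assert aperiodic_model(1.0, a, fk, chi, 1.0) == pytest.approx(a)

    def test_zero_exponent_is_flat(self):
        f = np.array([1.0, 10.0, 60.0])
        np.testing.assert_allclose(aperiodic_model(f, 4.0, 2.0, 0.0, 1.0), 4.0)

    def test_power_halves_at_distant_knee(self):
        # f_k = 100 f_min, chi = 2: L(f_k)/A = (f_k^2 + 1) / (2 f_k^2) ~ 0.5
        ratio = aperiodic_model(100.0, 1.0, 100.0, 2.0, 1.0)
        expected = (100.0**2 + 1.0) / (2 * 100.0**2)
        assert ratio == pytest.approx(expected)
        assert ratio == pytest.approx(0.5, abs=1e-4)

    def test_nonpositive_frequency_errors(self):
        with pytest.raises(ValueError):
            aperiodic_model(0.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            aperiodic_model(10.0, 1.0, 1.0, 1.0, -1.0)


class TestFitSpecparam:
    def test_noiseless_aperiodic_self_consistency(self):
        p = model_psd(FREQS, 10.0, 0.5, 1.5, np.zeros((0, 3)))
        fit = fit_specparam(PowerSpectrum(FREQS, p))
        assert abs(fit.exponent - 1.5) < 0.05
        assert fit.n_peaks == 0
        assert fit.r_squared > 0.999

    def test_alpha_peak_recovery_with_noise(self, rng):
        p = model_psd(FREQS, 10.0, 0.5, 1.5, [(0.4, 10.0, 1.5)])
        noisy = p * 10 ** rng.normal(0, 0.02, FREQS.size)
        fit = fit_specparam(PowerSpectrum(FREQS, noisy))
        alpha = fit.peaks[(fit.peaks[:, 1] > 7) & (fit.peaks[:, 1] < 14)]
        assert alpha.shape[0] >= 1
        best = alpha[np.argmax(alpha[:, 0])]
        assert abs(best[1] - 10.0) < 0.25
        assert abs(best[2] - 1.5) < 0.5

    def test_peak_cap_enforced(self):
        centers = np.linspace(6, 60, 10)
        peaks = [(0.8, fc, 1.2) for fc in centers]
        p = model_psd(FREQS, 10.0, 0.5, 1.5, peaks)
        fit = fit_specparam(PowerSpectrum(FREQS, p))
        assert fit.n_peaks <= 8

    def test_grid_must_cover_fit_range(self):
        f = np.arange(2.0, 40.0, 0.5)
        with pytest.raises(ValueError, match="fit range"):
            fit_specparam(PowerSpectrum(f, np.ones(f.size)))

    def test_lambda_penalty_shrinks_negative_frequency_mass(self, rng):
        # a wide near-zero-centered bump leaks mass below 0 Hz; raising
        # lambda must not increase that leaked mass
        from gpalpha.spectral import _neg_freq_mass
        p = model_psd(FREQS, 10.0, 0.5, 1.0, [(0.8, 2.0, 4.0)])
        noisy = p * 10 ** rng.normal(0, 0.01, FREQS.size)
        masses = []
        for lam in (0.0, 100.0, 10_000.0):
            st = SpecparamSettings(lam=lam)
            fit = fit_specparam(PowerSpectrum(FREQS, noisy), st)
            masses.append(_neg_freq_mass(fit.peaks).sum())
        assert masses[0] >= masses[1] >= masses[2] - 1e-12


class TestPeriodicSpectrum:
    def test_pure_aperiodic_gives_zero_residual(self):
        p = model_psd(FREQS, 10.0, 0.5, 1.5, np.zeros((0, 3)))
        psd = PowerSpectrum(FREQS, p)
        fit = fit_specparam(psd)
        per = periodic_spectrum(psd, fit)
        assert np.max(np.abs(per.power)) < 1e-3

    def test_gaussian_bump_appears_in_residual(self):
        p = model_psd(FREQS, 10.0, 0.5, 1.5, [(0.4, 10.0, 1.5)])
        psd = PowerSpectrum(FREQS, p)
        fit = fit_specparam(psd)
        per = periodic_spectrum(psd, fit)
        at10 = per.power[per.freqs == 10.0][0]
        assert at10 == pytest.approx(0.4, abs=0.05)

    def test_invariant_to_multiplicative_scaling(self):
        p = model_psd(FREQS, 10.0, 0.5, 1.5, [(0.4, 10.0, 1.5)])
        psd1 = PowerSpectrum(FREQS, p)
        psd2 = PowerSpectrum(FREQS, 7.3 * p)
        per1 = periodic_spectrum(psd1, fit_specparam(psd1))
        per2 = periodic_spectrum(psd2, fit_specparam(psd2))
        np.testing.assert_allclose(per1.power, per2.power, atol=1e-3)


class TestClassifyKnee:
    @pytest.mark.parametrize("knee_hz,expected", [(0.3, False), (5.0, True),
                                                  (1.0, False)])
    def test_threshold_convention(self, knee_hz, expected):
        p = model_psd(FREQS, 10.0, knee_hz, 1.5, np.zeros((0, 3)))
        fit = fit_specparam(PowerSpectrum(FREQS, p))
        fit.knee_hz = knee_hz  # exact boundary convention, not fit recovery
        assert classify_knee(fit) is expected


class TestGenerativeRoundTrip:
    def test_generated_lfp_matches_target_spectrum(self):
        # drift filtering first removes the steep sub-1 Hz power whose
        # spectral leakage would otherwise bias the lowest bins; the narrow
        # line peak is checked as a band integral because 1-s windows smear it
        from scipy import signal as sig

        from gpalpha.preprocess import drift_filter
        peaks = [(0.45, 10.0, 1.5), (0.15, 20.0, 3.0), (0.5, 60.0, 1.0)]
        target = model_psd(FREQS, 5.0, 0.3, 1.5, peaks)
        # zero-phase filtering multiplies the PSD by |H|^4
        b, a = sig.butter(4, 1.0, btype="highpass", fs=250.0)
        _, h = sig.freqz(b, a, worN=np.maximum(FREQS, 1e-6), fs=250.0)
        target = target * np.abs(h) ** 4
        powers = []
        for seed in range(20):
            x = generate_lfp(5.0, 0.3, 1.5, peaks, 20.0, 250.0, seed)
            powers.append(welch_psd(drift_filter(_rec(x))).power)
        mean_psd = np.mean(powers, axis=0)
        # the ~2 Hz Hann kernel smears sharp spectral features (the filter
        # corner near 1 Hz, the narrow line); those regions are compared as
        # band integrals, which smoothing preserves
        m = (FREQS > 2) & (FREQS <= 65) & (np.abs(FREQS - 60.0) > 2.0)
        np.testing.assert_allclose(mean_psd[m], target[m], rtol=0.15)
        for region in ((FREQS >= 1) & (FREQS <= 2),
                       np.abs(FREQS - 60.0) <= 2.0):
            assert mean_psd[region].sum() == pytest.approx(
                target[region].sum(), rel=0.15)

    def test_no_planted_alpha_means_no_fitted_alpha_peak(self):
        # beta and line peaks stay; the alpha band must come out clean
        peaks = [(0.15, 20.0, 3.0), (0.5, 60.0, 1.0)]
        x = generate_lfp(5.0, 0.3, 1.5, peaks, 20.0, 250.0, 0)
        fit = fit_specparam(welch_psd(_rec(x)))
        alpha = fit.peaks[(fit.peaks[:, 1] >= 7) & (fit.peaks[:, 1] <= 14)]
        assert alpha.shape[0] == 0
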