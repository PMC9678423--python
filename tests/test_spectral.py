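"""Welch cross-spectra, transfer function, band summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import baroflex as bx
from baroflex.spectral import segment_length
from oracles import brute_welch, narrowband_delay_pair, windowed_detrended_variance


class TestWelch:
    def test_segmentation_arithmetic(self):
        # 5 min at 4 Hz: five 100 s segments at 50% overlap, 0.01 Hz bins
        assert segment_length(1200, 5) == 400
        est = bx.welch_cross_spectra(np.random.default_rng(0).normal(size=1200),
                                     np.random.default_rng(1).normal(size=1200),
                                     fs=4.0)
        assert est.segment_len_s == pytest.approx(100.0)
        assert est.df == pytest.approx(0.01)
        assert est.n_segments == 5

    @pytest.mark.parametrize("n", [300, 333, 512])
    def test_matches_brute_force_dft(self, n, rng):
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * x
        est = bx.welch_cross_spectra(x, y, fs=4.0)
        f2, sxx2, syy2, sxy2 = brute_welch(x, y, fs=4.0)
        np.testing.assert_allclose(est.freqs, f2, atol=1e-12)
        np.testing.assert_allclose(est.sxx, sxx2, rtol=1e-9, atol=1e-15)
        np.testing.assert_allclose(est.syy, syy2, rtol=1e-9, atol=1e-15)
        np.testing.assert_allclose(est.sxy, sxy2, rtol=1e-9, atol=1e-15)

    def test_identical_inputs_coherence_one(self, rng):
        x = rng.normal(size=1200)
        tf = bx.transfer_function(bx.welch_cross_spectra(x, x, fs=4.0))
        good = np.isfinite(tf.gain)
        np.testing.assert_allclose(tf.coherence[good], 1.0, atol=1e-10)
        np.testing.assert_allclose(tf.gain[good], 1.0, rtol=1e-9)

    def test_too_short_record(self):
        with pytest.raises(bx.InsufficientDataError):
            bx.welch_cross_spectra(np.zeros(60), np.zeros(60), fs=4.0)

    def test_parseval_window_corrected(self, rng):
        for _ in range(5):
            y = rng.normal(size=1200)
            est = bx.welch_cross_spectra(y, y, fs=4.0)
            integ = np.sum(est.syy) * est.df
            ref = windowed_detrended_variance(y, fs=4.0)
            assert integ == pytest.approx(ref, rel=1e-9)

    def test_cauchy_schwarz(self, rng):
        x = rng.normal(size=800)
        y = np.sin(np.arange(800) / 5) + 0.1 * rng.normal(size=800)
        est = bx.welch_cross_spectra(x, y, fs=4.0)
        assert np.all(np.abs(est.sxy) ** 2 <= est.sxx * est.syy * (1 + 1e-12))


class TestTransferFunction:
    def test_pure_scaling(self, rng):
        x = rng.normal(size=1200)
        tf = bx.transfer_function(bx.welch_cross_spectra(x, 10 * x, fs=4.0))
        good = np.isfinite(tf.gain)
        np.testing.assert_allclose(tf.gain[good], 10.0, rtol=1e-9)
        np.testing.assert_allclose(tf.phase[good], 0.0, atol=1e-9)
        np.testing.assert_allclose(tf.coherence[good], 1.0, atol=1e-10)

    def test_delay_line_band_gain_and_coherence(self):
        x, y = narrowband_delay_pair(gain=8.0, tau_s=1.5)
        est = bx.welch_cross_spectra(x, y, fs=4.0)
        tf = bx.band_summary(bx.transfer_function(est), s=est)
        assert tf.bands["lf"].gain == pytest.approx(8.0, rel=0.01)
        assert tf.bands["lf"].coherence > 0.99

    def test_delayed_tone_gain_and_phase_at_carrier(self):
        # a pure 0.10 Hz tone delayed by 1.5 s: the bin at the carrier must
        # show gain G and phase -2 pi f tau exactly (no neighboring leakage)
        t = np.arange(1200) / 4.0
        x = np.cos(2 * np.pi * 0.10 * t + 0.7)
        y = 8.0 * np.cos(2 * np.pi * 0.10 * (t - 1.5) + 0.7)
        tf = bx.transfer_function(bx.welch_cross_spectra(x, y, fs=4.0))
        i0 = np.argmin(np.abs(tf.freqs - 0.10))
        assert tf.gain[i0] == pytest.approx(8.0, rel=0.01)
        assert tf.phase[i0] == pytest.approx(-2 * np.pi * 0.10 * 1.5, abs=0.05)
        assert tf.phase[i0] == pytest.approx(-0.9425, abs=0.05)

    def test_conjugation_flips_phase(self, rng):
        x = rng.normal(size=1200)
        y = np.roll(x, 3) + 0.1 * rng.normal(size=1200)
        est = bx.welch_cross_spectra(x, y, fs=4.0)
        tf = bx.transfer_function(est)
        est.sxy = np.conj(est.sxy)
        tf2 = bx.transfer_function(est)
        good = np.isfinite(tf.phase) & (np.abs(np.abs(tf.phase) - np.pi) > 1e-6)
        np.testing.assert_allclose(tf2.phase[good], -tf.phase[good], atol=1e-12)
        np.testing.assert_allclose(tf2.gain, tf.gain, equal_nan=True)

    def test_gain_invariant_to_added_constant(self, rng):
        x = rng.normal(size=1200)
        y = 5 * x + rng.normal(size=1200)
        tf1 = bx.transfer_function(bx.welch_cross_spectra(x, y, fs=4.0))
        tf2 = bx.transfer_function(bx.welch_cross_spectra(x + 50, y - 30, fs=4.0))
        np.testing.assert_allclose(tf1.gain, tf2.gain, rtol=1e-9, equal_nan=True)

    def test_zero_input_spectrum_gives_missing_gain(self):
        x = np.zeros(1200)
        y = np.random.default_rng(0).normal(size=1200)
        tf = bx.transfer_function(bx.welch_cross_spectra(x, y, fs=4.0))
        assert np.all(np.isnan(tf.gain))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_coherence_bounded_for_arbitrary_inputs(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=400) * rng.uniform(0.1, 100)
        y = rng.normal(size=400) + rng.uniform(-5, 5) * x
        tf = bx.transfer_function(bx.welch_cross_spectra(x, y, fs=4.0))
        c = tf.coherence[np.isfinite(tf.coherence)]
        assert np.all((c >= 0) & (c <= 1))


class TestBands:
    def test_lf_bin_membership_half_open(self):
        freqs = np.round(np.arange(0, 2.001, 0.01), 10)
        lf = bx.BandScheme().lf
        members = freqs[lf.mask(freqs)]
        assert members[0] == pytest.approx(0.04)
        assert members[-1] == pytest.approx(0.14)
        assert members.size == 11

    def test_hf_closed_at_upper_edge(self):
        freqs = np.round(np.arange(0, 2.001, 0.01), 10)
        hf = bx.BandScheme().hf
        members = freqs[hf.mask(freqs)]
        assert members[-1] == pytest.approx(0.40)

    def test_dc_excluded_from_vlf(self):
        freqs = np.array([0.0, 0.01, 0.02, 0.03])
        vlf = bx.BandScheme().vlf
        assert not vlf.mask(freqs)[0]

    def test_constant_gain_band_mean(self):
        freqs = np.round(np.arange(0, 0.51, 0.01), 10)
        n = freqs.size
        tf = bx.TransferFunctionResult(
            freqs=freqs, gain=np.full(n, 7.4), phase=np.zeros(n),
            coherence=np.full(n, 0.8),
        )
        tf = bx.band_summary(tf)
        assert tf.cbrs_lf_gain == pytest.approx(7.4)

    def test_coherence_gate_can_empty_band(self):
        freqs = np.round(np.arange(0, 0.51, 0.01), 10)
        n = freqs.size
        tf = bx.TransferFunctionResult(
            freqs=freqs, gain=np.full(n, 5.0), phase=np.zeros(n),
            coherence=np.full(n, 0.2),
        )
        tf = bx.band_summary(tf, coherence_min=0.5)
        assert np.isnan(tf.bands["lf"].gain)
        assert tf.bands["lf"].n_bins == 0
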