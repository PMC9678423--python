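"""Beat series construction, artifact flagging, equidistant resampling."""

import numpy as np
import pytest

import baroflex as bx
from baroflex.detect import BeatAnnotations


def _regular_annotations(n=40, rr_s=0.8):
    return BeatAnnotations(r_times=np.arange(n) * rr_s)


class TestBuild:
    def test_rr_arithmetic(self):
        ann = _regular_annotations(40, 0.8)
        series = bx.build_beat_series(ann, sbp=np.full(39, 120.0))
        np.testing.assert_allclose(series.rr, 800.0)
        assert len(series) == 40
        assert series.rr.size == 39

    def test_pairing_is_zero_lag(self):
        ann = _regular_annotations(40, 0.8)
        sbp = 120 + np.arange(39.0)
        series = bx.build_beat_series(ann, sbp=sbp)
        np.testing.assert_array_equal(series.sbp, sbp)  # rr_k <-> sbp_k

    def test_lag_shifts_pairing(self):
        ann = _regular_annotations(40, 0.8)
        sbp = 120 + np.arange(39.0)
        series = bx.build_beat_series(ann, sbp=sbp, lag_beats=1)
        np.testing.assert_array_equal(series.sbp[1:], sbp[:-1])
        assert not series.valid[0]  # no delayed pressure for the first cycle

    def test_too_few_beats(self):
        with pytest.raises(bx.InsufficientDataError):
            bx.build_beat_series(_regular_annotations(10), sbp=np.full(9, 120.0))

    def test_simulator_couples_reproduced(self, day0_session):
        series, _ = day0_session
        ann = BeatAnnotations(r_times=series.t)
        rebuilt = bx.build_beat_series(ann, sbp=series.sbp, dbp=series.dbp,
                                       map_=series.map)
        np.testing.assert_allclose(rebuilt.rr, series.rr, atol=1e-9)
        np.testing.assert_array_equal(rebuilt.sbp, series.sbp)


class TestFlagging:
    def test_single_short_beat_flagged(self):
        t = np.cumsum(np.r_[0.0, np.full(10, 0.8)])
        rr = np.full(10, 800.0)
        rr[5] = 400.0
        series = bx.BeatSeries(t=t, rr=rr, sbp=np.full(10, 120.0))
        flagged = bx.flag_artifacts(series)
        assert list(np.flatnonzero(~flagged.valid)) == [5]
        assert flagged.ectopic_fraction == pytest.approx(0.1)

    def test_all_equal_rr_clean(self):
        t = np.arange(20) * 0.8
        series = bx.BeatSeries(t=t, rr=np.full(19, 800.0), sbp=np.full(19, 120.0))
        assert bx.flag_artifacts(series).ectopic_fraction == 0.0

    def test_even_window_rejected(self):
        t = np.arange(20) * 0.8
        series = bx.BeatSeries(t=t, rr=np.full(19, 800.0), sbp=np.full(19, 120.0))
        with pytest.raises(bx.ConfigurationError):
            bx.flag_artifacts(series, window=10)

    def test_injected_ectopics_recovered(self):
        hits, total, fp, neg = 0, 0, 0, 0
        for seed in range(5):
            cfg = bx.preset("day0", seed=seed, ectopic_rate=0.03)
            series, truth = bx.simulate_beat_series(cfg)
            flagged = set(np.flatnonzero(~bx.flag_artifacts(series).valid))
            injected = set(truth.ectopic_indices.tolist())
            hits += len(flagged & injected)
            total += len(injected)
            fp += len(flagged - injected)
            neg += series.rr.size - len(injected)
        assert hits / total >= 0.95
        assert fp / neg <= 0.01


class TestSuitability:
    @pytest.mark.parametrize(
        "n_bad,expect", [(2, True), (5, True), (10, False)]  # of 100 cycles
    )
    def test_threshold_semantics(self, n_bad, expect):
        t = np.arange(101) * 0.8
        valid = np.ones(100, dtype=bool)
        valid[:n_bad] = False
        series = bx.BeatSeries(t=t, rr=np.full(100, 800.0),
                               sbp=np.full(100, 120.0), valid=valid)
        suitable, reason = bx.assess_suitability(series)
        assert suitable is expect
        if not expect:
            assert "ectop" in reason

    def test_boundary_is_suitable(self):
        # exactly 5% flagged sits on the <= boundary
        t = np.arange(41) * 0.8
        valid = np.ones(40, dtype=bool)
        valid[:2] = False
        series = bx.BeatSeries(t=t, rr=np.full(40, 800.0),
                               sbp=np.full(40, 120.0), valid=valid)
        assert bx.assess_suitability(series)[0] is True


class TestResampling:
    def _series(self, rr_values, rr_s=0.8):
        n = rr_values.size + 1
        t = np.arange(n) * rr_s
        return bx.BeatSeries(t=t, rr=rr_values, sbp=np.full(n - 1, 120.0))

    def test_constant_reproduced_exactly(self):
        eq = bx.interpolate_resample(self._series(np.full(50, 800.0)), "rr")
        np.testing.assert_allclose(eq.values, 800.0, rtol=1e-12)
        assert eq.fs == 4.0
        assert np.diff(eq.times).std() < 1e-12

    def test_linear_trend_reproduced(self):
        rr = 700.0 + 2.0 * np.arange(50)
        eq = bx.interpolate_resample(self._series(rr), "rr")
        expected = 700.0 + 2.0 * (eq.times / 0.8)
        np.testing.assert_allclose(eq.values, expected, rtol=1e-9)

    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(510) * 0.8  # ~75 beats/min
        rr = 800 + 50 * np.sin(2 * np.pi * 0.1 * t)
        series = bx.BeatSeries(t=t, rr=rr[:-1], sbp=np.full(509, 120.0))
        eq = bx.interpolate_resample(series, "rr")
        # analyze an integer number of 10 s cycles so 0.1 Hz is an exact bin
        n = (len(eq) // 40) * 40
        vals = eq.values[:n]
        spec = np.abs(np.fft.rfft(vals - vals.mean())) * 2 / n
        freqs = np.fft.rfftfreq(n, 1 / eq.fs)
        amp = spec[np.argmin(np.abs(freqs - 0.1))]
        assert amp == pytest.approx(50.0, rel=0.02)

    def test_no_extrapolation(self):
        series = self._series(np.full(50, 777.0))
        series.valid[0] = series.valid[-1] = False
        eq = bx.interpolate_resample(series, "rr")
        tt = eq.times
        inner = series.interval_times[series.valid]
        assert tt[0] >= inner[0] - 1e-12
        assert tt[-1] <= inner[-1] + 1e-12

    def test_flagged_beat_value_is_ignored(self):
        base = self._series(np.full(50, 800.0))
        base.valid[20] = False
        tampered = bx.BeatSeries(t=base.t, rr=base.rr.copy(), sbp=base.sbp,
                                 valid=base.valid.copy())
        tampered.rr[20] = 9999.0  # arbitrary value on an excluded beat
        a = bx.interpolate_resample(base, "rr")
        b = bx.interpolate_resample(tampered, "rr")
        np.testing.assert_array_equal(a.values, b.values)

    def test_mean_preserved_for_stationary_input(self, rng):
        rr = 800 + rng.normal(0, 30, size=200)
        series = self._series(rr)
        eq = bx.interpolate_resample(series, "rr")
        assert eq.values.mean() == pytest.approx(rr.mean(), rel=0.01)

    def test_short_span_rejected(self):
        t = np.array([0.0, 0.4, 0.9, 1.4, 1.9])
        series = bx.BeatSeries(t=t, rr=np.diff(t) * 1000, sbp=np.full(4, 120.0))
        with pytest.raises(bx.InsufficientDataError):
            bx.interpolate_resample(series, "rr")
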