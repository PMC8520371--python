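"""Detector: demodulation, autocorrelation, lookup table, estimation, tracking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fhrdop import (
    DISTRESS,
    NO_SIGNAL,
    NORMAL,
    DopplerConfig,
    DopplerSignal,
    Envelope,
    InsufficientDataError,
    autocorrelate,
    build_lookup,
    classify_fhr,
    demodulate,
    estimate_hr,
    estimate_hr_amdf,
    synthesize_doppler,
    track,
)

from conftest import naive_autocorr


def impulse_train_envelope(period, n, rate=200.0, amplitude=1.0):
    x = np.zeros(n)
    x[::period] = amplitude
    return Envelope(samples=x, sample_rate_hz=rate)


class TestDemodulate:
    def test_zero_signal_gives_zero_envelope(self):
        sig = DopplerSignal(np.zeros(4000), 4000.0)
        env = demodulate(sig)
        assert not np.any(env.samples)

    def test_stationary_tone_gives_flat_envelope(self):
        t = np.arange(0, 4.0, 1 / 4000)
        sig = DopplerSignal(np.sin(2 * np.pi * 300 * t), 4000.0)
        env = demodulate(sig, cutoff_hz=20.0)
        core = env.samples[200:-200]  # ignore filter edges
        assert np.std(core) / np.mean(core) < 0.05

    def test_envelope_spectral_peak_at_beat_frequency(self):
        # HR=120 -> envelope fundamental at 2.0 Hz, found by FFT oracle
        sig = synthesize_doppler(
            DopplerConfig(heart_rate_bpm=120.0, snr_db=float("inf"), duration_s=8.0)
        )
        env = demodulate(sig)
        x = env.samples - env.samples.mean()
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), d=1 / env.sample_rate_hz)
        peak_hz = freqs[np.argmax(spec)]
        bin_hz = freqs[1]
        assert abs(peak_hz - 2.0) <= bin_hz

    def test_cutoff_above_nyquist_rejected(self):
        sig = DopplerSignal(np.zeros(100), 100.0)
        with pytest.raises(ValueError):
            demodulate(sig, cutoff_hz=60.0)


class TestAutocorrelate:
    def test_constant_envelope_is_zero_after_mean_removal(self):
        env = Envelope(np.full(500, 3.0), 200.0)
        r = autocorrelate(env, 100)
        np.testing.assert_allclose(r.values, 0.0, atol=1e-12)

    def test_impulse_train_peak_at_period(self):
        env = impulse_train_envelope(period=40, n=1000)
        r = autocorrelate(env, 200)
        assert int(np.argmax(r.values[1:])) + 1 == 40

    def test_matches_naive_double_loop(self, rng):
        for _ in range(10):
            n = int(rng.integers(64, 1024))
            x = rng.normal(size=n)
            env = Envelope(np.abs(x), 200.0)
            max_lag = n // 2
            got = autocorrelate(env, max_lag).values
            want = naive_autocorr(env.centered, max_lag)
            assert np.max(np.abs(got - want)) <= 1e-9 * np.max(np.abs(want))

    def test_zero_lag_dominates(self, rng):
        env = Envelope(np.abs(rng.normal(size=800)), 200.0)
        r = autocorrelate(env, 300)
        assert np.all(r.values[0] >= r.values)

    def test_short_window_rejected(self):
        env = Envelope(np.ones(10), 200.0)
        with pytest.raises(InsufficientDataError):
            autocorrelate(env, 50)


class TestBuildLookup:
    @pytest.mark.parametrize("fs, hr, expected", [(1000.0, 120.0, 500), (1000.0, 60.0, 1000)])
    def test_serial_number_values(self, fs, hr, expected):
        table = build_lookup(fs, hr_min_bpm=50, hr_max_bpm=240)
        i = np.where(table.hr_grid_bpm == hr)[0][0]
        assert table.serial_numbers[i] == expected

    def test_serials_strictly_decreasing(self):
        table = build_lookup(200.0, 50, 240, 1)
        assert np.all(np.diff(table.serial_numbers) < 0)

    def test_rate_lag_product_within_rounding(self):
        # R_f * S_n ~ 60 fs, with |error| bounded by half a lag step (R_f/2)
        for fs in (200.0, 1000.0):
            table = build_lookup(fs, 50, 240, 1)
            err = np.abs(table.hr_grid_bpm * table.serial_numbers - 60 * fs)
            assert np.all(err <= table.hr_grid_bpm / 2 + 1e-9)

    def test_too_low_rate_rejected(self):
        with pytest.raises(ValueError):
            build_lookup(1.0, 100, 240, 1)


class TestEstimateHR:
    def test_impulse_train_at_120bpm(self):
        # 2 Hz impulse train at 200 Hz envelope rate: period 100 samples
        env = impulse_train_envelope(period=100, n=2000, rate=200.0)
        table = build_lookup(200.0, 50, 240, 1)
        est = estimate_hr(autocorrelate(env, table.max_serial), table)
        assert est.bpm == pytest.approx(120.0, abs=1.0)
        assert est.status == NORMAL

    def test_all_zero_envelope_is_no_signal(self):
        env = Envelope(np.zeros(2000), 200.0)
        table = build_lookup(200.0, 50, 240, 1)
        est = estimate_hr(autocorrelate(env, table.max_serial), table)
        assert est.status == NO_SIGNAL

    def test_table_longer_than_autocorr_rejected(self):
        env = Envelope(np.abs(np.sin(np.arange(500))), 200.0)
        table = build_lookup(200.0, 50, 240, 1)
        with pytest.raises(InsufficientDataError):
            estimate_hr(autocorrelate(env, 100), table)

    def test_agrees_with_exhaustive_lag_argmax(self, rng):
        # lookup-sampled maximum vs full-lag search, noiseless synthesis
        for _ in range(20):
            hr = float(rng.uniform(55, 235))
            sig = synthesize_doppler(
                DopplerConfig(heart_rate_bpm=hr, snr_db=float("inf"), duration_s=4.0)
            )
            env = demodulate(sig)
            table = build_lookup(env.sample_rate_hz)
            ac = autocorrelate(env, table.max_serial)
            est = estimate_hr(ac, table)
            smin = int(table.serial_numbers.min())
            m = smin + int(np.argmax(ac.values[smin:]))
            assert est.bpm == pytest.approx(60 * env.sample_rate_hz / m, abs=1.0)


class TestAMDF:
    def test_periodic_envelope_recovers_period(self):
        env = impulse_train_envelope(period=100, n=2000, rate=200.0)
        table = build_lookup(200.0, 50, 240, 1)
        est = estimate_hr_amdf(env, table)
        assert est.bpm == pytest.approx(120.0, abs=1.0)
        assert est.confidence > 0.9

    def test_all_zero_envelope_is_no_signal(self):
        table = build_lookup(200.0, 50, 240, 1)
        est = estimate_hr_amdf(Envelope(np.zeros(2000), 200.0), table)
        assert est.status == NO_SIGNAL

    @pytest.mark.parametrize("hr", [60.0, 120.0, 180.0, 240.0])
    def test_agrees_with_autocorrelation_noiseless(self, hr):
        sig = synthesize_doppler(DopplerConfig(heart_rate_bpm=hr, snr_db=float("inf")))
        a = track(sig, method="autocorr")
        b = track(sig, method="amdf")
        for ea, eb in zip(a, b):
            assert abs(ea.bpm - eb.bpm) <= 1.0


class TestClassifyFHR:
    @pytest.mark.parametrize(
        "bpm, expected",
        [
            (140.0, NORMAL),
            (110.0, DISTRESS),
            (120.0, NORMAL),   # inclusive lower bound
            (160.0, NORMAL),   # inclusive upper bound
            (119.9, DISTRESS),
            (160.1, DISTRESS),
        ],
    )
    def test_normal_band(self, bpm, expected):
        assert classify_fhr(bpm) == expected

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            classify_fhr(0.0)

    @given(bpm=st.floats(1.0, 300.0))
    def test_threshold_is_exact(self, bpm):
        assert (classify_fhr(bpm) == NORMAL) == (120.0 <= bpm <= 160.0)


class TestTrack:
    def test_noiseless_recovery_every_window(self):
        sig = synthesize_doppler(
            DopplerConfig(heart_rate_bpm=150.0, snr_db=float("inf"), duration_s=8.0)
        )
        for est in track(sig):
            assert est.bpm == pytest.approx(150.0, abs=1.0)
            assert est.status == NORMAL

    def test_single_window_signal(self):
        sig = synthesize_doppler(
            DopplerConfig(heart_rate_bpm=140.0, snr_db=float("inf"), duration_s=4.0)
        )
        ests = track(sig)
        assert len(ests) == 1
        assert ests[0].bpm == pytest.approx(140.0, abs=1.0)

    def test_too_short_signal_rejected(self):
        sig = synthesize_doppler(DopplerConfig(duration_s=2.0))
        with pytest.raises(InsufficientDataError):
            track(sig)

    def test_window_must_cover_two_periods(self):
        sig = synthesize_doppler(DopplerConfig(duration_s=8.0))
        with pytest.raises(ValueError):
            track(sig, window_s=2.0, hr_min_bpm=50.0)

    def test_step_change_transitions_monotonically(self):
        # 120 bpm for 6 s then 160 bpm for 6 s; estimates move one way
        a = synthesize_doppler(
            DopplerConfig(heart_rate_bpm=120.0, snr_db=float("inf"), duration_s=6.0)
        )
        b = synthesize_doppler(
            DopplerConfig(heart_rate_bpm=160.0, snr_db=float("inf"), duration_s=6.0)
        )
        sig = DopplerSignal(np.concatenate([a.samples, b.samples]), 4000.0)
        bpm = np.array([e.bpm for e in track(sig) if e.status != NO_SIGNAL])
        assert bpm[0] == pytest.approx(120.0, abs=1.0)
        assert bpm[-1] == pytest.approx(160.0, abs=1.0)
        assert np.all(np.diff(bpm) >= -1.0)  # monotone up to grid resolution
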