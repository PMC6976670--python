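"""EEG preprocessing, epoching, rejection and spectral estimation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from statebold.design import Event, EventSchedule, SessionDesign, generate_event_schedule
from statebold.eeg import (
    EpochSet,
    PreprocessConfig,
    epoch_events,
    estimate_power,
    peak_frequency,
    preprocess,
    reject_artifacts,
    trial_power,
)
from statebold.recording import EEGRecording
from statebold.simulate import NoiseParams, simulate_eeg

CFG4 = PreprocessConfig(reference_channels=("P2", "FC4", "Cz", "Pz"))


def _recording(samples, rate=5000.0, channels=("P2", "FC4", "Cz", "Pz")):
    return EEGRecording(channels=list(channels), sample_rate=rate, samples=samples)


class TestPreprocess:
    def test_reference_mean_channel_zeroed(self):
        # every channel identical -> after average referencing all zero
        x = np.tile(np.sin(2 * np.pi * 7 * np.arange(5000) / 5000.0), (4, 1))
        out = preprocess(_recording(x), CFG4)
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_zero_phase_and_passband_gain(self):
        # 10 Hz tone: zero lag (cross-correlation peak at 0) and ~unit gain
        rate, dur = 5000.0, 8.0
        t = np.arange(int(rate * dur)) / rate
        tone = np.sin(2 * np.pi * 10 * t)
        x = np.vstack([tone, -tone, np.zeros_like(t), np.zeros_like(t)])
        out = preprocess(_recording(x), CFG4)
        y = out.get_channel("P2")
        t2 = np.arange(len(y)) / out.sample_rate
        ref = np.sin(2 * np.pi * 10 * t2)
        # interior, away from filter edge effects
        sl = slice(500, len(y) - 500)
        lags = np.arange(-20, 21)
        xc = [np.dot(y[sl], np.roll(ref, l)[sl]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0
        amp = 2 * np.abs(np.dot(y[sl], ref[sl])) / np.sum(ref[sl] ** 2) / 2
        # channel carries tone minus reference mean (tone - tone/... ) -> compare shape
        fitted = np.dot(y[sl], ref[sl]) / np.dot(ref[sl], ref[sl])
        resid = y[sl] - fitted * ref[sl]
        assert np.sqrt(np.mean(resid**2)) < 0.01 * abs(fitted)

    def test_downsample_rate(self):
        x = np.zeros((4, 10000))
        out = preprocess(_recording(x), CFG4)
        assert out.sample_rate == 500.0
        assert out.n_samples == 1000

    def test_missing_reference_channel_named(self):
        x = np.zeros((2, 1000))
        with pytest.raises(KeyError, match="FC4"):
            preprocess(_recording(x, channels=("P2", "Cz")), CFG4)


def _single_event_schedule(onset=2.0, n=1, spacing=1.5):
    evs = [Event(onset=onset + i * spacing, type="tms", run_index=0) for i in range(n)]
    return EventSchedule(events=evs)


class TestEpoching:
    def test_epoch_sample_count(self):
        # [-500, -5) ms at 500 Hz -> 248 samples
        rec = EEGRecording(["P2"], 500.0, np.zeros((1, 5000)))
        ep = epoch_events(rec, _single_event_schedule(), run_offsets={0: 0.0})
        assert ep.n_samples == 248

    def test_linear_ramp_annihilated(self):
        rec = EEGRecording(["P2"], 500.0, 3.7 * np.arange(5000)[None, :].astype(float))
        ep = epoch_events(rec, _single_event_schedule(), run_offsets={0: 0.0})
        assert np.allclose(ep.data, 0.0, atol=1e-8)

    def test_constant_epoch_zeroed_by_baseline(self):
        rec = EEGRecording(["P2"], 500.0, np.full((1, 5000), 7.0))
        ep = epoch_events(rec, _single_event_schedule(), run_offsets={0: 0.0})
        assert np.allclose(ep.data, 0.0, atol=1e-10)

    def test_event_near_start_flagged_not_dropped(self):
        rec = EEGRecording(["P2"], 500.0, np.zeros((1, 5000)))
        ep = epoch_events(rec, _single_event_schedule(onset=0.1), run_offsets={0: 0.0})
        assert ep.n_trials == 1
        assert ep.rejected[0, 0]
        assert "out_of_range" in ep.reasons[0][0]


def _epochs_from_array(data):
    """Wrap (n_trials, n_samples) data as a single-channel EpochSet."""
    arr = np.asarray(data, dtype=float)[:, None, :]
    evs = [Event(onset=2.0 + 2 * i, type="tms", run_index=0) for i in range(arr.shape[0])]
    return EpochSet(
        data=arr,
        channels=["P2"],
        sample_rate=500.0,
        events=evs,
        window=(-0.5, -0.005),
        baseline_window=(-0.45, -0.05),
    )


class TestRejection:
    def test_direct_rule_evaluation(self):
        # 25 µV jump over 2 ms = 12.5 µV/ms < 20, max 30 µV < 80 -> kept
        ep = np.zeros(248)
        ep[100:] = 25.0
        ep[0] = 30.0
        es = reject_artifacts(_epochs_from_array([ep]))
        assert not es.rejected[0, 0]

    def test_amplitude_over_80_rejected(self):
        ep = np.zeros(248)
        ep[120] = 85.0
        es = reject_artifacts(_epochs_from_array([ep]))
        assert es.rejected[0, 0]
        assert "amplitude" in es.reasons[0][0]

    def test_all_zero_kept(self):
        es = reject_artifacts(_epochs_from_array([np.zeros(248)]))
        assert not es.rejected.any()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 1.0))
    def test_rejection_monotone_in_thresholds(self, seed, shrink):
        data = np.random.default_rng(seed).normal(scale=40, size=(6, 248))
        base = reject_artifacts(_epochs_from_array(data))
        tight = reject_artifacts(
            _epochs_from_array(data),
            gradient_thresh=20 * shrink,
            step_thresh=200 * shrink,
            amp_thresh=80 * shrink,
        )
        assert np.all(tight.rejected | ~base.rejected)  # base-rejected stays rejected


class TestPower:
    def _tone_epochs(self, freq, amp=1.0, n_trials=3, n=248, rate=500.0):
        t = np.arange(n) / rate
        return _epochs_from_array([amp * np.sin(2 * np.pi * freq * t)] * n_trials)

    def test_grid_is_8_to_18_step_2(self):
        spec = estimate_power(self._tone_epochs(10.0), "P2")
        assert np.array_equal(spec.freqs, [8, 10, 12, 14, 16, 18])

    def test_pure_tone_peaks_at_generating_frequency(self):
        spec = estimate_power(self._tone_epochs(10.0), "P2")
        assert spec.freqs[np.argmax(spec.mean_spectrum())] == 10.0

    def test_power_scales_quadratically(self):
        p1 = estimate_power(self._tone_epochs(10.0, amp=1.0), "P2").power[0, 1]
        p2 = estimate_power(self._tone_epochs(10.0, amp=2.0), "P2").power[0, 1]
        assert p2 == pytest.approx(4 * p1, rel=0.01)

    def test_power_nonnegative_and_offset_invariant(self, rng):
        data = rng.normal(size=(4, 248))
        a = estimate_power(_epochs_from_array(data), "P2")
        b = estimate_power(_epochs_from_array(data + 11.3), "P2")
        assert np.all(a.power >= 0)
        assert np.allclose(a.power, b.power, rtol=1e-8, atol=1e-12)

    def test_too_short_epoch_lists_frequencies(self):
        short = _epochs_from_array(np.zeros((2, 100)))  # 200 ms < 3 cycles at 8 Hz
        with pytest.raises(ValueError, match="8"):
            estimate_power(short, "P2")


class TestPeakAndTrialPower:
    def _spectra(self, power):
        es = _epochs_from_array(np.zeros((power.shape[0], 248)))
        spec = estimate_power(es, "P2")
        spec.power = power
        return spec

    def test_flat_spectrum_tie_returns_lowest(self):
        spec = self._spectra(np.ones((3, 6)))
        assert peak_frequency(spec, (8, 12)) == 8.0

    def test_peak_equals_linear_scan(self, rng):
        power = rng.uniform(size=(10, 6))
        spec = self._spectra(power)
        band = (8, 12)
        sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
        expect = spec.freqs[sel][np.argmax(power.mean(0)[sel])]
        assert peak_frequency(spec, band) == expect

    def test_empty_band_errors(self):
        with pytest.raises(ValueError, match="intersect"):
            peak_frequency(self._spectra(np.ones((2, 6))), (30, 35))

    def test_trial_power_filters_rejected(self, rng):
        power = rng.uniform(size=(5, 6))
        spec = self._spectra(power)
        spec.retained = np.array([True, False, True, True, False])
        tp = trial_power(spec, 10.0)
        assert len(tp) == 3
        assert np.allclose(tp.power, power[[0, 2, 3], 1])
        assert list(tp.trial_ids) == [0, 2, 3]

    def test_off_grid_peak_errors(self):
        with pytest.raises(ValueError, match="not on grid"):
            trial_power(self._spectra(np.ones((2, 6))), 9.0)

    def test_trial_order_equivariance(self, rng):
        power = rng.uniform(size=(6, 6))
        spec = self._spectra(power)
        perm = rng.permutation(6)
        spec2 = self._spectra(power[perm])
        a = trial_power(spec, 10.0).power
        b = trial_power(spec2, 10.0).power
        assert np.allclose(b, a[perm])


def test_end_to_end_power_tracks_ground_truth():
    """Estimated trial power rank-correlates > 0.8 with the true envelope
    power at default signal-to-noise."""
    from scipy.stats import spearmanr

    d = SessionDesign(n_runs=1, eeg_rate=1000.0)
    sched = generate_event_schedule(d, seed=3)
    eeg, truth = simulate_eeg(sched, seed=4)
    clean = preprocess(eeg, CFG4)
    epochs = reject_artifacts(epoch_events(clean, sched))
    spec = estimate_power(epochs, "P2")
    tp = trial_power(spec, peak_frequency(spec, (8, 12)))
    rho = spearmanr(truth.alpha_power[tp.trial_ids], tp.power).statistic
    assert rho > 0.8


def test_constant_envelope_noiseless_power_constant():
    """Zero noise and constant alpha envelope: per-trial power identical up
    to taper tolerance."""
    d = SessionDesign(n_runs=1, run_duration=313 * 2.25, eeg_rate=1000.0)
    sched = generate_event_schedule(d, seed=5)
    from statebold.simulate import EnvelopeParams

    eeg, _ = simulate_eeg(
        sched,
        envelope_params=EnvelopeParams(log_sd=0.0, mean_amplitude=10.0),
        beta_envelope_params=EnvelopeParams(log_sd=0.0, mean_amplitude=0.0),
        noise_params=NoiseParams(amplitude=0.0),
        seed=6,
    )
    clean = preprocess(eeg, CFG4)
    spec = estimate_power(epoch_events(clean, sched), "P2")
    col = spec.power[:, 1]  # 10 Hz
    assert col.std() / col.mean() < 0.02
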