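"""EEG preprocessing, epoching, artifact rejection and pre-event band power.

The chain mirrors a standard concurrent-TMS EEG recipe: downsample to
500 Hz, re-reference to an average of a fixed electrode set, zero-phase
Butterworth band-pass (0.5-40 Hz, 24 dB/oct) plus 50 Hz notch, epoch the
artifact-free pre-event window (-500 to -5 ms before the first pulse),
baseline-correct and detrend, reject epochs with steep gradients / large
steps / excessive amplitude, then estimate single-trial 8-18 Hz power with
Hanning tapers of three cycles per frequency.

Per-trial power at the peak frequency of the across-trial mean spectrum
(alpha 8-12 Hz on a parietal channel, low-beta 14-18 Hz on a frontal
channel) is the brain-state covariate carried into the fMRI analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal

from .design import Event, EventSchedule
from .recording import EEGRecording

__all__ = [
    "DEFAULT_REFERENCE",
    "PreprocessConfig",
    "EpochSet",
    "PowerSpectrumSet",
    "TrialPowerVector",
    "preprocess",
    "epoch_events",
    "reject_artifacts",
    "estimate_power",
    "peak_frequency",
    "trial_power",
]

# 22-electrode fronto-central/parietal average-reference montage
DEFAULT_REFERENCE = (
    "F1 F2 FC1 FC2 F3 F4 FC3 FC4 Fz FCz C1 C2 C3 C4 "
    "CP1 CP2 CP3 CP4 CPz P1 P2 Pz"
).split()


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate: float = 500.0
    reference_channels: tuple[str, ...] = tuple(DEFAULT_REFERENCE)
    bandpass: tuple[float, float] = (0.5, 40.0)
    bandpass_slope: float = 24.0  # dB/octave; order = slope / 6
    notch: float = 50.0
    notch_q: float = 30.0

    def validate(self, raw_rate: float) -> None:
        if raw_rate % self.target_rate != 0:
            raise ValueError(
                f"target_rate {self.target_rate} must divide raw rate {raw_rate}"
            )
        if self.bandpass[1] >= self.target_rate / 2:
            raise ValueError("bandpass upper edge must be below target Nyquist")
        if self.bandpass[0] <= 0 or self.bandpass[0] >= self.bandpass[1]:
            raise ValueError("invalid bandpass interval")


def preprocess(raw: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Downsample, re-reference, band-pass (zero phase) and notch-filter.

    Reference channels absent from the recording raise a ``KeyError``
    naming the first missing one. The Butterworth order is derived from
    the configured slope (24 dB/oct -> order 4) and applied
    forward-backward, so the passband shows no phase lag.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    cfg.validate(raw.sample_rate)
    for ch in cfg.reference_channels:
        if ch not in raw.channels:
            raise KeyError(f"reference channel {ch!r} missing from recording")

    q = int(raw.sample_rate // cfg.target_rate)
    x = raw.samples
    if q > 1:
        x = scipy.signal.resample_poly(x, up=1, down=q, axis=1)
    rate = cfg.target_rate

    ref_idx = [raw.channels.index(ch) for ch in cfg.reference_channels]
    x = x - x[ref_idx].mean(axis=0, keepdims=True)

    order = max(1, int(round(cfg.bandpass_slope / 6.0)))
    sos = scipy.signal.butter(order, cfg.bandpass, btype="bandpass", fs=rate, output="sos")
    x = scipy.signal.sosfiltfilt(sos, x, axis=1)

    if cfg.notch and cfg.notch < rate / 2:
        b, a = scipy.signal.iirnotch(cfg.notch, cfg.notch_q, fs=rate)
        x = scipy.signal.filtfilt(b, a, x, axis=1)

    return EEGRecording(
        channels=list(raw.channels),
        sample_rate=rate,
        samples=np.ascontiguousarray(x),
        annotations=list(raw.annotations),
    )


@dataclass
class EpochSet:
    """Pre-event segments, baseline-corrected and detrended.

    ``rejected[i, c]`` flags trial i on channel c; ``reasons[i][c]`` holds
    the matching reason codes. Trials whose window falls outside the
    recording are flagged (reason ``out_of_range``), never silently dropped.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples), µV
    channels: list[str]
    sample_rate: float
    events: list[Event]
    window: tuple[float, float]
    baseline_window: tuple[float, float]
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reasons: list[list[list[str]]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n_tr, n_ch, _ = self.data.shape
        if self.rejected is None:
            self.rejected = np.zeros((n_tr, n_ch), dtype=bool)
        if self.reasons is None:
            self.reasons = [[[] for _ in range(n_ch)] for _ in range(n_tr)]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        start = self.window[0]
        return start + np.arange(self.n_samples) / self.sample_rate

    def retained_mask(self, channel: str) -> np.ndarray:
        ci = self.channels.index(channel)
        return ~self.rejected[:, ci]


def _window_samples(window: tuple[float, float], rate: float) -> int:
    # closed-start / open-end: sample times window[0] + k/rate < window[1]
    return int(np.ceil((window[1] - window[0]) * rate - 1e-9))


def epoch_events(
    clean: EEGRecording,
    schedule: EventSchedule,
    window: tuple[float, float] = (-0.500, -0.005),
    baseline_window: tuple[float, float] = (-0.450, -0.050),
    run_offsets: dict[int, float] | None = None,
) -> EpochSet:
    """Extract per-event pre-stimulus segments; baseline-correct and detrend.

    Event onsets in the schedule are relative to their run's start;
    ``run_offsets`` maps run index to the run's start time within the
    recording (defaults to runs concatenated back-to-back at
    ``design.run_duration`` spacing, or all zero for a single run).
    TMS and null events are handled identically.
    """
    rate = clean.sample_rate
    n_samp = _window_samples(window, rate)
    if run_offsets is None:
        run_offsets = _default_run_offsets(schedule)

    bsl_lo = int(np.round((baseline_window[0] - window[0]) * rate))
    bsl_hi = int(np.round((baseline_window[1] - window[0]) * rate))

    n_ch = len(clean.channels)
    data = np.zeros((len(schedule.events), n_ch, n_samp))
    rejected = np.zeros((len(schedule.events), n_ch), dtype=bool)
    reasons: list[list[list[str]]] = [
        [[] for _ in range(n_ch)] for _ in range(len(schedule.events))
    ]
    for i, ev in enumerate(schedule.events):
        t0 = run_offsets[ev.run_index] + ev.onset + window[0]
        i0 = int(np.round(t0 * rate))
        if i0 < 0 or i0 + n_samp > clean.n_samples:
            rejected[i, :] = True
            for c in range(n_ch):
                reasons[i][c].append("out_of_range")
            continue
        seg = clean.samples[:, i0 : i0 + n_samp].copy()
        seg -= seg[:, bsl_lo:bsl_hi].mean(axis=1, keepdims=True)
        seg = scipy.signal.detrend(seg, axis=1, type="linear")
        data[i] = seg
    return EpochSet(
        data=data,
        channels=list(clean.channels),
        sample_rate=rate,
        events=list(schedule.events),
        window=window,
        baseline_window=baseline_window,
        rejected=rejected,
        reasons=reasons,
    )


def _default_run_offsets(schedule: EventSchedule) -> dict[int, float]:
    if schedule.design is not None:
        d = schedule.design
        return {r: r * d.run_duration for r in range(d.n_runs)}
    return {r: 0.0 for r in range(schedule.n_runs)}


def reject_artifacts(
    epochs: EpochSet,
    gradient_thresh: float = 20.0,  # µV/ms between adjacent samples
    step_thresh: float = 200.0,  # µV range within any 50 ms interval
    amp_thresh: float = 80.0,  # µV absolute
    step_interval: float = 0.050,
) -> EpochSet:
    """Flag epochs containing steep gradients, large steps or high amplitude.

    Rejection is monotone in each threshold: lowering a threshold can only
    add flags. Flags are combined with any pre-existing ones.
    """
    if min(gradient_thresh, step_thresh, amp_thresh) <= 0:
        raise ValueError("thresholds must be positive")
    out = EpochSet(
        data=epochs.data,
        channels=epochs.channels,
        sample_rate=epochs.sample_rate,
        events=epochs.events,
        window=epochs.window,
        baseline_window=epochs.baseline_window,
        rejected=epochs.rejected.copy(),
        reasons=[[list(c) for c in row] for row in epochs.reasons],
    )
    dt_ms = 1000.0 / epochs.sample_rate
    win = max(2, int(round(step_interval * epochs.sample_rate)) + 1)
    x = epochs.data
    grad_bad = (np.abs(np.diff(x, axis=2)) / dt_ms > gradient_thresh).any(axis=2)
    mx = scipy.ndimage.maximum_filter1d(x, size=win, axis=2, mode="nearest")
    mn = scipy.ndimage.minimum_filter1d(x, size=win, axis=2, mode="nearest")
    step_bad = (mx - mn > step_thresh).any(axis=2)
    amp_bad = (np.abs(x) > amp_thresh).any(axis=2)
    for i in range(epochs.n_trials):
        for c in range(len(epochs.channels)):
            if grad_bad[i, c]:
                out.reasons[i][c].append("gradient")
            if step_bad[i, c]:
                out.reasons[i][c].append("step")
            if amp_bad[i, c]:
                out.reasons[i][c].append("amplitude")
    out.rejected |= grad_bad | step_bad | amp_bad
    return out


DEFAULT_FREQS = np.arange(8.0, 19.0, 2.0)  # 8-18 Hz at 2 Hz resolution


@dataclass
class PowerSpectrumSet:
    """Single-trial power spectra for one channel on a fixed frequency grid."""

    freqs: np.ndarray  # Hz
    power: np.ndarray  # (n_trials, n_freqs), µV²
    channel: str
    events: list[Event]
    retained: np.ndarray  # (n_trials,) bool

    def mean_spectrum(self) -> np.ndarray:
        if not self.retained.any():
            raise ValueError("no retained trials")
        return self.power[self.retained].mean(axis=0)


def estimate_power(
    epochs: EpochSet,
    channel: str,
    freqs: np.ndarray | None = None,
    cycles: float = 3.0,
) -> PowerSpectrumSet:
    """Hanning-taper moving-window power at each grid frequency.

    For each frequency f a Hanning window of length ``cycles``/f slides
    across the (detrended) epoch at one-sample steps; per-trial power at f
    is the squared magnitude of the tapered Fourier coefficient, averaged
    over window positions, scaled so a unit-amplitude sinusoid at f yields
    its variance (0.5 µV²).
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    rate = epochs.sample_rate
    n_samp = epochs.n_samples
    too_long = [f for f in freqs if int(round(cycles / f * rate)) > n_samp]
    if too_long:
        raise ValueError(
            f"epoch of {n_samp / rate * 1e3:.0f} ms too short for {cycles} cycles at "
            f"{too_long} Hz"
        )
    ci = epochs.channels.index(channel)
    x = scipy.signal.detrend(epochs.data[:, ci, :], axis=1, type="linear")
    power = np.empty((epochs.n_trials, len(freqs)))
    for j, f in enumerate(freqs):
        wlen = int(round(cycles / f * rate))
        taper = np.hanning(wlen)
        t = np.arange(wlen) / rate
        kernel = taper * np.exp(-2j * np.pi * f * t)
        # amplitude calibration: unit sinusoid at f -> |coef| = 1
        scale = 2.0 / taper.sum()
        coef = scipy.signal.fftconvolve(x, kernel[None, ::-1], mode="valid", axes=1)
        amp2 = (np.abs(coef) * scale) ** 2
        power[:, j] = amp2.mean(axis=1) / 2.0  # power of sinusoid = A²/2
    return PowerSpectrumSet(
        freqs=freqs,
        power=power,
        channel=channel,
        events=list(epochs.events),
        retained=epochs.retained_mask(channel).copy(),
    )


def peak_frequency(spectra: PowerSpectrumSet, band: tuple[float, float]) -> float:
    """Grid frequency maximizing the across-trial mean spectrum within band.

    Ties resolve to the lowest frequency (ascending grid, first argmax).
    """
    sel = (spectra.freqs >= band[0]) & (spectra.freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} does not intersect grid {spectra.freqs}")
    mean = spectra.mean_spectrum()[sel]
    return float(spectra.freqs[sel][np.argmax(mean)])


@dataclass
class TrialPowerVector:
    """Per-trial power at a fixed peak frequency, retained trials only."""

    power: np.ndarray  # (n_retained,)
    peak: float  # Hz
    band: str  # "alpha" | "beta"
    channel: str
    events: list[Event]  # retained trials, schedule order
    trial_ids: np.ndarray  # indices into the original schedule

    def __len__(self) -> int:
        return len(self.power)


def trial_power(
    spectra: PowerSpectrumSet, peak: float, band: str = "alpha"
) -> TrialPowerVector:
    """Extract the retained-trial power column at the peak frequency."""
    hits = np.flatnonzero(np.isclose(spectra.freqs, peak))
    if len(hits) == 0:
        raise ValueError(f"peak {peak} Hz not on grid {spectra.freqs}")
    col = spectra.power[:, hits[0]]
    keep = np.flatnonzero(spectra.retained)
    return TrialPowerVector(
        power=col[keep].copy(),
        peak=float(peak),
        band=band,
        channel=spectra.channel,
        events=[spectra.events[i] for i in keep],
        trial_ids=keep,
    )
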