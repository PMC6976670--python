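"""Motor-evoked potential detection in post-event EMG epochs.

A subthreshold-stimulation check: epochs following the first TMS pulse
(and count-matched null events) are screened for MEPs with a baseline-SD
threshold rule, and per-run detection counts are compared between event
types with an exact Wilcoxon signed-rank test. Equal counts on TMS and
null events indicate stimulation below the motor threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .design import Event, EventSchedule
from .recording import EEGRecording

__all__ = ["EMGEpochs", "MEPDetection", "epoch_emg", "detect_mep", "compare_counts"]


@dataclass
class EMGEpochs:
    """Post-event bipolar EMG segments (time 0 = first pulse)."""

    data: np.ndarray  # (n_trials, n_samples), µV
    sample_rate: float
    events: list[Event]
    epoch_length: float  # seconds
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(self.data.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def epoch_emg(
    emg: EEGRecording,
    schedule: EventSchedule,
    epoch_length: float = 0.260,
    run_offsets: dict[int, float] | None = None,
) -> EMGEpochs:
    """Segment the locally-referenced bipolar EMG after each event onset.

    Epoch length is configurable between 160 and 260 ms. With two channels
    the bipolar derivation is their difference; a single channel is taken
    as already bipolar. Events whose epoch would overrun the recording are
    flagged, not dropped.
    """
    if not (0.160 <= epoch_length <= 0.260):
        raise ValueError("epoch_length must lie in [0.160, 0.260] s")
    if len(emg.channels) == 2:
        sig = emg.samples[0] - emg.samples[1]
    else:
        sig = emg.samples[0]
    rate = emg.sample_rate
    n_samp = int(round(epoch_length * rate))
    if run_offsets is None:
        if schedule.design is not None:
            d = schedule.design
            run_offsets = {r: r * d.run_duration for r in range(d.n_runs)}
        else:
            run_offsets = {r: 0.0 for r in range(schedule.n_runs)}
    data = np.zeros((len(schedule.events), n_samp))
    flagged = np.zeros(len(schedule.events), dtype=bool)
    for i, ev in enumerate(schedule.events):
        i0 = int(np.round((run_offsets[ev.run_index] + ev.onset) * rate))
        if i0 < 0 or i0 + n_samp > len(sig):
            flagged[i] = True
            continue
        data[i] = sig[i0 : i0 + n_samp]
    return EMGEpochs(
        data=data,
        sample_rate=rate,
        events=list(schedule.events),
        epoch_length=epoch_length,
        flagged=flagged,
    )


@dataclass
class MEPDetection:
    trial_id: int
    detected: bool
    onset_ms: float | None
    peak_ms: float | None
    baseline_sd: float
    flagged: bool = False


def detect_mep(
    epoch: np.ndarray,
    sample_rate: float,
    sd_thresh: float = 5.0,
    baseline_window: tuple[float, float] = (0.0, 0.010),
    onset_window: tuple[float, float] = (0.005, 0.040),
    peak_window: tuple[float, float] = (0.015, 0.050),
    trial_id: int = 0,
) -> MEPDetection:
    """Threshold MEP detector on one post-event epoch.

    The 0-10 ms baseline supplies mean and SD; the epoch (baseline mean
    subtracted) is screened for |signal| > ``sd_thresh`` x SD. A detection
    requires the first threshold crossing inside the onset search window
    and the absolute extremum inside the peak search window. The criterion
    scales with the baseline SD, so the decision is invariant to overall
    amplitude scaling. A zero baseline SD flags the trial and skips
    detection.
    """
    epoch = np.asarray(epoch, dtype=float)
    t = np.arange(len(epoch)) / sample_rate
    for w in (baseline_window, onset_window, peak_window):
        if w[1] > t[-1] + 1.0 / sample_rate:
            raise ValueError(f"window {w} extends beyond epoch of {t[-1]:.3f} s")
    bsl = epoch[(t >= baseline_window[0]) & (t < baseline_window[1])]
    sd = float(bsl.std(ddof=0))
    if sd == 0:
        return MEPDetection(trial_id, False, None, None, 0.0, flagged=True)
    x = epoch - bsl.mean()
    above = np.abs(x) > sd_thresh * sd
    if not above.any():
        return MEPDetection(trial_id, False, None, None, sd)
    first = int(np.argmax(above))
    onset_t = t[first]
    peak_i = int(np.argmax(np.abs(x)))
    peak_t = t[peak_i]
    ok = (onset_window[0] <= onset_t <= onset_window[1]) and (
        peak_window[0] <= peak_t <= peak_window[1]
    )
    return MEPDetection(
        trial_id,
        bool(ok),
        float(onset_t * 1e3) if ok else None,
        float(peak_t * 1e3) if ok else None,
        sd,
    )


def detect_all(epochs: EMGEpochs, **kwargs) -> list[MEPDetection]:
    """Run the detector on every non-flagged epoch."""
    out = []
    for i in range(epochs.n_trials):
        if epochs.flagged[i]:
            out.append(MEPDetection(i, False, None, None, 0.0, flagged=True))
        else:
            out.append(detect_mep(epochs.data[i], epochs.sample_rate, trial_id=i, **kwargs))
    return out


def compare_counts(
    tms_counts: np.ndarray, null_counts: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-unit MEP counts.

    Uses the exact null distribution for n <= 25 pairs; zero differences
    are dropped (standard convention). All-zero differences give
    (0, p = 1) rather than an error.
    """
    tms_counts = np.asarray(tms_counts, dtype=float)
    null_counts = np.asarray(null_counts, dtype=float)
    if tms_counts.shape != null_counts.shape:
        raise ValueError("paired count vectors must have equal length")
    diffs = tms_counts - null_counts
    if np.all(diffs == 0):
        return 0.0, 1.0
    n_nonzero = int(np.sum(diffs != 0))
    method = "exact" if n_nonzero <= 25 else "approx"
    res = scipy.stats.wilcoxon(
        tms_counts, null_counts, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)
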