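"""Session design and event scheduling for concurrent TMS-EEG-fMRI runs.

The temporal design interleaves triple-pulse TMS events with count-matched
null events (no pulse delivered) inside the silent acquisition gap at the
end of each sparse-sampling TR, so that the pre-event EEG window is free of
gradient artifacts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["SessionDesign", "Event", "EventSchedule", "generate_event_schedule"]


@dataclass(frozen=True)
class SessionDesign:
    """Parameters of one simulated TMS-EEG-fMRI session.

    The defaults reproduce a sparse-sampling EPI protocol: TR 2.25 s of
    which the final 0.75 s is a silent acquisition gap, events (TMS or
    null) every 13.5 s on average with uniform jitter, subthreshold
    triple pulses at 15 Hz, EEG digitized at 5 kHz.
    """

    n_runs: int = 5
    run_duration: float = 313 * 2.25  # seconds (313 volumes at TR 2.25 s)
    tr: float = 2.25
    acquisition_gap: float = 0.75
    mean_iti: float = 13.5
    iti_jitter: tuple[float, float] = (11.25, 15.75)
    pulses_per_event: int = 3
    pulse_rate: float = 15.0
    eeg_rate: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.iti_jitter
        if not (lo <= self.mean_iti <= hi):
            raise ValueError(
                f"iti_jitter bounds {self.iti_jitter} must bracket mean_iti={self.mean_iti}"
            )
        if self.acquisition_gap >= self.tr:
            raise ValueError("acquisition_gap must be shorter than tr")
        if self.pulse_train_duration >= self.acquisition_gap:
            raise ValueError(
                f"pulse train ({self.pulse_train_duration * 1e3:.0f} ms) does not fit "
                f"inside the acquisition gap ({self.acquisition_gap * 1e3:.0f} ms)"
            )
        if self.eeg_rate <= 0:
            raise ValueError("eeg_rate must be positive")

    @property
    def pulse_train_duration(self) -> float:
        """Duration of one pulse train in seconds (133 ms at defaults)."""
        return (self.pulses_per_event - 1) / self.pulse_rate

    @property
    def n_scans_per_run(self) -> int:
        return int(round(self.run_duration / self.tr))

    def gap_centers(self) -> np.ndarray:
        """Onset grid: centers of the silent gaps, within one run."""
        k = np.arange(self.n_scans_per_run)
        return k * self.tr + (self.tr - self.acquisition_gap) + self.acquisition_gap / 2.0


@dataclass(frozen=True)
class Event:
    onset: float  # seconds from run start
    type: Literal["tms", "null"]
    run_index: int


@dataclass
class EventSchedule:
    """Timed TMS and null events across runs, onsets relative to run start."""

    events: list[Event] = field(default_factory=list)
    design: SessionDesign | None = None

    def __len__(self) -> int:
        return len(self.events)

    def per_run(self, run_index: int) -> list[Event]:
        return [e for e in self.events if e.run_index == run_index]

    def onsets(self, event_type: str | None = None, run_index: int | None = None) -> np.ndarray:
        sel = [
            e.onset
            for e in self.events
            if (event_type is None or e.type == event_type)
            and (run_index is None or e.run_index == run_index)
        ]
        return np.asarray(sel, dtype=float)

    def count(self, event_type: str, run_index: int | None = None) -> int:
        return sum(
            1
            for e in self.events
            if e.type == event_type and (run_index is None or e.run_index == run_index)
        )

    @property
    def n_runs(self) -> int:
        return 1 + max((e.run_index for e in self.events), default=-1)

    def validate(self) -> None:
        for r in range(self.n_runs):
            evs = self.per_run(r)
            on = np.array([e.onset for e in evs])
            if np.any(np.diff(on) <= 0):
                raise ValueError(f"onsets not strictly increasing in run {r}")
            if self.count("tms", r) != self.count("null", r):
                raise ValueError(f"TMS/null counts differ in run {r}")


def _slot_onsets(design: SessionDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw a merged event-slot stream for one run and snap onsets to gap centers.

    ITIs are uniform on the jitter interval; each onset then snaps to the
    nearest silent-gap center (never backwards past the previous slot).
    """
    centers = design.gap_centers()
    margin = 2.0 * design.tr  # keep events clear of run edges
    t = centers[0] + rng.uniform(0.0, design.mean_iti / 2.0)
    onsets: list[float] = []
    last_idx = -1
    lo, hi = design.iti_jitter
    while True:
        idx = int(np.argmin(np.abs(centers - t)))
        if idx <= last_idx:
            idx = last_idx + 1
        if idx >= len(centers) or centers[idx] > design.run_duration - margin:
            break
        onsets.append(float(centers[idx]))
        last_idx = idx
        t = centers[idx] + rng.uniform(lo, hi)
    return np.asarray(onsets)


def generate_event_schedule(design: SessionDesign, seed: int | None = None) -> EventSchedule:
    """Generate the interleaved TMS/null event schedule for a full session.

    One merged stream of event slots is drawn per run with inter-slot
    intervals uniform on ``design.iti_jitter``; slots snap to the nearest
    acquisition-gap center, and are then assigned ``tms`` / ``null`` labels
    by a balanced random shuffle per run (equal counts; an odd trailing
    slot is dropped). Deterministic given the seed.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    events: list[Event] = []
    for r in range(design.n_runs):
        onsets = _slot_onsets(design, rng)
        if len(onsets) < 2:
            raise ValueError(
                f"run_duration={design.run_duration} s too short for at least one "
                "TMS and one null event"
            )
        n_pairs = len(onsets) // 2
        onsets = onsets[: 2 * n_pairs]
        labels = np.array(["tms"] * n_pairs + ["null"] * n_pairs)
        rng.shuffle(labels)
        for t, lab in zip(onsets, labels):
            events.append(Event(onset=float(t), type=str(lab), run_index=r))
    sched = EventSchedule(events=events, design=design)
    sched.validate()
    return sched
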