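"""Synthetic concurrent TMS-EEG-fMRI sessions with known state-dependent gating.

The generator is the verification backbone of the package: it produces a
complete session — jittered triple-pulse TMS schedule with count-matched
null events, pre-event alpha/beta oscillations with slowly drifting
envelopes, BOLD responses whose single-trial amplitude is linearly gated
by standardized pre-event alpha power, AR-correlated scanner noise with
drift and motion confounds, and EMG with a controllable motor-evoked
potential rate — while recording the ground truth needed for parameter
recovery.

Gating model: for TMS event i in a gated region,

    amplitude_i = beta0 + gamma * z_i + eps_i,   eps_i ~ N(0, sigma_eps),

where z_i is the standardized true pre-event alpha envelope power.
``gamma = 0`` produces a valid null world; ``gamma < 0`` encodes
inhibitory gating (strong alpha -> weaker evoked response). Null events
evoke nothing, and non-gated regions use gamma = 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .design import EventSchedule, SessionDesign, generate_event_schedule
from .glm import BOLDSeries, HRFParams, hrf
from .recording import EEGRecording

__all__ = [
    "EnvelopeParams",
    "NoiseParams",
    "GroundTruth",
    "ROIDef",
    "ROILayout",
    "default_roi_layout",
    "replicated_roi_layout",
    "BOLDSimulation",
    "simulate_eeg",
    "simulate_bold",
    "simulate_emg",
    "simulate_trial_table",
]


@dataclass(frozen=True)
class EnvelopeParams:
    """Log-Gaussian Ornstein-Uhlenbeck envelope of a band-limited oscillation.

    The log-amplitude relaxes toward its mean with time constant ``tau``
    (seconds) and stationary standard deviation ``log_sd``; the envelope is
    therefore smooth, positive and lognormal, with median amplitude
    ``mean_amplitude`` (µV).
    """

    tau: float = 2.0
    log_sd: float = 0.5
    mean_amplitude: float = 20.0


@dataclass(frozen=True)
class NoiseParams:
    """1/f background noise: RMS ``amplitude`` (µV) and spectral exponent."""

    amplitude: float = 5.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")


@dataclass
class GroundTruth:
    """Simulation ground truth stored alongside every synthetic dataset."""

    gating_coefficient: float
    baseline_amplitude: float
    amplitude_noise_sd: float
    alpha_power: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_power: np.ndarray = field(default_factory=lambda: np.zeros(0))
    roi_flags: dict[str, str] = field(default_factory=dict)  # label -> motor | non_motor
    gated_rois: list[str] = field(default_factory=list)
    mep_rate: float = 0.0
    amplitudes: dict[str, np.ndarray] = field(default_factory=dict)  # per TMS event
    mep_present: np.ndarray | None = None  # per TMS event

    def alpha_z(self, event_mask: np.ndarray) -> np.ndarray:
        """Standardized true alpha power over the selected events."""
        x = self.alpha_power[event_mask]
        sd = x.std(ddof=0)
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd


def _ou_log_envelope(n: int, rate: float, params: EnvelopeParams, rng: np.random.Generator) -> np.ndarray:
    """Stationary log-Gaussian OU envelope sampled at ``rate``."""
    dt = 1.0 / rate
    a = np.exp(-dt / params.tau)
    innov_sd = params.log_sd * np.sqrt(1.0 - a * a)
    e = rng.standard_normal(n) * innov_sd
    e[0] = rng.standard_normal() * params.log_sd  # stationary start
    x = scipy.signal.lfilter([1.0], [1.0, -a], e)
    return params.mean_amplitude * np.exp(x)


def _pink_noise(n: int, params: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    if params.amplitude == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-params.exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    rms = x.std()
    return x / rms * params.amplitude if rms > 0 else x


def _pre_event_power(
    envelope: np.ndarray,
    rate: float,
    onsets: np.ndarray,
    window: tuple[float, float] = (-0.500, -0.005),
) -> np.ndarray:
    """True mean oscillation power (envelope²/2) over each pre-event window."""
    n_samp = int(np.ceil((window[1] - window[0]) * rate - 1e-9))
    out = np.empty(len(onsets))
    for i, t in enumerate(onsets):
        i0 = int(np.round((t + window[0]) * rate))
        i0 = max(i0, 0)
        seg = envelope[i0 : i0 + n_samp]
        out[i] = float(np.mean(seg**2) / 2.0)
    return out


def simulate_eeg(
    schedule: EventSchedule,
    alpha_freq: float = 10.0,
    beta_freq: float = 14.0,
    envelope_params: EnvelopeParams | None = None,
    beta_envelope_params: EnvelopeParams | None = None,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    alpha_channel: str = "P2",
    beta_channel: str = "FC4",
    extra_channels: tuple[str, ...] = ("Cz", "Pz"),
) -> tuple[EEGRecording, GroundTruth]:
    """Simulate the continuous EEG of a full session.

    The parietal-labelled channel carries the alpha oscillation (smooth
    lognormal envelope times a sinusoid at ``alpha_freq``), the frontal
    channel an independent beta oscillation, and every channel adds 1/f
    background noise. Runs are concatenated back-to-back; event markers
    become annotations. The true mean envelope power over each pre-event
    window is recorded in the returned :class:`GroundTruth`.
    """
    if not (8.0 <= alpha_freq <= 12.0):
        raise ValueError("alpha_freq must lie in 8-12 Hz")
    if not (14.0 <= beta_freq <= 18.0):
        raise ValueError("beta_freq must lie in 14-18 Hz")
    design = schedule.design
    if design is None:
        raise ValueError("schedule must carry its SessionDesign")
    envelope_params = envelope_params or EnvelopeParams()
    beta_envelope_params = beta_envelope_params or EnvelopeParams(mean_amplitude=10.0)
    noise_params = noise_params or NoiseParams()
    rate = design.eeg_rate
    rng = np.random.default_rng(seed)

    n_run = int(round(design.run_duration * rate))
    channels = [alpha_channel, beta_channel, *extra_channels]
    run_sigs = []
    alpha_pow: list[np.ndarray] = []
    beta_pow: list[np.ndarray] = []
    annotations: list[tuple[float, str]] = []
    for r in range(design.n_runs):
        t = np.arange(n_run) / rate
        env_a = _ou_log_envelope(n_run, rate, envelope_params, rng)
        env_b = _ou_log_envelope(n_run, rate, beta_envelope_params, rng)
        phase_a = rng.uniform(0, 2 * np.pi)
        phase_b = rng.uniform(0, 2 * np.pi)
        sig = np.zeros((len(channels), n_run))
        sig[0] = env_a * np.sin(2 * np.pi * alpha_freq * t + phase_a)
        sig[1] = env_b * np.sin(2 * np.pi * beta_freq * t + phase_b)
        for c in range(len(channels)):
            sig[c] = sig[c] + _pink_noise(n_run, noise_params, rng)
        run_sigs.append(sig.astype(np.float32))
        evs = schedule.per_run(r)
        onsets = np.array([e.onset for e in evs])
        alpha_pow.append(_pre_event_power(env_a, rate, onsets))
        beta_pow.append(_pre_event_power(env_b, rate, onsets))
        for e in evs:
            annotations.append((r * design.run_duration + e.onset, e.type))

    samples = np.concatenate(run_sigs, axis=1).astype(float)
    rec = EEGRecording(
        channels=channels, sample_rate=rate, samples=samples, annotations=annotations
    )
    truth = GroundTruth(
        gating_coefficient=0.0,
        baseline_amplitude=0.0,
        amplitude_noise_sd=0.0,
        alpha_power=np.concatenate(alpha_pow),
        beta_power=np.concatenate(beta_pow),
    )
    return rec, truth


# --------------------------------------------------------------------------
# ROI geometry


@dataclass
class ROIDef:
    label: str
    kind: str  # "motor" | "non_motor"
    gated: bool
    voxels: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.kind not in ("motor", "non_motor"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")


@dataclass
class ROILayout:
    """Small 3-D grid with labelled, face-connected, non-overlapping clusters."""

    shape: tuple[int, int, int] = (20, 20, 12)
    rois: list[ROIDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for roi in self.rois:
            for v in map(tuple, roi.voxels):
                if any(not (0 <= v[d] < self.shape[d]) for d in range(3)):
                    raise ValueError(f"voxel {v} of {roi.label} outside grid {self.shape}")
                if v in seen:
                    raise ValueError(f"overlapping voxel {v} in {roi.label}")
                seen.add(v)

    def get(self, label: str) -> ROIDef:
        for roi in self.rois:
            if roi.label == label:
                return roi
        raise KeyError(f"unknown ROI label {label!r}")

    def labels(self) -> list[str]:
        return [r.label for r in self.rois]


def _block(corner: tuple[int, int, int], size: tuple[int, int, int]) -> np.ndarray:
    gx, gy, gz = np.meshgrid(
        *[np.arange(c, c + s) for c, s in zip(corner, size)], indexing="ij"
    )
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def default_roi_layout(cluster_size: tuple[int, int, int] = (3, 3, 2)) -> ROILayout:
    """Three gated motor clusters and three non-motor control clusters.

    Mimics the study geometry at desk scale: motor-system regions whose
    evoked response is state-gated, plus heterogeneous control regions.
    """
    motor_labels = ["rPMd", "SMA", "rM1"]
    control_labels = ["OFC", "AngularGyrus", "PAC"]
    corners = [(2, 2, 2), (2, 10, 2), (10, 2, 2), (10, 10, 6), (15, 15, 8), (2, 15, 8)]
    rois = []
    for lab, c in zip(motor_labels, corners[:3]):
        rois.append(ROIDef(label=lab, kind="motor", gated=True, voxels=_block(c, cluster_size)))
    for lab, c in zip(control_labels, corners[3:]):
        rois.append(ROIDef(label=lab, kind="non_motor", gated=False, voxels=_block(c, cluster_size)))
    return ROILayout(rois=rois)


def replicated_roi_layout(
    n_gated: int = 100,
    n_control: int = 0,
    cluster_size: tuple[int, int, int] = (2, 2, 2),
) -> ROILayout:
    """Many disjoint gated clusters for replicate-style recovery studies."""
    shape = (20, 20, 12)
    step = (cluster_size[0] + 1, cluster_size[1] + 1, cluster_size[2] + 1)
    corners = []
    for z in range(0, shape[2] - cluster_size[2], step[2]):
        for y in range(0, shape[1] - cluster_size[1], step[1]):
            for x in range(0, shape[0] - cluster_size[0], step[0]):
                corners.append((x, y, z))
    if n_gated + n_control > len(corners):
        raise ValueError(f"grid holds at most {len(corners)} clusters")
    rois = [
        ROIDef(label=f"gated_{i:03d}", kind="motor", gated=True, voxels=_block(c, cluster_size))
        for i, c in enumerate(corners[:n_gated])
    ]
    rois += [
        ROIDef(
            label=f"control_{i:03d}",
            kind="non_motor",
            gated=False,
            voxels=_block(c, cluster_size),
        )
        for i, c in enumerate(corners[n_gated : n_gated + n_control])
    ]
    return ROILayout(shape=shape, rois=rois)


@dataclass
class BOLDSimulation:
    """Output bundle of :func:`simulate_bold`."""

    roi_series: BOLDSeries
    motion: pd.DataFrame
    truth: GroundTruth
    layout: ROILayout
    volumes: np.ndarray | None = None  # (x, y, z, n_scans) if requested


def _check_stationary(ar_coeffs: np.ndarray) -> None:
    if len(ar_coeffs) and np.any(np.abs(np.roots(np.r_[1.0, -ar_coeffs])) >= 1.0):
        raise ValueError(f"AR coefficients {ar_coeffs} outside the stationarity region")


def simulate_bold(
    schedule: EventSchedule,
    truth: GroundTruth,
    roi_layout: ROILayout | None = None,
    ar_coeffs: tuple[float, float] = (0.4, 0.1),
    seed: int = 0,
    gamma: float = -0.5,
    beta0: float = 1.0,
    sigma_eps: float = 1.0,
    noise_sd: float = 1.0,
    drift_amplitude: float = 0.5,
    motion_amplitude: float = 0.3,
    motion_coupling_sd: float = 0.1,
    hrf_params: HRFParams | None = None,
    voxels: bool = False,
    dt: float = 0.05,
) -> BOLDSimulation:
    """Simulate ROI-level (and optionally voxel-level) BOLD for the session.

    Every TMS event in a gated region evokes an HRF-shaped response with
    amplitude ``beta0 + gamma * z_i + eps_i`` (z_i: standardized true
    pre-event alpha power from ``truth``); non-gated regions use gamma = 0
    and null events evoke nothing. Scanner noise is AR(2) (independently
    per voxel), plus a slow drift and a random linear coupling of six
    simulated motion confounds. Amplitude noise is drawn independently per
    region, so regions act as near-independent replicates of the gating
    model. True amplitudes are appended to ``truth.amplitudes``.
    """
    design = schedule.design
    if design is None:
        raise ValueError("schedule must carry its SessionDesign")
    ar = np.asarray(ar_coeffs, dtype=float)
    _check_stationary(ar)
    if roi_layout is None:
        roi_layout = default_roi_layout()
    rng = np.random.default_rng(seed)

    n_scans_run = design.n_scans_per_run
    n_runs = design.n_runs
    n_scans = n_scans_run * n_runs
    run_index = np.repeat(np.arange(n_runs), n_scans_run)
    run_dur = n_scans_run * design.tr

    event_types = np.array([e.type for e in schedule.events])
    tms_mask = event_types == "tms"
    if len(truth.alpha_power) != len(schedule.events):
        raise ValueError("truth.alpha_power length must match schedule events")
    z = truth.alpha_z(tms_mask)

    h = hrf(np.arange(0.0, (hrf_params or HRFParams()).length + dt, dt), hrf_params)
    n_fine = int(round(run_dur / dt))
    scan_idx = np.round((np.arange(n_scans_run) * design.tr) / dt).astype(int)

    truth.gating_coefficient = gamma
    truth.baseline_amplitude = beta0
    truth.amplitude_noise_sd = sigma_eps
    truth.roi_flags = {r.label: r.kind for r in roi_layout.rois}
    truth.gated_rois = [r.label for r in roi_layout.rois if r.gated]

    tms_events = [e for e in schedule.events if e.type == "tms"]

    def evoked_series(amplitudes: np.ndarray) -> np.ndarray:
        col = np.zeros(n_scans)
        for ri in range(n_runs):
            fine = np.zeros(n_fine)
            for amp, e in zip(amplitudes, tms_events):
                if e.run_index == ri:
                    fine[int(round(e.onset / dt))] += amp
            conv = np.convolve(fine, h)[:n_fine]
            col[ri * n_scans_run : (ri + 1) * n_scans_run] = conv[scan_idx]
        return col

    # six motion confounds: smoothed random walks
    motion = np.cumsum(rng.standard_normal((n_scans, 6)), axis=0)
    motion = scipy.ndimage.uniform_filter1d(motion, size=5, axis=0)
    motion -= motion.mean(axis=0)
    sd = motion.std(axis=0)
    motion = motion / np.where(sd > 0, sd, 1.0) * motion_amplitude
    motion_df = pd.DataFrame(
        motion, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
    )

    def noise_block(n_series: int) -> np.ndarray:
        eps = rng.standard_normal((n_scans, n_series)) * noise_sd
        if len(ar):
            out = np.empty_like(eps)
            for r in range(n_runs):
                m = run_index == r
                out[m] = scipy.signal.lfilter([1.0], np.r_[1.0, -ar], eps[m], axis=0)
            eps = out
        return eps

    def drift_block(n_series: int) -> np.ndarray:
        t = np.linspace(-0.5, 0.5, n_scans_run)
        pieces = []
        for _ in range(n_runs):
            lin = rng.normal(scale=drift_amplitude, size=n_series)
            per = rng.normal(scale=drift_amplitude, size=n_series)
            phase = rng.uniform(0, 2 * np.pi, size=n_series)
            pieces.append(
                t[:, None] * lin[None, :]
                + np.sin(2 * np.pi * 0.5 * (t[:, None] + 0.5) + phase[None, :]) * per[None, :]
            )
        return np.concatenate(pieces, axis=0)

    roi_cols = {}
    vols = None
    if voxels:
        shape = roi_layout.shape
        n_vox = int(np.prod(shape))
        vox_data = noise_block(n_vox) + drift_block(n_vox)
        vox_data += motion @ (rng.standard_normal((6, n_vox)) * motion_coupling_sd)
        for roi in roi_layout.rois:
            g = gamma if roi.gated else 0.0
            eps = rng.standard_normal(len(tms_events)) * sigma_eps
            amps = beta0 + g * z + eps
            truth.amplitudes[roi.label] = amps
            ev = evoked_series(amps)
            flat = np.ravel_multi_index(roi.voxels.T, shape)
            vox_data[:, flat] += ev[:, None]
            roi_cols[roi.label] = vox_data[:, flat].mean(axis=1)
        vols = vox_data.T.reshape(*shape, n_scans)
    else:
        for roi in roi_layout.rois:
            g = gamma if roi.gated else 0.0
            eps = rng.standard_normal(len(tms_events)) * sigma_eps
            amps = beta0 + g * z + eps
            truth.amplitudes[roi.label] = amps
            ev = evoked_series(amps)
            n_eff = max(roi.voxels.shape[0], 1)
            noise = noise_block(1)[:, 0] / np.sqrt(n_eff)
            drift = drift_block(1)[:, 0]
            coupling = rng.standard_normal(6) * motion_coupling_sd
            roi_cols[roi.label] = ev + noise + drift + motion @ coupling

    labels = roi_layout.labels()
    series = BOLDSeries(
        data=np.column_stack([roi_cols[lab] for lab in labels]),
        tr=design.tr,
        run_index=run_index,
        labels=labels,
    )
    return BOLDSimulation(
        roi_series=series, motion=motion_df, truth=truth, layout=roi_layout, volumes=vols
    )


def simulate_emg(
    schedule: EventSchedule,
    mep_rate: float = 0.0,
    mep_amplitude: float = 10.0,  # peak amplitude in baseline-SD units
    seed: int = 0,
    baseline_sd: float = 10.0,  # µV
    truth: GroundTruth | None = None,
) -> EEGRecording:
    """Simulate the bipolar EMG channel of a session.

    Background is white Gaussian noise. For a Bernoulli(``mep_rate``)
    subset of TMS events a biphasic motor-evoked potential is injected:
    onset latency uniform in 15-30 ms after the first pulse, positive lobe
    peaking 8 ms later (absolute extremum inside the 15-50 ms search
    window), followed by a smaller opposite lobe. Null events never carry
    an MEP. If ``truth`` is given, the per-TMS-event MEP indicator and the
    rate are recorded there.
    """
    if not (0.0 <= mep_rate <= 1.0):
        raise ValueError("mep_rate must lie in [0, 1]")
    design = schedule.design
    if design is None:
        raise ValueError("schedule must carry its SessionDesign")
    rate = design.eeg_rate
    rng = np.random.default_rng(seed)
    n_run = int(round(design.run_duration * rate))
    n_total = n_run * design.n_runs
    sig = rng.standard_normal(n_total) * baseline_sd

    lobe = int(round(0.016 * rate))  # 16 ms half-sine lobes
    wave = np.concatenate(
        [np.sin(np.pi * np.arange(lobe) / lobe), -0.6 * np.sin(np.pi * np.arange(lobe) / lobe)]
    )
    tms_events = [e for e in schedule.events if e.type == "tms"]
    present = rng.random(len(tms_events)) < mep_rate
    annotations = []
    for e in schedule.events:
        annotations.append((e.run_index * design.run_duration + e.onset, e.type))
    for has_mep, e in zip(present, tms_events):
        if not has_mep:
            continue
        latency = rng.uniform(0.015, 0.030)
        i0 = int(round((e.run_index * design.run_duration + e.onset + latency) * rate))
        seg = wave * mep_amplitude * baseline_sd
        end = min(i0 + len(seg), n_total)
        if i0 < n_total:
            sig[i0:end] += seg[: end - i0]
    if truth is not None:
        truth.mep_rate = mep_rate
        truth.mep_present = present
    return EEGRecording(
        channels=["FDI_bipolar"],
        sample_rate=rate,
        samples=sig[None, :],
        annotations=annotations,
    )


def simulate_trial_table(
    n_trials: int = 135,
    gamma: float = -0.5,
    beta0: float = 1.0,
    sigma_eps: float = 1.0,
    roi_specs: dict[str, tuple[str, bool]] | None = None,
    power_log_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a trial-level dataset directly from the gating model.

    Skips the waveform stages: per-trial alpha and beta power are lognormal
    (the stationary law of the envelope process), TMS-event amplitudes in
    gated regions follow ``beta0 + gamma * z + eps`` and null-event
    amplitudes are pure noise around zero. Suitable for large-replicate
    statistical calibration where simulating full EEG/BOLD time series
    per replicate adds nothing.

    ``roi_specs`` maps label -> (kind, gated); default is one gated motor
    region and one non-gated control.
    """
    if roi_specs is None:
        roi_specs = {"rPMd": ("motor", True), "PAC": ("non_motor", False)}
    rng = np.random.default_rng(seed)
    n_total = 2 * n_trials
    event_type = np.array(["tms"] * n_trials + ["null"] * n_trials)
    order = rng.permutation(n_total)
    event_type = event_type[order]
    alpha = np.exp(rng.standard_normal(n_total) * power_log_sd)
    beta_pow = np.exp(rng.standard_normal(n_total) * power_log_sd)
    tms_mask = event_type == "tms"
    z = (alpha[tms_mask] - alpha[tms_mask].mean()) / alpha[tms_mask].std()

    table = pd.DataFrame(
        {
            "trial_id": np.arange(n_total),
            "event_type": event_type,
            "alpha_power": alpha,
            "beta_power": beta_pow,
        }
    )
    truth = GroundTruth(
        gating_coefficient=gamma,
        baseline_amplitude=beta0,
        amplitude_noise_sd=sigma_eps,
        alpha_power=alpha,
        beta_power=beta_pow,
        roi_flags={k: v[0] for k, v in roi_specs.items()},
        gated_rois=[k for k, v in roi_specs.items() if v[1]],
    )
    for label, (_, gated) in roi_specs.items():
        g = gamma if gated else 0.0
        amps = np.zeros(n_total)
        amps[tms_mask] = beta0 + g * z + rng.standard_normal(n_trials) * sigma_eps
        amps[~tms_mask] = rng.standard_normal(n_total - n_trials) * sigma_eps
        table[f"roi:{label}"] = amps
        truth.amplitudes[label] = amps[tms_mask]
    return table, truth
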