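"""End-to-end orchestration: simulate -> EEG power -> GLM -> state statistics.

A YAML-configurable pipeline ties the stages together reproducibly: one
master seed spawns independent child seeds per stage, a manifest records
the configuration hash, seeds and stage completion, and a stage whose
outputs already exist under an identical manifest is skipped on rerun.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as sbio
from .design import SessionDesign, generate_event_schedule
from .eeg import (
    PreprocessConfig,
    epoch_events,
    estimate_power,
    peak_frequency,
    preprocess,
    reject_artifacts,
    trial_power,
)
from .emg import compare_counts, detect_all, epoch_emg
from .glm import BOLDSeries, build_design, fit_glm, preprocess_bold
from .simulate import (
    EnvelopeParams,
    NoiseParams,
    default_roi_layout,
    simulate_bold,
    simulate_eeg,
    simulate_emg,
)
from .stats import PermutationConfig, drift_check, specificity_battery

log = logging.getLogger("statebold")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated pipeline settings; defaults are the study's stated values
    (500 Hz EEG rate, 0.5-40 Hz band-pass, 20000 permutations, 40-trial
    bins, q = 0.05, 10-voxel clusters)."""

    session: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    glm: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.session = {**self._session_defaults(), **self.session}
        self.simulation = {**self._simulation_defaults(), **self.simulation}
        self.preprocess = {**self._preprocess_defaults(), **self.preprocess}
        self.glm = {**{"ar_order": 2}, **self.glm}
        self.stats = {**self._stats_defaults(), **self.stats}
        if self.stats["n_perm"] < 1 or self.stats["bin_size"] < 1:
            raise ValueError("stats.n_perm and stats.bin_size must be positive")

    @staticmethod
    def _session_defaults() -> dict:
        return dict(
            n_runs=5,
            run_duration=313 * 2.25,
            tr=2.25,
            acquisition_gap=0.75,
            mean_iti=13.5,
            iti_jitter=[11.25, 15.75],
            pulses_per_event=3,
            pulse_rate=15.0,
            eeg_rate=5000.0,
        )

    @staticmethod
    def _simulation_defaults() -> dict:
        return dict(
            gamma=-0.5,
            beta0=1.0,
            sigma_eps=1.0,
            noise_sd=1.0,
            alpha_freq=10.0,
            beta_freq=14.0,
            mep_rate=0.0,
            mep_amplitude=10.0,
        )

    @staticmethod
    def _preprocess_defaults() -> dict:
        return dict(
            target_rate=500.0,
            reference_channels=["P2", "FC4", "Cz", "Pz"],
            bandpass=[0.5, 40.0],
            notch=50.0,
            alpha_channel="P2",
            beta_channel="FC4",
        )

    @staticmethod
    def _stats_defaults() -> dict:
        return dict(n_perm=20000, bin_size=40, q=0.05, min_cluster=10)

    def design(self) -> SessionDesign:
        s = self.session
        return SessionDesign(
            n_runs=int(s["n_runs"]),
            run_duration=float(s["run_duration"]),
            tr=float(s["tr"]),
            acquisition_gap=float(s["acquisition_gap"]),
            mean_iti=float(s["mean_iti"]),
            iti_jitter=tuple(s["iti_jitter"]),
            pulses_per_event=int(s["pulses_per_event"]),
            pulse_rate=float(s["pulse_rate"]),
            eeg_rate=float(s["eeg_rate"]),
            seed=self.seed,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"session", "simulation", "preprocess", "glm", "stats", "seed", "log_level"}
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    raw.update(overrides)
    return PipelineConfig(**raw)


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


class _Manifest:
    def __init__(self, out: Path, cfg: PipelineConfig, seeds: dict[str, int]):
        self.path = out / "manifest.json"
        self.data = {
            "config_hash": cfg.hash(),
            "version": __version__,
            "seeds": seeds,
            "stages": {},
        }
        if self.path.exists():
            prev = json.loads(self.path.read_text())
            if prev.get("config_hash") == self.data["config_hash"]:
                self.data["stages"] = prev.get("stages", {})

    def done(self, stage: str) -> bool:
        return self.data["stages"].get(stage, {}).get("status") == "complete"

    def start(self, stage: str) -> None:
        self.data["stages"][stage] = {"status": "running", "started": time.time()}
        self.write()

    def finish(self, stage: str) -> None:
        self.data["stages"][stage]["status"] = "complete"
        self.data["stages"][stage]["finished"] = time.time()
        self.write()

    def write(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute simulate -> run-eeg -> run-glm -> analyze and write all outputs.

    Returns a result bundle with the trial table, the specificity battery
    and summary statistics. Completed stages (same config hash) are not
    recomputed on rerun.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(
        zip(["schedule", "eeg", "bold", "emg", "stats"], _child_seeds(cfg.seed, 5))
    )
    manifest = _Manifest(out, cfg, seeds)
    log.info("config hash %s; seeds %s", cfg.hash(), seeds)

    design = cfg.design()
    sim = cfg.simulation

    # ---- stage: simulate -------------------------------------------------
    stage = "simulate"
    if not (manifest.done(stage) and (out / "ground_truth.json").exists()):
        manifest.start(stage)
        schedule = generate_event_schedule(design, seed=seeds["schedule"])
        sbio.write_events(schedule, out / "events.tsv")
        eeg_raw, truth = simulate_eeg(
            schedule,
            alpha_freq=sim["alpha_freq"],
            beta_freq=sim["beta_freq"],
            seed=seeds["eeg"],
        )
        sbio.write_recording(eeg_raw, out / "eeg")
        layout = default_roi_layout()
        bold = simulate_bold(
            schedule,
            truth,
            roi_layout=layout,
            seed=seeds["bold"],
            gamma=sim["gamma"],
            beta0=sim["beta0"],
            sigma_eps=sim["sigma_eps"],
            noise_sd=sim["noise_sd"],
        )
        pd.DataFrame(
            bold.roi_series.data, columns=bold.roi_series.labels
        ).assign(run=bold.roi_series.run_index).to_csv(
            out / "roi_series.tsv", sep="\t", index=False
        )
        bold.motion.to_csv(out / "motion.tsv", sep="\t", index=False)
        emg = simulate_emg(
            schedule,
            mep_rate=sim["mep_rate"],
            mep_amplitude=sim["mep_amplitude"],
            seed=seeds["emg"],
            truth=truth,
        )
        sbio.write_recording(emg, out / "emg")
        sbio.write_ground_truth(truth, out / "ground_truth.json")
        manifest.finish(stage)

    schedule = sbio.read_events(out / "events.tsv", design=design)
    truth = sbio.read_ground_truth(out / "ground_truth.json")

    # ---- stage: run-eeg --------------------------------------------------
    stage = "run-eeg"
    if not (manifest.done(stage) and (out / "trial_power_alpha.tsv").exists()):
        manifest.start(stage)
        eeg_raw = sbio.read_recording(out / "eeg")
        pcfg = PreprocessConfig(
            target_rate=float(cfg.preprocess["target_rate"]),
            reference_channels=tuple(cfg.preprocess["reference_channels"]),
            bandpass=tuple(cfg.preprocess["bandpass"]),
            notch=float(cfg.preprocess["notch"]),
        )
        clean = preprocess(eeg_raw, pcfg)
        epochs = reject_artifacts(epoch_events(clean, schedule))
        for band, chan in (
            ("alpha", cfg.preprocess["alpha_channel"]),
            ("beta", cfg.preprocess["beta_channel"]),
        ):
            spectra = estimate_power(epochs, chan)
            lo, hi = (8.0, 12.0) if band == "alpha" else (14.0, 18.0)
            peak = peak_frequency(spectra, (lo, hi))
            tp = trial_power(spectra, peak, band=band)
            sbio.write_trial_power(tp, out / f"trial_power_{band}.tsv")
            log.info("%s peak %.1f Hz, %d retained trials", band, peak, len(tp))
        manifest.finish(stage)

    # ---- stage: run-glm --------------------------------------------------
    stage = "run-glm"
    if not (manifest.done(stage) and (out / "roi_betas_tms.tsv").exists()):
        manifest.start(stage)
        roi_df = pd.read_csv(out / "roi_series.tsv", sep="\t")
        run_index = roi_df.pop("run").to_numpy()
        motion = pd.read_csv(out / "motion.tsv", sep="\t")
        series = BOLDSeries(
            data=roi_df.to_numpy(), tr=design.tr, run_index=run_index,
            labels=list(roi_df.columns),
        )
        series = preprocess_bold(series)
        n_scans_run = design.n_scans_per_run
        for ev_type in ("tms", "null"):
            X = build_design(
                schedule, tr=design.tr, n_scans_per_run=n_scans_run,
                motion=motion, mode="single_trial", event_type=ev_type,
            )
            betas = {}
            for j, lab in enumerate(series.labels):
                fit = fit_glm(series.data[:, j], X, ar_order=int(cfg.glm["ar_order"]))
                betas[lab] = fit.params[X.event_columns].to_numpy()
            sbio.write_roi_betas(betas, np.asarray(X.event_ids), out / f"roi_betas_{ev_type}.tsv")
        manifest.finish(stage)

    # ---- stage: analyze --------------------------------------------------
    stage = "analyze"
    manifest.start(stage)
    table = build_trial_table(
        alpha=sbio.read_trial_power(out / "trial_power_alpha.tsv"),
        beta=sbio.read_trial_power(out / "trial_power_beta.tsv"),
        betas_tms=sbio.read_roi_betas(out / "roi_betas_tms.tsv"),
        betas_null=sbio.read_roi_betas(out / "roi_betas_null.tsv"),
    )
    table.to_csv(out / "trial_table.tsv", sep="\t", index=False)
    scfg = PermutationConfig(
        n_perm=int(cfg.stats["n_perm"]),
        bin_size=int(cfg.stats["bin_size"]),
        seed=seeds["stats"],
    )
    battery = specificity_battery(table, roi_kinds=truth.roi_flags, cfg=scfg)
    battery.insert(0, "config_hash", cfg.hash())
    battery.to_csv(out / "state_dependence.tsv", sep="\t", index=False)

    null_alpha = table[table["event_type"] == "null"]["alpha_power"].to_numpy()
    drift_rho, drift_p = drift_check(null_alpha)

    emg_rec = sbio.read_recording(out / "emg")
    emg_epochs = epoch_emg(emg_rec, schedule)
    detections = detect_all(emg_epochs)
    det = np.array([d.detected for d in detections])
    types = np.array([e.type for e in schedule.events])
    runs = np.array([e.run_index for e in schedule.events])
    tms_counts = np.array(
        [det[(types == "tms") & (runs == r)].sum() for r in np.unique(runs)]
    )
    null_counts = np.array(
        [det[(types == "null") & (runs == r)].sum() for r in np.unique(runs)]
    )
    w_stat, w_p = compare_counts(tms_counts, null_counts)

    summary = {
        "config_hash": cfg.hash(),
        "seeds": seeds,
        "n_trials": int(len(table)),
        "drift_rho": drift_rho,
        "drift_p": drift_p,
        "mep_counts_tms": tms_counts.tolist(),
        "mep_counts_null": null_counts.tolist(),
        "mep_wilcoxon_p": w_p,
        "n_significant_cells": int(battery["significant"].sum()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    manifest.finish(stage)
    return {"table": table, "battery": battery, "summary": summary, "truth": truth}


def build_trial_table(
    alpha: pd.DataFrame,
    beta: pd.DataFrame,
    betas_tms: pd.DataFrame,
    betas_null: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-trial power and per-trial ROI amplitudes on trial id.

    Trials rejected on either analysis channel drop from both sides of the
    analysis (pairing requires joint retention). Null-event amplitude rows
    come from the separate null-trial model.
    """
    a = alpha[["trial_id", "event_type", "power"]].rename(columns={"power": "alpha_power"})
    b = beta[["trial_id", "power"]].rename(columns={"power": "beta_power"})
    table = a.merge(b, on="trial_id", how="inner")
    amps = pd.concat([betas_tms, betas_null], ignore_index=True)
    wide = amps.pivot(index="trial_id", columns="roi", values="beta")
    wide.columns = [f"roi:{c}" for c in wide.columns]
    table = table.merge(wide, left_on="trial_id", right_index=True, how="inner")
    return table.dropna().reset_index(drop=True)
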