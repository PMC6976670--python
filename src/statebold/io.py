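"""File-format adapters: BIDS-style events TSV, EEG containers, NIfTI maps,
trial tables and ground-truth JSON.

Continuous EEG/EMG is written as a plain-text sample table plus a JSON
sidecar (rate, channel labels, annotations); EDF and BrainVision
recordings are read through :mod:`mne` when available.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Event, EventSchedule, SessionDesign
from .eeg import TrialPowerVector
from .glm import ROI, ROISet, StatMap
from .recording import EEGRecording
from .simulate import GroundTruth

__all__ = [
    "write_events",
    "read_events",
    "write_recording",
    "read_recording",
    "read_raw_eeg",
    "write_trial_power",
    "read_trial_power",
    "write_roi_betas",
    "read_roi_betas",
    "write_roiset",
    "read_roiset",
    "write_statmap_nifti",
    "write_ground_truth",
    "read_ground_truth",
]


def write_events(schedule: EventSchedule, path: str | Path) -> None:
    """Write the schedule as a BIDS-style events TSV (onset, duration,
    trial_type, run)."""
    dur = 0.0
    if schedule.design is not None:
        dur = schedule.design.pulse_train_duration
    rows = [
        {
            "onset": e.onset,
            "duration": dur if e.type == "tms" else 0.0,
            "trial_type": e.type,
            "run": e.run_index,
        }
        for e in schedule.events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: str | Path, design: SessionDesign | None = None) -> EventSchedule:
    """Read and validate a BIDS-style events TSV; reports offending lines."""
    # keep_default_na: the literal trial_type "null" must not parse as NaN
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    required = {"onset", "trial_type", "run"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    events = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after header
        try:
            onset = float(row["onset"])
            run = int(row["run"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {line}: {exc}") from exc
        ttype = str(row["trial_type"])
        if ttype not in ("tms", "null"):
            raise ValueError(
                f"{path}: line {line}: trial_type must be 'tms' or 'null', got {ttype!r}"
            )
        events.append(Event(onset=onset, type=ttype, run_index=run))
    sched = EventSchedule(events=events, design=design)
    for r in range(sched.n_runs):
        on = sched.onsets(run_index=r)
        if np.any(np.diff(on) <= 0):
            raise ValueError(f"{path}: onsets not strictly increasing within run {r}")
    return sched


def write_recording(rec: EEGRecording, prefix: str | Path) -> None:
    """Write a recording as <prefix>.tsv samples + <prefix>.json sidecar."""
    prefix = Path(prefix)
    df = pd.DataFrame(rec.samples.T, columns=rec.channels)
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False, float_format="%.4f")
    sidecar = {
        "sample_rate": rec.sample_rate,
        "channels": rec.channels,
        "units": "uV",
        "annotations": [[onset, label] for onset, label in rec.annotations],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(prefix: str | Path) -> EEGRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    return EEGRecording(
        channels=meta["channels"],
        sample_rate=float(meta["sample_rate"]),
        samples=df[meta["channels"]].to_numpy().T,
        annotations=[(float(o), str(l)) for o, l in meta.get("annotations", [])],
    )


def read_raw_eeg(path: str | Path) -> EEGRecording:
    """Read EDF or BrainVision EEG via mne; TSV+JSON pairs natively."""
    path = Path(path)
    if path.suffix in (".tsv", ".json") or path.with_suffix(".json").exists():
        return read_recording(path.with_suffix(""))
    import mne  # heavy; only needed for real recordings

    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format: {path.suffix}")
    data = raw.get_data() * 1e6  # volts -> µV
    annotations = [
        (float(a["onset"]), str(a["description"])) for a in raw.annotations
    ]
    return EEGRecording(
        channels=list(raw.ch_names),
        sample_rate=float(raw.info["sfreq"]),
        samples=data,
        annotations=annotations,
    )


def write_trial_power(tp: TrialPowerVector, path: str | Path) -> None:
    rows = [
        {
            "trial_id": int(tid),
            "onset": ev.onset,
            "run": ev.run_index,
            "event_type": ev.type,
            "band": tp.band,
            "channel": tp.channel,
            "peak_hz": tp.peak,
            "power": p,
            "retained": True,
        }
        for tid, ev, p in zip(tp.trial_ids, tp.events, tp.power)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_trial_power(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_roi_betas(betas: dict[str, np.ndarray], trial_ids: np.ndarray, path: str | Path) -> None:
    """Long-format per-trial amplitudes: trial_id, roi, beta."""
    rows = []
    for roi_label, vec in betas.items():
        for tid, b in zip(trial_ids, vec):
            rows.append({"trial_id": int(tid), "roi": roi_label, "beta": float(b)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_roi_betas(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_roiset(rois: ROISet, path: str | Path) -> None:
    payload = [
        {
            "label": r.label,
            "definition_type": r.definition_type,
            "voxels": r.voxels.tolist(),
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roiset(path: str | Path) -> ROISet:
    payload = json.loads(Path(path).read_text())
    return ROISet(
        rois=[
            ROI(
                label=d["label"],
                voxels=np.asarray(d["voxels"], dtype=int),
                definition_type=d.get("definition_type", "tms_responsive"),
            )
            for d in payload
        ]
    )


def write_statmap_nifti(stat_map: StatMap, path: str | Path, voxel_size: float = 3.0) -> None:
    """Write the t map as a NIfTI-1 volume (isotropic voxels)."""
    import nibabel as nib

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(stat_map.t.astype(np.float32), affine)
    nib.save(img, str(path))


def write_volumes_nifti(volumes: np.ndarray, path: str | Path, voxel_size: float = 3.0) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(volumes.astype(np.float32), affine), str(path))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "gating_coefficient": truth.gating_coefficient,
        "baseline_amplitude": truth.baseline_amplitude,
        "amplitude_noise_sd": truth.amplitude_noise_sd,
        "alpha_power": truth.alpha_power.tolist(),
        "beta_power": truth.beta_power.tolist(),
        "roi_flags": truth.roi_flags,
        "gated_rois": truth.gated_rois,
        "mep_rate": truth.mep_rate,
        "amplitudes": {k: v.tolist() for k, v in truth.amplitudes.items()},
        "mep_present": truth.mep_present.tolist() if truth.mep_present is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        gating_coefficient=d["gating_coefficient"],
        baseline_amplitude=d["baseline_amplitude"],
        amplitude_noise_sd=d["amplitude_noise_sd"],
        alpha_power=np.asarray(d["alpha_power"], dtype=float),
        beta_power=np.asarray(d["beta_power"], dtype=float),
        roi_flags=d.get("roi_flags", {}),
        gated_rois=d.get("gated_rois", []),
        mep_rate=d.get("mep_rate", 0.0),
        amplitudes={k: np.asarray(v, dtype=float) for k, v in d.get("amplitudes", {}).items()},
        mep_present=(
            np.asarray(d["mep_present"], dtype=bool) if d.get("mep_present") is not None else None
        ),
    )
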