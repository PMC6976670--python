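"""Single-trial fMRI GLM with AR(2) prewhitening, contrasts and ROI definition.

Evoked amplitudes are estimated per event with double-gamma-HRF-convolved
stick regressors, six motion confounds and per-run constants. Serial
correlations are handled with a two-pass (Cochrane-Orcutt-style) AR(2)
correction: OLS residuals give Yule-Walker AR coefficients, data and
design are prewhitened per run, and the whitened system is refit by OLS.
ROIs are connected clusters (face connectivity) of voxels surviving a
Benjamini-Hochberg FDR threshold and a minimum cluster extent.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.ndimage
import scipy.stats

from .design import EventSchedule

__all__ = [
    "BOLDSeries",
    "HRFParams",
    "hrf",
    "preprocess_bold",
    "build_design",
    "DesignMatrix",
    "BetaEstimates",
    "fit_glm",
    "fit_glm_voxels",
    "StatMap",
    "contrast_map",
    "fdr_threshold",
    "ROI",
    "ROISet",
    "define_rois",
    "roi_betas",
]


@dataclass
class BOLDSeries:
    """Voxel- or ROI-level BOLD time series across runs.

    ``data`` is (n_scans, n_series); ``run_index`` assigns each scan to a
    run; ``labels`` names the series (ROI labels or voxel ids).
    """

    data: np.ndarray
    tr: float
    run_index: np.ndarray
    labels: list[str] | None = None
    invalid: np.ndarray | None = None  # series flagged during preprocessing

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (scans x series)")
        self.run_index = np.asarray(self.run_index, dtype=int)
        if len(self.run_index) != self.data.shape[0]:
            raise ValueError("run_index length must match number of scans")
        for r in np.unique(self.run_index):
            if (self.run_index == r).sum() < 3:
                raise ValueError(f"run {r} has fewer than 3 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in BOLD data")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_index)


def preprocess_bold(
    series: BOLDSeries, highpass_cycles: float = 2.0, normalize: bool = True
) -> BOLDSeries:
    """Per run: remove linear trend and slow frequencies, then z-normalize.

    Slow fluctuations are removed by regressing out, per run, a constant,
    a linear ramp and sine/cosine pairs at every whole number of cycles
    per run below ``highpass_cycles``. Constant (zero-variance) series are
    flagged in ``invalid`` and set to zero rather than raising.
    ``normalize=False`` skips the z-scoring (fitted amplitudes then stay in
    the input units).
    """
    out = np.empty_like(series.data)
    invalid = np.zeros(series.data.shape[1], dtype=bool)
    for r in series.runs:
        m = series.run_index == r
        y = series.data[m]
        n = y.shape[0]
        t = np.arange(n) / n
        cols = [np.ones(n), t - t.mean()]
        k = 1
        while k < highpass_cycles:
            cols.append(np.sin(2 * np.pi * k * t))
            cols.append(np.cos(2 * np.pi * k * t))
            k += 1
        basis = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(basis, y, rcond=None)
        resid = y - basis @ beta
        sd = resid.std(axis=0, ddof=0)
        bad = sd == 0
        invalid |= bad
        if normalize:
            sd = np.where(bad, 1.0, sd)
            resid = resid / sd
            resid[:, bad] = 0.0
        out[m] = resid
    if invalid.any():
        warnings.warn(f"{invalid.sum()} constant series could not be z-normalized")
    return BOLDSeries(
        data=out,
        tr=series.tr,
        run_index=series.run_index.copy(),
        labels=series.labels,
        invalid=invalid,
    )


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak: float = 5.0
    undershoot: float = 15.0
    ratio: float = 6.0  # peak-to-undershoot amplitude ratio
    dispersion: float = 1.0
    length: float = 30.0

    def __post_init__(self) -> None:
        if min(self.peak, self.undershoot, self.ratio, self.dispersion) <= 0:
            raise ValueError("HRF shape parameters must be positive")


def hrf(time_grid: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Double-gamma HRF: positive gamma peaking at ``params.peak`` seconds
    minus a later undershoot gamma scaled by 1/``params.ratio``; zero at t=0.
    """
    if params is None:
        params = HRFParams()
    t = np.asarray(time_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time_grid must be non-negative")
    d = params.dispersion
    a1 = params.peak / d + 1.0  # gamma mode = (a-1)*scale
    a2 = params.undershoot / d + 1.0

    def curve(x: np.ndarray) -> np.ndarray:
        return scipy.stats.gamma.pdf(x, a1, scale=d) - scipy.stats.gamma.pdf(
            x, a2, scale=d
        ) / params.ratio

    # grid-invariant unit peak: normalize on a dense internal grid
    fine = np.arange(0.0, params.length, 1e-3)
    peak_val = float(np.max(curve(fine)))
    h = curve(t) / (peak_val if peak_val > 0 else 1.0)
    h[t > params.length] = 0.0
    return h


@dataclass
class DesignMatrix:
    """Labelled GLM design: event regressors + motion confounds + run constants."""

    matrix: pd.DataFrame  # (n_scans, n_regressors)
    run_index: np.ndarray
    event_columns: list[str]
    event_ids: list[int]  # schedule indices matching event_columns (single-trial)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()


def build_design(
    schedule: EventSchedule,
    tr: float,
    n_scans_per_run: int,
    motion: pd.DataFrame | np.ndarray | None = None,
    mode: str = "single_trial",
    event_type: str = "tms",
    aggregate_other: bool | None = None,
    event_duration: float = 0.0,
    hrf_params: HRFParams | None = None,
    dt: float = 0.05,
) -> DesignMatrix:
    """Build the scan-level design matrix for one session.

    ``single_trial`` mode gives one stick column per ``event_type`` event;
    ``aggregate`` mode pools them into a single column. When estimating
    null-event responses trial-wise, the opposite type is kept as one
    aggregate column (``aggregate_other`` defaults to True for
    ``event_type='null'``). Sticks (or ``event_duration``-second boxcars)
    are placed on a ``dt`` grid, convolved with the double-gamma HRF and
    sampled at volume onsets. Six motion confounds and one constant per
    run complete the matrix.
    """
    runs = sorted({e.run_index for e in schedule.events})
    n_runs = len(runs)
    n_scans = n_scans_per_run * n_runs
    scan_run = np.repeat(np.arange(n_runs), n_scans_per_run)
    if aggregate_other is None:
        aggregate_other = event_type == "null"
    h = hrf(np.arange(0.0, (hrf_params or HRFParams()).length + dt, dt), hrf_params)

    run_dur = n_scans_per_run * tr
    n_fine = int(round(run_dur / dt))
    width = max(1, int(round(event_duration / dt)))

    def convolved_column(onsets_by_run: dict[int, list[float]]) -> np.ndarray:
        col = np.zeros(n_scans)
        for ri, r in enumerate(runs):
            ons = onsets_by_run.get(r, [])
            if not ons:
                continue
            fine = np.zeros(n_fine)
            for t0 in ons:
                if not (0 <= t0 < run_dur):
                    raise ValueError(f"event at {t0} s outside run timeline [0, {run_dur})")
                i0 = int(round(t0 / dt))
                fine[i0 : i0 + width] = 1.0
            conv = np.convolve(fine, h)[:n_fine]
            scan_t = np.arange(n_scans_per_run) * tr
            idx = np.round(scan_t / dt).astype(int)
            col[ri * n_scans_per_run : (ri + 1) * n_scans_per_run] = conv[idx]
        return col

    cols: dict[str, np.ndarray] = {}
    event_columns: list[str] = []
    event_ids: list[int] = []
    sel = [(i, e) for i, e in enumerate(schedule.events) if e.type == event_type]
    if mode == "single_trial":
        for i, e in sel:
            name = f"{event_type}_{i:03d}"
            cols[name] = convolved_column({e.run_index: [e.onset]})
            event_columns.append(name)
            event_ids.append(i)
    elif mode == "aggregate":
        by_run: dict[int, list[float]] = {}
        for _, e in sel:
            by_run.setdefault(e.run_index, []).append(e.onset)
        cols[event_type] = convolved_column(by_run)
        event_columns.append(event_type)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if aggregate_other:
        other = "null" if event_type == "tms" else "tms"
        by_run = {}
        for e in schedule.events:
            if e.type == other:
                by_run.setdefault(e.run_index, []).append(e.onset)
        if by_run:
            cols[f"{other}_aggregate"] = convolved_column(by_run)

    for name, col in cols.items():
        if np.allclose(col, 0):
            raise ValueError(f"regressor {name!r} is all zero (event outside timeline?)")

    if motion is not None:
        mo = np.asarray(motion, dtype=float)
        if mo.shape[0] != n_scans:
            raise ValueError("motion table rows must equal number of scans")
        names = (
            list(motion.columns)
            if isinstance(motion, pd.DataFrame)
            else [f"motion_{k}" for k in range(mo.shape[1])]
        )
        for k, nm in enumerate(names):
            cols[str(nm)] = mo[:, k]
    for ri, r in enumerate(runs):
        cols[f"constant_run{r}"] = (scan_run == ri).astype(float)

    X = pd.DataFrame(cols)
    return DesignMatrix(matrix=X, run_index=scan_run, event_columns=event_columns, event_ids=event_ids)


@dataclass
class BetaEstimates:
    """Fitted GLM coefficients after AR prewhitening, with inference pieces."""

    params: pd.Series
    ar_coeffs: np.ndarray
    resid_var: float
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    xtx_inv: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """Return (estimate, t, p) for contrast vector ``c``."""
        c = np.asarray(c, dtype=float)
        if len(c) != len(self.params):
            raise ValueError(
                f"contrast length {len(c)} != {len(self.params)} coefficients"
            )
        est = float(c @ self.params.to_numpy())
        var = float(self.resid_var * c @ self.xtx_inv @ c)
        t = est / np.sqrt(var) if var > 0 else 0.0
        p = 2 * scipy.stats.t.sf(abs(t), self.df_resid)
        return est, t, p


def _yule_walker(resid: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients from sample autocovariances (Yule-Walker)."""
    n = len(resid)
    r = np.array([resid[: n - k] @ resid[k:] / n for k in range(order + 1)])
    if r[0] <= 0:
        return np.zeros(order)
    R = scipy.linalg.toeplitz(r[:-1])
    try:
        phi = np.linalg.solve(R, r[1:])
    except np.linalg.LinAlgError:
        return np.zeros(order)
    # enforce stationarity: shrink toward zero if any root is inside unit circle
    while np.any(np.abs(np.roots(np.r_[1.0, -phi])) >= 1.0 - 1e-6):
        phi *= 0.95
    return phi


def _prewhiten(arr: np.ndarray, phi: np.ndarray, run_index: np.ndarray) -> np.ndarray:
    """Apply v_t = y_t - sum_k phi_k y_{t-k} within each run, dropping the
    first ``len(phi)`` rows of every run."""
    p = len(phi)
    pieces = []
    for r in np.unique(run_index):
        seg = arr[run_index == r]
        v = seg[p:].copy()
        for k in range(1, p + 1):
            v = v - phi[k - 1] * seg[p - k : len(seg) - k]
        pieces.append(v)
    return np.concatenate(pieces, axis=0)


def fit_glm(
    y: np.ndarray,
    X: DesignMatrix | pd.DataFrame | np.ndarray,
    ar_order: int = 2,
    run_index: np.ndarray | None = None,
) -> BetaEstimates:
    """Fit one series by OLS with two-pass AR(``ar_order``) prewhitening.

    Pass 1: OLS residuals -> Yule-Walker AR coefficients. Pass 2: data and
    design prewhitened per run, refit by OLS; t and p are computed on the
    whitened system.
    """
    if isinstance(X, DesignMatrix):
        names = list(X.matrix.columns)
        run_index = X.run_index if run_index is None else run_index
        Xv = X.values
    elif isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy()
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != len(y):
        raise ValueError("design rows must equal series length")
    if run_index is None:
        run_index = np.zeros(len(y), dtype=int)

    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name the offending columns via QR pivoting
        _, _, piv = scipy.linalg.qr(Xv, pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    beta0, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    if ar_order > 0:
        resid = y - Xv @ beta0
        phi = _yule_walker(resid, ar_order)
        yw = _prewhiten(y[:, None], phi, run_index).ravel()
        Xw = _prewhiten(Xv, phi, run_index)
    else:
        phi = np.zeros(0)
        yw, Xw = y, Xv

    xtx = Xw.T @ Xw
    xtx_inv = np.linalg.pinv(xtx)
    beta = xtx_inv @ Xw.T @ yw
    resid_w = yw - Xw @ beta
    df = Xw.shape[0] - Xv.shape[1]
    s2 = float(resid_w @ resid_w / max(df, 1))
    se = np.sqrt(np.clip(s2 * np.diag(xtx_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2 * scipy.stats.t.sf(np.abs(t), max(df, 1))
    return BetaEstimates(
        params=pd.Series(beta, index=names),
        ar_coeffs=phi,
        resid_var=s2,
        tvalues=pd.Series(t, index=names),
        pvalues=pd.Series(p, index=names),
        df_resid=df,
        xtx_inv=xtx_inv,
    )


def fit_glm_voxels(
    Y: np.ndarray,
    X: DesignMatrix,
    ar_order: int = 2,
) -> list[BetaEstimates]:
    """Fit every column of ``Y`` (scans x voxels) with its own AR correction."""
    return [fit_glm(Y[:, v], X, ar_order=ar_order) for v in range(Y.shape[1])]


@dataclass
class StatMap:
    """Per-voxel t and p for a contrast, on a 3-D grid."""

    t: np.ndarray
    p: np.ndarray
    df: int

    def __post_init__(self) -> None:
        if self.t.shape != self.p.shape:
            raise ValueError("t and p shapes differ")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values outside [0, 1]")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite t values")


def contrast_map(
    fits: list[BetaEstimates],
    contrasts: np.ndarray | list[np.ndarray],
    shape: tuple[int, int, int],
    conjunction: bool = False,
) -> StatMap:
    """t/p map for one contrast, or a minimum-t conjunction of several.

    Conjunction: per voxel the minimum t over contrasts, with p the
    maximum of the per-contrast p-values (significant only if every
    component is).
    """
    C = np.atleast_2d(np.asarray(contrasts, dtype=float))
    if not conjunction and C.shape[0] != 1:
        raise ValueError("pass conjunction=True for multiple contrasts")
    n_vox = len(fits)
    if int(np.prod(shape)) != n_vox:
        raise ValueError(f"shape {shape} does not match {n_vox} fitted voxels")
    t_all = np.empty((C.shape[0], n_vox))
    p_all = np.empty_like(t_all)
    for ci, c in enumerate(C):
        for v, fit in enumerate(fits):
            _, t, _ = fit.contrast(c)
            t_all[ci, v] = t
            # one-sided p for activation contrasts (positive tail)
            p_all[ci, v] = scipy.stats.t.sf(t, fit.df_resid)
    t_map = t_all.min(axis=0)
    p_map = p_all.max(axis=0)
    df = min(f.df_resid for f in fits)
    return StatMap(t=t_map.reshape(shape), p=p_map.reshape(shape), df=df)


def fdr_threshold(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask over ``pvals``."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = np.flatnonzero(ranked <= q * (np.arange(1, m + 1) / m))
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask.reshape(np.shape(pvals))


@dataclass
class ROI:
    label: str
    voxels: np.ndarray  # (n_voxels, 3) integer grid coordinates
    definition_type: str = "tms_responsive"  # motor_execution | tms_responsive | non_motor_control

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise ValueError("voxels must be (n, 3) coordinates")
        if len(np.unique(self.voxels, axis=0)) != len(self.voxels):
            raise ValueError(f"duplicate voxels in ROI {self.label}")

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def labels(self) -> list[str]:
        return [r.label for r in self.rois]


def define_rois(
    stat_map: StatMap,
    q: float = 0.05,
    min_cluster: int = 10,
    definition_type: str = "tms_responsive",
) -> ROISet:
    """Clusters of FDR-surviving voxels with at least ``min_cluster`` members.

    The p map is thresholded by Benjamini-Hochberg at level ``q``;
    suprathreshold voxels are grouped into face-connected (6-neighbour)
    components; components below the size floor are discarded. An empty
    result warns rather than raising.
    """
    mask = fdr_threshold(stat_map.p, q=q)
    if not mask.any():
        warnings.warn("no voxels survive the FDR threshold; empty ROI set")
        return ROISet()
    structure = scipy.ndimage.generate_binary_structure(3, 1)  # faces only
    labelled, n_comp = scipy.ndimage.label(mask, structure=structure)
    rois = []
    for k in range(1, n_comp + 1):
        coords = np.argwhere(labelled == k)
        if len(coords) >= min_cluster:
            rois.append(
                ROI(
                    label=f"cluster_{len(rois):02d}",
                    voxels=coords,
                    definition_type=definition_type,
                )
            )
    if not rois:
        warnings.warn(f"no cluster reached {min_cluster} voxels; empty ROI set")
    return ROISet(rois=rois)


def roi_betas(
    single_trial_fits: list[BetaEstimates] | np.ndarray,
    roi: ROI,
    shape: tuple[int, int, int] | None = None,
    event_columns: list[str] | None = None,
) -> np.ndarray:
    """Per-trial evoked amplitude of an ROI: trial betas averaged over voxels.

    ``single_trial_fits`` is either a list of per-voxel fits (with
    ``event_columns`` naming the trial regressors) or a pre-extracted
    (n_voxels, n_trials) beta array in flat voxel order; ``shape`` maps the
    ROI's grid coordinates to flat indices.
    """
    if roi.size == 0:
        raise ValueError(f"ROI {roi.label} is empty")
    if isinstance(single_trial_fits, np.ndarray):
        if shape is None:
            raise ValueError("shape required with a beta array")
        flat = np.ravel_multi_index(roi.voxels.T, shape)
        return single_trial_fits[flat].mean(axis=0)
    if event_columns is None:
        raise ValueError("event_columns required with per-voxel fits")
    if shape is None:
        raise ValueError("shape required with per-voxel fits")
    flat = np.ravel_multi_index(roi.voxels.T, shape)
    rows = [single_trial_fits[v].params[event_columns].to_numpy() for v in flat]
    return np.mean(rows, axis=0)
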