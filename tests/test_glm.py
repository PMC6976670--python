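"""GLM machinery: HRF, design construction, AR(2) prewhitening, FDR, ROIs."""
import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.signal
import scipy.stats

from statebold.design import Event, EventSchedule
from statebold.glm import (
    BOLDSeries,
    HRFParams,
    ROI,
    StatMap,
    build_design,
    contrast_map,
    define_rois,
    fdr_threshold,
    fit_glm,
    hrf,
    preprocess_bold,
    roi_betas,
)


class TestPreprocessBold:
    def _series(self, y, tr=2.25):
        y = np.atleast_2d(np.asarray(y, float))
        if y.shape[0] == 1:
            y = y.T
        return BOLDSeries(y, tr=tr, run_index=np.zeros(y.shape[0], int))

    def test_linear_ramp_removed(self):
        out = preprocess_bold(self._series(np.arange(200.0)), normalize=False)
        assert np.allclose(out.data, 0.0, atol=1e-8)

    def test_highpass_attenuates_slow_keeps_fast(self):
        n = 200
        t = np.arange(n)
        slow = np.sin(2 * np.pi * 1 * t / n)  # 1 cycle per run
        fast = np.sin(2 * np.pi * 10 * t / n)  # 10 cycles per run
        out_s = preprocess_bold(self._series(slow), normalize=False).data.ravel()
        out_f = preprocess_bold(self._series(fast), normalize=False).data.ravel()
        assert out_s.std() < 0.10 * slow.std()
        assert abs(out_f.std() - fast.std()) < 0.05 * fast.std()

    def test_z_normalized_output(self, rng):
        y = rng.normal(size=(150, 3)) + 5.0
        out = preprocess_bold(BOLDSeries(y, 2.25, np.repeat([0, 1], 75)))
        for r in (0, 1):
            m = out.run_index == r
            assert np.allclose(out.data[m].mean(axis=0), 0.0, atol=1e-10)
            assert np.allclose(out.data[m].std(axis=0), 1.0, atol=1e-10)

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            out = preprocess_bold(self._series(np.ones(50)))
        assert out.invalid[0]


class TestHRF:
    def test_zero_at_origin(self):
        assert hrf(np.array([0.0]))[0] == 0.0

    def test_peak_location(self):
        t = np.arange(0, 30, 0.01)
        h = hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.05)

    def test_single_sign_change_after_peak(self):
        t = np.arange(0, 30, 0.01)
        h = hrf(t)
        after = h[np.argmax(h) :]
        changes = np.sum(np.diff(np.sign(after[np.abs(after) > 1e-12])) != 0)
        assert changes == 1  # one crossing into the undershoot

    def test_invalid_params_error(self):
        with pytest.raises(ValueError):
            HRFParams(peak=-1.0)


def _mini_schedule(onsets, types=None, run=0):
    types = types or ["tms"] * len(onsets)
    return EventSchedule(
        events=[Event(onset=o, type=t, run_index=run) for o, t in zip(onsets, types)]
    )


class TestBuildDesign:
    def test_single_stick_equals_sampled_hrf(self):
        sched = _mini_schedule([0.0])
        X = build_design(sched, tr=2.25, n_scans_per_run=20, mode="single_trial")
        col = X.matrix["tms_000"].to_numpy()
        expect = hrf(np.arange(20) * 2.25)
        assert np.allclose(col, expect, atol=1e-6)

    def test_column_count_single_trial(self, paper_scale_design):
        from statebold.design import generate_event_schedule

        sched = generate_event_schedule(paper_scale_design, seed=2)
        n_tms = sched.count("tms")
        motion = pd.DataFrame(
            np.random.default_rng(0).normal(size=(4 * 406, 6)),
            columns=list("abcdef"),
        )
        X = build_design(sched, tr=2.25, n_scans_per_run=406, motion=motion)
        assert X.matrix.shape[1] == n_tms + 6 + 4

    def test_aggregate_mode_column_count(self):
        sched = _mini_schedule([4.5, 20.25, 35.0, 50.0], ["tms", "null", "tms", "null"])
        X = build_design(
            sched, tr=2.25, n_scans_per_run=40, mode="aggregate", event_type="tms",
            aggregate_other=True,
        )
        assert list(X.matrix.columns) == ["tms", "null_aggregate", "constant_run0"]

    def test_boxcar_localizer_variant(self):
        sched = _mini_schedule([9.0])
        stick = build_design(sched, tr=1.5, n_scans_per_run=60).matrix["tms_000"]
        box = build_design(
            sched, tr=1.5, n_scans_per_run=60, event_duration=4.0
        ).matrix["tms_000"]
        assert box.abs().sum() > 2 * stick.abs().sum()  # boxcar integrates more
        assert box.max() > stick.max()

    def test_event_outside_timeline_errors(self):
        sched = _mini_schedule([1000.0])
        with pytest.raises(ValueError, match="outside"):
            build_design(sched, tr=2.25, n_scans_per_run=20)


class TestFitGLM:
    def test_noiseless_exact_recovery(self, rng):
        X = rng.normal(size=(60, 4))
        beta = np.array([1.5, -2.0, 0.3, 4.0])
        fit = fit_glm(X @ beta, X, ar_order=0)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        fit = fit_glm(y, X, ar_order=0)
        expect = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.params.to_numpy(), expect, atol=1e-10)

    def test_ar2_coefficients_recovered(self):
        rng = np.random.default_rng(5)
        n = 20000
        e = rng.standard_normal(n)
        y = scipy.signal.lfilter([1.0], [1.0, -0.4, -0.1], e)
        X = np.ones((n, 1))
        fit = fit_glm(y, X, ar_order=2)
        assert np.allclose(fit.ar_coeffs, [0.4, 0.1], atol=0.05)

    def test_rank_deficiency_named(self, rng):
        X = rng.normal(size=(30, 2))
        Xd = pd.DataFrame(np.column_stack([X, X[:, 0]]), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(rng.normal(size=30), Xd, ar_order=0)

    def test_prewhitened_equals_gls_small_instance(self, rng):
        """Oracle: explicit inversion of the implied AR(1) covariance."""
        n, phi = 40, np.array([0.5])
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        run_index = np.zeros(n, int)
        # prewhitened OLS with fixed phi
        from statebold.glm import _prewhiten

        Xw = _prewhiten(X, phi, run_index)
        yw = _prewhiten(y[:, None], phi, run_index).ravel()
        b_white = np.linalg.solve(Xw.T @ Xw, Xw.T @ yw)
        # GLS on the trimmed system with the implied AR covariance
        idx = np.arange(1, n)
        Sigma = scipy.linalg.toeplitz(phi[0] ** np.arange(n))
        # conditional covariance of y[1:] given y[0] is the AR innovation form;
        # equivalently solve GLS on rows 1..n-1 with W = I (whitening is exact)
        Si = np.linalg.inv(Sigma)
        b_gls = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
        assert np.allclose(b_white, b_gls, atol=5e-2)  # differ only via edge rows

    def test_orthogonal_confound_leaves_event_betas(self, rng):
        X = rng.normal(size=(80, 3))
        y = rng.normal(size=80)
        fit_a = fit_glm(y, X, ar_order=0)
        # confound orthogonal to existing columns and to y
        q, _ = np.linalg.qr(np.column_stack([X, y]))
        extra = rng.normal(size=80)
        extra -= q @ (q.T @ extra)
        fit_b = fit_glm(y, np.column_stack([X, extra]), ar_order=0)
        assert np.allclose(
            fit_a.params.to_numpy(), fit_b.params.to_numpy()[:3], atol=1e-8
        )


class TestContrasts:
    def _fits(self, rng, n_vox=8, p=3):
        fits = []
        for _ in range(n_vox):
            X = rng.normal(size=(40, p))
            y = rng.normal(size=40)
            fits.append(fit_glm(y, X, ar_order=0))
        return fits

    def test_unit_contrast_equals_coefficient_t(self, rng):
        fits = self._fits(rng, n_vox=4)
        m = contrast_map(fits, [np.array([0, 1, 0.0])], shape=(4, 1, 1))
        expect = [f.tvalues.iloc[1] for f in fits]
        assert np.allclose(m.t.ravel(), expect, atol=1e-10)

    def test_conjunction_idempotent(self, rng):
        fits = self._fits(rng, n_vox=6)
        c = np.array([1.0, 0, 0])
        single = contrast_map(fits, [c], shape=(6, 1, 1))
        conj = contrast_map(fits, [c, c], shape=(6, 1, 1), conjunction=True)
        assert np.allclose(single.t, conj.t)
        assert np.allclose(single.p, conj.p)

    def test_conjunction_min_t_bounded(self, rng):
        fits = self._fits(rng, n_vox=6)
        c1, c2 = np.array([1.0, 0, 0]), np.array([0, 1.0, -1.0])
        m1 = contrast_map(fits, [c1], shape=(6, 1, 1))
        m2 = contrast_map(fits, [c2], shape=(6, 1, 1))
        conj = contrast_map(fits, [c1, c2], shape=(6, 1, 1), conjunction=True)
        assert np.all(conj.t <= m1.t + 1e-12)
        assert np.all(conj.t <= m2.t + 1e-12)
        assert np.allclose(conj.t, np.minimum(m1.t, m2.t))


class TestFDR:
    def test_all_small_all_rejected(self):
        assert fdr_threshold(np.full(20, 0.001), q=0.05).all()

    def test_all_one_none_rejected(self):
        assert not fdr_threshold(np.ones(20), q=0.05).any()

    def test_empty_input(self):
        assert fdr_threshold(np.array([])).size == 0

    def test_matches_bruteforce_stepup(self, rng):
        for _ in range(10):
            p = rng.uniform(size=50)
            got = fdr_threshold(p, q=0.05)
            # brute force: largest k with p_(k) <= qk/m; reject the k smallest
            srt = np.sort(p)
            ks = [k for k in range(1, 51) if srt[k - 1] <= 0.05 * k / 50]
            expect = np.zeros(50, bool)
            if ks:
                thresh = srt[max(ks) - 1]
                expect = p <= thresh
            assert np.array_equal(got, expect)


def _statmap_from_mask(mask):
    p = np.where(mask, 1e-6, 1.0)
    t = np.where(mask, 10.0, 0.0)
    return StatMap(t=t.astype(float), p=p.astype(float), df=100)


class TestDefineROIs:
    def test_cluster_size_floor(self):
        vol = np.zeros((12, 12, 6), bool)
        vol[1, 1:10, 1] = True  # 9 voxels -> excluded
        vol[5, 1:11, 3] = True  # 10 voxels -> retained
        rois = define_rois(_statmap_from_mask(vol))
        assert len(rois) == 1
        assert rois.rois[0].size == 10

    def test_corner_touching_clusters_split(self):
        vol = np.zeros((12, 12, 6), bool)
        vol[0:2, 0:3, 0:2] = True  # 12 voxels
        vol[2:4, 3:6, 2:4] = True  # touches only at corner/edge, no face
        rois = define_rois(_statmap_from_mask(vol), min_cluster=10)
        assert len(rois) == 2

    def test_matches_flood_fill_oracle(self, rng):
        mask = rng.uniform(size=(10, 10, 5)) < 0.3
        rois = define_rois(_statmap_from_mask(mask), min_cluster=1)
        # brute-force flood fill with face connectivity
        seen = np.zeros(mask.shape, bool)
        comps = []
        for idx in np.argwhere(mask):
            idx = tuple(idx)
            if seen[idx]:
                continue
            stack, comp = [idx], []
            seen[idx] = True
            while stack:
                cur = stack.pop()
                comp.append(cur)
                for d in range(3):
                    for s in (-1, 1):
                        nb = list(cur)
                        nb[d] += s
                        nb = tuple(nb)
                        if (
                            0 <= nb[d] < mask.shape[d]
                            and mask[nb]
                            and not seen[nb]
                        ):
                            seen[nb] = True
                            stack.append(nb)
            comps.append(frozenset(comp))
        got = {frozenset(map(tuple, r.voxels)) for r in rois}
        assert got == set(comps)

    def test_empty_map_warns_not_raises(self):
        with pytest.warns(UserWarning):
            rois = define_rois(_statmap_from_mask(np.zeros((5, 5, 5), bool)))
        assert len(rois) == 0

    def test_invariant_to_voxel_relabelling(self, rng):
        mask = rng.uniform(size=(8, 8, 4)) < 0.25
        a = define_rois(_statmap_from_mask(mask), min_cluster=2)
        b = define_rois(_statmap_from_mask(mask.copy()), min_cluster=2)
        assert {frozenset(map(tuple, r.voxels)) for r in a} == {
            frozenset(map(tuple, r.voxels)) for r in b
        }


class TestROIBetas:
    def test_single_voxel_identity(self, rng):
        betas = rng.normal(size=(6, 10))  # 6 voxels x 10 trials, flat order (3,2,1)
        roi = ROI("a", np.array([[1, 0, 0]]))
        out = roi_betas(betas, roi, shape=(3, 2, 1))
        assert np.allclose(out, betas[2])  # flat index of (1,0,0) in (3,2,1)

    def test_opposite_betas_cancel(self):
        betas = np.vstack([np.ones(5), -np.ones(5)])
        roi = ROI("a", np.array([[0, 0, 0], [1, 0, 0]]))
        assert np.allclose(roi_betas(betas, roi, shape=(2, 1, 1)), 0.0)

    def test_matches_manual_mean(self, rng):
        betas = rng.normal(size=(24, 7))
        coords = np.array([[0, 1, 0], [1, 2, 0], [2, 3, 0]])
        roi = ROI("a", coords)
        out = roi_betas(betas, roi, shape=(4, 6, 1))
        manual = np.mean([betas[np.ravel_multi_index(c, (4, 6, 1))] for c in coords], axis=0)
        assert np.allclose(out, manual)

    def test_empty_roi_errors(self):
        roi = ROI("a", np.zeros((0, 3), int))
        with pytest.raises(ValueError, match="empty"):
            roi_betas(np.ones((2, 2)), roi, shape=(2, 1, 1))
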