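"""Lesion-aware preprocessing operations against hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psdconn.core import BoldSeries, MotionTrace
from psdconn import preprocess as pre


def _bold(x, tr=2.0):
    return BoldSeries(data=np.asarray(x, dtype=float), tr_seconds=tr)


class TestFlip:
    def test_left_lesion_identity(self, rng):
        v = rng.random((6, 5, 4))
        np.testing.assert_array_equal(pre.flip_to_ipsilesional(v, "left"), v)

    def test_involution(self, rng):
        v = rng.random((6, 5, 4, 3))
        twice = pre.flip_to_ipsilesional(pre.flip_to_ipsilesional(v, "right"), "right")
        np.testing.assert_array_equal(twice, v)

    def test_index_arithmetic(self):
        v = np.zeros((3, 2, 2))
        v[0, 1, 0] = 7.0
        out = pre.flip_to_ipsilesional(v, "right")
        assert out[2, 1, 0] == 7.0 and out[0, 1, 0] == 0.0

    def test_unknown_side(self):
        with pytest.raises(ValueError, match="side"):
            pre.flip_to_ipsilesional(np.zeros((2, 2, 2)), "both")


class TestEnantiomorphicFill:
    def test_empty_lesion_identity(self, rng):
        v = rng.random((4, 4, 4))
        out = pre.enantiomorphic_fill(v, np.zeros((4, 4, 4), bool))
        np.testing.assert_array_equal(out, v)

    def test_mirror_index(self, rng):
        v = rng.random((4, 3, 3))
        lesion = np.zeros((4, 3, 3), bool)
        lesion[0, 1, 2] = True
        out = pre.enantiomorphic_fill(v, lesion)
        assert out[0, 1, 2] == v[3, 1, 2]
        untouched = ~lesion
        np.testing.assert_array_equal(out[untouched], v[untouched])

    def test_symmetric_image_fixed_point(self, rng):
        half = rng.random((3, 4, 4))
        v = np.concatenate([half, half[::-1]], axis=0)
        lesion = np.zeros_like(v, bool)
        lesion[1, 2, 2] = True
        out = pre.enantiomorphic_fill(v, lesion)
        np.testing.assert_allclose(out, v)

    def test_lesioned_mirror_falls_back(self, rng):
        v = rng.random((4, 2, 2))
        lesion = np.zeros((4, 2, 2), bool)
        lesion[0, 0, 0] = lesion[3, 0, 0] = True  # mirror pair both lesioned
        out = pre.enantiomorphic_fill(v, lesion)
        assert out[0, 0, 0] == v[0, 0, 0]  # original kept


class TestFramewiseDisplacement:
    def test_constant_params_zero_fd(self):
        fd = pre.compute_fd(np.ones((6, 10)))
        np.testing.assert_array_equal(fd, np.zeros(10))

    def test_translation_step(self):
        p = np.zeros((6, 5))
        p[0, 3:] = 0.5  # one 0.5 mm x-translation step at frame 3
        fd = pre.compute_fd(p)
        assert fd[3] == pytest.approx(0.5) and fd[[0, 1, 2, 4]].sum() == 0

    def test_rotation_scaling_50mm(self):
        p = np.zeros((6, 4))
        p[4, 2:] = 0.02  # 0.02 rad rotation step -> 50 * 0.02 = 1.0 mm
        fd = pre.compute_fd(p)
        assert fd[2] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_direct_formula(self, seed):
        p = np.random.default_rng(seed).normal(size=(6, 8))
        fd = pre.compute_fd(p)
        assert fd[0] == 0.0
        for t in range(1, 8):
            d = np.abs(p[:, t] - p[:, t - 1])
            assert fd[t] == pytest.approx(d[:3].sum() + 50 * d[3:].sum())


class TestQC:
    def test_zero_motion_keep(self):
        d = pre.qc_exclude(MotionTrace(params=np.zeros((6, 20))))
        assert d.keep and d.reason is None

    def test_mean_fd_excludes(self):
        p = np.zeros((6, 11))
        p[0] = 0.33 * (-1.0) ** np.arange(11)  # steps of 0.66 mm -> mean FD 0.6
        d = pre.qc_exclude(MotionTrace(params=p))
        assert not d.keep and d.reason == "mean_fd"
        assert d.mean_fd == pytest.approx(0.6)

    def test_boundary_is_kept(self):
        # value exactly at a threshold is kept: the criteria are strict
        p = np.zeros((6, 30))
        p[0, -1] = 3.0  # displacement of exactly 3 mm
        d = pre.qc_exclude(MotionTrace(params=p))
        assert d.max_disp_mm == 3.0
        assert d.keep

    def test_rotation_threshold_strict(self):
        for deg, keep in ((2.999, True), (3.001, False)):
            p = np.zeros((6, 30))
            p[3, -1] = np.deg2rad(deg)
            assert pre.qc_exclude(MotionTrace(params=p)).keep is keep

    def test_first_failing_reason_named(self):
        p = np.zeros((6, 4))
        p[0] = [0, 4, 4, 4]   # displacement 4 mm fails first
        p[3] = [0, 1, 1, 1]   # rotation also fails
        assert pre.qc_exclude(MotionTrace(params=p)).reason == "max_disp"


class TestFriston24:
    def test_zero_params(self):
        out = pre.build_friston24(np.zeros((6, 7)))
        assert out.shape == (24, 7) and not out.any()

    def test_shape_contract(self, rng):
        assert pre.build_friston24(rng.normal(size=(6, 13))).shape == (24, 13)

    def test_symbolic_construction(self):
        p = np.tile(np.arange(1.0, 6.0), (6, 1))  # p(t) = t+1
        out = pre.build_friston24(p)
        np.testing.assert_array_equal(out[:6], p)
        np.testing.assert_array_equal(out[6:12, 0], np.zeros(6))
        np.testing.assert_array_equal(out[6:12, 1:], p[:, :-1])
        np.testing.assert_array_equal(out[12:18], p ** 2)
        np.testing.assert_array_equal(out[18:, 1:], p[:, :-1] ** 2)


class TestNuisanceRegression:
    def test_orthogonal_regressor_leaves_centered_input(self, rng):
        T = 8
        reg = np.zeros((1, T)); reg[0, 0], reg[0, 1] = 1.0, -1.0
        x = np.ones(T)  # centered input is zero -> residual zero
        out = pre.nuisance_regress(_bold(x.reshape(1, 1, 1, T)), reg)
        np.testing.assert_allclose(out.data, 0, atol=1e-12)

    def test_voxel_equal_to_regressor_removed(self, rng):
        reg = rng.normal(size=(1, 10))
        out = pre.nuisance_regress(_bold(reg.reshape(1, 1, 1, 10)), reg)
        np.testing.assert_allclose(out.data, 0, atol=1e-10)

    def test_three_timepoint_normal_equations(self):
        # explicit OLS on [1, z] with y = (1, 3, 2), z = (0, 1, 2)
        y = np.array([1.0, 3.0, 2.0])
        z = np.array([0.0, 1.0, 2.0])
        X = np.column_stack([np.ones(3), z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        expected = y - X @ beta
        out = pre.nuisance_regress(_bold(y.reshape(1, 1, 1, 3)), z.reshape(1, 3))
        np.testing.assert_allclose(out.data.ravel(), expected, atol=1e-12)

    def test_rank_deficient_design_handled(self, rng, caplog):
        reg = np.vstack([np.ones(6), np.ones(6)])  # collinear with intercept
        out = pre.nuisance_regress(_bold(rng.normal(size=(1, 1, 1, 6))), reg)
        assert np.isfinite(out.data).all()


class TestDetrend:
    def test_constant_and_ramp_removed(self):
        t = np.arange(20.0)
        for series in (np.full(20, 3.3), 2.0 + 0.5 * t):
            out = pre.detrend_linear(_bold(series.reshape(1, 1, 1, -1)))
            np.testing.assert_allclose(out.data, 0, atol=1e-10)

    def test_sinusoid_recovered_via_two_column_oracle(self):
        t = np.arange(50.0)
        s = np.sin(2 * np.pi * t / 10)
        y = 1.5 - 0.2 * t + s
        X = np.column_stack([np.ones(50), t])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        out = pre.detrend_linear(_bold(y.reshape(1, 1, 1, -1)))
        np.testing.assert_allclose(out.data.ravel(), resid, atol=1e-9)

    def test_idempotent(self, rng):
        b = _bold(rng.normal(size=(2, 2, 1, 30)))
        once = pre.detrend_linear(b)
        twice = pre.detrend_linear(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)


class TestBandpass:
    def test_constant_zeroed(self):
        out = pre.bandpass(_bold(np.full((1, 1, 1, 64), 5.0)))
        np.testing.assert_allclose(out.data, 0, atol=1e-12)

    @pytest.mark.parametrize("freq,kept", [(0.04, True), (0.2, False)])
    def test_bin_aligned_sinusoids(self, freq, kept):
        t = np.arange(100) * 2.0  # df = 1/200 Hz: both bins exact
        x = np.sin(2 * np.pi * freq * t)
        out = pre.bandpass(_bold(x.reshape(1, 1, 1, -1)), 0.01, 0.08).data.ravel()
        ratio = np.abs(out).max() / np.abs(x).max()
        assert ratio == pytest.approx(1.0 if kept else 0.0, abs=1e-9)

    def test_empty_band_reports_minimum_length(self):
        with pytest.raises(ValueError, match="at least T="):
            pre.bandpass(_bold(np.zeros((1, 1, 1, 10)), tr=2.0), 0.01, 0.02)

    def test_high_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pre.bandpass(_bold(np.zeros((1, 1, 1, 50)), tr=2.0), 0.01, 0.3)


class TestLagEstimation:
    def test_identical_voxel_lag_zero(self, rng):
        ref = rng.normal(size=40)
        b = _bold(ref.reshape(1, 1, 1, -1))
        lag, corrected = pre.estimate_and_correct_lag(b, ref, max_lag_tr=3)
        assert lag.ravel()[0] == 0
        np.testing.assert_allclose(corrected.data.ravel(), ref)

    @pytest.mark.parametrize("true_lag", [-3, -1, 1, 2, 4])
    def test_circular_shift_recovered(self, rng, true_lag):
        ref = rng.normal(size=60)
        voxel = np.roll(ref, true_lag)  # voxel lags reference by true_lag
        b = _bold(voxel.reshape(1, 1, 1, -1))
        lag, corrected = pre.estimate_and_correct_lag(b, ref, max_lag_tr=4)
        assert lag.ravel()[0] == true_lag
        # after correction the overlap region matches the reference
        got = corrected.data.ravel()
        sl = slice(max(0, -true_lag), 60 - max(0, true_lag))
        np.testing.assert_allclose(got[sl], ref[sl], atol=1e-12)

    def test_zero_variance_voxel_flagged_lag_zero(self, rng):
        data = np.vstack([np.zeros(40), rng.normal(size=40)])
        ref = data[1].copy()
        b = _bold(data.reshape(2, 1, 1, 40))
        lag, _ = pre.estimate_and_correct_lag(b, ref, max_lag_tr=2)
        assert lag.ravel()[0] == 0 and lag.ravel()[1] == 0

    def test_noiseless_cohort_ground_truth_recovery(self):
        # pure shifted factors: estimated lag map equals injected truth
        from psdconn.cohort import CohortSpec, generate_cohort
        blocks = {i: np.arange(i * 8, (i + 1) * 8) + 64 for i in range(6)}
        spec = CohortSpec(n_per_group={"HC": 1, "Stroke": 2, "PSD": 2},
                          grid_shape=(8, 8, 6), n_timepoints=150,
                          network_blocks=blocks, hub_blocks=(0, 1),
                          effect_delta_r=0.2, noise_sd=0.0, global_r=0.0,
                          lag_range_tr=3, lesion_size_range=(2, 4), rng_seed=9)
        subjects, _, truth = generate_cohort(spec)
        for s in subjects:
            if s.group == "HC":
                continue
            data = s.bold.data if s.lesion_side == "left" else s.bold.data[::-1]
            b = BoldSeries(data=np.ascontiguousarray(data), tr_seconds=2.0)
            for bi, bid in enumerate(sorted(blocks)):
                mask = np.zeros(spec.grid_shape, bool)
                mask.ravel()[blocks[bid]] = True
                ref = truth.factors[s.subject_id][bi]
                lag, _ = pre.estimate_and_correct_lag(b, ref, max_lag_tr=3,
                                                      mask=mask)
                np.testing.assert_array_equal(
                    lag.ravel()[blocks[bid]],
                    truth.lag_maps[s.subject_id].ravel()[blocks[bid]])


class TestSmoothing:
    def test_constant_preserved(self):
        out = pre.smooth_gaussian(np.full((8, 8, 8), 3.7), 3.0, 6.0)
        np.testing.assert_allclose(out, 3.7)

    def test_delta_kernel_center(self):
        d = np.zeros((15, 15, 15)); d[7, 7, 7] = 1.0
        out = pre.smooth_gaussian(d, 3.0, 6.0)
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        analytic = (1 / (np.sqrt(2 * np.pi) * sigma)) ** 3
        assert out[7, 7, 7] == pytest.approx(analytic, rel=1e-3)

    def test_sum_conserved_under_reflection(self, rng):
        m = rng.random((10, 11, 9))
        out = pre.smooth_gaussian(m, 3.0, 6.0)
        assert out.sum() == pytest.approx(m.sum(), rel=1e-12)

    def test_4d_smooths_only_spatially(self, rng):
        x = rng.normal(size=(6, 6, 6, 3))
        out = pre.smooth_gaussian(x, 3.0, 6.0)
        for t in range(3):
            np.testing.assert_allclose(out[..., t],
                                       pre.smooth_gaussian(x[..., t], 3.0, 6.0))


class TestGroupMask:
    def test_all_ones_subjects(self):
        atlas = np.zeros((4, 4, 4), bool); atlas[1:3] = True
        lesion = np.zeros((4, 4, 4), bool); lesion[1, 0, 0] = True
        out = pre.build_group_mask([np.ones((4, 4, 4), bool)] * 3, atlas, [lesion])
        np.testing.assert_array_equal(out, atlas & ~lesion)

    def test_missing_slab_absent(self):
        atlas = np.ones((4, 4, 4), bool)
        subj = np.ones((4, 4, 4), bool); subj[:, :, 0] = False
        out = pre.build_group_mask([subj], atlas, [])
        assert not out[:, :, 0].any() and out[:, :, 1:].all()

    def test_set_algebra_oracle(self, rng):
        subs = [rng.random((4, 4, 4)) > 0.2 for _ in range(3)]
        atlas = rng.random((4, 4, 4)) > 0.3
        lesions = [rng.random((4, 4, 4)) > 0.9 for _ in range(2)]
        expected = atlas.copy()
        for m in subs:
            expected &= m
        for l in lesions:
            expected &= ~l
        if not expected.any():
            pytest.skip("degenerate random fixture")
        out = pre.build_group_mask(subs, atlas, lesions)
        np.testing.assert_array_equal(out, expected)

    def test_empty_result_raises(self):
        with pytest.raises(ValueError, match="empty"):
            pre.build_group_mask([np.zeros((2, 2, 2), bool)],
                                 np.ones((2, 2, 2), bool), [])

    def test_intersection_idempotent(self, rng):
        subs = [rng.random((4, 4, 4)) > 0.2]
        atlas = np.ones((4, 4, 4), bool)
        once = pre.build_group_mask(subs, atlas, [])
        twice = pre.build_group_mask(subs + [once], atlas, [])
        np.testing.assert_array_equal(once, twice)
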