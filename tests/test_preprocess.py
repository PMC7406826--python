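"""Unit tests of the cleanup chain against hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippomediate import preprocess as pp
from hippomediate.types import MotionParams, Volume4D


def _vol(T=40, grid=(6, 6, 3), fill=None, rng=None, tr=2.0):
    if fill is not None:
        data = np.full((T,) + grid, float(fill))
    else:
        data = (rng or np.random.default_rng(0)).standard_normal((T,) + grid)
    return Volume4D(data=data, voxel_size=(3.0, 3.0, 4.5), tr=tr)


class TestDiscard:
    def test_drops_first_volumes_from_both(self):
        vol = _vol(T=200)
        motion = MotionParams(np.zeros((200, 6)))
        v2, m2 = pp.discard_initial(vol, motion, k=4)
        assert v2.n_volumes == 196
        assert m2.n_volumes == 196
        np.testing.assert_array_equal(v2.data, vol.data[4:])

    def test_zero_is_identity(self):
        vol = _vol(T=10)
        motion = MotionParams(np.zeros((10, 6)))
        v2, m2 = pp.discard_initial(vol, motion, k=0)
        np.testing.assert_array_equal(v2.data, vol.data)

    def test_too_short_series_rejected(self):
        vol = _vol(T=3)
        motion = MotionParams(np.zeros((3, 6)))
        with pytest.raises(ValueError):
            pp.discard_initial(vol, motion, k=4)


class TestFD:
    def test_constant_trace_gives_zero(self):
        m = MotionParams(np.tile([0.3, -0.1, 0.2, 0.01, 0.0, -0.02], (20, 1)))
        np.testing.assert_allclose(pp.compute_fd(m), 0.0)

    def test_single_translation_step(self):
        vals = np.zeros((20, 6))
        vals[7:, 1] = 0.3  # +0.3 mm step at t=7
        fd = pp.compute_fd(MotionParams(vals))
        expected = np.zeros(20)
        expected[7] = 0.3
        np.testing.assert_allclose(fd, expected, atol=1e-12)

    def test_rotation_scaled_by_head_radius(self):
        vals = np.zeros((10, 6))
        vals[4:, 5] = 0.01  # +0.01 rad
        fd = pp.compute_fd(MotionParams(vals))
        assert fd[4] == pytest.approx(0.5)  # 50 mm * 0.01 rad
        assert np.all(fd[np.arange(10) != 4] == 0)


class TestExclusion:
    def test_still_subject_not_excluded(self):
        m = MotionParams(np.zeros((20, 6)))
        rep = pp.exclusion_decision(m, pp.compute_fd(m))
        assert not rep.excluded and rep.reasons == []

    def test_rotation_in_radians_converted_to_degrees(self):
        vals = np.zeros((20, 6))
        vals[5, 3] = 0.03  # 0.03 rad = 1.72 deg > 1.5 deg
        m = MotionParams(vals)
        rep = pp.exclusion_decision(m, pp.compute_fd(m))
        assert rep.excluded and rep.reasons == ["rotation"]
        assert rep.max_abs_rotation_deg == pytest.approx(np.degrees(0.03))

    def test_mean_fd_rule(self):
        m = MotionParams(np.zeros((20, 6)))
        rep = pp.exclusion_decision(m, np.full(20, 0.6))
        assert rep.excluded and rep.reasons == ["mean_fd"]

    def test_raising_thresholds_never_excludes_more(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            m = MotionParams(np.cumsum(rng.normal(0, 0.05, (30, 6)), axis=0))
            fd = pp.compute_fd(m)
            excluded = [
                pp.exclusion_decision(m, fd, max_translation=t, max_rotation_deg=r, max_mean_fd=f).excluded
                for t, r, f in [(0.5, 0.5, 0.1), (1.0, 1.0, 0.3), (1.5, 1.5, 0.5), (3.0, 3.0, 1.0)]
            ]
            # once a subject survives a threshold set, it survives all looser ones
            assert excluded == sorted(excluded, reverse=True)


class TestScrubbing:
    def test_quiet_series_yields_no_columns(self):
        cols, times = pp.scrubbing_regressors(np.full(20, 0.1))
        assert cols.shape == (20, 0) and times == []

    def test_window_one_before_two_after(self):
        fd = np.zeros(20)
        fd[10] = 0.7
        cols, times = pp.scrubbing_regressors(fd)
        assert times == [9, 10, 11, 12]
        assert cols.shape == (20, 4)
        for j, t in enumerate(times):
            expected = np.zeros(20)
            expected[t] = 1.0
            np.testing.assert_array_equal(cols[:, j], expected)

    def test_window_clipped_at_series_start(self):
        fd = np.zeros(20)
        fd[1] = 0.9
        _, times = pp.scrubbing_regressors(fd)
        assert times == [0, 1, 2, 3]


class TestFriston24:
    def test_zero_motion_all_zero(self):
        out = pp.friston24(MotionParams(np.zeros((15, 6))))
        assert out.shape == (15, 24)
        np.testing.assert_array_equal(out, 0.0)

    def test_binary_parameter_square_idempotent(self):
        vals = np.zeros((12, 6))
        vals[:, 2] = np.arange(12) % 2
        out = pp.friston24(MotionParams(vals))
        np.testing.assert_array_equal(out[:, 12 + 2], out[:, 2])  # p^2 == p for 0/1

    def test_lag_column_definition(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((10, 6))
        out = pp.friston24(MotionParams(vals))
        assert np.all(out[0, 6:12] == 0)
        np.testing.assert_allclose(out[1:, 6:12], vals[:-1])
        np.testing.assert_allclose(out[:, 12:18], vals**2)


class TestCompCor:
    def test_planted_rank_one_recovered(self):
        rng = np.random.default_rng(7)
        T, grid = 100, (6, 6, 3)
        s = rng.standard_normal(T)
        mask = np.zeros(grid, bool)
        mask[:3] = True
        data = 0.01 * rng.standard_normal((T,) + grid)
        data[:, mask] += np.outer(s, 1.0 + 0.1 * rng.standard_normal(mask.sum()))
        vol = Volume4D(data=data)
        comps = pp.compcor(vol, mask, k=3)
        assert abs(np.corrcoef(comps[:, 0], s)[0, 1]) > 0.99

    def test_white_noise_spectrum_is_flat(self):
        # with no structure the top singular values are Marchenko-Pastur flat
        rng = np.random.default_rng(8)
        T, n_vox = 196, 500
        data = rng.standard_normal((T, 10, 10, 5))
        vol = Volume4D(data=data)
        mask = np.zeros((10, 10, 5), bool)
        mask.ravel()[:n_vox] = True
        ts = vol.data[:, mask]
        from scipy.signal import detrend

        ts = detrend(ts, axis=0)
        ts /= ts.std(axis=0)
        s = np.linalg.svd(ts, compute_uv=False)
        assert s[0] / s[4] < 3.0

    def test_k_zero_returns_empty(self, tiny_vol):
        mask = np.zeros(tiny_vol.grid, bool)
        mask[0, 0, 0] = True
        comps = pp.compcor(tiny_vol, mask, k=0)
        assert comps.shape == (tiny_vol.n_volumes, 0)

    def test_rank_deficient_mask_warns(self, tiny_vol):
        mask = np.zeros(tiny_vol.grid, bool)
        mask[0, 0, :2] = True  # 2 voxels cannot support 5 components
        with pytest.warns(RuntimeWarning):
            comps = pp.compcor(tiny_vol, mask, k=5)
        assert comps.shape[1] <= 2


class TestNuisanceAssembly:
    def test_column_arithmetic_without_spikes(self, still_motion):
        fd = pp.compute_fd(still_motion)
        cc = np.random.default_rng(0).standard_normal((40, 5))
        nuis = pp.build_nuisance(still_motion, fd, compcor_cols=cc)
        assert nuis.n_columns == 24 + 0 + 5 + 1 + 1

    def test_column_arithmetic_with_spikes(self, still_motion):
        fd = np.zeros(40)
        fd[20] = 0.9  # flags 19,20,21,22
        cc = np.random.default_rng(0).standard_normal((40, 5))
        nuis = pp.build_nuisance(still_motion, fd, compcor_cols=cc)
        assert nuis.n_columns == 24 + 4 + 5 + 1 + 1

    def test_labels_unique_and_ordered(self, still_motion):
        nuis = pp.build_nuisance(still_motion, pp.compute_fd(still_motion))
        assert len(set(nuis.labels)) == len(nuis.labels)
        assert nuis.labels[0] == "friston01"
        assert nuis.labels[-2:] == ["trend", "intercept"]


class TestRegression:
    def test_design_combination_removed_exactly(self, still_motion):
        fd = pp.compute_fd(still_motion)
        nuis = pp.build_nuisance(still_motion, fd)
        rng = np.random.default_rng(2)
        coef = rng.standard_normal(nuis.n_columns)
        series = nuis.design @ coef
        data = np.tile(series[:, None, None, None], (1, 3, 3, 2))
        out = pp.regress_out(Volume4D(data=data), nuis)
        assert np.abs(out.data).max() < 1e-8

    def test_intercept_only_mean_centres(self, tiny_vol):
        from hippomediate.types import NuisanceMatrix

        nuis = NuisanceMatrix(design=np.ones((tiny_vol.n_volumes, 1)), labels=["intercept"])
        out = pp.regress_out(tiny_vol, nuis)
        np.testing.assert_allclose(out.data, tiny_vol.data - tiny_vol.data.mean(0), atol=1e-12)

    def test_residuals_orthogonal_to_design(self, tiny_vol, still_motion):
        fd = np.zeros(40)
        fd[15] = 0.8
        cc = np.random.default_rng(5).standard_normal((40, 3))
        nuis = pp.build_nuisance(still_motion, fd, compcor_cols=cc)
        out = pp.regress_out(tiny_vol, nuis)
        ts = out.timeseries_matrix()
        D = nuis.design / np.linalg.norm(nuis.design, axis=0, keepdims=True).clip(1e-12)
        assert np.abs(D.T @ ts).max() < 1e-6


class TestSmoothing:
    def test_constant_image_preserved(self):
        vol = _vol(T=3, fill=2.5)
        out = pp.smooth_gaussian(vol, fwhm=4.0)
        assert np.abs(out.data - 2.5).max() < 1e-10

    def test_impulse_response_matches_sampled_gaussian(self):
        grid = (15, 15, 9)
        data = np.zeros((1,) + grid)
        c = (7, 7, 4)
        data[0][c] = 1.0
        vol = Volume4D(data=data, voxel_size=(3.0, 3.0, 4.5))
        out = pp.smooth_gaussian(vol, fwhm=4.0)
        # independent oracle: separable normalized sampled-Gaussian kernel
        sig = [4.0 / (2 * np.sqrt(2 * np.log(2))) / v for v in (3.0, 3.0, 4.5)]
        kernels = []
        for s in sig:
            r = int(4.0 * s + 0.5)
            k = np.exp(-0.5 * (np.arange(-r, r + 1) / s) ** 2)
            kernels.append(k / k.sum())
        expected = np.zeros(grid)
        for i, ki in enumerate(kernels[0], start=c[0] - (len(kernels[0]) // 2)):
            for j, kj in enumerate(kernels[1], start=c[1] - (len(kernels[1]) // 2)):
                for k, kk in enumerate(kernels[2], start=c[2] - (len(kernels[2]) // 2)):
                    if 0 <= i < grid[0] and 0 <= j < grid[1] and 0 <= k < grid[2]:
                        expected[i, j, k] = ki * kj * kk
        interior = np.s_[3:-3, 3:-3, 2:-2]
        np.testing.assert_allclose(out.data[0][interior], expected[interior], atol=1e-6)

    def test_zero_fwhm_is_identity(self, tiny_vol):
        out = pp.smooth_gaussian(tiny_vol, fwhm=0.0)
        np.testing.assert_array_equal(out.data, tiny_vol.data)


class TestBandpass:
    def _sine_vol(self, freq, T=196, tr=2.0):
        t = np.arange(T) * tr
        series = np.sin(2 * np.pi * freq * t)
        data = np.tile(series[:, None, None, None], (1, 2, 2, 1))
        return Volume4D(data=data, tr=tr)

    def test_in_band_sinusoid_retained(self):
        vol = self._sine_vol(0.05)
        out = pp.bandpass(vol)
        assert (out.data**2).sum() >= 0.90 * (vol.data**2).sum()

    def test_out_of_band_sinusoid_rejected(self):
        vol = self._sine_vol(0.005)
        out = pp.bandpass(vol)
        assert (out.data**2).sum() <= 0.10 * (vol.data**2).sum()

    def test_constant_series_zeroed(self):
        vol = _vol(T=50, fill=3.0)
        out = pp.bandpass(vol)
        assert np.abs(out.data).max() < 1e-10

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass(_vol(T=50), lo=0.01, hi=0.3)  # Nyquist is 0.25 at TR=2

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(alpha=st.floats(-3, 3), beta=st.floats(-3, 3), seed=st.integers(0, 100))
    def test_linearity(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal(60)
        w = rng.standard_normal(60)
        lhs = pp.bandpass_series(alpha * u + beta * w, tr=2.0)
        rhs = alpha * pp.bandpass_series(u, tr=2.0) + beta * pp.bandpass_series(w, tr=2.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


def test_band_variance_fraction_matches_empirical():
    rng = np.random.default_rng(0)
    T, tr = 196, 2.0
    noise = rng.standard_normal((T, 2000))
    out = pp.bandpass_series(noise, tr)
    frac = (out**2).sum() / (noise**2).sum()
    assert frac == pytest.approx(pp.band_variance_fraction(T, tr), abs=0.01)
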