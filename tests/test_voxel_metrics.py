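"""Sample entropy, ICC, map normalisation, smoothing, overlap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consdyn import (
    SampEnConfig,
    VolumeSeries,
    VoxelMap,
    binarize_and_overlap,
    icc_map,
    normalize_zscore_map,
    sampen_map,
    sample_entropy,
    smooth_map_gaussian,
)


def sampen_bruteforce(x, m, r_factor):
    """O(T^2) double-loop template-pair oracle (closed tolerance, pop. SD)."""
    x = np.asarray(x, float)
    t = x.size
    r = r_factor * x.std(ddof=0)
    n_templ = t - m
    a = b = 0
    for i in range(n_templ):
        for j in range(i + 1, n_templ):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    return a, b


class TestSampleEntropy:
    def test_constant_series_is_exactly_zero(self):
        res = sample_entropy(np.ones(100), SampEnConfig(m=3))
        assert res.value == 0.0
        assert res.n_matches_m == res.n_matches_m_plus_1 > 0

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy(np.arange(4.0), SampEnConfig(m=3))

    def test_ramp_matches_bruteforce_exactly(self):
        x = np.arange(1.0, 11.0)
        cfg = SampEnConfig(m=2, r_factor=0.6)
        res = sample_entropy(x, cfg)
        a, b = sampen_bruteforce(x, 2, 0.6)
        assert (res.n_matches_m_plus_1, res.n_matches_m) == (a, b)
        assert res.value == -math.log(a / b)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_series_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(40)
        cfg = SampEnConfig(m=3, r_factor=0.6)
        res = sample_entropy(x, cfg)
        a, b = sampen_bruteforce(x, 3, 0.6)
        assert (res.n_matches_m_plus_1, res.n_matches_m) == (a, b)

    def test_undefined_sentinel_distinguishable_from_zero(self):
        # strictly increasing with huge steps: no matches at tiny r
        x = np.array([1.0, 10.0, 100.0, 1000.0, 10000.0, 100000.0])
        res = sample_entropy(x, SampEnConfig(m=2, r_factor=1e-6))
        assert not res.is_defined
        assert math.isnan(res.value)

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    @settings(deadline=None, max_examples=25)
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(60)
        r1 = sample_entropy(x)
        r2 = sample_entropy(scale * x + shift)
        assert (r2.n_matches_m, r2.n_matches_m_plus_1) == (r1.n_matches_m, r1.n_matches_m_plus_1)

    def test_match_counts_nondecreasing_in_r(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(80)
        prev_b = -1
        for rf in (0.2, 0.4, 0.6, 1.0, 2.0):
            res = sample_entropy(x, SampEnConfig(m=2, r_factor=rf))
            assert res.n_matches_m >= prev_b
            prev_b = res.n_matches_m


class TestSampEnMap:
    def test_noise_region_exceeds_sinusoid_region(self):
        rng = np.random.default_rng(0)
        t = np.arange(120)
        data = np.zeros((2, 2, 1, 120))
        data[0, :, 0] = rng.standard_normal((2, 120))
        data[1, :, 0] = np.sin(2 * np.pi * t / 60) + 0.01 * rng.standard_normal((2, 120))
        vol = VolumeSeries(data, np.ones((2, 2, 1), bool))
        m = sampen_map(vol)
        assert m.data[0, :, 0].mean() > m.data[1, :, 0].mean()

    def test_constant_volume_all_zero(self):
        vol = VolumeSeries(np.ones((2, 2, 1, 30)), np.ones((2, 2, 1), bool))
        m = sampen_map(vol)
        assert np.all(m.data[m.mask] == 0.0)

    def test_equals_voxelwise_application(self, rng):
        vol = VolumeSeries(rng.standard_normal((3, 2, 2, 40)), np.ones((3, 2, 2), bool))
        m = sampen_map(vol)
        for idx in np.argwhere(vol.mask):
            expected = sample_entropy(vol.data[tuple(idx)]).value
            assert m.data[tuple(idx)] == expected


class TestIccMap:
    def test_orthogonal_and_identical_voxels(self):
        t = np.arange(40, dtype=float)
        s1 = np.sin(2 * np.pi * t / 10)
        s2 = 2.0 * s1 + 1.0  # r = 1 with s1
        s3 = np.cos(2 * np.pi * t / 10)  # r = 0 with s1 over whole periods
        data = np.stack([s1, s2, s3])[:, None, None, :]
        vol = VolumeSeries(data, np.ones((3, 1, 1), bool))
        m = icc_map(vol)
        assert m.data[0, 0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_identical_series_give_v_minus_one(self, rng):
        base = rng.standard_normal(30)
        data = np.tile(base, (4, 1))[:, None, None, :]
        vol = VolumeSeries(data, np.ones((4, 1, 1), bool))
        m = icc_map(vol)
        np.testing.assert_allclose(m.values(), 3.0, atol=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        vol = VolumeSeries(rng.standard_normal((4, 4, 4, 60)), np.ones((4, 4, 4), bool))
        m = icc_map(vol)
        series = vol.data.reshape(-1, 60)
        for v in range(0, 64, 7):  # subsample voxels for speed
            icc = sum(
                np.corrcoef(series[v], series[u])[0, 1] ** 2 for u in range(64) if u != v
            )
            assert m.data.reshape(-1)[v] == pytest.approx(icc, abs=1e-10)

    def test_per_voxel_rescale_invariance(self, rng):
        data = rng.standard_normal((3, 1, 1, 30))
        vol = VolumeSeries(data, np.ones((3, 1, 1), bool))
        scaled = VolumeSeries(data * np.array([2.0, -3.0, 0.5])[:, None, None, None],
                              vol.mask)
        np.testing.assert_allclose(icc_map(vol).values(), icc_map(scaled).values(), atol=1e-10)


class TestNormalizeAndSmooth:
    def test_zscore_mean_zero_sd_one(self, rng):
        vmap = VoxelMap(rng.standard_normal((4, 4, 4)), np.ones((4, 4, 4), bool), kind="icc_raw")
        z = normalize_zscore_map(vmap)
        assert z.values().mean() == pytest.approx(0.0, abs=1e-12)
        assert z.values().std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_map_all_zero(self):
        vmap = VoxelMap(np.full((2, 2, 2), 7.0), np.ones((2, 2, 2), bool))
        assert np.all(normalize_zscore_map(vmap).values() == 0)

    def test_hand_zscore_three_values(self):
        vmap = VoxelMap(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1), np.ones((3, 1, 1), bool))
        z = normalize_zscore_map(vmap)
        sd = math.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(z.values(), (np.array([1, 2, 3]) - 2) / sd)

    def test_smoothing_identity_and_constancy(self, rng):
        vmap = VoxelMap(rng.standard_normal((5, 5, 5)), np.ones((5, 5, 5), bool))
        np.testing.assert_array_equal(smooth_map_gaussian(vmap, 0.0).data, vmap.data)
        const = VoxelMap(np.full((5, 5, 5), 3.0), np.ones((5, 5, 5), bool))
        np.testing.assert_allclose(smooth_map_gaussian(const, 10.0).values(), 3.0)

    def test_impulse_profile_matches_analytic_gaussian(self):
        grid = (41, 41, 41)
        data = np.zeros(grid)
        data[20, 20, 20] = 1.0
        vmap = VoxelMap(data, np.ones(grid, bool), voxel_size_mm=(2.0, 2.0, 2.0))
        sm = smooth_map_gaussian(vmap, 10.0)
        sigma_vox = 10.0 / (2 * math.sqrt(2 * math.log(2))) / 2.0
        x = np.arange(41) - 20
        prof = sm.data[:, 20, 20]
        analytic = np.exp(-(x**2) / (2 * sigma_vox**2))
        analytic /= analytic.sum() * (prof[20] / analytic[20]) ** 0  # shape comparison
        ratio = prof / prof.max()
        expected = analytic / analytic.max()
        np.testing.assert_allclose(ratio[15:26], expected[15:26], rtol=0.01)


class TestOverlap:
    def test_idempotence_and_disjoint(self):
        grid = (3, 3, 1)
        m1 = np.zeros(grid)
        m1[0] = 1
        m2 = np.zeros(grid)
        m2[1] = 1
        mask = np.ones(grid, bool)
        a = VoxelMap(m1, mask, kind="mask")
        same = binarize_and_overlap([a, a], [0.5, 0.5])
        np.testing.assert_array_equal(same.mask, m1 > 0.5)
        empty = binarize_and_overlap([a, VoxelMap(m2, mask, kind="mask")], [0.5, 0.5])
        assert not empty.mask.any()

    def test_four_way_equals_and_of_masks(self, rng):
        grid = (4, 4, 2)
        mask = np.ones(grid, bool)
        maps = [VoxelMap(rng.random(grid), mask) for _ in range(4)]
        thr = [0.3, 0.5, 0.4, 0.6]
        overlap = binarize_and_overlap(maps, thr)
        expected = np.ones(grid, bool)
        for m, t in zip(maps, thr):
            expected &= m.data >= t
        np.testing.assert_array_equal(overlap.mask, expected)

    def test_grid_mismatch_errors(self, rng):
        a = VoxelMap(rng.random((2, 2, 2)), np.ones((2, 2, 2), bool))
        b = VoxelMap(rng.random((3, 2, 2)), np.ones((3, 2, 2), bool))
        with pytest.raises(ValueError, match="grid"):
            binarize_and_overlap([a, b], [0.5, 0.5])
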