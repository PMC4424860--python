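import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import icsift as ic
from icsift.clusters import find_clusters
from icsift.features import (
    DEGENERATE_BBOX_RATIO,
    andrews_projection,
    apply_conditioning,
    extract_features,
    feat_bbox_voxel_ratio,
    feat_freq_ratio,
    feat_gm_pos_overlap,
    feat_lag1_autocorr,
    feat_peak_in_gm,
    fit_conditioning,
)


GRID = ic.VolumeGrid.isotropic((6, 6, 6), 3.0)


def _mask(*voxels):
    member = np.zeros(GRID.dims, dtype=bool)
    for v in voxels:
        member[v] = True
    return ic.BinaryMask(GRID, member)


class TestGmPosOverlap:
    def test_all_inside_gm(self):
        values = np.zeros(GRID.dims)
        values[1, 1, 1] = values[2, 2, 2] = 5.0
        supra = _mask((1, 1, 1), (2, 2, 2))
        gm = _mask((1, 1, 1), (2, 2, 2), (3, 3, 3))
        assert feat_gm_pos_overlap(ic.StatMap(GRID, values), supra, gm) == 1.0

    def test_all_outside_gm(self):
        values = np.zeros(GRID.dims)
        values[1, 1, 1] = 5.0
        assert feat_gm_pos_overlap(ic.StatMap(GRID, values), _mask((1, 1, 1)), _mask((0, 0, 0))) == 0.0

    def test_equal_voxels_half_inside(self):
        values = np.zeros(GRID.dims)
        values[1, 1, 1] = values[2, 2, 2] = 4.0
        result = feat_gm_pos_overlap(
            ic.StatMap(GRID, values), _mask((1, 1, 1), (2, 2, 2)), _mask((1, 1, 1))
        )
        assert result == pytest.approx(0.5)

    def test_empty_mask_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert feat_gm_pos_overlap(ic.StatMap(GRID, np.zeros(GRID.dims)), _mask(), _mask((0, 0, 0))) == 0.0


class TestPeakInGm:
    def test_single_voxel_inside(self):
        values = np.zeros(GRID.dims)
        values[2, 2, 2] = 5.0
        assert feat_peak_in_gm(ic.StatMap(GRID, values), _mask((2, 2, 2)), _mask((2, 2, 2))) == 1.0

    def test_peak_outside_with_lesser_inside(self):
        values = np.zeros(GRID.dims)
        values[0, 0, 0] = 9.0
        values[2, 2, 2] = 5.0
        supra = _mask((0, 0, 0), (2, 2, 2))
        assert feat_peak_in_gm(ic.StatMap(GRID, values), supra, _mask((2, 2, 2))) == 0.0

    def test_tie_broken_by_lowest_linear_index(self):
        # equal peaks at (1,1,1) and (3,3,3); the lower raster index wins,
        # verified against an exhaustive scan
        values = np.zeros(GRID.dims)
        values[1, 1, 1] = values[3, 3, 3] = 6.0
        supra = _mask((1, 1, 1), (3, 3, 3))
        flat = values.ravel()
        supra_idx = np.flatnonzero(supra.membership.ravel())
        expected_peak = min(
            (i for i in supra_idx if flat[i] == flat[supra_idx].max()),
        )
        gm_at_first = _mask((1, 1, 1))
        gm_at_second = _mask((3, 3, 3))
        stat = ic.StatMap(GRID, values)
        assert np.unravel_index(expected_peak, GRID.dims) == (1, 1, 1)
        assert feat_peak_in_gm(stat, supra, gm_at_first) == 1.0
        assert feat_peak_in_gm(stat, supra, gm_at_second) == 0.0


class TestFreqRatio:
    def test_slow_sinusoid_all_in_band(self):
        t = np.arange(256) * 2.0
        tc = ic.ICTimeCourse(np.sin(2 * np.pi * 0.02 * t), tr=2.0)
        assert feat_freq_ratio(tc, (0.01, 0.08)) > 0.99

    def test_fast_sinusoid_out_of_band(self):
        t = np.arange(256) * 2.0
        tc = ic.ICTimeCourse(np.sin(2 * np.pi * 0.20 * t), tr=2.0)
        assert feat_freq_ratio(tc, (0.01, 0.08)) < 0.01

    def test_white_noise_matches_band_fraction(self):
        # flat spectrum: expected ratio = (0.08 - 0.01) / 0.25 = 0.28
        ratios = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tc = ic.ICTimeCourse(rng.standard_normal(4096), tr=2.0)
            ratios.append(feat_freq_ratio(tc, (0.01, 0.08)))
        assert np.mean(ratios) == pytest.approx(0.28, abs=0.05)

    def test_constant_series_warns_zero(self):
        with pytest.warns(UserWarning):
            assert feat_freq_ratio(ic.ICTimeCourse(np.ones(64), 2.0)) == 0.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            feat_freq_ratio(ic.ICTimeCourse(np.random.default_rng(0).standard_normal(64), 2.0), (0.01, 0.3))


class TestLag1Autocorr:
    def test_alternating_series(self):
        tc = ic.ICTimeCourse(np.tile([1.0, -1.0], 50), tr=1.0)
        assert feat_lag1_autocorr(tc) == pytest.approx(-1.0, abs=1e-9)

    def test_slow_sinusoid_is_smooth(self):
        t = np.arange(200) * 2.0
        tc = ic.ICTimeCourse(np.sin(2 * np.pi * 0.01 * t), tr=2.0)
        assert feat_lag1_autocorr(tc) > 0.9

    def test_ar1_recovers_population_coefficient(self):
        rng = np.random.default_rng(12)
        phi, n = 0.6, 10000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        assert feat_lag1_autocorr(ic.ICTimeCourse(x, 1.0)) == pytest.approx(phi, abs=0.03)

    def test_constant_series_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            feat_lag1_autocorr(ic.ICTimeCourse(np.full(32, 3.0), 1.0))


def _clusters_from(*blocks):
    member = np.zeros((10, 10, 10), dtype=bool)
    for block in blocks:
        member[block] = True
    grid = ic.VolumeGrid.isotropic((10, 10, 10), 3.0)
    return find_clusters(ic.BinaryMask(grid, member))


class TestBboxVoxelRatio:
    def test_solid_block_is_one(self):
        clusters = _clusters_from((slice(0, 2), slice(0, 3), slice(0, 4)))
        assert feat_bbox_voxel_ratio(clusters) == pytest.approx(1.0)

    def test_body_diagonal_line(self):
        member = np.zeros((10, 10, 10), dtype=bool)
        for i in range(3):
            member[i, i, i] = True
        grid = ic.VolumeGrid.isotropic((10, 10, 10), 3.0)
        clusters = find_clusters(ic.BinaryMask(grid, member), connectivity=26)
        assert feat_bbox_voxel_ratio(clusters) == pytest.approx(9.0)

    def test_size_weighted_mixture(self):
        # solid 2x2x2 cube (ratio 1) + 3-voxel diagonal (ratio 9):
        # (8*1 + 3*9) / 11 = 35/11
        member = np.zeros((10, 10, 10), dtype=bool)
        member[0:2, 0:2, 0:2] = True
        for i in range(3):
            member[5 + i, 5 + i, 5 + i] = True
        grid = ic.VolumeGrid.isotropic((10, 10, 10), 3.0)
        clusters = find_clusters(ic.BinaryMask(grid, member), connectivity=26)
        assert feat_bbox_voxel_ratio(clusters) == pytest.approx(35 / 11)

    def test_empty_list_degenerate_default(self):
        with pytest.warns(UserWarning):
            assert feat_bbox_voxel_ratio([]) == DEGENERATE_BBOX_RATIO


class TestConditioning:
    def test_two_point_hand_example(self):
        vecs = [
            ic.FeatureVector(0.0, 0.0, 0.0, 0.0, 1.0),
            ic.FeatureVector(2.0, 1.0, 0.5, 0.5, 3.0),
        ]
        stats = fit_conditioning(vecs)
        z0 = apply_conditioning(vecs[0], stats)
        z1 = apply_conditioning(vecs[1], stats)
        assert z0.gm_pos_overlap == pytest.approx(-1 / np.sqrt(2))
        assert z1.gm_pos_overlap == pytest.approx(+1 / np.sqrt(2))

    def test_training_set_centred_and_scaled(self):
        rng = np.random.default_rng(8)
        mat = rng.random((40, 5)) * [1, 1, 1, 2, 10]
        stats = fit_conditioning(mat)
        z = stats.transform(mat)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_single_vector_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_conditioning([ic.FeatureVector(0, 0, 0, 0, 1)])

    def test_zero_variance_names_feature(self):
        mat = np.ones((5, 5))
        mat[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="peak_in_gm"):
            fit_conditioning(mat)

    def test_double_conditioning_rejected(self):
        vecs = [ic.FeatureVector(0, 0, 0, 0, 1), ic.FeatureVector(1, 1, 1, 1, 2)]
        stats = fit_conditioning(vecs)
        z = apply_conditioning(vecs[0], stats)
        with pytest.raises(ValueError, match="already conditioned"):
            apply_conditioning(z, stats)


class TestAndrewsProjection:
    def test_zero_vector_is_zero_curve(self):
        for t in np.linspace(-np.pi, np.pi, 9):
            assert andrews_projection(np.zeros(5), t) == 0.0

    def test_basis_vector_at_right_angle(self):
        assert andrews_projection(np.array([1, 0, 0, 0, 0.0]), np.pi / 2) == pytest.approx(1.0)

    def test_ones_vector_at_origin(self):
        assert andrews_projection(np.ones(5), 0.0) == pytest.approx(2.0)

    @given(st.lists(st.floats(-5, 5), min_size=5, max_size=5),
           st.lists(st.floats(-5, 5), min_size=5, max_size=5),
           st.floats(-np.pi, np.pi))
    def test_linearity_in_the_feature_vector(self, a, b, t):
        a, b = np.array(a), np.array(b)
        total = andrews_projection(a + b, t)
        assert total == pytest.approx(andrews_projection(a, t) + andrews_projection(b, t), abs=1e-9)


class TestExtractFeatures:
    def test_rfn_component_margins(self, small_cfg, templates, gm):
        comp = ic.make_rfn_component(small_cfg, templates, seed=17)
        fv = extract_features(comp, gm)
        assert fv.gm_pos_overlap > 0.9
        assert fv.peak_in_gm == 1.0
        assert fv.freq_ratio > 0.8
        assert not fv.degenerate

    def test_rim_artifact_margins(self, small_cfg, templates, gm):
        comp = ic.make_artifact_component(small_cfg, templates, "rim", seed=17)
        fv = extract_features(comp, gm)
        assert fv.gm_pos_overlap < 0.3
        assert fv.bbox_voxel_ratio > 3.0

    def test_degenerate_component_flagged(self, small_cfg, gm):
        rng = np.random.default_rng(0)
        noise_only = ic.Component(
            0,
            ic.StatMap(small_cfg.grid, 0.5 * rng.standard_normal(small_cfg.dims)),
            ic.ICTimeCourse(rng.standard_normal(small_cfg.n_timepoints), small_cfg.tr),
        )
        fv = extract_features(noise_only, gm)
        assert fv.degenerate
        assert fv.gm_pos_overlap == 0.0
        assert fv.peak_in_gm == 0.0
        assert fv.bbox_voxel_ratio == DEGENERATE_BBOX_RATIO

    def test_extraction_is_deterministic(self, small_cfg, templates, gm):
        comp = ic.make_rfn_component(small_cfg, templates, seed=4)
        a = extract_features(comp, gm).to_array()
        b = extract_features(comp, gm).to_array()
        np.testing.assert_array_equal(a, b)

    def test_raw_ranges_on_random_components(self, small_cfg, templates, gm):
        styles = ("rim", "ventricle", "spike", "highfreq")
        for seed in range(60):
            if seed % 2:
                comp = ic.make_rfn_component(small_cfg, templates, seed=seed)
            else:
                comp = ic.make_artifact_component(
                    small_cfg, templates, styles[seed % 4], seed=seed
                )
            fv = extract_features(comp, gm)
            assert 0.0 <= fv.gm_pos_overlap <= 1.0
            assert fv.peak_in_gm in (0.0, 1.0)
            assert 0.0 <= fv.freq_ratio <= 1.0
            assert -1.0 <= fv.lag1_autocorr <= 1.0
            assert fv.bbox_voxel_ratio >= 1.0
            assert np.all(np.isfinite(fv.to_array()))

    def test_class_conditional_separation(self, small_set, gm):
        ica_set, labels = small_set
        table = ic.extract_feature_table(ica_set, gm)
        is_rfn = np.array([labels[i] == ic.RFN for i in table.index])
        gm_margin = table["gm_pos_overlap"][is_rfn].mean() - table["gm_pos_overlap"][~is_rfn].mean()
        fr_margin = table["freq_ratio"][is_rfn].mean() - table["freq_ratio"][~is_rfn].mean()
        assert gm_margin > 0.5
        assert fr_margin > 0.3
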