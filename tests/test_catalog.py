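import numpy as np
import pytest

import oracles
from habrad import texture
from habrad.catalog import (ExtractionConfig, apply_log_filter, build_catalog,
                            build_feature_table, category_names,
                            extract_region_features, filtered_stack,
                            wavelet_subbands)
from habrad.habitats import HabitatMap
from habrad.imaging import Mask, Volume
from habrad.phantom import PhantomSubject, PhantomTruth


class TestCatalogEnumeration:
    def test_total_and_per_class_counts_match_printed_decomposition(self):
        cat = build_catalog()
        assert len(cat) == 1197
        assert cat.count("firstorder") == 234
        assert cat.count("glcm") == 286
        assert cat.count("gldm") == 182
        assert cat.count("glrlm") == 208
        assert cat.count("glszm") == 208
        assert cat.count("ngtdm") == 65
        assert cat.count("shape") == 14

    def test_shape_attaches_to_original_filter_only(self):
        cat = build_catalog()
        assert all(f == "original" for f, c, _ in cat.entries if c == "shape")

    def test_entry_order_is_deterministic(self):
        assert build_catalog().entries == build_catalog().entries

    def test_column_count_formula_for_all_k(self):
        cat = build_catalog()
        for k in range(1, 11):
            assert len(category_names(k)) * len(cat) == 1197 * (2 * k + 2)


class TestLoGFilter:
    def test_constant_volume_gives_zero_response(self):
        vol = Volume(np.full((16, 16, 16), 7.0), (1, 1, 1))
        out = apply_log_filter(vol, 2.0)
        inner = (slice(4, -4),) * 3
        assert np.max(np.abs(out.values[inner])) < 1e-8

    def test_impulse_response_matches_analytic_log_kernel(self):
        shape = (21, 21, 21)
        vals = np.zeros(shape)
        vals[10, 10, 10] = 1.0
        sigma = 2.0
        out = apply_log_filter(Volume(vals, (1, 1, 1)), sigma)
        xx, yy, zz = np.meshgrid(*[np.arange(n) - 10.0 for n in shape],
                                 indexing="ij")
        r2 = xx ** 2 + yy ** 2 + zz ** 2
        g = np.exp(-r2 / (2 * sigma ** 2)) / (2 * np.pi * sigma ** 2) ** 1.5
        analytic = g * (r2 - 3 * sigma ** 2) / sigma ** 4
        inner = (slice(4, -4),) * 3
        np.testing.assert_allclose(out.values[inner], analytic[inner],
                                   atol=1e-6)

    def test_linearity(self, rng):
        a = rng.random((12, 12, 12))
        b = rng.random((12, 12, 12))
        la = apply_log_filter(Volume(a, (1, 1, 1)), 2.0).values
        lb = apply_log_filter(Volume(b, (1, 1, 1)), 2.0).values
        lab = apply_log_filter(Volume(2 * a + 3 * b, (1, 1, 1)), 2.0).values
        np.testing.assert_allclose(lab, 2 * la + 3 * lb, atol=1e-10)

    def test_sub_voxel_sigma_warns(self):
        vol = Volume(np.zeros((8, 8, 8)), (1.0, 1.0, 6.0))
        with pytest.warns(RuntimeWarning, match="aliased"):
            apply_log_filter(vol, 2.0)


class TestWaveletSubbands:
    def test_eight_subbands_with_fixed_names(self, rng):
        vol = Volume(rng.random((8, 8, 8)), (1, 1, 1))
        bands = wavelet_subbands(vol)
        assert list(bands) == ["LLL", "LLH", "LHL", "LHH",
                               "HLL", "HLH", "HHL", "HHH"]
        for b in bands.values():
            assert b.values.shape == (8, 8, 8)

    def test_constant_volume_lands_in_lll_only(self):
        vol = Volume(np.full((8, 8, 8), 5.0), (1, 1, 1))
        bands = wavelet_subbands(vol)
        for name, b in bands.items():
            if "H" in name:
                assert np.max(np.abs(b.values)) < 1e-10, name
            else:
                assert np.allclose(b.values, b.values.flat[0])
                assert abs(b.values.flat[0]) > 1.0  # scaled constant

    def test_subbands_match_direct_separable_circular_convolution(self, rng):
        import pywt

        x = rng.random((8, 8, 8))
        bands = wavelet_subbands(Volume(x, (1, 1, 1)), "coif1")
        w = pywt.Wavelet("coif1")
        lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)

        def circ_filter(arr, taps, axis):
            n = arr.shape[axis]
            out = np.zeros_like(arr)
            arr = np.moveaxis(arr, axis, 0)
            res = np.moveaxis(out, axis, 0)
            for shift, t in enumerate(taps[::-1]):
                res += t * np.roll(arr, shift - (len(taps) - 1), axis=0)
            return np.moveaxis(res, 0, axis)

        for name, vol in bands.items():
            ref = x.copy()
            for axis, ch in enumerate(name):
                ref = circ_filter(ref, lo if ch == "L" else hi, axis)
            # periodised SWT agrees with circular convolution up to an
            # index roll; compare the energy, which is roll-invariant
            assert np.sum(vol.values ** 2) == pytest.approx(
                np.sum(ref ** 2), rel=1e-8), name


@pytest.fixture(scope="module")
def region_fixture():
    rng = np.random.default_rng(99)
    vals = rng.random((6, 6, 6)) * 40 + 80
    region = rng.random((6, 6, 6)) < 0.7
    region[3, 3, 3] = True
    return vals, region


class TestRegionFeaturesAgainstOracles:

    def test_first_order_on_four_listed_values(self):
        fo = texture.first_order_features(np.array([1.0, 2.0, 3.0, 4.0]), 1.0)
        assert fo["Mean"] == pytest.approx(2.5)
        assert fo["Range"] == pytest.approx(3.0)
        assert fo["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))
        assert fo["Energy"] == pytest.approx(30.0)
        assert fo["Median"] == pytest.approx(2.5)

    def test_constant_region_conventions(self):
        fo = texture.first_order_features(np.full(20, -3.0), 1.0)
        assert fo["Range"] == 0.0
        assert fo["Variance"] == 0.0
        assert fo["Kurtosis"] == 0.0
        assert fo["Skewness"] == 0.0
        assert fo["RootMeanSquared"] == pytest.approx(3.0)
        assert fo["Uniformity"] == pytest.approx(1.0)

    def test_first_order_moments_match_direct_formulas(self, region_fixture):
        vals, region = region_fixture
        x = vals[region]
        fo = texture.first_order_features(x, 2.0)
        assert fo["Skewness"] == pytest.approx(
            np.mean((x - x.mean()) ** 3) / np.var(x) ** 1.5, abs=1e-12)
        assert fo["Kurtosis"] == pytest.approx(
            np.mean((x - x.mean()) ** 4) / np.var(x) ** 2 - 3, abs=1e-12)
        assert fo["TotalEnergy"] == pytest.approx(2.0 * (x ** 2).sum())
        assert fo["MeanAbsoluteDeviation"] == pytest.approx(
            np.abs(x - x.mean()).mean(), abs=1e-12)

    @pytest.mark.parametrize("n_levels", [4, 6])
    def test_matrices_equal_nested_loop_enumeration(self, region_fixture,
                                                    n_levels):
        vals, region = region_fixture
        lev = np.zeros(region.shape, dtype=np.int64)
        lev[region] = texture.discretize(vals[region], n_levels)
        np.testing.assert_allclose(
            texture.glcm_matrix(lev, n_levels),
            oracles.glcm_matrix(lev, n_levels))
        np.testing.assert_allclose(
            texture.glrlm_matrix(lev, n_levels),
            oracles.glrlm_matrix(lev, n_levels))
        np.testing.assert_allclose(
            texture.glszm_matrix(lev, n_levels)[:, :region.sum()],
            oracles.glszm_matrix(lev, n_levels))
        np.testing.assert_allclose(
            texture.gldm_matrix(lev, n_levels, alpha=0),
            oracles.gldm_matrix(lev, n_levels, alpha=0))
        for mine, ref in zip(texture.ngtdm_table(lev, n_levels),
                             oracles.ngtdm_table(lev, n_levels)):
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_feature_values_follow_their_formulas(self, region_fixture):
        vals, region = region_fixture
        n_levels = 5
        lev = np.zeros(region.shape, dtype=np.int64)
        lev[region] = texture.discretize(vals[region], n_levels)
        n_vox = int(region.sum())

        mat = oracles.glcm_matrix(lev, n_levels)
        p = mat / mat.sum()
        i = np.arange(1, n_levels + 1)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        glcm = texture.glcm_features(texture.glcm_matrix(lev, n_levels))
        assert glcm["Contrast"] == pytest.approx(
            ((ii - jj) ** 2 * p).sum(), abs=1e-12)
        assert glcm["MaximumProbability"] == pytest.approx(p.max())
        mu = (ii * p).sum()
        sig2 = ((i - mu) ** 2 * p.sum(axis=1)).sum()
        assert glcm["Correlation"] == pytest.approx(
            (((ii - mu) * (jj - mu) * p).sum()) / sig2, abs=1e-12)

        rmat = oracles.glrlm_matrix(lev, n_levels)
        glrlm = texture.glrlm_features(texture.glrlm_matrix(lev, n_levels),
                                       n_vox)
        lengths = np.arange(1, rmat.shape[1] + 1)
        levels = np.arange(1, n_levels + 1)[:, None]
        assert glrlm["LongRunLowGrayLevelEmphasis"] == pytest.approx(
            (rmat * lengths ** 2 / levels ** 2).sum() / rmat.sum(), abs=1e-12)
        assert glrlm["RunPercentage"] == pytest.approx(
            rmat.sum() / (n_vox * 13), abs=1e-12)

        zmat = oracles.glszm_matrix(lev, n_levels)
        glszm = texture.glszm_features(
            texture.glszm_matrix(lev, n_levels), n_vox)
        sizes = np.arange(1, zmat.shape[1] + 1)
        assert glszm["SmallAreaHighGrayLevelEmphasis"] == pytest.approx(
            (zmat * levels ** 2 / sizes ** 2).sum() / zmat.sum(), abs=1e-12)

        dmat = oracles.gldm_matrix(lev, n_levels)
        gldm = texture.gldm_features(texture.gldm_matrix(lev, n_levels))
        deps = np.arange(1, dmat.shape[1] + 1)
        assert gldm["LargeDependenceEmphasis"] == pytest.approx(
            (dmat * deps ** 2).sum() / dmat.sum(), abs=1e-12)


class TestShapeFeatures:
    def test_cuboid_volume_and_surface(self):
        region = np.zeros((10, 10, 10), dtype=bool)
        region[2:6, 2:8, 2:5] = True  # 4 x 6 x 3 cuboid
        shp = texture.shape_features(region, (1.0, 1.0, 1.0))
        assert shp["VoxelVolume"] == pytest.approx(4 * 6 * 3)
        # marching-cubes isosurface of a voxelized cuboid sits half a voxel
        # out: compare against the bounding box of voxel centres +- 0.5
        assert shp["MeshVolume"] == pytest.approx(4 * 6 * 3, rel=0.35)
        assert shp["SurfaceArea"] > 0
        assert shp["Sphericity"] < 1.0
        assert shp["SurfaceVolumeRatio"] == pytest.approx(
            shp["SurfaceArea"] / shp["MeshVolume"])

    def test_axis_lengths_match_pca_oracle(self):
        region = np.zeros((12, 12, 12), dtype=bool)
        region[2:10, 3:7, 5:7] = True
        spacing = (1.0, 1.0, 1.0)
        shp = texture.shape_features(region, spacing)
        coords = np.argwhere(region).astype(float)
        cov = np.cov(coords.T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert shp["MajorAxisLength"] == pytest.approx(4 * np.sqrt(eig[0]))
        assert shp["LeastAxisLength"] == pytest.approx(4 * np.sqrt(eig[2]))
        assert shp["Elongation"] == pytest.approx(np.sqrt(eig[1] / eig[0]))
        assert shp["Flatness"] == pytest.approx(np.sqrt(eig[2] / eig[0]))

    def test_max_diameters_on_axis_aligned_box(self):
        region = np.zeros((10, 10, 10), dtype=bool)
        region[1:7, 2:5, 3:5] = True  # extents 6, 3, 2 along axes 0, 1, 2
        shp = texture.shape_features(region, (1.0, 1.0, 1.0))
        assert shp["Maximum3DDiameter"] == pytest.approx(
            np.sqrt(5 ** 2 + 2 ** 2 + 1 ** 2))
        assert shp["Maximum2DDiameterSlice"] == pytest.approx(
            np.sqrt(5 ** 2 + 2 ** 2))  # plane normal to axis 2

    def test_sphere_is_more_spherical_than_slab(self):
        xx, yy, zz = np.meshgrid(*[np.arange(16) - 7.5] * 3, indexing="ij")
        sphere = xx ** 2 + yy ** 2 + zz ** 2 <= 36
        slab = np.zeros((16, 16, 16), dtype=bool)
        slab[1:15, 1:15, 7:9] = True
        s1 = texture.shape_features(sphere, (1, 1, 1))["Sphericity"]
        s2 = texture.shape_features(slab, (1, 1, 1))["Sphericity"]
        assert s1 > s2


class TestRegionExtraction:
    def test_vector_length_and_order(self, rng):
        cat = build_catalog()
        cfg = ExtractionConfig()
        vol = Volume(rng.random((14, 14, 14)) * 50 + 50, (1, 1, 1))
        region = np.zeros((14, 14, 14), dtype=bool)
        region[3:11, 3:11, 3:11] = True
        vec = extract_region_features(filtered_stack(vol, cfg), region,
                                      (1, 1, 1), cat, cfg)
        assert vec.shape == (1197,)
        assert np.all(np.isfinite(vec))

    def test_small_region_flags_texture_missing_but_keeps_shape(self, rng):
        cat = build_catalog()
        cfg = ExtractionConfig(min_region_voxels=10)
        vol = Volume(rng.random((10, 10, 10)), (1, 1, 1))
        region = np.zeros((10, 10, 10), dtype=bool)
        region[4:6, 4:6, 4] = True  # 4 voxels
        vec = extract_region_features(filtered_stack(vol, cfg), region,
                                      (1, 1, 1), cat, cfg)
        shape_idx = [i for i, e in enumerate(cat.entries) if e[1] == "shape"]
        other_idx = [i for i, e in enumerate(cat.entries) if e[1] != "shape"]
        assert np.all(np.isfinite(vec[shape_idx]))
        assert np.all(np.isnan(vec[other_idx]))

    def test_empty_region_is_all_missing(self, rng):
        cat = build_catalog()
        cfg = ExtractionConfig()
        vol = Volume(rng.random((8, 8, 8)), (1, 1, 1))
        vec = extract_region_features(filtered_stack(vol, cfg),
                                      np.zeros((8, 8, 8), dtype=bool),
                                      (1, 1, 1), cat, cfg)
        assert np.all(np.isnan(vec))


def _tiny_subject(rng, shape=(12, 12, 10), sid="S0", cls=0):
    labels = np.zeros(shape, dtype=np.int32)
    labels[2:10, 2:10, 2:8] = 1
    mask = Mask(labels, (1, 1, 1), region_names={1: "voi"})
    t1 = Volume(rng.random(shape) * 40 + 80, (1, 1, 1), None, "T1W", sid)
    t2 = Volume(rng.random(shape) * 40 + 80, (1, 1, 1), None, "T2W", sid)
    truth = PhantomTruth(labels.copy(), cls)
    return PhantomSubject(sid, t1, t2, mask, truth)


def _tiny_habitat_map(subject, k, rng):
    fg = subject.voi_mask.foreground()
    labels = np.zeros(fg.shape, dtype=np.int32)
    labels[fg] = rng.integers(1, k + 1, size=int(fg.sum()))
    return HabitatMap(labels, k, subject.subject_id)


class TestFeatureTable:
    def test_k5_table_has_12_categories_and_14364_columns(self, rng):
        subj = _tiny_subject(rng)
        maps = {subj.subject_id: _tiny_habitat_map(subj, 5, rng)}
        cat = build_catalog()
        table = build_feature_table([subj], maps, cat, ExtractionConfig())
        assert table.n_categories == 12
        assert table.values.shape == (1, 14364)
        assert len(set(table.values.columns)) == 14364

    def test_k1_table_follows_printed_formula(self, rng):
        subj = _tiny_subject(rng)
        maps = {subj.subject_id: _tiny_habitat_map(subj, 1, rng)}
        table = build_feature_table([subj], maps, build_catalog(),
                                    ExtractionConfig())
        assert table.n_categories == 4
        assert table.values.shape[1] == 1197 * (2 * 1 + 2) == 4788

    def test_inconsistent_k_across_subjects_is_rejected(self, rng):
        s1 = _tiny_subject(rng, sid="S1")
        s2 = _tiny_subject(rng, sid="S2")
        maps = {"S1": _tiny_habitat_map(s1, 2, rng),
                "S2": _tiny_habitat_map(s2, 3, rng)}
        with pytest.raises(ValueError, match="inconsistent k"):
            build_feature_table([s1, s2], maps, build_catalog(),
                                ExtractionConfig())

    def test_missing_values_are_flagged_not_zeroed(self, rng):
        subj = _tiny_subject(rng)
        # habitat 2 gets no voxels at all -> its features must be missing
        fg = subj.voi_mask.foreground()
        labels = np.zeros(fg.shape, dtype=np.int32)
        labels[fg] = 1
        maps = {subj.subject_id: HabitatMap(labels, 2, subj.subject_id)}
        table = build_feature_table([subj], maps, build_catalog(),
                                    ExtractionConfig())
        h2_cols = [c for c in table.values.columns if c.endswith("_H2")]
        assert table.missing[h2_cols].to_numpy().all()
        h1_cols = [c for c in table.values.columns if c.endswith("_H1")]
        assert not table.missing[h1_cols].to_numpy().any()
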