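import numpy as np
import pytest

import oracles
from habrad.imaging import Mask, Volume
from habrad.voxel_features import (FEATURE_NAMES, VoxelFeatureConfig,
                                   assemble_voxel_matrix, compute_feature_maps,
                                   discretize, local_first_order, local_glcm,
                                   local_glrlm, local_glszm, local_ngtdm,
                                   matrix_column_names)


class TestDiscretize:
    def test_constant_input_maps_to_level_one(self):
        assert np.all(discretize(np.full(10, 3.3), 8) == 1)

    def test_four_values_four_levels_are_identity(self):
        np.testing.assert_array_equal(
            discretize(np.array([0.0, 1.0, 2.0, 3.0]), 4), [1, 2, 3, 4])

    def test_bin_counts_match_direct_histogram(self, rng):
        x = rng.random(1000)
        lev = discretize(x, 8)
        edges = np.linspace(x.min(), x.max(), 9)
        hist, _ = np.histogram(x, bins=edges)
        # the histogram puts the maximum in the last bin, as discretize does
        counts = np.bincount(lev, minlength=9)[1:]
        np.testing.assert_array_equal(counts, hist)


def _random_volume_and_mask(rng, shape=(7, 7, 7)):
    vals = rng.random(shape) * 50 + 50
    labels = (rng.random(shape) < 0.85).astype(int)
    labels[3, 3, 3] = 1
    return (Volume(vals, (1, 1, 1)), Mask(labels, (1, 1, 1)))


def _local_level_cube(vals, fg, center, radius, n_levels):
    """Oracle replica of the kernel's gather + local discretization."""
    box = 2 * radius + 1
    cube_vals = np.zeros((box, box, box))
    inside = np.zeros((box, box, box), dtype=bool)
    gathered = []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                p = (center[0] + dx, center[1] + dy, center[2] + dz)
                if all(0 <= c < s for c, s in zip(p, vals.shape)) and fg[p]:
                    cube_vals[dx + radius, dy + radius, dz + radius] = vals[p]
                    inside[dx + radius, dy + radius, dz + radius] = True
                    gathered.append(vals[p])
    gathered = np.asarray(gathered)
    lev = np.zeros((box, box, box), dtype=np.int64)
    lev[inside] = oracles.discretize(cube_vals[inside], n_levels)
    return lev, gathered


def _entropy_bits(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if len(p) else 0.0


@pytest.fixture(scope="module")
def fixture():
    local = np.random.default_rng(20240917)
    vol, mask = _random_volume_and_mask(local)
    cfg = VoxelFeatureConfig(neighborhood_radius_voxels=2, n_gray_levels=6)
    coords = np.argwhere(mask.foreground())
    picks = coords[local.choice(len(coords), size=15, replace=False)]
    return vol, mask, cfg, picks


class TestVoxelMapsAgainstNaiveOracles:
    """Every kernel map equals a nested-loop reference on random fixtures."""

    def test_first_order_maps(self, fixture):
        vol, mask, cfg, picks = fixture
        maps = local_first_order(vol, mask, cfg)
        for c in picks:
            lev, vals = _local_level_cube(vol.values, mask.foreground(),
                                          tuple(c), 2, cfg.n_gray_levels)
            hist = np.bincount(lev[lev > 0], minlength=cfg.n_gray_levels + 1)
            p = hist[1:] / hist[1:].sum()
            assert maps["Entropy"][tuple(c)] == pytest.approx(
                _entropy_bits(p), abs=1e-10)
            assert maps["MeanAbsoluteDeviation"][tuple(c)] == pytest.approx(
                np.abs(vals - vals.mean()).mean(), abs=1e-10)
            assert maps["Median"][tuple(c)] == pytest.approx(
                np.median(vals), abs=1e-12)

    def test_glcm_maps(self, fixture):
        vol, mask, cfg, picks = fixture
        maps = local_glcm(vol, mask, cfg)
        for c in picks:
            lev, _ = _local_level_cube(vol.values, mask.foreground(),
                                       tuple(c), 2, cfg.n_gray_levels)
            mat = oracles.glcm_matrix(lev, cfg.n_gray_levels)
            total = mat.sum()
            P = mat / total
            ng = cfg.n_gray_levels
            p_diff = np.zeros(ng)
            p_sum = np.zeros(2 * ng - 1)
            px = P.sum(axis=1)
            for i in range(ng):
                for j in range(ng):
                    p_diff[abs(i - j)] += P[i, j]
                    p_sum[i + j] += P[i, j]
            k = np.arange(ng)
            da = (k * p_diff).sum()
            expected = {
                "DifferenceAverage": da,
                "DifferenceEntropy": _entropy_bits(p_diff),
                "DifferenceVariance": ((k - da) ** 2 * p_diff).sum(),
                "JointEnergy": (P ** 2).sum(),
                "JointEntropy": _entropy_bits(P.ravel()),
                "SumEntropy": _entropy_bits(p_sum),
                "InverseVariance": (p_diff[1:] / k[1:] ** 2).sum(),
            }
            hx = _entropy_bits(px)
            outer = np.outer(px, px)
            hxy1 = -sum(P[i, j] * np.log2(outer[i, j])
                        for i in range(ng) for j in range(ng)
                        if P[i, j] > 0 and outer[i, j] > 0)
            hxy2 = _entropy_bits(outer.ravel())
            expected["Imc1"] = ((expected["JointEntropy"] - hxy1) / hx
                                if hx > 0 else 0.0)
            arg = 1 - np.exp(-2 * (hxy2 - expected["JointEntropy"]))
            expected["Imc2"] = np.sqrt(arg) if arg > 0 else 0.0
            for name, want in expected.items():
                assert maps[name][tuple(c)] == pytest.approx(
                    want, abs=1e-10), name

    def test_glrlm_maps(self, fixture):
        vol, mask, cfg, picks = fixture
        maps = local_glrlm(vol, mask, cfg)
        for c in picks:
            lev, _ = _local_level_cube(vol.values, mask.foreground(),
                                       tuple(c), 2, cfg.n_gray_levels)
            mat = oracles.glrlm_matrix(lev, cfg.n_gray_levels)
            nr = mat.sum()
            P = mat / nr
            lengths = np.arange(1, mat.shape[1] + 1)
            lre = (P * lengths ** 2).sum()
            mu = (P * lengths).sum()
            assert maps["LongRunEmphasis"][tuple(c)] == pytest.approx(
                lre, abs=1e-10)
            assert maps["RunEntropy"][tuple(c)] == pytest.approx(
                _entropy_bits(P.ravel()), abs=1e-10)
            assert maps["RunVariance"][tuple(c)] == pytest.approx(
                (P * (lengths - mu) ** 2).sum(), abs=1e-10)

    def test_glszm_maps(self, fixture):
        vol, mask, cfg, picks = fixture
        maps = local_glszm(vol, mask, cfg)
        for c in picks:
            lev, _ = _local_level_cube(vol.values, mask.foreground(),
                                       tuple(c), 2, cfg.n_gray_levels)
            zones = oracles.zones(lev)
            nz = len(zones)
            sizes = [s for _, s in zones]
            sznn = sum(sizes.count(s) ** 2 for s in set(sizes)) / nz ** 2
            sahgle = sum(g ** 2 / s ** 2 for g, s in zones) / nz
            assert maps["SizeZoneNonUniformityNormalized"][tuple(c)] == \
                pytest.approx(sznn, abs=1e-10)
            assert maps["SmallAreaHighGrayLevelEmphasis"][tuple(c)] == \
                pytest.approx(sahgle, abs=1e-10)

    def test_ngtdm_maps(self, fixture):
        vol, mask, cfg, picks = fixture
        maps = local_ngtdm(vol, mask, cfg)
        for c in picks:
            lev, _ = _local_level_cube(vol.values, mask.foreground(),
                                       tuple(c), 2, cfg.n_gray_levels)
            n_i, p_i, s_i = oracles.ngtdm_table(lev, cfg.n_gray_levels)
            nv = n_i.sum()
            present = np.flatnonzero(p_i > 0)
            ngp = len(present)
            if ngp > 1:
                contrast = sum(p_i[a] * p_i[b] * (a - b) ** 2
                               for a in present for b in present) \
                    / (ngp * (ngp - 1)) * s_i.sum() / nv
                strength = sum((p_i[a] + p_i[b]) * (a - b) ** 2
                               for a in present for b in present) / s_i.sum()
            else:
                contrast = strength = 0.0
            assert maps["Contrast"][tuple(c)] == pytest.approx(
                contrast, abs=1e-10)
            assert maps["Strength"][tuple(c)] == pytest.approx(
                strength, abs=1e-10)


class TestDegenerateNeighbourhoods:
    def _constant_fixture(self):
        vol = Volume(np.full((7, 7, 7), 42.0), (1, 1, 1))
        labels = np.ones((7, 7, 7), dtype=int)
        return vol, Mask(labels, (1, 1, 1)), VoxelFeatureConfig()

    def test_constant_first_order(self):
        vol, mask, cfg = self._constant_fixture()
        maps = local_first_order(vol, mask, cfg)
        c = (3, 3, 3)
        assert maps["Entropy"][c] == 0.0
        assert maps["MeanAbsoluteDeviation"][c] == 0.0
        assert maps["Median"][c] == 42.0

    def test_constant_glcm_takes_constant_image_limits(self):
        vol, mask, cfg = self._constant_fixture()
        maps = local_glcm(vol, mask, cfg)
        c = (3, 3, 3)
        assert maps["JointEnergy"][c] == 1.0
        for name in ("JointEntropy", "DifferenceAverage", "DifferenceEntropy",
                     "DifferenceVariance", "InverseVariance", "SumEntropy",
                     "Imc1", "Imc2"):
            assert maps[name][c] == 0.0, name

    def test_constant_ngtdm_and_glszm(self):
        vol, mask, cfg = self._constant_fixture()
        ngtdm = local_ngtdm(vol, mask, cfg)
        assert ngtdm["Contrast"][3, 3, 3] == 0.0
        assert ngtdm["Strength"][3, 3, 3] == 0.0
        glszm = local_glszm(vol, mask, cfg)
        assert glszm["SizeZoneNonUniformityNormalized"][3, 3, 3] == 1.0

    def test_half_zeros_half_ones_two_bins_gives_one_bit(self):
        vals = np.zeros((1, 1, 4))
        vals[0, 0, 2:] = 1.0
        vol = Volume(vals, (1, 1, 1))
        mask = Mask(np.ones((1, 1, 4), dtype=int), (1, 1, 1))
        cfg = VoxelFeatureConfig(neighborhood_radius_voxels=2, n_gray_levels=2)
        maps = local_first_order(vol, mask, cfg)
        assert maps["Entropy"][0, 0, 1] == pytest.approx(1.0)


class TestCanonicalRunConfigurations:
    def test_constant_segment_single_direction_run(self):
        lev = np.ones((1, 1, 5), dtype=np.int64)
        runs = oracles.runs_one_direction(lev, (0, 0, 1))
        assert runs == [(1, 5)]
        # single run of length N: LRE = N^2, entropy 0
        assert 5 ** 2 == 25

    def test_alternating_line_has_unit_long_run_emphasis(self):
        vals = np.zeros((1, 1, 6))
        vals[0, 0, ::2] = 1.0
        vol = Volume(vals, (1, 1, 1))
        mask = Mask(np.ones((1, 1, 6), dtype=int), (1, 1, 1))
        cfg = VoxelFeatureConfig(neighborhood_radius_voxels=2, n_gray_levels=2)
        maps = local_glrlm(vol, mask, cfg)
        assert np.nanmax(maps["LongRunEmphasis"]) == pytest.approx(1.0)

    def test_checkerboard_cooccurrence_mass_off_diagonal(self):
        idx = np.indices((5, 5, 5)).sum(axis=0) % 2
        vol = Volume(idx.astype(float), (1, 1, 1))
        mask = Mask(np.ones((5, 5, 5), dtype=int), (1, 1, 1))
        cfg = VoxelFeatureConfig(neighborhood_radius_voxels=2, n_gray_levels=2)
        lev = np.where(idx == 0, 1, 2).astype(np.int64)
        # restrict the oracle matrix to the 6 unit (face) offsets
        mat = np.zeros((2, 2))
        for off in [(0, 0, 1), (0, 1, 0), (1, 0, 0)]:
            a, b = [], []
            for x in range(5):
                for y in range(5):
                    for z in range(5):
                        q = (x + off[0], y + off[1], z + off[2])
                        if all(c < 5 for c in q):
                            mat[lev[x, y, z] - 1, lev[q] - 1] += 1
                            mat[lev[q] - 1, lev[x, y, z] - 1] += 1
        assert mat[0, 0] == 0 and mat[1, 1] == 0
        # and the kernel's JointEnergy on the strict checkerboard matches the
        # explicit 2x2 enumeration over all 13 offsets
        maps = local_glcm(vol, mask, cfg)
        full = oracles.glcm_matrix(lev, 2)
        p = full / full.sum()
        assert maps["JointEnergy"][2, 2, 2] == pytest.approx(
            (p ** 2).sum(), abs=1e-12)

    def test_gray_level_inversion_leaves_symmetric_features_unchanged(
            self, rng):
        vol, mask = _random_volume_and_mask(rng, (6, 6, 6))
        cfg = VoxelFeatureConfig(n_gray_levels=4)
        inverted = Volume(vol.values.max() + vol.values.min() - vol.values,
                          (1, 1, 1))
        a = local_glcm(vol, mask, cfg)
        b = local_glcm(inverted, mask, cfg)
        fg = mask.foreground()
        for name in ("DifferenceAverage", "DifferenceEntropy", "JointEnergy"):
            np.testing.assert_allclose(a[name][fg], b[name][fg], atol=1e-10)

    def test_intensity_shift_invariance_of_ngtdm(self, rng):
        vol, mask = _random_volume_and_mask(rng, (6, 6, 6))
        cfg = VoxelFeatureConfig(n_gray_levels=4)
        shifted = Volume(vol.values + 123.0, (1, 1, 1))
        a = local_ngtdm(vol, mask, cfg)
        b = local_ngtdm(shifted, mask, cfg)
        fg = mask.foreground()
        for name in ("Contrast", "Strength"):
            np.testing.assert_allclose(a[name][fg], b[name][fg], atol=1e-10)


class TestAssembly:
    def test_matrix_has_38_columns_and_one_row_per_voi_voxel(
            self, small_subject, voxel_cfg):
        m1 = compute_feature_maps(small_subject.t1w, small_subject.voi_mask,
                                  voxel_cfg)
        m2 = compute_feature_maps(small_subject.t2w, small_subject.voi_mask,
                                  voxel_cfg)
        X, coords = assemble_voxel_matrix(m1, m2, small_subject.voi_mask)
        assert X.shape == (small_subject.voi_mask.foreground().sum(), 38)
        assert np.all(np.isfinite(X))
        assert len(matrix_column_names()) == 38
        assert len(FEATURE_NAMES) == 19

    def test_permuting_and_unpermuting_rows_restores_matrix(
            self, small_subject, voxel_cfg, rng):
        m1 = compute_feature_maps(small_subject.t1w, small_subject.voi_mask,
                                  voxel_cfg)
        m2 = compute_feature_maps(small_subject.t2w, small_subject.voi_mask,
                                  voxel_cfg)
        X, _ = assemble_voxel_matrix(m1, m2, small_subject.voi_mask)
        perm = rng.permutation(len(X))
        np.testing.assert_array_equal(X[perm][np.argsort(perm)], X)

    def test_contrast_mismatch_is_rejected(self, small_subject, voxel_cfg):
        m1 = compute_feature_maps(small_subject.t1w, small_subject.voi_mask,
                                  voxel_cfg)
        with pytest.raises(ValueError, match="T1W, T2W"):
            assemble_voxel_matrix(m1, m1, small_subject.voi_mask)
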