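"""Voxelwise GLM, thresholding, clustering, permutation FWE."""

import numpy as np
import pytest
from scipy import stats

from wpet import (DesignMatrix, Volume, cluster_fwe, clusterize, fit_glm,
                  height_threshold, make_group_design, percent_difference,
                  slope_interaction_test)
from wpet.glm import Cluster
from wpet.preprocess import AnalysisMask


def _mask(shape=(10, 10, 10), vox=3.0):
    return AnalysisMask(Volume(np.ones(shape, bool), voxel_mm=vox))


def _vols(data, vox=3.0):
    return [Volume(d, voxel_mm=vox) for d in data]


class TestDesign:
    def test_zero_contrast_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            DesignMatrix(np.ones((5, 1)), np.array([0.0]))

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(X, np.array([1.0, 0.0]))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            make_group_design(["carrier"] * 6, np.arange(6))


class TestFitGLM:
    def test_null_construction_gives_small_t(self, rng):
        """Equal group means: the t-map is centred on zero."""
        mask = _mask()
        n = 24
        images = _vols(rng.normal(0, 1, (n, 10, 10, 10)))
        groups = ["control"] * 12 + ["carrier"] * 12
        design = make_group_design(groups, rng.uniform(30, 60, n))
        tmap, df = fit_glm(images, design, mask)
        assert df == n - 3
        assert abs(np.nanmean(tmap.data)) < 0.1

    def test_matches_brute_force_oracle(self, rng):
        """Vectorised t equals an independent per-voxel regression oracle
        to 1e-8 on 100 random voxels."""
        mask = _mask((6, 6, 6))
        n = 20
        images = _vols(rng.normal(0, 1, (n, 6, 6, 6)))
        groups = np.array(["control"] * 11 + ["carrier"] * 9)
        ages = rng.uniform(30, 60, n)
        design = make_group_design(groups, ages)
        tmap, df = fit_glm(images, design, mask)

        Y = np.stack([im.data for im in images]).reshape(n, -1)
        flat = tmap.data.ravel()
        vox_ids = rng.choice(Y.shape[1], size=100, replace=False)
        for v in vox_ids:
            # oracle: textbook OLS via normal equations, one voxel at a time
            X = design.X
            b = np.linalg.solve(X.T @ X, X.T @ Y[:, v])
            r = Y[:, v] - X @ b
            s2 = (r @ r) / (n - X.shape[1])
            se = np.sqrt(s2 * (design.contrast
                               @ np.linalg.inv(X.T @ X) @ design.contrast))
            t_oracle = (design.contrast @ b) / se
            assert abs(flat[v] - t_oracle) < 1e-8

    def test_two_sample_t_equivalence(self, rng):
        """Group-only design reproduces the classic two-sample t."""
        mask = _mask((4, 4, 4))
        n = 16
        data = rng.normal(0, 1, (n, 4, 4, 4))
        groups = np.array(["control"] * 8 + ["carrier"] * 8)
        design = make_group_design(groups, direction="hypo")
        tmap, df = fit_glm(_vols(data), design, mask)
        x = data[groups == "control"].reshape(8, -1)
        y = data[groups == "carrier"].reshape(8, -1)
        t_oracle = stats.ttest_ind(x, y, axis=0).statistic
        np.testing.assert_allclose(tmap.data.ravel(), t_oracle, atol=1e-10)

    def test_undefined_voxel_propagates(self, rng):
        mask = _mask((4, 4, 4))
        data = rng.normal(0, 1, (12, 4, 4, 4))
        data[3, 1, 1, 1] = np.nan
        design = make_group_design(["control"] * 6 + ["carrier"] * 6)
        tmap, _ = fit_glm(_vols(data), design, mask)
        assert np.isnan(tmap.data[1, 1, 1])
        assert np.isfinite(tmap.data[0, 0, 0])


class TestHeightThreshold:
    def test_critical_value_at_p001_df40(self):
        """Upper-tail t quantile at p=.001, df=40 is 3.307."""
        assert stats.t.isf(0.001, 40) == pytest.approx(3.307, abs=1e-3)
        tmap = Volume(np.array([[[3.30, 3.32]]]))
        out = height_threshold(tmap, df=40, p=0.001)
        assert not out.data[0, 0, 0]
        assert out.data[0, 0, 1]

    def test_zero_map_empty(self):
        out = height_threshold(Volume(np.zeros((4, 4, 4))), df=20)
        assert not out.data.any()

    def test_half_p_keeps_about_half_of_noise(self, rng):
        t = Volume(rng.standard_t(df=30, size=(20, 20, 20)))
        out = height_threshold(t, df=30, p=0.5)
        frac = out.data.mean()
        assert 0.45 < frac < 0.55

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            height_threshold(Volume(np.zeros((4, 4, 4))), df=20, p=0.7)


class TestClusterize:
    def test_empty_map(self):
        assert clusterize(Volume(np.zeros((6, 6, 6), bool))) == []

    def test_extent_filter_drops_small_component(self):
        data = np.zeros((20, 20, 20), bool)
        data[1:9, 1:5, 1:9] = True        # 8*4*8 = 256 voxels
        data[12:17, 12:16, 12:17] = True  # 5*4*5 = 100 voxels
        out = clusterize(Volume(data), extent=150)
        assert len(out) == 1
        assert out[0].size == 256

    def test_single_voxel_extent_one(self):
        data = np.zeros((5, 5, 5), bool)
        data[2, 2, 2] = True
        out = clusterize(Volume(data), extent=1)
        assert len(out) == 1 and out[0].size == 1

    def test_18_vs_6_connectivity(self):
        """Edge-touching voxels connect under 18- but not 6-connectivity."""
        data = np.zeros((4, 4, 4), bool)
        data[1, 1, 1] = data[1, 2, 2] = True
        assert len(clusterize(Volume(data), connectivity=18, extent=1)) == 1
        assert len(clusterize(Volume(data), connectivity=6, extent=1)) == 2
        # corner-touching requires 26
        data[:] = False
        data[1, 1, 1] = data[2, 2, 2] = True
        assert len(clusterize(Volume(data), connectivity=18, extent=1)) == 2
        assert len(clusterize(Volume(data), connectivity=26, extent=1)) == 1

    def test_agrees_with_flood_fill_oracle(self, rng):
        """Component count and sizes match a brute-force flood fill on a
        random binary volume."""
        from collections import deque
        data = rng.random((10, 10, 10)) < 0.25
        out = clusterize(Volume(data), connectivity=6, extent=1)

        seen = np.zeros_like(data)
        sizes = []
        for idx in zip(*np.nonzero(data)):
            if seen[idx]:
                continue
            q, size = deque([idx]), 0
            seen[idx] = True
            while q:
                i, j, k = q.popleft()
                size += 1
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                          (0, 0, 1), (0, 0, -1)):
                    ni, nj, nk = i + d[0], j + d[1], k + d[2]
                    if 0 <= ni < 10 and 0 <= nj < 10 and 0 <= nk < 10 \
                            and data[ni, nj, nk] and not seen[ni, nj, nk]:
                        seen[ni, nj, nk] = True
                        q.append((ni, nj, nk))
            sizes.append(size)
        assert sorted(c.size for c in out) == sorted(sizes)


class TestPercentDifference:
    def test_hand_arithmetic(self):
        imgs = _vols(np.stack([np.full((4, 4, 4), 1.0),
                               np.full((4, 4, 4), 0.8)]))
        cl = Cluster(voxels=tuple(np.nonzero(np.ones((4, 4, 4), bool))),
                     size=64)
        out = percent_difference(imgs, ["control", "carrier"], cl)
        assert out == pytest.approx(20.0)

    def test_equal_means_zero(self):
        imgs = _vols(np.stack([np.full((4, 4, 4), 1.0)] * 2))
        cl = Cluster(voxels=tuple(np.nonzero(np.ones((4, 4, 4), bool))),
                     size=64)
        assert percent_difference(imgs, ["control", "carrier"], cl) == 0.0

    def test_zero_control_mean_rejected(self):
        imgs = _vols(np.stack([np.zeros((4, 4, 4)), np.ones((4, 4, 4))]))
        cl = Cluster(voxels=tuple(np.nonzero(np.ones((4, 4, 4), bool))),
                     size=64)
        with pytest.raises(ValueError):
            percent_difference(imgs, ["control", "carrier"], cl)


class TestClusterFWE:
    def test_identical_images_give_empty_table(self):
        imgs = _vols(np.stack([np.ones((8, 8, 8))] * 12))
        design = make_group_design(["control"] * 6 + ["carrier"] * 6,
                                   np.arange(12.0))
        table = cluster_fwe(imgs, design, _mask((8, 8, 8)), n_perm=500,
                            seed=0, extent=1)
        assert len(table) == 0

    def test_small_groups_rejected(self, rng):
        imgs = _vols(rng.normal(size=(5, 6, 6, 6)))
        design = make_group_design(["control"] * 3 + ["carrier"] * 2)
        with pytest.raises(ValueError, match="3 subjects"):
            cluster_fwe(imgs, design, _mask((6, 6, 6)), n_perm=500, seed=0)

    def test_low_n_perm_warns(self, rng):
        imgs = _vols(rng.normal(size=(12, 6, 6, 6)))
        design = make_group_design(["control"] * 6 + ["carrier"] * 6)
        with pytest.warns(UserWarning, match="n_perm"):
            cluster_fwe(imgs, design, _mask((6, 6, 6)), n_perm=50, seed=0,
                        extent=1)

    def test_injected_effect_detected_and_quantified(self, rng):
        """A strong focal effect yields a significant cluster covering the
        seeded block, with the configured percent difference."""
        shape = (12, 12, 12)
        n_ctrl, n_carr = 12, 10
        block = np.s_[3:9, 3:9, 3:9]
        data = rng.normal(1.0, 0.02, (n_ctrl + n_carr, *shape))
        data[n_ctrl:, *block] *= 0.75
        groups = ["control"] * n_ctrl + ["carrier"] * n_carr
        design = make_group_design(groups, rng.uniform(30, 60, 22))
        table = cluster_fwe(_vols(data), design, _mask(shape), n_perm=500,
                            seed=1, extent=50, groups=groups)
        assert len(table) >= 1
        top = table.iloc[0]
        assert top["significant"]
        assert top["size_voxels"] >= 6 ** 3
        assert top["percent_difference"] == pytest.approx(25.0, abs=3.0)

    def test_determinism_under_seed(self, rng):
        imgs = _vols(rng.normal(size=(12, 8, 8, 8)))
        design = make_group_design(["control"] * 6 + ["carrier"] * 6)
        t1 = cluster_fwe(imgs, design, _mask((8, 8, 8)), n_perm=500, seed=7,
                         height_p=0.05, extent=1)
        t2 = cluster_fwe(imgs, design, _mask((8, 8, 8)), n_perm=500, seed=7,
                         height_p=0.05, extent=1)
        assert t1.equals(t2)


class TestSlopeInteraction:
    def test_equal_slopes_give_null_t(self, rng):
        shape = (6, 6, 6)
        n = 30
        ages = rng.uniform(30, 60, n)
        groups = np.array(["control"] * 15 + ["carrier"] * 15)
        data = (100 - 0.5 * ages)[:, None, None, None] \
            + rng.normal(0, 1, (n, *shape))
        tmap, df = slope_interaction_test(_vols(data), ages, groups,
                                          _mask(shape))
        assert abs(np.nanmean(tmap.data)) < 0.2

    def test_different_slopes_detected(self, rng):
        shape = (6, 6, 6)
        n = 40
        ages = rng.uniform(30, 60, n)
        groups = np.array(["control"] * 20 + ["carrier"] * 20)
        slopes = np.where(groups == "carrier", -1.5, -0.5)
        data = (100 + slopes * ages)[:, None, None, None] \
            + rng.normal(0, 1, (n, *shape))
        tmap, df = slope_interaction_test(_vols(data), ages, groups,
                                          _mask(shape))
        # steeper carrier decline -> strongly negative interaction t
        crit = stats.t.isf(0.001, df)
        assert np.nanmean(tmap.data) < -crit

    def test_degenerate_ages_rejected(self, rng):
        data = rng.normal(size=(12, 4, 4, 4))
        with pytest.raises(ValueError, match="age"):
            slope_interaction_test(_vols(data), np.full(12, 50.0),
                                   ["control"] * 6 + ["carrier"] * 6,
                                   _mask((4, 4, 4)))
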