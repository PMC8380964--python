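"""Voxel-wise GLM and permutation cluster inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nethom.inference import (
    GroupDesign,
    cluster_extent_inference,
    extract_region_means,
    fit_voxelwise_glm,
)
from nethom.types import NHMap, NetworkMask, NethomError


def _design(n_pat, n_con, rng, ids=None):
    n = n_pat + n_con
    return GroupDesign(
        subject_ids=ids or [f"s{i}" for i in range(n)],
        group=np.array(["patient"] * n_pat + ["control"] * n_con),
        age=rng.normal(26, 6, n),
        mean_fd=rng.uniform(0.05, 0.2, n),
    )


def _maps_from_matrix(Y, shape=(4, 4, 4)):
    mask = NetworkMask(np.ones(shape, bool), np.eye(4))
    out = []
    for i, row in enumerate(Y):
        v = np.full(shape, np.nan)
        v[mask.indicator] = row
        out.append(NHMap(v, mask, subject_id=f"s{i}"))
    return out, mask


class TestGLM:
    def test_covariate_free_equals_pooled_t_oracle(self, rng):
        """Group t with no covariates equals the textbook two-sample
        pooled-variance t at every voxel."""
        n_pat, n_con, v = 12, 10, 64
        Y = rng.standard_normal((n_pat + n_con, v))
        maps, _ = _maps_from_matrix(Y)
        des = _design(n_pat, n_con, rng)
        tmap = fit_voxelwise_glm(maps, des, use_covariates=False)
        got = tmap.in_mask()
        a, b = Y[:n_pat], Y[n_pat:]
        sp = np.sqrt(
            ((n_pat - 1) * a.var(0, ddof=1) + (n_con - 1) * b.var(0, ddof=1))
            / (n_pat + n_con - 2)
        )
        oracle = (a.mean(0) - b.mean(0)) / (sp * np.sqrt(1 / n_pat + 1 / n_con))
        np.testing.assert_allclose(got, oracle, atol=1e-10)
        assert tmap.df == n_pat + n_con - 2

    def test_null_t_bounded(self, rng):
        Y = rng.standard_normal((30, 200))
        maps, _ = _maps_from_matrix(Y, (10, 10, 2))
        tmap = fit_voxelwise_glm(maps, _design(15, 15, rng))
        # 99.9th percentile bound of |t| under the null, with slack
        bound = stats.t.ppf(1 - 0.0005, tmap.df)
        assert np.abs(tmap.in_mask()).max() < bound + 2.0

    def test_separation_limit_positive_sign(self, rng):
        Y = 0.001 * rng.standard_normal((20, 64))
        Y[:10, 5] += 1.0  # patients shifted up at voxel 5
        maps, _ = _maps_from_matrix(Y)
        tmap = fit_voxelwise_glm(maps, _design(10, 10, rng), use_covariates=False)
        assert tmap.in_mask()[5] > 50

    def test_rank_deficient_rejected(self, rng):
        Y = rng.standard_normal((10, 8))
        maps, _ = _maps_from_matrix(Y, (2, 2, 2))
        des = _design(5, 5, rng)
        des.age[:] = 1.0  # collinear with intercept
        with pytest.raises(NethomError, match="rank"):
            fit_voxelwise_glm(maps, des)


class TestClusterInference:
    def test_planted_effect_detected_with_correct_sign(self, rng):
        n = 24
        Y = 0.05 * rng.standard_normal((n, 125))
        effect = np.zeros((5, 5, 5), bool)
        effect[1:4, 1:4, 1:4] = True
        Y[: n // 2, effect.ravel()] += 0.5
        maps, mask = _maps_from_matrix(Y, (5, 5, 5))
        tab = cluster_extent_inference(
            maps, _design(n // 2, n // 2, rng), n_perm=199, seed=0
        )
        assert len(tab) == 1
        cl = tab.clusters[0]
        assert cl.direction == "patients>controls"
        got = np.zeros((5, 5, 5), bool)
        got[tuple(cl.voxels.T)] = True
        dice = 2 * (got & effect).sum() / (got.sum() + effect.sum())
        assert dice >= 0.5
        assert cl.peak_t > 0

    def test_permutation_p_floor(self, rng):
        """0 exceedances in 199 permutations gives p = 1/200, doubled
        across signs to 0.01."""
        n = 24
        Y = 0.05 * rng.standard_normal((n, 125))
        Y[: n // 2, :50] += 1.0
        maps, _ = _maps_from_matrix(Y, (5, 5, 5))
        tab = cluster_extent_inference(
            maps, _design(n // 2, n // 2, rng), n_perm=199, seed=0
        )
        assert any(c.p_fwe == pytest.approx(2 / 200) for c in tab.clusters)

    def test_seed_determinism(self, rng):
        Y = rng.standard_normal((20, 64))
        Y[:10, :20] += 0.8
        maps, _ = _maps_from_matrix(Y)
        des = _design(10, 10, rng)
        t1 = cluster_extent_inference(maps, des, n_perm=150, seed=11)
        t2 = cluster_extent_inference(maps, des, n_perm=150, seed=11)
        pd.testing.assert_frame_equal(t1.to_dataframe(), t2.to_dataframe())

    def test_empty_table_not_error(self, rng):
        Y = rng.standard_normal((20, 64))
        maps, _ = _maps_from_matrix(Y)
        tab = cluster_extent_inference(maps, _design(10, 10, rng), n_perm=120, seed=2)
        assert isinstance(len(tab), int)

    def test_peak_mm_through_affine(self, rng):
        n = 20
        Y = 0.01 * rng.standard_normal((n, 64))
        Y[: n // 2, :] += np.eye(64)[10] * 1.0  # single-voxel effect at index 10
        mask = NetworkMask(np.ones((4, 4, 4), bool), np.diag([3.0, 3.0, 3.0, 1.0]))
        maps = []
        for i, row in enumerate(Y):
            v = np.full((4, 4, 4), np.nan)
            v[mask.indicator] = row
            maps.append(NHMap(v, mask, subject_id=f"s{i}"))
        tab = cluster_extent_inference(
            maps, _design(n // 2, n // 2, rng), n_perm=150, seed=3
        )
        if len(tab):  # single-voxel cluster survives only if extent null allows
            peak = tab.clusters[0].peak_ijk
            mm = tab.clusters[0].peak_mni_mm
            assert mm == tuple(3.0 * p for p in peak)


class TestRegionMeans:
    def _table_with_cluster(self, rng):
        Y = 0.1 * rng.standard_normal((10, 64))
        Y[:5, :30] += 2.0
        maps, mask = _maps_from_matrix(Y)
        tab = cluster_extent_inference(maps, _design(5, 5, rng), n_perm=120, seed=0)
        assert len(tab) >= 1
        return Y, maps, tab

    def test_uniform_map_gives_constant_mean(self, rng):
        Y, maps, tab = self._table_with_cluster(rng)
        const_maps, _ = _maps_from_matrix(np.full((10, 64), 0.42))
        feats = extract_region_means(const_maps, tab)
        assert np.allclose(feats.to_numpy(), 0.42)

    def test_matches_direct_summation_oracle(self, rng):
        Y, maps, tab = self._table_with_cluster(rng)
        feats = extract_region_means(maps, tab)
        cl = tab.clusters[0]
        lin = np.ravel_multi_index(cl.voxels.T, (4, 4, 4))
        oracle = Y[:, lin].mean(axis=1)
        np.testing.assert_allclose(feats[cl.label].to_numpy(), oracle, atol=1e-12)

    def test_empty_cluster_table_rejected(self, rng):
        from nethom.inference import ClusterTable

        Y = rng.standard_normal((6, 64))
        maps, mask = _maps_from_matrix(Y)
        with pytest.raises(NethomError):
            extract_region_means(maps, ClusterTable([], mask, 4, 3.0, 100))


def test_empty_group_rejected(rng):
    with pytest.raises(NethomError, match="empty group"):
        GroupDesign(
            subject_ids=["a", "b"],
            group=np.array(["patient", "patient"]),
            age=np.array([20.0, 30.0]),
            mean_fd=np.array([0.1, 0.1]),
        )
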