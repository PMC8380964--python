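"""Group PCA/ICA mask derivation: reduction oracle, planted-source
recovery, template selection and thresholding."""

import numpy as np
import pytest
from scipy import stats

from nethom.ica_mask import (
    ComponentSet,
    concatenate_and_reduce,
    derive_mask_from_controls,
    select_network_component,
    spatial_ica,
    threshold_to_mask,
)
from nethom.preprocess import preprocess_run
from nethom.simulate import default_spec, generate_cohort
from nethom.types import BoldRun, NetworkMask, NethomError

from conftest import make_run


class TestReduce:
    def test_duplicated_runs_leading_share(self, rng):
        run = make_run(rng, shape=(6, 6, 4), t=30)
        red1 = concatenate_and_reduce([run, run.with_data(run.data.copy())], None, 5)
        # duplication cannot reduce the top component's variance share:
        # oracle = spectrum of one variance-normalised run
        y = run.data.reshape(-1, 30).astype(float)
        y = y - y.mean(1, keepdims=True)
        y = y / y.std(1, keepdims=True)
        single = np.linalg.svd(y.T, compute_uv=False)
        share_single = single[0] ** 2 / (single**2).sum()
        assert red1.explained_variance_ratio[0] >= share_single - 1e-9

    def test_pca_matches_eigendecomposition_oracle(self, rng):
        """Variance spectrum of the reduction equals the dense
        eigensolver of the concatenated covariance."""
        runs = [make_run(rng, shape=(5, 5, 4), t=20, subject_id=f"s{i}")
                for i in range(3)]
        red = concatenate_and_reduce(runs, None, 10)
        blocks = []
        for r in runs:
            y = r.data.reshape(-1, 20).astype(float)
            y = y - y.mean(1, keepdims=True)
            sd = y.std(1, keepdims=True)
            sd[sd < 1e-12] = 1
            blocks.append((y / sd).T)
        X = np.concatenate(blocks, 0)
        evals = np.sort(np.linalg.eigvalsh(X @ X.T))[::-1]
        ratio_oracle = evals[:10] / evals.sum()
        np.testing.assert_allclose(
            red.explained_variance_ratio, ratio_oracle, atol=1e-6
        )

    def test_near_full_rank_retains_variance(self, rng):
        runs = [make_run(rng, shape=(4, 4, 3), t=20, subject_id=f"s{i}")
                for i in range(2)]
        red = concatenate_and_reduce(runs, None, 39)
        assert red.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_inconsistent_grids_rejected(self, rng):
        r1 = make_run(rng, shape=(4, 4, 3), t=20)
        r2 = make_run(rng, shape=(5, 4, 3), t=20)
        with pytest.raises(NethomError):
            concatenate_and_reduce([r1, r2], None, 5)


class TestSpatialICA:
    def _planted_two_source_runs(self, rng, t=120):
        """Two spatially disjoint non-Gaussian sources mixed over time."""
        shape = (10, 10, 4)
        s1 = np.zeros(shape)
        s1[1:5, 1:5, :] = 1.0
        s2 = np.zeros(shape)
        s2[6:9, 6:9, :] = 1.0
        tc1 = np.sin(2 * np.pi * 0.03 * np.arange(t) * 2.0)
        tc2 = np.sin(2 * np.pi * 0.06 * np.arange(t) * 2.0 + 1.0)
        data = (
            s1[..., None] * tc1
            + s2[..., None] * tc2
            + 0.1 * rng.standard_normal((*shape, t))
        )
        return [BoldRun("a", data, 2.0, np.eye(4)),
                BoldRun("b", data + 0.1 * rng.standard_normal(data.shape), 2.0, np.eye(4))], (s1, s2)

    def test_planted_source_recovery(self, rng):
        runs, (s1, s2) = self._planted_two_source_runs(rng)
        red = concatenate_and_reduce(runs, None, 6)
        comps = spatial_ica(red, 2, seed=0)
        corrs = np.zeros((2, 2))
        for i in range(2):
            for j, s in enumerate((s1, s2)):
                corrs[i, j] = abs(
                    np.corrcoef(comps.maps[i].ravel(), s.ravel())[0, 1]
                )
        # each source matched by some component (up to permutation)
        assert max(corrs[0, 0], corrs[1, 0]) > 0.95
        assert max(corrs[0, 1], corrs[1, 1]) > 0.95

    def test_seed_determinism(self, rng):
        runs, _ = self._planted_two_source_runs(rng)
        red = concatenate_and_reduce(runs, None, 6)
        c1 = spatial_ica(red, 2, seed=5)
        c2 = spatial_ica(red, 2, seed=5)
        np.testing.assert_array_equal(c1.maps, c2.maps)

    def test_positive_skew_sign_convention(self, rng):
        runs, _ = self._planted_two_source_runs(rng)
        red = concatenate_and_reduce(runs, None, 6)
        comps = spatial_ica(red, 2, seed=0)
        for c in range(2):
            assert stats.skew(comps.maps[c].ravel()) >= 0

    def test_rank_exceeded_rejected(self, rng):
        runs, _ = self._planted_two_source_runs(rng)
        red = concatenate_and_reduce(runs, None, 4)
        with pytest.raises(NethomError):
            spatial_ica(red, 10, seed=0)


class TestSelection:
    def _comps(self, maps):
        maps = np.asarray(maps, dtype=float)
        return ComponentSet(
            maps=maps,
            brain_indicator=np.ones(maps.shape[1:], dtype=bool),
            affine=np.eye(4),
        )

    def test_self_match(self, rng):
        maps = rng.standard_normal((4, 6, 6, 4))
        template = NetworkMask(np.abs(maps[2]) > 1.0, np.eye(4))
        idx, score = select_network_component(self._comps(maps), template)
        assert idx == 2
        assert score > 0

    def test_empty_template_rejected(self, rng):
        maps = rng.standard_normal((2, 4, 4, 4))
        with pytest.raises(NethomError):
            template = NetworkMask(np.zeros((4, 4, 4), bool), np.eye(4))

    def test_all_zero_components_rejected(self):
        maps = np.zeros((2, 4, 4, 4))
        template = NetworkMask(np.ones((4, 4, 4), bool), np.eye(4))
        template.indicator[0, 0, 0] = False
        with pytest.raises(NethomError):
            select_network_component(self._comps(maps), template)


class TestThreshold:
    def test_blob_kept(self):
        m = np.zeros((10, 10, 10))
        m[2:7, 2:7, 2:6] = 5.0  # 100-voxel blob
        mask = threshold_to_mask(m, np.eye(4), 2.3, 10)
        assert mask.n_voxels == 100

    def test_min_cluster_filter_empties(self):
        m = np.zeros((10, 10, 10))
        m[2:7, 2:7, 2:6] = 5.0
        with pytest.raises(NethomError, match="lower"):
            threshold_to_mask(m, np.eye(4), 2.3, 200)

    def test_gaussian_tail_fraction(self, rng):
        """Kept fraction before cluster filtering matches P(Z >= 2.3)."""
        z = rng.standard_normal((40, 40, 40))
        kept = (z >= 2.3).mean()
        p = 1 - stats.norm.cdf(2.3)
        n = z.size
        ci = 4 * np.sqrt(p * (1 - p) / n)
        assert abs(kept - p) < ci


class TestEndToEnd:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mask_recovery_dice(self, seed):
        """Control-only group ICA recovers the planted network."""
        c = generate_cohort(default_spec(seed=seed))
        controls = [
            preprocess_run(r, m)
            for r, m in zip(c.controls(), c.motions[c.spec.n_patients :])
        ]
        mask, comps, idxs = derive_mask_from_controls(
            controls, c.mask_truth, seed=seed
        )
        tm = c.mask_truth.indicator
        dice = 2 * (mask.indicator & tm).sum() / (mask.indicator.sum() + tm.sum())
        assert dice >= 0.7
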