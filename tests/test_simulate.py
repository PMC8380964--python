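"""Generator contracts: determinism, planted effects, motion and
phenotype calibration."""

import numpy as np
import pandas as pd
import pytest

from nethom.homogeneity import compute_nh_map
from nethom.preprocess import compute_framewise_displacement
from nethom.simulate import (
    NetworkRegion,
    PlantedCorrelation,
    PlantedEffect,
    SimSpec,
    default_spec,
    generate_cohort,
    generate_motion_trace,
    generate_phenotypes,
    true_region_nh,
)
from nethom.types import NethomError


def _tiny_spec(**kw):
    args = dict(
        grid_shape=(8, 8, 6),
        n_volumes=30,
        n_patients=4,
        n_controls=4,
        network_regions=[
            NetworkRegion("a", ((1, 4), (1, 4), (1, 4)), weight=0.30),
            NetworkRegion("b", ((5, 8), (4, 7), (1, 4)), weight=0.30),
        ],
        subject_w_sd=0.0,
    )
    args.update(kw)
    return SimSpec(**args)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        spec = _tiny_spec(seed=5)
        c1 = generate_cohort(spec)
        c2 = generate_cohort(_tiny_spec(seed=5))
        for r1, r2 in zip(c1.runs, c2.runs):
            np.testing.assert_array_equal(r1.data, r2.data)
        pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)

    def test_different_seed_differs(self):
        c1 = generate_cohort(_tiny_spec(seed=5))
        c2 = generate_cohort(_tiny_spec(seed=6))
        assert not np.array_equal(c1.runs[0].data, c2.runs[0].data)


class TestPlantedEffects:
    def test_zero_delta_equal_true_nh(self):
        c = generate_cohort(_tiny_spec(seed=0))
        nh = c.truth.region_true_nh
        grp = c.phenotypes["group"]
        diff = nh[grp == "patient"].mean() - nh[grp == "control"].mean()
        assert np.allclose(diff, 0.0)

    def test_positive_delta_raises_empirical_nh(self):
        """Planted increase shows in measured NH in >= 95% of replicates."""
        hits = 0
        reps = 50
        for seed in range(reps):
            spec = _tiny_spec(
                seed=seed,
                effect_regions=[PlantedEffect("a", +1, 0.4)],
                subject_w_sd=0.01,
            )
            c = generate_cohort(spec)
            sl = spec.region("a").slices()
            means = []
            for run in c.runs:
                nh = compute_nh_map(run, c.mask_truth)
                means.append(np.nanmean(nh.values[sl]))
            means = np.asarray(means)
            hits += means[:4].mean() > means[4:].mean()
        assert hits >= int(0.95 * reps)

    def test_effect_monotonicity_in_delta(self):
        diffs = []
        for delta in (0.1, 0.25, 0.4):
            spec = _tiny_spec(effect_regions=[PlantedEffect("a", +1, delta)])
            c = generate_cohort(spec)
            nh = c.truth.region_true_nh["a"]
            grp = c.phenotypes["group"]
            diffs.append(nh[grp == "patient"].mean() - nh[grp == "control"].mean())
        assert diffs[0] < diffs[1] < diffs[2]

    def test_conflicting_signs_rejected(self):
        with pytest.raises(NethomError, match="conflicting"):
            _tiny_spec(
                effect_regions=[
                    PlantedEffect("a", +1, 0.1),
                    PlantedEffect("a", -1, 0.1),
                ]
            )

    def test_zero_noise_rejected(self):
        with pytest.raises(NethomError, match="noise"):
            _tiny_spec(noise_sd=0.0)

    def test_true_region_nh_closed_form(self):
        """Hand-computed closed form for a 2-region layout."""
        spec = _tiny_spec()
        # region 'a': 27 voxels at w=0.5, region 'b': 27 voxels at a=0.05 cross
        val = true_region_nh(spec, {"a": 0.5, "b": 0.3}, q=0.0)
        n = 27
        expect_a = ((n - 1) * 0.5 + n * spec.global_weight) / (2 * n - 1)
        assert val["a"] == pytest.approx(expect_a, abs=1e-12)


class TestMotion:
    def test_zero_scale_all_zero(self):
        m = generate_motion_trace(50, 0.0, seed=3)
        assert np.all(m.params == 0)
        assert compute_framewise_displacement(m).mean_fd == 0.0

    def test_doubling_scale_doubles_fd(self):
        m1 = generate_motion_trace(50, 0.1, seed=3)
        m2 = generate_motion_trace(50, 0.2, seed=3)
        fd1 = compute_framewise_displacement(m1).mean_fd
        fd2 = compute_framewise_displacement(m2).mean_fd
        assert fd2 == pytest.approx(2 * fd1, rel=1e-9)
        assert fd2 > fd1

    @pytest.mark.parametrize("target", [0.1, 0.3])
    def test_fd_calibration_within_20pct(self, target):
        fds = [
            compute_framewise_displacement(
                generate_motion_trace(100, target, seed=s)
            ).mean_fd
            for s in range(20)
        ]
        assert np.mean(fds) == pytest.approx(target, rel=0.2)

    def test_negative_scale_rejected(self):
        with pytest.raises(NethomError):
            generate_motion_trace(50, -0.1, seed=0)


class TestPhenotypes:
    def _nh_frame(self, spec, rng):
        ids = spec.subject_ids()
        return pd.DataFrame(
            {"a": rng.normal(0.4, 0.05, spec.n_subjects),
             "b": rng.normal(0.4, 0.05, spec.n_subjects)},
            index=pd.Index(ids, name="subject_id"),
        )

    def test_planted_r_mean_recovery(self):
        """Mean sample correlation over 50 draws within +-0.05 of 0.5."""
        spec = _tiny_spec(
            n_patients=40,
            n_controls=4,
            phenotype_plan=[PlantedCorrelation("TG", "a", 0.5)],
        )
        rng = np.random.default_rng(0)
        rs = []
        for seed in range(50):
            nh = self._nh_frame(spec, rng)
            df = generate_phenotypes(spec, nh, seed)
            pat = df["group"] == "patient"
            rs.append(np.corrcoef(df.loc[pat, "TG"], nh.loc[pat.index[pat], "a"])[0, 1])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.05)

    def test_planted_null_r(self):
        spec = _tiny_spec(
            n_patients=40,
            n_controls=4,
            phenotype_plan=[PlantedCorrelation("TG", "a", 0.0)],
        )
        rng = np.random.default_rng(1)
        rs = []
        for seed in range(50):
            nh = self._nh_frame(spec, rng)
            df = generate_phenotypes(spec, nh, seed)
            pat = df["group"] == "patient"
            rs.append(np.corrcoef(df.loc[pat, "TG"], nh.loc[pat.index[pat], "a"])[0, 1])
        assert abs(np.mean(rs)) < 2 / np.sqrt(40)

    def test_extreme_r_strong_sample_correlation(self):
        spec = _tiny_spec(
            n_patients=40,
            n_controls=4,
            phenotype_plan=[PlantedCorrelation("TG", "a", 0.99)],
        )
        rng = np.random.default_rng(2)
        nh = self._nh_frame(spec, rng)
        df = generate_phenotypes(spec, nh, 0)
        pat = df["group"] == "patient"
        r = np.corrcoef(df.loc[pat, "TG"], nh.loc[pat.index[pat], "a"])[0, 1]
        assert r > 0.9

    def test_unit_r_rejected(self):
        with pytest.raises(NethomError):
            _tiny_spec(phenotype_plan=[PlantedCorrelation("TG", "a", 1.0)])

    def test_controls_missing_clinical(self, desk_cohort):
        ph = desk_cohort.phenotypes
        con = ph[ph["group"] == "control"]
        assert con["TG"].isna().all()
        assert con["age_years"].notna().all()


class TestCohortStructure:
    def test_one_of_each_per_subject(self, desk_cohort):
        n = desk_cohort.spec.n_subjects
        assert len(desk_cohort.runs) == n
        assert len(desk_cohort.motions) == n
        assert desk_cohort.phenotypes.shape[0] == n

    def test_effect_masks_in_network(self, desk_cohort):
        net = desk_cohort.mask_truth.indicator
        for m in desk_cohort.truth.effect_masks.values():
            assert np.all(net[m != 0])
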