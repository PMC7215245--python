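import numpy as np
import pytest
from scipy import stats

from neurometab import voxel
from neurometab.cohort import (
    CohortConfig,
    GeneratorTruth,
    PlantedClusterSpec,
    default_ins_cr_truth,
    generate_cohort,
    generate_metabolites,
    generate_voxel_stack,
    simulate_study,
)
from neurometab.lmm import SESSIONS


def _missing_counts(df):
    conc = df[df.group == "concussed"]
    return tuple(
        int((~conc[conc.session == s]["observed"]).sum()) for s in SESSIONS
    )


class TestGenerateCohort:
    def test_retention_counts_exact(self):
        df = generate_cohort(CohortConfig(seed=1))
        assert _missing_counts(df) == (6, 8, 8, 20)

    def test_group_sizes_and_hoc_counts(self):
        df = generate_cohort(CohortConfig(seed=2))
        subj = df.drop_duplicates("subject_id")
        assert (subj.group == "control").sum() == 66
        assert (subj.group == "concussed").sum() == 33
        assert subj[subj.group == "control"].hoc.sum() == 31
        assert subj[subj.group == "concussed"].hoc.sum() == 19

    def test_controls_have_single_baseline_session(self):
        df = generate_cohort(CohortConfig(seed=3))
        ctl = df[df.group == "control"]
        assert set(ctl.session) == {"BASE"}
        assert ctl.groupby("subject_id").size().eq(1).all()

    def test_dacu_range_and_drtp_positive(self):
        df = generate_cohort(CohortConfig(seed=4))
        conc = df[df.group == "concussed"]
        assert conc.dacu.between(1, 7).all()
        assert (conc.drtp > 0).all()

    def test_drtp_heavy_tail_quantiles(self):
        """Median ~22 days, upper quartile ~95 days across many cohorts."""
        draws = np.concatenate([
            generate_cohort(CohortConfig(seed=s))
            .drop_duplicates("subject_id")
            .query("group == 'concussed'")["drtp"]
            .to_numpy()
            for s in range(40)
        ])
        assert np.median(draws) == pytest.approx(22, rel=0.25)
        assert np.percentile(draws, 75) == pytest.approx(95, rel=0.35)

    def test_attrition_rank_correlation_hits_target(self):
        rhos = []
        for s in range(40):
            df = generate_cohort(CohortConfig(seed=s, attrition_drtp_rho=0.5))
            conc = df[(df.group == "concussed") & (df.session == "RTP")]
            rhos.append(
                stats.spearmanr(conc.drtp, ~conc.observed).statistic
            )
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.15)

    def test_attrition_independent_when_target_zero(self):
        rhos = []
        for s in range(100):
            df = generate_cohort(CohortConfig(seed=s, attrition_drtp_rho=0.0))
            conc = df[(df.group == "concussed") & (df.session == "1YR")]
            rhos.append(stats.spearmanr(conc.drtp, ~conc.observed).statistic)
        assert abs(np.mean(rhos)) < 0.2

    def test_deterministic_under_seed(self):
        a = generate_cohort(CohortConfig(seed=7))
        b = generate_cohort(CohortConfig(seed=7))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_retention_above_group_size_rejected(self):
        with pytest.raises(ValueError, match="retention"):
            CohortConfig(n_concussed=10, retention=(27, 25, 25, 13))


class TestGenerateMetabolites:
    def test_degenerate_generator_is_exactly_zero(self, rng):
        df = generate_cohort(CohortConfig(seed=1))
        truth = GeneratorTruth(beta=(0.0,) * 12, sigma_b=0.0, sigma_e=1e-300)
        out = generate_metabolites(df, truth, rng, "m")
        np.testing.assert_allclose(out["m_complete"], 0.0, atol=1e-12)

    def test_session_effect_recovered_in_means(self, rng):
        """RTP coefficient 0.230 appears as the RTP-ACU mean difference in a
        large no-HOC cohort with small noise."""
        cfg = CohortConfig(
            seed=11, n_concussed=400, n_control=2,
            hoc_fraction_concussed=0.0, retention=(400,) * 4,
        )
        beta = [0.0] * 12
        beta[1] = 0.230
        truth = GeneratorTruth(beta=tuple(beta), sigma_b=0.05, sigma_e=0.02)
        out = generate_metabolites(generate_cohort(cfg), truth, rng, "m")
        conc = out[out.group == "concussed"]
        diff = (
            conc[conc.session == "RTP"]["m_complete"].mean()
            - conc[conc.session == "ACU"]["m_complete"].mean()
        )
        assert diff == pytest.approx(0.230, abs=0.02)

    def test_between_subject_variance_algebra(self, rng):
        """var(subject means over 4 sessions) ~ sigma_b^2 + sigma_e^2/4."""
        cfg = CohortConfig(seed=12, n_concussed=500, n_control=2,
                           retention=(500,) * 4)
        truth = GeneratorTruth(beta=(0.0,) * 12, sigma_b=0.1, sigma_e=0.05)
        out = generate_metabolites(generate_cohort(cfg), truth, rng, "m")
        conc = out[out.group == "concussed"]
        v = conc.groupby("subject_id")["m_complete"].mean().var()
        assert v == pytest.approx(0.01 + 0.05**2 / 4, rel=0.15)

    def test_missingness_applied_after_generation(self, rng):
        out = generate_metabolites(
            generate_cohort(CohortConfig(seed=1)), default_ins_cr_truth(), rng, "m"
        )
        assert np.isfinite(out["m_complete"]).all()
        assert out["m"].isna().to_numpy().sum() == (~out["observed"]).sum()
        obs = out[out.observed]
        np.testing.assert_array_equal(obs["m"], obs["m_complete"])

    def test_complete_data_estimator_unbiased_under_attrition(self):
        """Missing-at-random given dRTP: pre-mask data estimate the session
        means without bias even though dropout tracks dRTP."""
        diffs = []
        for s in range(30):
            df = simulate_study(CohortConfig(seed=s), cho_variants=False)
            conc = df[df.group == "concussed"]
            grp = conc.groupby("session")["ins_cr_complete"].mean()
            diffs.append(grp["1YR"] - grp["ACU"])
        truth = default_ins_cr_truth()
        expected = truth.beta[3] + truth.beta[7] * 19 / 33  # 1YR + HOC share
        assert np.mean(diffs) == pytest.approx(expected, abs=0.05)


class TestGenerateVoxelStack:
    def test_null_field_has_no_correlation(self, rng):
        x = rng.normal(size=40)
        spec = PlantedClusterSpec(grid_shape=(16, 16, 16), clusters=[])
        stack = generate_voxel_stack(x, spec, rng)
        rho = voxel.spearman_map(x, stack)
        assert np.mean(np.abs(rho) < 2 / np.sqrt(40)) > 0.90

    def test_planted_correlation_calibrated(self):
        meds = []
        for s in range(25):
            r = np.random.default_rng(s)
            x = r.normal(size=60)
            spec = PlantedClusterSpec(
                grid_shape=(16, 16, 16), clusters=[((8, 8, 8), 3, 0.7)]
            )
            stack = generate_voxel_stack(x, spec, r)
            rho = voxel.spearman_map(x, stack)
            meds.append(np.median(rho[spec.cluster_mask()[stack.mask]]))
        assert np.mean(meds) == pytest.approx(0.7, abs=0.1)

    def test_smoothing_round_trip(self, rng):
        x = rng.normal(size=30)
        spec = PlantedClusterSpec(grid_shape=(20, 20, 20), smoothing_fwhm=6.0)
        stack = generate_voxel_stack(x, spec, rng)
        vols = np.stack([stack.unflatten(v) for v in stack.data[:5]])
        fw = voxel.estimate_fwhm(np.nan_to_num(vols), stack.mask, (3, 3, 3))
        assert np.all(np.abs(fw - 6.0) < 1.0)

    def test_deterministic_under_seed(self):
        x = np.arange(10.0)
        spec = PlantedClusterSpec(grid_shape=(8, 8, 8), clusters=[((4, 4, 4), 2, 0.5)])
        a = generate_voxel_stack(x, spec, np.random.default_rng(3))
        b = generate_voxel_stack(x, spec, np.random.default_rng(3))
        np.testing.assert_array_equal(a.data, b.data)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            PlantedClusterSpec(grid_shape=(4, 4, 4), mask=np.zeros((4, 4, 4), bool))
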