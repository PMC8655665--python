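"""Cohort generator: randomization balance, marginal calibration,
generator/classifier consistency, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stratcare import CohortConfig, OutcomeThresholds, PolicyConfig
from stratcare.allocation import allocate_cohort
from stratcare.cohort import (
    generate_cohort,
    randomize_clinicians,
    simulate_case_outcomes,
    simulate_pathway_and_outcomes,
)
from stratcare.errors import ConfigError, InvalidDesignError
from stratcare.io import write_patient_table


class TestRandomizeClinicians:
    def test_thirty_clinicians_split_fifteen_per_arm(self):
        for seed in range(10):
            arms = list(randomize_clinicians(30, 4, seed=seed).values())
            assert arms.count("stratified") == 15
            assert arms.count("stepped") == 15

    def test_single_block_is_balanced(self):
        arms = list(randomize_clinicians(4, 4, seed=0).values())
        assert sorted(arms) == ["stepped", "stepped", "stratified", "stratified"]

    def test_every_complete_block_prefix_is_balanced(self):
        for seed in range(25):
            arms = list(randomize_clinicians(8, 4, seed=seed).values())
            for start in (0, 4):
                block = arms[start : start + 4]
                assert block.count("stratified") == 2

    def test_too_few_clinicians_rejected(self):
        with pytest.raises(InvalidDesignError):
            randomize_clinicians(1, 4)

    def test_partial_block_disallowed_when_flagged(self):
        with pytest.raises(InvalidDesignError):
            randomize_clinicians(30, 4, allow_partial_final_block=False)

    def test_deterministic_given_seed(self):
        assert randomize_clinicians(30, 4, seed=3) == randomize_clinicians(30, 4, seed=3)


class TestGenerateCohort:
    def test_trial_scale_baseline_mean_within_three_se(self):
        config = CohortConfig()
        cohort = generate_cohort(config, seed=42)
        se = config.phq9_sd / np.sqrt(config.n_patients)
        assert abs(cohort["baseline_phq9"].mean() - 15.47) < 3 * se

    def test_scores_are_integers_within_bounds(self, completed_cohort):
        for col, (lo, hi) in [
            ("baseline_phq9", (0, 27)),
            ("baseline_gad7", (0, 21)),
            ("wsas", (0, 40)),
            ("sapas", (0, 8)),
        ]:
            values = completed_cohort[col]
            assert (values == values.astype(int)).all()
            assert values.between(lo, hi).all()

    def test_truncated_moments_match_numerical_oracle(self):
        """Empirical mean/SD of PHQ-9 with the latent factor switched off vs
        the exact moments of the rounded truncated normal."""
        config = CohortConfig(n_patients=10_000, score_correlation=0.0, seed=0)
        cohort = generate_cohort(config, seed=0)
        # Oracle: direct numerical moments of round(X), X ~ N(mu, sd) truncated
        # to the acceptance window [-0.5, 27.5).
        k = np.arange(0, 28)
        dist = stats.norm(config.phq9_mean, config.phq9_sd)
        pmf = dist.cdf(k + 0.5) - dist.cdf(k - 0.5)
        pmf /= pmf.sum()
        mean = (k * pmf).sum()
        sd = np.sqrt((k**2 * pmf).sum() - mean**2)
        assert abs(cohort["baseline_phq9"].mean() - mean) < 4 * sd / np.sqrt(10_000)
        emp_sd = cohort["baseline_phq9"].std(ddof=0)
        assert abs(emp_sd - sd) < 0.15

    def test_configured_correlation_is_induced(self):
        config = CohortConfig(n_patients=20_000, seed=0)
        cohort = generate_cohort(config, seed=0)
        r = np.corrcoef(cohort["baseline_phq9"], cohort["wsas"])[0, 1]
        assert 0.40 < r < 0.60

    def test_complex_prevalence_exact_by_quantile(self):
        cohort = generate_cohort(CohortConfig(n_patients=951), seed=5)
        assert (cohort["complexity_label"] == "complex").sum() == round(0.237 * 951)

    def test_prognosis_decreases_with_severity(self):
        cohort = generate_cohort(CohortConfig(n_patients=5000), seed=3)
        r = np.corrcoef(cohort["baseline_phq9"], cohort["latent_prognosis"])[0, 1]
        assert r < -0.5

    def test_degenerate_config_is_deterministic_across_seeds(self):
        config = CohortConfig(
            n_patients=50,
            phq9_sd=0, gad7_sd=0, wsas_sd=0, sapas_sd=0, age_sd=0,
            prop_female=1.0, prop_unemployed=0.0, prop_white=1.0,
            diagnosis_probs={"affective": 1.0, "anxiety": 0.0, "PTSD": 0.0, "OCD": 0.0},
        )
        a = generate_cohort(config, seed=1)
        b = generate_cohort(config, seed=99)
        cols = [c for c in a.columns if c not in ("clinician_id", "arm")]
        pd.testing.assert_frame_equal(a[cols], b[cols])

    def test_infeasible_proportions_rejected(self):
        config = CohortConfig(prop_female=1.3)
        with pytest.raises(ConfigError):
            generate_cohort(config)
        bad = CohortConfig(diagnosis_probs={"affective": 0.9, "anxiety": 0.9,
                                            "PTSD": 0.0, "OCD": 0.0})
        with pytest.raises(ConfigError):
            generate_cohort(bad)

    def test_identical_seed_gives_byte_identical_files(self, tmp_path, small_config):
        paths = []
        for name in ("a.csv", "b.csv"):
            cohort = generate_cohort(small_config, seed=21)
            decisions = allocate_cohort(cohort, PolicyConfig(), seed=22)
            done = simulate_pathway_and_outcomes(
                cohort, decisions, small_config, seed=23
            )
            path = tmp_path / name
            write_patient_table(done, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestPathwayAndOutcomes:
    def test_generated_remitters_all_satisfy_rcsi_criteria(self, completed_cohort):
        t = OutcomeThresholds()
        obs = completed_cohort.dropna(subset=["post_phq9"])
        rem = obs[obs["latent_rcsi_phq9"] == 1]
        assert ((rem["post_phq9"] < t.phq9_cutoff)
                & ((rem["baseline_phq9"] - rem["post_phq9"]) >= t.phq9_reliable_change)).all()
        non = obs[obs["latent_rcsi_phq9"] == 0]
        assert (~((non["post_phq9"] < t.phq9_cutoff)
                  & ((non["baseline_phq9"] - non["post_phq9"]) >= t.phq9_reliable_change))).all()

    def test_subthreshold_patients_flagged_not_classified(self, completed_cohort):
        sub = completed_cohort[completed_cohort["baseline_phq9"] < 10]
        assert sub["latent_rcsi_phq9"].isna().all()

    def test_sessions_at_least_one_and_capped(self, completed_cohort):
        assert (completed_cohort["sessions"] >= 1).all()
        lit_only = completed_cohort[completed_cohort["allocated_intensity"] == "LIT"]
        assert (lit_only["sessions"] <= 8).all()
        assert (completed_cohort["sessions_hit"] <= 20).all()

    def test_no_dropouts_when_probability_zero(self, small_config):
        config = CohortConfig(n_patients=200, dropout_prob=0.0)
        cohort = generate_cohort(config, seed=1)
        decisions = allocate_cohort(cohort, PolicyConfig(), seed=1)
        done = simulate_pathway_and_outcomes(cohort, decisions, config, seed=1)
        assert done["dropout"].sum() == 0
        assert (done["sessions"] >= 1).all()

    def test_missing_allocation_rejected(self, small_config):
        cohort = generate_cohort(small_config, seed=2)
        decisions = allocate_cohort(cohort, PolicyConfig(), seed=2).iloc[:-5]
        with pytest.raises(ConfigError):
            simulate_pathway_and_outcomes(cohort, decisions, small_config, seed=2)

    def test_arm_rate_is_mixture_of_subgroup_probabilities(self):
        """Law of total probability: the marginal case remission rate equals
        the complexity-weighted average of the subgroup probabilities."""
        config = CohortConfig(n_patients=20_000, endpoint_missing_prob=0.0)
        cohort = generate_cohort(config, seed=6)
        decisions = allocate_cohort(cohort, PolicyConfig(), seed=6)
        done = simulate_pathway_and_outcomes(cohort, decisions, config, seed=6)
        for arm in ("stratified", "stepped"):
            cases = done[(done["arm"] == arm) & (done["baseline_phq9"] >= 10)]
            weights = cases["complexity_label"].value_counts(normalize=True)
            expected = sum(
                weights.get(level, 0.0) * config.subgroup_rcsi_probs[arm][level]
                for level in ("standard", "complex")
            )
            observed = cases["latent_rcsi_phq9"].mean()
            se = np.sqrt(expected * (1 - expected) / len(cases))
            assert abs(observed - expected) < 4 * se

    def test_case_subsample_simulator_hits_subgroup_probabilities(self):
        df = simulate_case_outcomes("stratified", 4000, 0, seed=0)
        assert abs(df["latent_rcsi_phq9"].mean() - 0.583) < 4 * np.sqrt(0.583 * 0.417 / 4000)
        assert (df["baseline_phq9"] >= 10).all()
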