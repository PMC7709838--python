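import hashlib

import numpy as np
import pytest
from scipy.special import expit

import cogdecline as cd
from cogdecline.cohort import DeclineShift, SubjectLatents
from cogdecline.exceptions import ConfigurationError


def small_config(**kwargs):
    defaults = dict(
        n_intervention=3,
        n_control=3,
        test_specs=cd.default_battery(n_trials=15),
        seed=7,
    )
    defaults.update(kwargs)
    return cd.ScenarioConfig(**defaults)


def table_hash(df):
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


class TestSubjectOccasion:
    def _latents(self, ability=0.0, speed=0.0):
        return SubjectLatents("S1", "intervention", False, ability, speed)

    def test_noiseless_limit_recovers_deterministic_scores(self):
        spec = cd.TestSpec("stroop", n_trials=20, log_rt_offset=-0.5)
        trials = cd.simulate_subject_occasion(
            self._latents(ability=20.0, speed=0.1),
            spec,
            occasion=1,
            prior_attempts=0,
            rt_sigma_log=1e-12,
            rt_shift_seconds=0.2,
            rng=np.random.default_rng(0),
        )
        assert trials["response_correct"].all()
        expected_rt = 0.2 + np.exp(0.1 - 0.5)
        assert np.allclose(trials["rt_seconds"], expected_rt, atol=1e-6)

    def test_saturated_negative_shift_gives_zero_accuracy(self):
        spec = cd.TestSpec("ldt", n_trials=20)
        trials = cd.simulate_subject_occasion(
            self._latents(),
            spec,
            occasion=2,
            prior_attempts=1,
            accuracy_logit_shift=-20.0,
            rng=np.random.default_rng(1),
        )
        assert not trials["response_correct"].any()

    def test_even_odds_accuracy_within_binomial_error(self):
        spec = cd.TestSpec("stroop", n_trials=2000)
        trials = cd.simulate_subject_occasion(
            self._latents(ability=0.0),
            spec,
            occasion=1,
            prior_attempts=0,
            rng=np.random.default_rng(2),
        )
        se = np.sqrt(0.25 / 2000)
        assert abs(trials["response_correct"].mean() - 0.5) < 3 * se

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            cd.simulate_subject_occasion(
                self._latents(),
                cd.TestSpec("stroop"),
                occasion=1,
                prior_attempts=0,
                rt_log_shift=float("nan"),
                rng=np.random.default_rng(0),
            )


class TestSimulateCohort:
    def test_default_scenario_covers_all_cells(self):
        config = cd.ScenarioConfig(test_specs=cd.default_battery(n_trials=10))
        trials, control, truth = cd.simulate_cohort(config)
        cells = trials.groupby(["subject_id", "occasion", "test_id"]).size()
        assert len(cells) == 15 * 9 * 5
        ccells = control.groupby(["subject_id", "occasion", "test_id"]).size()
        assert len(ccells) == 5 * 4 * 5
        assert len(truth) == 15 * 9 + 5 * 4

    def test_identical_seed_gives_byte_identical_exports(self):
        a = cd.simulate_cohort(small_config())
        b = cd.simulate_cohort(small_config())
        for x, y in zip(a, b):
            assert table_hash(x) == table_hash(y)

    def test_different_seed_changes_data(self):
        a, _, _ = cd.simulate_cohort(small_config(seed=1))
        b, _, _ = cd.simulate_cohort(small_config(seed=2))
        assert table_hash(a) != table_hash(b)

    def test_null_scenario_ground_truth_shifts_are_zero(self):
        config = small_config(susceptible_fraction=0.0, decline_profile={})
        _, _, truth = cd.simulate_cohort(config)
        assert (truth["rt_log_shift"] == 0).all()
        assert (truth["accuracy_logit_shift"] == 0).all()
        assert not truth["susceptible"].any()

    def test_control_cohort_never_receives_decline_shifts(self):
        _, _, truth = cd.simulate_cohort(small_config())
        ctrl = truth[truth["cohort"] == "control"]
        assert (ctrl[["rt_log_shift", "accuracy_logit_shift"]] == 0).all().all()

    def test_rt_always_exceeds_nondecision_shift(self):
        config = small_config(rt_shift_seconds=0.2)
        trials, control, _ = cd.simulate_cohort(config)
        assert (trials["rt_seconds"] > 0.2).all()
        assert (control["rt_seconds"] > 0.2).all()

    def test_changing_one_tests_trial_count_leaves_others_untouched(self):
        base = small_config()
        specs = list(cd.default_battery(n_trials=15))
        specs[1] = specs[1].with_trials(25)
        modified = small_config(test_specs=tuple(specs))
        a, _, _ = cd.simulate_cohort(base)
        b, _, _ = cd.simulate_cohort(modified)
        for t in ("nback1", "nback3", "stroop", "ldt"):
            assert table_hash(a[a.test_id == t]) == table_hash(b[b.test_id == t])

    def test_score_path_equals_trial_path(self):
        config = small_config()
        trials, control, _ = cd.simulate_cohort(config)
        via_trials = cd.score_battery(trials)
        via_scores, _, _ = cd.simulate_scores(cd.ScenarioConfig(**{
            k: getattr(config, k)
            for k in ("n_intervention", "n_control", "test_specs", "seed")
        }))
        np.testing.assert_allclose(
            via_trials[["accuracy", "mean_rt"]].to_numpy(),
            via_scores[["accuracy", "mean_rt"]].to_numpy(),
            rtol=1e-13,
        )
        assert via_trials["n_scorable"].tolist() == via_scores["n_scorable"].tolist()


class TestModelCalibration:
    def test_null_accuracy_matches_formula_monte_carlo(self):
        """Empirical accuracy under the null equals the logistic-model mean."""
        config = cd.ScenarioConfig(
            n_intervention=40,
            n_control=2,
            test_specs=cd.default_battery(n_trials=50),
            practice_gain_logit=0.0,
            practice_rt_log=0.0,
            decline_profile={},
            susceptible_fraction=0.0,
            susceptibility_multiplier=1.0,
            occasion_sd_logit=0.0,
            occasion_sd_rt_log=0.0,
            seed=13,
        )
        scores, _, _ = cd.simulate_scores(config)
        oracle_rng = np.random.default_rng(99)
        abilities = config.ability_mean_logit + config.subject_sd_logit * (
            oracle_rng.standard_normal(100_000)
        )
        for spec in config.test_specs:
            expected = expit(abilities - spec.difficulty_logit).mean()
            part = scores[scores["test_id"] == spec.test_id]
            observed = part["accuracy"].mean()
            n_eff = part["n_scorable"].sum()
            se = np.sqrt(expected * (1 - expected) / n_eff + config.subject_sd_logit**2 / len(part))
            assert abs(observed - expected) < 4 * se

    @pytest.mark.parametrize("metric", ["rt", "accuracy"])
    def test_injected_decline_moves_population_means_monotonically(self, metric):
        shifts = [0.0, 0.15, 0.4]
        means = []
        for s in shifts:
            profile = {
                occ: DeclineShift(s, 0.0) if metric == "rt" else DeclineShift(0.0, -s)
                for occ in range(2, 10)
            }
            config = cd.ScenarioConfig(
                n_intervention=4,
                n_control=2,
                test_specs=(cd.TestSpec("stroop", n_trials=5000),),
                decline_profile=profile,
                susceptible_fraction=0.0,
                susceptibility_multiplier=1.0,
                seed=3,
            )
            scores, _, _ = cd.simulate_scores(config)
            post = scores[scores["occasion"] > 1]
            means.append(post["mean_rt" if metric == "rt" else "accuracy"].mean())
        if metric == "rt":
            assert means[0] <= means[1] <= means[2]
        else:
            assert means[0] >= means[1] >= means[2]


class TestScenarioValidation:
    def test_baseline_decline_shift_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(decline_profile={1: DeclineShift(0.1, 0.0)})

    def test_profile_occasion_outside_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(decline_profile={12: DeclineShift(0.1, 0.0)})

    def test_bad_susceptible_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(susceptible_fraction=1.5)
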