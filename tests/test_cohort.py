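import numpy as np
import pandas as pd
import pytest
from scipy import stats

from precom.cohort import (
    DEFAULT_PRIORS,
    SubjectGenerativeSpec,
    draw_subject_params,
    simulate_cohort,
    simulate_subject_task,
    simulate_trial,
)
from precom.design import TaskDesign, TrialSpec
from precom.io import validate_trials
from precom.valuation import p_choice_lr, subjective_value


def _point_spec(eps=0.25, gamma=8.0, theta=3.0, b=0.0, **kwargs):
    prior = {
        "epsilon": {"dist": "point", "value": eps},
        "kappa": {"dist": "point", "value": eps},
        "gamma_effort": {"dist": "point", "value": gamma},
        "gamma_delay": {"dist": "point", "value": gamma},
        "theta_effort": {"dist": "point", "value": theta},
        "theta_delay": {"dist": "point", "value": theta},
        "b_effort": {"dist": "point", "value": b},
        "b_delay": {"dist": "point", "value": b},
    }
    return draw_subject_params(prior_config=prior, seed=5, **kwargs)


def _standard_only_design(n, cost=4.0, task="effort"):
    trials = tuple(
        TrialSpec(task=task, trial_type="standard", cost_level=cost, trial_index=i)
        for i in range(n)
    )
    return TaskDesign(task=task, trials=trials, seed=0)


class TestParameterDraws:
    def test_point_priors_are_exact(self):
        spec = _point_spec(eps=0.3, gamma=12.0, theta=2.5, b=-1.0)
        cp = spec.choice_params["effort"]
        assert (cp.discount_rate, cp.inverse_temperature) == (0.3, 12.0)
        pp = spec.precom_params["delay"]
        assert (pp.sensitivity, pp.bias) == (2.5, -1.0)

    def test_draws_respect_bounds_and_prior_mean(self):
        eps = np.array(
            [
                draw_subject_params(seed=s).choice_params["effort"].discount_rate
                for s in range(400)
            ]
        )
        assert np.all((eps >= 0) & (eps <= 1))
        p = DEFAULT_PRIORS["epsilon"]
        a, b = (p["low"] - p["mean"]) / p["sd"], (p["high"] - p["mean"]) / p["sd"]
        dist = stats.truncnorm(a, b, loc=p["mean"], scale=p["sd"])
        se = dist.std() / np.sqrt(len(eps))
        assert abs(eps.mean() - dist.mean()) < 3 * se

    def test_unknown_prior_key_rejected(self):
        with pytest.raises(ValueError, match="unknown prior"):
            draw_subject_params(prior_config={"zeta": {"dist": "point", "value": 1}})

    def test_unbounded_prior_rejected(self):
        with pytest.raises(ValueError):
            draw_subject_params(
                prior_config={"epsilon": {"dist": "uniform", "low": 0.0, "high": np.inf}}
            )

    def test_wp_agent_requires_iota(self):
        spec = draw_subject_params(seed=3, generative_model="wp")
        assert 0.0 <= spec.choice_params["effort"].willpower <= 1.0
        with pytest.raises(ValueError, match="iota"):
            SubjectGenerativeSpec(
                subject_id="X",
                reward_set=spec.reward_set,
                choice_params={"effort": spec.choice_params["effort"].__class__(0.2, 5.0)},
                precom_params=spec.precom_params,
                generative_model="wp",
            )


class TestTrialSimulation:
    def test_deterministic_limit_high_temperature(self, rng):
        spec = _point_spec(eps=0.05, gamma=60.0, opt_out_prob={"effort": 0.0, "delay": 0.0})
        design = _standard_only_design(200)
        rec = simulate_subject_task(spec, design, rng)
        assert (rec["choice"] == "LR").all()
        assert rec["achieved_LR"].all()

    def test_precommitted_trial_without_failure_always_achieves(self, rng):
        spec = _point_spec(b=5.0, theta=0.0, achievement_failure_prob=0.0)
        trial = TrialSpec("effort", "precommitment", 6.0, 0)
        recs = [simulate_trial(spec, trial, rng) for _ in range(50)]
        pre = [r for r in recs if r["precommit"] == "yes"]
        assert pre and all(r["achieved_LR"] and r["choice"] == "LR" for r in pre)

    def test_choice_frequency_matches_softmax_probability(self, rng):
        spec = _point_spec(eps=0.25, gamma=2.0, opt_out_prob={"effort": 0.0, "delay": 0.0})
        cost = 4.0
        design = _standard_only_design(10_000, cost=cost)
        rec = simulate_subject_task(spec, design, rng)
        rs = spec.reward_set
        dv = subjective_value(rs.m_lr, cost, 0.25) - rs.m_sr
        p = float(p_choice_lr(dv, 2.0))
        lo, hi = stats.binom.interval(0.99, len(design), p)
        assert lo <= (rec["choice"] == "LR").sum() <= hi


class TestCohortSimulation:
    def test_single_subject_record_count(self):
        cohort = simulate_cohort(1, seed=0)
        assert len(cohort.records) == 120
        assert set(cohort.records["task"].unique()) == {"effort", "delay"}

    def test_same_seed_is_bit_identical(self):
        a = simulate_cohort(3, seed=77)
        b = simulate_cohort(3, seed=77)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.true_params, b.true_params)

    def test_different_seed_changes_outcomes_not_shape(self):
        a = simulate_cohort(3, seed=1)
        b = simulate_cohort(3, seed=2)
        assert a.records.shape == b.records.shape
        assert not a.records.equals(b.records)

    def test_nonpositive_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(0)

    def test_opt_out_rate_near_configured_lapse(self):
        cohort = simulate_cohort(
            40, seed=11, tasks=("effort",), opt_out_prob={"effort": 0.005}
        )
        std = cohort.records[cohort.records["trial_type"] == "standard"]
        lr = std[std["choice"] == "LR"]
        k, n = int(lr["opt_out"].sum()), len(lr)
        lo, hi = stats.binom.interval(0.999, n, 0.005)
        assert lo <= k <= hi

    @pytest.mark.parametrize("generative", ["mm", "wp"])
    @pytest.mark.parametrize("seed", [0, 13])
    def test_record_invariants_hold(self, generative, seed):
        cohort = simulate_cohort(4, seed=seed, generative_model=generative)
        validate_trials(cohort.records)  # raises on any violated invariant
        rec = cohort.records
        std = rec[rec["trial_type"] == "standard"]
        assert (std["precommit"] == "").all()

    def test_precommit_override_forces_rates(self):
        always = simulate_cohort(2, seed=4, precommit_override=1.0, tasks=("effort",))
        pre = always.records[always.records["trial_type"] == "precommitment"]
        assert (pre["precommit"] == "yes").all()
        never = simulate_cohort(2, seed=4, precommit_override=0.0, tasks=("effort",))
        pre = never.records[never.records["trial_type"] == "precommitment"]
        assert (pre["precommit"] == "no").all()

    def test_willpower_suppression_raises_lr_choice_probability(self):
        """Closed form: a WP agent with iota < 1 has larger net LR value than
        an MM agent with the same discount rate, hence higher P(LR)."""
        spec_wp = _point_spec(eps=0.3, gamma=3.0, generative_model="wp")
        rs = spec_wp.reward_set
        iota = spec_wp.choice_params["effort"].willpower
        for cost in (2.0, 4.0, 6.0):
            sv = subjective_value(rs.m_lr, cost, 0.3)
            p_mm = p_choice_lr(sv - rs.m_sr, 3.0)
            p_wp = p_choice_lr(sv - iota * rs.m_sr, 3.0)
            if iota < 1.0:
                assert p_wp > p_mm

    def test_generated_designs_match_task_structure(self):
        cohort = simulate_cohort(2, seed=9)
        for (_, task), grp in cohort.records.groupby(["subject_id", "task"]):
            assert len(grp) == 60
            assert grp["trial_type"].value_counts().to_dict() == {
                "standard": 30,
                "precommitment": 30,
            }
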