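import math

import numpy as np
import pytest

from precom.cohort import simulate_cohort
from precom.fitting import (
    FitSpec,
    InsufficientDataError,
    choice_design_matrix,
    fit_subject,
    fit_subject_all_models,
    fit_wp_achievement,
    negative_log_likelihood,
    select_fit_data,
)


def _force_precommit_pattern(records, n_yes):
    """Rewrite one subject's effort-task precommitment decisions to a fixed
    yes/no split (keeping record-level invariants intact)."""
    rec = records.copy()
    mask = (rec["trial_type"] == "precommitment") & (rec["task"] == "effort")
    idx = rec[mask].index
    rec.loc[idx, "precommit"] = ["yes"] * n_yes + ["no"] * (len(idx) - n_yes)
    yes_idx = idx[:n_yes]
    rec.loc[yes_idx, "choice"] = "LR"
    rec.loc[yes_idx, "opt_out"] = False
    rec.loc[yes_idx, "achieved_LR"] = True
    return rec


class TestSelectFitData:
    @pytest.mark.parametrize(
        "n_yes, expected_choice_trials", [(30, 30), (0, 60), (16, 44)]
    )
    def test_choice_subset_counts(self, n_yes, expected_choice_trials):
        cohort = simulate_cohort(1, seed=2, tasks=("effort",))
        rec = _force_precommit_pattern(cohort.records, n_yes)
        subset = select_fit_data(rec, "mm_choice", "S000", "effort")
        assert len(subset) == expected_choice_trials

    def test_precom_subset_is_all_precommitment_trials(self):
        cohort = simulate_cohort(1, seed=2, tasks=("effort",))
        subset = select_fit_data(cohort.records, "mm_precom", "S000", "effort")
        assert len(subset) == 30
        assert (subset["trial_type"] == "precommitment").all()

    def test_missing_subject_raises(self):
        cohort = simulate_cohort(1, seed=2)
        with pytest.raises(InsufficientDataError):
            select_fit_data(cohort.records, "mm_choice", "S999", "effort")

    def test_unknown_model_rejected(self):
        cohort = simulate_cohort(1, seed=2)
        with pytest.raises(ValueError):
            select_fit_data(cohort.records, "logit", "S000", "effort")


class TestNegativeLogLikelihood:
    def test_chance_parameters_give_n_ln2(self, tiny_trials):
        # gamma = 0 makes every predicted probability exactly 0.5
        nll = negative_log_likelihood([0.3, 0.0], tiny_trials, "mm_choice", "choice",
                                      m_lr=7.5, m_sr=3.5)
        assert nll == pytest.approx(len(tiny_trials) * math.log(2))

    def test_matches_per_trial_loop_oracle(self, tiny_trials):
        """Vectorized likelihood equals an explicit per-trial summation."""
        m_lr, m_sr, k, g = 7.5, 3.5, 0.22, 4.0
        nll = negative_log_likelihood([k, g], tiny_trials, "mm_choice", "choice",
                                      m_lr=m_lr, m_sr=m_sr)
        total = 0.0
        for _, row in tiny_trials.iterrows():
            sv = m_lr / (1 + k * row["cost_level"])
            p = 1.0 / (1.0 + math.exp(-g * (sv - m_sr)))
            p = min(max(p, 1e-12), 1 - 1e-12)
            total -= math.log(p) if row["choice"] == "LR" else math.log(1 - p)
        assert nll == pytest.approx(total, abs=1e-10)

    def test_precom_model_loop_oracle(self, tiny_trials):
        pre = tiny_trials[tiny_trials["trial_type"] == "precommitment"]
        theta, b, k = 1.5, -0.4, 0.22
        nll = negative_log_likelihood([theta, b], pre, "mm_precom", "precommit_decision",
                                      m_lr=7.5, m_sr=3.5, sv_discount_rate=k)
        total = 0.0
        for _, row in pre.iterrows():
            v = 7.5 / (1 + k * row["cost_level"]) - 3.5
            p = 1.0 / (1.0 + math.exp(-(theta * v + b)))
            total -= math.log(p) if row["precommit"] == "yes" else math.log(1 - p)
        assert nll == pytest.approx(total, abs=1e-10)

    def test_perfect_separation_approaches_zero(self, tiny_trials):
        # all-LR outcomes with huge gamma and positive dV: NLL -> 0 monotonically
        rec = tiny_trials.copy()
        rec["choice"] = "LR"
        nlls = [
            negative_log_likelihood([0.05, g], rec, "mm_choice", "choice", 7.5, 3.5)
            for g in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(nlls, nlls[1:]))
        assert negative_log_likelihood([0.05, 100.0], rec, "mm_choice", "choice", 7.5, 3.5) < 1e-6

    def test_nan_parameters_rejected(self, tiny_trials):
        with pytest.raises(ValueError):
            negative_log_likelihood([np.nan, 1.0], tiny_trials, "mm_choice", "choice", 7.5, 3.5)


class TestFitSpec:
    def test_outcome_model_consistency(self):
        with pytest.raises(ValueError):
            FitSpec(model="mm_choice", outcome="precommit_decision")
        with pytest.raises(ValueError):
            FitSpec(model="mm_precom", outcome="choice")


class TestFitSubject:
    def test_refit_same_seed_identical(self, mm_cohort):
        subset = select_fit_data(mm_cohort.records, "mm_choice", "S000", "effort")
        row = mm_cohort.true_params.query("subject_id == 'S000'").iloc[0]
        spec = FitSpec("mm_choice", "choice", n_starts=6, seed=11)
        a = fit_subject(subset, row["m_lr"], row["m_sr"], spec)
        b = fit_subject(subset, row["m_lr"], row["m_sr"], spec)
        assert a.estimates == b.estimates
        assert a.log_likelihood == b.log_likelihood

    def test_precom_fit_requires_fixed_subjective_values(self, mm_cohort):
        subset = select_fit_data(mm_cohort.records, "mm_precom", "S000", "effort")
        with pytest.raises(ValueError, match="sv_discount_rate"):
            fit_subject(subset, 7.5, 3.5, FitSpec("mm_precom", "precommit_decision"))

    def test_cascade_outputs_five_fits(self, mm_cohort):
        row = mm_cohort.true_params.query("subject_id == 'S001'").iloc[0]
        results = fit_subject_all_models(
            mm_cohort.records, "S001", "effort", row["m_lr"], row["m_sr"],
            n_starts=5, seed=0,
        )
        labels = {(r.model, r.outcome) for r in results}
        assert labels == {
            ("mm_choice", "choice"),
            ("wp_choice", "choice"),
            ("wp_choice", "achievement"),
            ("mm_precom", "precommit_decision"),
            ("wp_precom", "precommit_decision"),
        }
        for r in results:
            assert r.log_likelihood <= 0
            assert r.bic == pytest.approx(
                len(r.estimates) * np.log(r.n_trials) - 2 * r.log_likelihood
            )

    def test_degenerate_all_achieved_subject_unreliable(self):
        cohort = simulate_cohort(
            1, seed=6, tasks=("effort",),
            prior_config={
                "epsilon": {"dist": "point", "value": 0.0},
                "gamma_effort": {"dist": "point", "value": 50.0},
            },
            opt_out_prob={"effort": 0.0},
        )
        row = cohort.true_params.iloc[0]
        fit = fit_wp_achievement(cohort.records, "S000", "effort",
                                 row["m_lr"], row["m_sr"], n_starts=5, seed=0)
        assert fit.reliable is False

    def test_high_opt_out_raises_iota_reward_vs_iota_choice(self):
        """Opt-outs break achievement but not choice: the execution phase then
        behaves as if suppression of the SR partially failed, so the
        achievement fit yields a *larger* iota (1 = no suppression) than the
        choice fit."""
        cohort = simulate_cohort(
            20, seed=9, tasks=("effort",), generative_model="wp",
            opt_out_prob={"effort": 0.3},
        )
        diffs = []
        for _, row in cohort.true_params.iterrows():
            subset = select_fit_data(cohort.records, "wp_choice", row["subject_id"], "effort")
            choice_fit = fit_subject(subset, row["m_lr"], row["m_sr"],
                                     FitSpec("wp_choice", "choice", n_starts=5, seed=1))
            ach_fit = fit_subject(subset, row["m_lr"], row["m_sr"],
                                  FitSpec("wp_choice", "achievement", n_starts=5, seed=1))
            diffs.append(ach_fit.estimates["willpower"] - choice_fit.estimates["willpower"])
        assert np.mean(diffs) > 0


class TestChoiceDesignMatrix:
    def test_outcome_column_selection(self, tiny_trials):
        X, y_choice = choice_design_matrix(tiny_trials, 7.5, 3.5, "choice")
        _, y_ach = choice_design_matrix(tiny_trials, 7.5, 3.5, "achievement")
        assert list(X.columns) == ["m_lr", "m_sr", "cost"]
        assert y_choice.sum() == (tiny_trials["choice"] == "LR").sum()
        assert y_ach.sum() == tiny_trials["achieved_LR"].sum()
        with pytest.raises(ValueError):
            choice_design_matrix(tiny_trials, 7.5, 3.5, "precommit_decision")
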