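import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.base import clone

from precom.cohort import draw_subject_params, simulate_subject_task
from precom.design import generate_task_design
from precom.models import ChoiceModel, PrecommitModel, negative_log_likelihood_bernoulli


def _simulated_choice_data(eps=0.2, gamma=6.0, n_trials=600, seed=3):
    prior = {
        "epsilon": {"dist": "point", "value": eps},
        "gamma_effort": {"dist": "point", "value": gamma},
    }
    spec = draw_subject_params(prior_config=prior, seed=seed,
                               opt_out_prob={"effort": 0.0})
    reps = max(n_trials // 6, 1)
    design = generate_task_design("effort", reps_per_level_per_type=reps, seed=seed)
    rec = simulate_subject_task(spec, design, np.random.default_rng(seed))
    X = pd.DataFrame(
        {"m_lr": spec.reward_set.m_lr, "m_sr": spec.reward_set.m_sr,
         "cost": rec["cost_level"].to_numpy()}
    )
    y = (rec["choice"] == "LR").to_numpy(dtype=int)
    return X, y, spec


def _grid_search_mle(X, y, kind="mm"):
    """Independent dense-grid likelihood search (cross-check oracle)."""
    m_lr = X["m_lr"].to_numpy()
    m_sr = X["m_sr"].to_numpy()
    cost = X["cost"].to_numpy()
    best = (np.inf, None)
    iotas = [1.0] if kind == "mm" else np.linspace(0, 1, 21)
    for k in np.linspace(0, 1, 101):
        sv = m_lr / (1 + k * cost)
        for g in np.linspace(0.1, 40, 120):
            for iota in iotas:
                p = expit(g * (sv - iota * m_sr))
                nll = negative_log_likelihood_bernoulli(p, y)
                if nll < best[0]:
                    best = (nll, (k, g, iota))
    return best


class TestSklearnProtocol:
    def test_get_set_params_and_clone(self):
        est = ChoiceModel(kind="wp", n_starts=5, seed=3)
        params = est.get_params()
        assert params["kind"] == "wp" and params["n_starts"] == 5
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(seed=9)
        assert est.seed == 9

    def test_fitted_attributes_and_predict(self):
        X, y, _ = _simulated_choice_data(n_trials=120)
        est = ChoiceModel(n_starts=6, seed=0).fit(X, y)
        for attr in ("discount_rate_", "inverse_temperature_", "log_likelihood_",
                     "bic_", "pseudo_r2_", "percent_correct_", "reliable_"):
            assert hasattr(est, attr)
        proba = est.predict_proba(X)
        assert proba.shape == (len(y), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(X)) <= {0, 1}

    def test_unfitted_predict_raises(self):
        X, y, _ = _simulated_choice_data(n_trials=30)
        with pytest.raises(AttributeError):
            ChoiceModel().predict_proba(X)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ChoiceModel().fit(pd.DataFrame({"m_lr": [], "m_sr": [], "cost": []}), [])
        X = pd.DataFrame({"m_lr": [7.0], "m_sr": [3.0], "cost": [2.0]})
        with pytest.raises(ValueError):
            ChoiceModel().fit(X, [2])  # non-binary
        with pytest.raises(ValueError):
            ChoiceModel(kind="xx").fit(X, [1])


class TestChoiceModelFit:
    def test_recovers_generating_parameters(self):
        """MLE on 600 trials from a known agent recovers the discount rate
        within +/-0.05, agreeing with an independent dense-grid search."""
        X, y, spec = _simulated_choice_data(eps=0.2, gamma=6.0, n_trials=600)
        est = ChoiceModel(n_starts=10, seed=1).fit(X, y)
        assert est.discount_rate_ == pytest.approx(0.2, abs=0.05)
        grid_nll, (k_grid, *_rest) = _grid_search_mle(X, y, "mm")
        assert est.discount_rate_ == pytest.approx(k_grid, abs=0.02)
        assert -est.log_likelihood_ <= grid_nll + 1e-6  # MLE at least as good

    def test_deterministic_given_seed(self):
        X, y, _ = _simulated_choice_data(n_trials=60)
        a = ChoiceModel(kind="wp", n_starts=8, seed=5).fit(X, y)
        b = ChoiceModel(kind="wp", n_starts=8, seed=5).fit(X, y)
        assert a.params_ == b.params_
        assert a.log_likelihood_ == b.log_likelihood_

    def test_wp_with_iota_pinned_reproduces_mm_likelihood(self):
        X, y, _ = _simulated_choice_data(n_trials=120)
        mm = ChoiceModel(kind="mm", n_starts=8, seed=2).fit(X, y)
        wp = ChoiceModel(kind="wp", bounds={"willpower": (1.0, 1.0)},
                         n_starts=8, seed=2).fit(X, y)
        assert wp.log_likelihood_ == pytest.approx(mm.log_likelihood_, abs=1e-6)
        assert wp.willpower_ == 1.0

    def test_free_wp_nests_mm(self):
        X, y, _ = _simulated_choice_data(n_trials=120, seed=8)
        mm = ChoiceModel(kind="mm", n_starts=8, seed=2).fit(X, y)
        wp = ChoiceModel(kind="wp", n_starts=8, seed=2).fit(X, y)
        assert wp.log_likelihood_ >= mm.log_likelihood_ - 1e-6
        assert wp.bic_ > mm.bic_ - np.log(len(y))  # extra parameter costs ln n

    def test_no_outcome_variance_flagged_unreliable(self):
        X = pd.DataFrame({"m_lr": 7.5, "m_sr": 3.5, "cost": [2.0, 4.0, 6.0] * 10})
        est = ChoiceModel(kind="wp", n_starts=6, seed=0).fit(X, np.ones(30, dtype=int))
        assert est.reliable_ is False
        assert est.outcome_variance_ is False

    def test_bic_and_pseudo_r2_bookkeeping(self):
        X, y, _ = _simulated_choice_data(n_trials=60)
        est = ChoiceModel(n_starts=6, seed=0).fit(X, y)
        assert est.bic_ == pytest.approx(
            2 * np.log(est.n_trials_) - 2 * est.log_likelihood_
        )
        assert 0.0 <= est.pseudo_r2_ <= 1.0


class TestPrecommitModelFit:
    def _precom_data(self, theta=2.0, b=-0.5, n=300, seed=4, kind="mm", iota=0.5):
        rng = np.random.default_rng(seed)
        sv_lr = rng.uniform(1.5, 6.0, n)
        sv_sr = np.full(n, 3.5)
        v = (sv_lr - sv_sr) if kind == "mm" else (iota * sv_sr - sv_lr)
        y = (rng.random(n) < expit(theta * v + b)).astype(int)
        return pd.DataFrame({"sv_lr": sv_lr, "sv_sr": sv_sr}), y

    def test_recovers_sensitivity_and_bias(self):
        X, y = self._precom_data(theta=2.0, b=-0.5, n=2000)
        est = PrecommitModel(kind="mm", n_starts=8, seed=0).fit(X, y)
        assert est.sensitivity_ == pytest.approx(2.0, abs=0.4)
        assert est.bias_ == pytest.approx(-0.5, abs=0.4)

    def test_wp_requires_iota_reward(self):
        X, y = self._precom_data(kind="mm")
        with pytest.raises(ValueError, match="iota_reward"):
            PrecommitModel(kind="wp").fit(X, y)
        with pytest.raises(ValueError):
            PrecommitModel(kind="wp", iota_reward=1.5).fit(X, y)

    def test_wp_value_sign_convention(self):
        X = pd.DataFrame({"sv_lr": [2.0, 5.0], "sv_sr": [4.0, 4.0]})
        model = PrecommitModel(kind="wp", iota_reward=1.0)
        np.testing.assert_allclose(model.precommitment_values(X), [2.0, -1.0])

    def test_saturated_regime_still_converges(self):
        """Deep-saturation fits (all-reject with strongly negative value)
        must land on the boundary flat fit, not stall mid-box."""
        X = pd.DataFrame({"sv_lr": np.full(40, 6.0), "sv_sr": np.full(40, 3.5)})
        y = np.zeros(40, dtype=int)
        est = PrecommitModel(kind="wp", iota_reward=0.2, n_starts=10, seed=0).fit(X, y)
        p = est.predict_proba(X)[:, 1]
        assert np.all(p < 0.05)
        assert est.log_likelihood_ > 40 * np.log(0.05)
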