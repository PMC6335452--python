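"""Scikit-learn-style estimators for the MM and WP choice and precommitment models.

:class:`ChoiceModel` fits trial-by-trial binary decisions between a costly
large reward (LR) and a free small reward (SR) by bounded multi-start
maximum likelihood under a softmax rule over net motivational value:

    MM:  dV = M_LR / (1 + k * cost) - M_SR
    WP:  dV = M_LR / (1 + k * cost) - iota * M_SR
    P(LR) = 1 / (1 + exp(-gamma * dV))

:class:`PrecommitModel` fits precommitment decisions given per-trial
subjective values fixed from a previously fitted choice model:

    MM:  V = SV_LR - SV_SR          WP:  V = iota_reward * SV_SR - SV_LR
    P(precommit) = 1 / (1 + exp(-(theta * V + b)))

Both estimators follow the sklearn protocol (``get_params``/``set_params``,
fitted attributes with a trailing underscore, ``fit``/``predict_proba``) and
compose with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, xlogy
from sklearn.base import BaseEstimator, ClassifierMixin

P_CLAMP = 1e-12  # likelihood floor keeping the objective finite at bound edges
AGREE_TOL = 1e-3  # starts within this NLL gap of the best count as agreeing
TIE_TOL = 1e-9  # NLL gap treated as an exact tie (broken lexicographically)

DEFAULT_CHOICE_BOUNDS = {
    "discount_rate": (0.0, 1.0),
    "inverse_temperature": (0.0, 100.0),
    "willpower": (0.0, 1.0),
}
DEFAULT_PRECOM_BOUNDS = {
    "sensitivity": (0.0, 100.0),
    "bias": (-5.0, 5.0),
}

__all__ = ["ChoiceModel", "PrecommitModel", "negative_log_likelihood_bernoulli"]


def negative_log_likelihood_bernoulli(p, y):
    """Summed Bernoulli negative log-likelihood with probabilities clamped
    to ``[1e-12, 1 - 1e-12]`` so the objective stays finite at the bounds."""
    p = np.clip(np.asarray(p, dtype=float), P_CLAMP, 1.0 - P_CLAMP)
    y = np.asarray(y, dtype=float)
    return float(-np.sum(xlogy(y, p) + xlogy(1.0 - y, 1.0 - p)))


def _nll_logit(a, y):
    """Exact Bernoulli NLL on the logit scale, -sum log sigma((2y-1) a),
    via softplus; smooth and overflow-safe even deep in saturation (where a
    clamped-probability objective would go flat and stall the optimizer)."""
    s = np.where(y == 1.0, -a, a)
    return float(np.sum(np.logaddexp(0.0, s)))


def _multistart(objective, bounds, n_starts, seed, tol):
    """Bounded L-BFGS-B from ``n_starts`` seeded uniform starts.

    The first start is the midpoint of the box; the rest are uniform draws.
    Returns the winning parameter vector, its NLL, and the number of starts
    whose converged NLL lies within ``AGREE_TOL`` of the best. Exact ties
    are broken by the lexicographically smallest parameter vector so the
    result is deterministic given the seed.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    starts += [rng.uniform(lo, hi) for _ in range(max(n_starts - 1, 0))]

    results = []
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        results.append((float(res.fun), tuple(np.clip(res.x, lo, hi))))
    if not results:
        raise RuntimeError("no optimization starts were run")
    best_nll = min(f for f, _ in results)
    if not np.isfinite(best_nll):
        raise RuntimeError("all optimization starts failed to produce a finite objective")
    tied = [x for f, x in results if f <= best_nll + TIE_TOL]
    best_x = min(tied)  # lexicographic tie-break
    n_agree = sum(f <= best_nll + AGREE_TOL for f, _ in results)
    return np.array(best_x), best_nll, n_agree


def _columns(X, names):
    """Extract named columns from a DataFrame or positional columns from an
    (n, len(names)) array."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in names if c not in X.columns]
        if missing:
            raise ValueError(f"X is missing columns {missing}")
        return [X[c].to_numpy(dtype=float) for c in names]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(names):
        raise ValueError(f"X must have columns {names} (shape (n, {len(names)}))")
    return [arr[:, i] for i in range(len(names))]


def _validate_binary(y, n):
    y = np.asarray(y)
    if y.shape != (n,):
        raise ValueError("y length must match X")
    y = y.astype(float)
    if np.any(np.isnan(y)) or not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary (0/1)")
    return y


class _BoundedMLEMixin:
    """Shared post-fit bookkeeping: likelihood summaries on the training data."""

    def _finalize(self, nll, y, p_hat, n_agree):
        self.log_likelihood_ = -nll
        self.n_trials_ = int(y.size)
        k = len(self._free_names())
        self.n_params_ = k
        self.bic_ = k * np.log(self.n_trials_) - 2.0 * self.log_likelihood_
        ll_null = self.n_trials_ * np.log(0.5)
        self.pseudo_r2_ = float(1.0 - self.log_likelihood_ / ll_null)
        self.percent_correct_ = float(np.mean((p_hat >= 0.5) == (y == 1.0)))
        self.n_starts_agreeing_ = int(n_agree)
        self.outcome_variance_ = bool(0.0 < y.mean() < 1.0)
        self.reliable_ = bool(self.outcome_variance_ and n_agree >= 2)


class ChoiceModel(_BoundedMLEMixin, ClassifierMixin, BaseEstimator):
    """MM or WP softmax choice model fitted by multi-start bounded MLE.

    Parameters
    ----------
    kind : {"mm", "wp"}
        MM has free parameters (discount rate k, inverse temperature gamma);
        WP adds the willpower suppression iota in [0, 1].
    bounds : dict, optional
        Override the default parameter boxes
        (k in [0,1], gamma in [0,100], iota in [0,1]). Pinning a parameter
        (equal bounds) is allowed, e.g. ``{"willpower": (1.0, 1.0)}``.
    n_starts : int
        Number of optimization starts (first is the box midpoint, the rest
        seeded uniform draws).
    seed : int
        Seed for the start draws; fits are deterministic given it.
    tol : float
        ``ftol`` convergence tolerance on the objective.

    Attributes
    ----------
    discount_rate_, inverse_temperature_, willpower_ : float
        Maximum-likelihood estimates (``willpower_`` only for kind="wp").
    log_likelihood_, bic_, pseudo_r2_, percent_correct_ : float
        Fit summaries on the training trials (pseudo R² against a fixed
        chance-prediction null, P = 0.5).
    reliable_ : bool
        False when the outcome has no variance or fewer than two starts
        agree on the optimum.
    """

    def __init__(self, kind="mm", bounds=None, n_starts=20, seed=0, tol=1e-8):
        self.kind = kind
        self.bounds = bounds
        self.n_starts = n_starts
        self.seed = seed
        self.tol = tol

    # -- internals -----------------------------------------------------
    def _free_names(self):
        names = ["discount_rate", "inverse_temperature"]
        if self.kind == "wp":
            names.append("willpower")
        return names

    def _bounds(self):
        merged = dict(DEFAULT_CHOICE_BOUNDS)
        if self.bounds:
            merged.update(self.bounds)
        return [tuple(merged[name]) for name in self._free_names()]

    def _delta_v(self, theta_vec, m_lr, m_sr, cost):
        k = theta_vec[0]
        sv_lr = m_lr / (1.0 + k * cost)
        if self.kind == "wp":
            return sv_lr - theta_vec[2] * m_sr
        return sv_lr - m_sr

    def _nll_and_grad(self, theta_vec, m_lr, m_sr, cost, y):
        k, gamma = theta_vec[0], theta_vec[1]
        denom = 1.0 + k * cost
        sv_lr = m_lr / denom
        dv = sv_lr - (theta_vec[2] * m_sr if self.kind == "wp" else m_sr)
        p = expit(gamma * dv)
        nll = _nll_logit(gamma * dv, y)
        resid = p - y  # d(nll)/d(gamma*dv)
        d_dv_dk = -m_lr * cost / denom**2
        grad = [float(np.sum(resid * gamma * d_dv_dk)), float(np.sum(resid * dv))]
        if self.kind == "wp":
            grad.append(float(np.sum(resid * gamma * (-m_sr))))
        return nll, np.array(grad)

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        """Fit to trials with features (M_LR, M_SR, cost) and binary LR choice y."""
        if self.kind not in ("mm", "wp"):
            raise ValueError("kind must be 'mm' or 'wp'")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        m_lr, m_sr, cost = _columns(X, ["m_lr", "m_sr", "cost"])
        if m_lr.size == 0:
            raise ValueError("cannot fit on an empty trial set")
        y = _validate_binary(y, m_lr.size)

        best, nll, n_agree = _multistart(
            lambda t: self._nll_and_grad(t, m_lr, m_sr, cost, y),
            self._bounds(),
            self.n_starts,
            self.seed,
            self.tol,
        )
        self.discount_rate_ = float(best[0])
        self.inverse_temperature_ = float(best[1])
        if self.kind == "wp":
            self.willpower_ = float(best[2])
        self.params_ = dict(zip(self._free_names(), (float(v) for v in best)))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 3
        p_hat = expit(self.inverse_temperature_ * self._delta_v(best, m_lr, m_sr, cost))
        # report the clamped-probability likelihood (the package's likelihood
        # contract); optimization itself used the exact logit-scale objective
        self._finalize(negative_log_likelihood_bernoulli(p_hat, y), y, p_hat, n_agree)
        return self

    def decision_values(self, X):
        """Net motivational value dV per trial under the fitted parameters."""
        self._check_fitted()
        m_lr, m_sr, cost = _columns(X, ["m_lr", "m_sr", "cost"])
        vec = [self.params_[n] for n in self._free_names()]
        return self._delta_v(vec, m_lr, m_sr, cost)

    def subjective_values(self, X):
        """Per-trial (SV_LR, SV_SR) under the fitted discount rate; the SR is
        free/immediate so SV_SR = M_SR."""
        self._check_fitted()
        m_lr, m_sr, cost = _columns(X, ["m_lr", "m_sr", "cost"])
        return m_lr / (1.0 + self.discount_rate_ * cost), m_sr

    def predict_proba(self, X):
        self._check_fitted()
        p = expit(self.inverse_temperature_ * self.decision_values(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise AttributeError("model is not fitted; call fit(X, y) first")


class PrecommitModel(_BoundedMLEMixin, ClassifierMixin, BaseEstimator):
    """MM or WP precommitment model over fixed per-trial subjective values.

    X carries (sv_lr, sv_sr) taken from a previously fitted choice model;
    only theta (sensitivity) and b (bias) are estimated. For kind="wp",
    ``iota_reward`` — the willpower estimate from the achievement fit — must
    be supplied and is held fixed.
    """

    def __init__(self, kind="mm", iota_reward=None, bounds=None, n_starts=20, seed=0, tol=1e-8):
        self.kind = kind
        self.iota_reward = iota_reward
        self.bounds = bounds
        self.n_starts = n_starts
        self.seed = seed
        self.tol = tol

    def _free_names(self):
        return ["sensitivity", "bias"]

    def _bounds(self):
        merged = dict(DEFAULT_PRECOM_BOUNDS)
        if self.bounds:
            merged.update(self.bounds)
        return [tuple(merged[name]) for name in self._free_names()]

    def precommitment_values(self, X):
        """Model-specific value of precommitment V per trial."""
        sv_lr, sv_sr = _columns(X, ["sv_lr", "sv_sr"])
        if self.kind == "mm":
            return sv_lr - sv_sr
        if self.kind == "wp":
            if self.iota_reward is None:
                raise ValueError("WP precommitment model requires iota_reward")
            if not 0.0 <= self.iota_reward <= 1.0:
                raise ValueError("iota_reward must lie in [0, 1]")
            return self.iota_reward * sv_sr - sv_lr
        raise ValueError("kind must be 'mm' or 'wp'")

    def _nll_and_grad(self, theta_vec, v, y):
        theta, b = theta_vec
        a = theta * v + b
        p = expit(a)
        nll = _nll_logit(a, y)
        resid = p - y
        return nll, np.array([float(np.sum(resid * v)), float(np.sum(resid))])

    def fit(self, X, y):
        """Fit to precommitment trials; y = 1 if precommitment was accepted."""
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        v = self.precommitment_values(X)
        if v.size == 0:
            raise ValueError("cannot fit on an empty trial set")
        y = _validate_binary(y, v.size)
        best, nll, n_agree = _multistart(
            lambda t: self._nll_and_grad(t, v, y),
            self._bounds(),
            self.n_starts,
            self.seed,
            self.tol,
        )
        self.sensitivity_ = float(best[0])
        self.bias_ = float(best[1])
        self.params_ = {"sensitivity": self.sensitivity_, "bias": self.bias_}
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        p_hat = expit(self.sensitivity_ * v + self.bias_)
        self._finalize(negative_log_likelihood_bernoulli(p_hat, y), y, p_hat, n_agree)
        return self

    def predict_proba(self, X):
        if not hasattr(self, "params_"):
            raise AttributeError("model is not fitted; call fit(X, y) first")
        p = expit(self.sensitivity_ * self.precommitment_values(X) + self.bias_)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
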