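"""Per-subject maximum-likelihood fitting of the four models.

The choice models (MM and WP) are fitted to decisions made while the SR was
still on offer: standard trials plus precommitment trials where
precommitment was rejected. The WP choice model is additionally fitted to
*achieved* rewards on that same subset, yielding the willpower estimate
``iota_reward`` (versus ``iota_choice`` from the choice-outcome fit). The
precommitment models are fitted to the accept/reject decisions on all
precommitment trials, with subjective values (and, for WP, iota_reward)
held fixed from the corresponding prior fit — only theta and b are free.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ChoiceModel, PrecommitModel, negative_log_likelihood_bernoulli
from .valuation import p_choice_lr, p_precommit, subjective_value, PrecomModelParams

CHOICE_MODELS = ("mm_choice", "wp_choice")
PRECOM_MODELS = ("mm_precom", "wp_precom")
MODELS = CHOICE_MODELS + PRECOM_MODELS

__all__ = [
    "FitSpec",
    "FitResult",
    "InsufficientDataError",
    "FitFailureError",
    "select_fit_data",
    "choice_design_matrix",
    "negative_log_likelihood",
    "fit_subject",
    "fit_wp_achievement",
    "fit_subject_all_models",
    "fit_cohort",
    "results_to_frame",
]


class InsufficientDataError(ValueError):
    """The requested trial subset is empty or lacks a required outcome."""


class FitFailureError(RuntimeError):
    """Every optimization start failed."""


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how: model, outcome variable, bounds and starts."""

    model: str = "mm_choice"
    outcome: str = "choice"  # choice | achievement | precommit_decision
    bounds: dict | None = None
    n_starts: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.outcome not in ("choice", "achievement", "precommit_decision"):
            raise ValueError("invalid outcome")
        if (self.outcome == "precommit_decision") != (self.model in PRECOM_MODELS):
            raise ValueError("precommit_decision outcome is for precommitment models only")


@dataclass
class FitResult:
    subject_id: str
    task: str
    model: str
    outcome: str
    estimates: dict = field(default_factory=dict)
    log_likelihood: float = np.nan
    n_trials: int = 0
    bic: float = np.nan
    pseudo_r2: float = np.nan
    percent_correct: float = np.nan
    reliable: bool = False
    n_starts_agreeing: int = 0


def select_fit_data(records: pd.DataFrame, model: str, subject, task) -> pd.DataFrame:
    """Trial subset a model is fitted to.

    Choice models: standard trials plus precommitment trials with
    precommitment rejected (trials where the subject actually faced the
    LR-vs-SR choice). Precommitment models: all precommitment trials.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    sub = records[(records["subject_id"] == subject) & (records["task"] == task)]
    if sub.empty:
        raise InsufficientDataError(f"no trials for subject {subject!r}, task {task!r}")
    if model in CHOICE_MODELS:
        pre = sub["precommit"].fillna("")
        out = sub[(sub["trial_type"] == "standard") | (pre == "no")]
    else:
        out = sub[sub["trial_type"] == "precommitment"]
    if out.empty:
        raise InsufficientDataError(f"empty fitting subset for {model} / {subject} / {task}")
    return out


def choice_design_matrix(subset: pd.DataFrame, m_lr: float, m_sr: float, outcome: str = "choice"):
    """(X, y) for a choice-model fit: features (m_lr, m_sr, cost) and a
    binary outcome (LR chosen, or LR achieved)."""
    X = pd.DataFrame(
        {
            "m_lr": m_lr,
            "m_sr": m_sr,
            "cost": subset["cost_level"].to_numpy(dtype=float),
        }
    )
    if outcome == "choice":
        y = (subset["choice"] == "LR").to_numpy(dtype=int)
    elif outcome == "achievement":
        y = subset["achieved_LR"].astype(bool).to_numpy().astype(int)
    else:
        raise ValueError("choice-model outcome must be 'choice' or 'achievement'")
    return X, y


def negative_log_likelihood(params, subset: pd.DataFrame, model: str, outcome: str,
                            m_lr: float, m_sr: float, iota_reward: float | None = None,
                            sv_discount_rate: float | None = None) -> float:
    """Summed Bernoulli negative log-likelihood of a parameter vector.

    ``params``: (k, gamma) for mm_choice, (k, gamma, iota) for wp_choice,
    (theta, b) for the precommitment models (which additionally need the
    fixed ``sv_discount_rate`` from the prior choice/achievement fit, and
    ``iota_reward`` for wp_precom).
    """
    params = np.asarray(params, dtype=float)
    if np.any(np.isnan(params)):
        raise ValueError("parameters must not be NaN")
    cost = subset["cost_level"].to_numpy(dtype=float)
    if model in CHOICE_MODELS:
        k, gamma = params[0], params[1]
        sv_lr = subjective_value(m_lr, cost, k)
        dv = sv_lr - (params[2] * m_sr if model == "wp_choice" else m_sr)
        p = p_choice_lr(dv, gamma)
        _, y = choice_design_matrix(subset, m_lr, m_sr, outcome)
    else:
        if sv_discount_rate is None:
            raise ValueError("precommitment models need sv_discount_rate from the prior fit")
        sv_lr = subjective_value(m_lr, cost, sv_discount_rate)
        if model == "wp_precom":
            if iota_reward is None:
                raise ValueError("wp_precom needs iota_reward")
            v = iota_reward * m_sr - sv_lr
        else:
            v = sv_lr - m_sr
        p = p_precommit(v, PrecomModelParams(max(params[0], 0.0), np.clip(params[1], -5, 5)))
        y = (subset["precommit"] == "yes").to_numpy(dtype=int)
    return negative_log_likelihood_bernoulli(p, y)


def _result_from_estimator(est, subject, task, model, outcome) -> FitResult:
    return FitResult(
        subject_id=subject,
        task=task,
        model=model,
        outcome=outcome,
        estimates=dict(est.params_),
        log_likelihood=est.log_likelihood_,
        n_trials=est.n_trials_,
        bic=est.bic_,
        pseudo_r2=est.pseudo_r2_,
        percent_correct=est.percent_correct_,
        reliable=est.reliable_,
        n_starts_agreeing=est.n_starts_agreeing_,
    )


def fit_subject(subset: pd.DataFrame, m_lr: float, m_sr: float, spec: FitSpec,
                sv_discount_rate: float | None = None,
                iota_reward: float | None = None) -> FitResult:
    """Fit one model to one subject's trial subset.

    For precommitment models, ``sv_discount_rate`` (and ``iota_reward`` for
    wp_precom) must come from the appropriate prior fit; they are never
    re-estimated here.
    """
    if subset.empty:
        raise InsufficientDataError("empty trial subset")
    subject = str(subset["subject_id"].iloc[0])
    task = str(subset["task"].iloc[0])
    try:
        if spec.model in CHOICE_MODELS:
            kind = "mm" if spec.model == "mm_choice" else "wp"
            est = ChoiceModel(kind=kind, bounds=spec.bounds, n_starts=spec.n_starts, seed=spec.seed)
            X, y = choice_design_matrix(subset, m_lr, m_sr, spec.outcome)
            est.fit(X, y)
        else:
            if sv_discount_rate is None:
                raise ValueError("precommitment models need sv_discount_rate")
            kind = "mm" if spec.model == "mm_precom" else "wp"
            cost = subset["cost_level"].to_numpy(dtype=float)
            X = pd.DataFrame(
                {"sv_lr": subjective_value(m_lr, cost, sv_discount_rate), "sv_sr": m_sr}
            )
            y = (subset["precommit"] == "yes").to_numpy(dtype=int)
            est = PrecommitModel(
                kind=kind, iota_reward=iota_reward, bounds=spec.bounds,
                n_starts=spec.n_starts, seed=spec.seed,
            )
            est.fit(X, y)
    except RuntimeError as exc:  # all starts failed
        raise FitFailureError(f"{spec.model} fit failed for {subject}/{task}: {exc}") from exc
    return _result_from_estimator(est, subject, task, spec.model, spec.outcome)


def fit_wp_achievement(records: pd.DataFrame, subject, task, m_lr: float, m_sr: float,
                       n_starts: int = 20, seed: int = 0, bounds: dict | None = None) -> FitResult:
    """WP choice model fitted to achieved rewards (yields iota_reward)."""
    subset = select_fit_data(records, "wp_choice", subject, task)
    spec = FitSpec(model="wp_choice", outcome="achievement", bounds=bounds,
                   n_starts=n_starts, seed=seed)
    return fit_subject(subset, m_lr, m_sr, spec)


def _fit_seed(base_seed: int, *keys) -> int:
    # crc32 (not hash()) so derived seeds are stable across processes
    digests = [zlib.crc32(str(k).encode()) for k in keys]
    ss = np.random.SeedSequence([int(base_seed)] + digests)
    return int(ss.generate_state(1)[0] % 2**31)


def fit_subject_all_models(records: pd.DataFrame, subject, task, m_lr: float, m_sr: float,
                           n_starts: int = 20, seed: int = 0) -> list[FitResult]:
    """The full fitting cascade for one subject on one task.

    1. MM and WP choice models on the choice subset (outcome: choice).
    2. WP choice model on the same subset with outcome: achievement
       (iota_reward).
    3. MM precommitment model with SVs from the MM choice fit; WP
       precommitment model with SVs and iota_reward from the achievement fit.
    """
    choice_subset = select_fit_data(records, "mm_choice", subject, task)
    precom_subset = select_fit_data(records, "mm_precom", subject, task)
    results = []

    mm = fit_subject(choice_subset, m_lr, m_sr,
                     FitSpec("mm_choice", "choice", n_starts=n_starts,
                             seed=_fit_seed(seed, subject, task, "mm_choice")))
    wp = fit_subject(choice_subset, m_lr, m_sr,
                     FitSpec("wp_choice", "choice", n_starts=n_starts,
                             seed=_fit_seed(seed, subject, task, "wp_choice")))
    wp_ach = fit_subject(choice_subset, m_lr, m_sr,
                         FitSpec("wp_choice", "achievement", n_starts=n_starts,
                                 seed=_fit_seed(seed, subject, task, "wp_achievement")))
    results += [mm, wp, wp_ach]

    mm_pre = fit_subject(precom_subset, m_lr, m_sr,
                         FitSpec("mm_precom", "precommit_decision", n_starts=n_starts,
                                 seed=_fit_seed(seed, subject, task, "mm_precom")),
                         sv_discount_rate=mm.estimates["discount_rate"])
    wp_pre = fit_subject(precom_subset, m_lr, m_sr,
                         FitSpec("wp_precom", "precommit_decision", n_starts=n_starts,
                                 seed=_fit_seed(seed, subject, task, "wp_precom")),
                         sv_discount_rate=wp_ach.estimates["discount_rate"],
                         iota_reward=wp_ach.estimates["willpower"])
    results += [mm_pre, wp_pre]
    return results


def fit_cohort(records: pd.DataFrame, rewards: pd.DataFrame, tasks=("effort", "delay"),
               n_starts: int = 20, seed: int = 0) -> pd.DataFrame:
    """Fit all models to every subject x task; returns a tidy results table.

    ``rewards``: one row per subject with columns subject_id, m_lr, m_sr.
    """
    reward_map = rewards.drop_duplicates("subject_id").set_index("subject_id")
    rows = []
    for subject in sorted(records["subject_id"].unique()):
        m_lr = float(reward_map.loc[subject, "m_lr"])
        m_sr = float(reward_map.loc[subject, "m_sr"])
        for task in tasks:
            if records[(records["subject_id"] == subject) & (records["task"] == task)].empty:
                continue
            rows += fit_subject_all_models(records, subject, task, m_lr, m_sr,
                                           n_starts=n_starts, seed=seed)
    return results_to_frame(rows)


def results_to_frame(results: list[FitResult]) -> pd.DataFrame:
    """Flatten FitResults into one row per subject x task x model x outcome."""
    rows = []
    for r in results:
        row = {
            "subject_id": r.subject_id,
            "task": r.task,
            "model": r.model,
            "outcome": r.outcome,
            "log_likelihood": r.log_likelihood,
            "n_trials": r.n_trials,
            "bic": r.bic,
            "pseudo_r2": r.pseudo_r2,
            "percent_correct": r.percent_correct,
            "reliable": r.reliable,
            "n_starts_agreeing": r.n_starts_agreeing,
        }
        for name, val in r.estimates.items():
            row[f"est_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
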