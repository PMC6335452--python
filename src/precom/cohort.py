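"""Synthetic cohorts of agents performing the effort and delay tasks.

Each simulated subject is an agent with known ("true") parameters: a reward
set built from a synthetic rating session, per-task choice parameters
(discount rate, inverse temperature and — for willpower agents — the
suppression factor iota), per-task precommitment parameters (theta, b), a
small lapse probability of abandoning a chosen LR mid-execution (opt-out),
and an optional probability of failing the effort requirement despite
trying. Trial generation composes exactly the equations the fitting stage
assumes, so downstream estimation can be validated by parameter recovery.

Default priors are centred on the empirical group estimates of the study
conditions this generator emulates (effort discounting rate ~0.21, delay
rate ~0.16, softmax temperatures of order 7 and 21 for the two tasks,
precommitment rates near 50%, opt-outs in ~0.5% of effort and ~1.7% of
delay standard trials).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import RewardSet, TaskDesign, build_reward_set, generate_task_design
from .io import TRIAL_COLUMNS, validate_trials
from .valuation import (
    ChoiceModelParams,
    PrecomModelParams,
    p_choice_lr,
    p_precommit,
    subjective_value,
    v_precom_mm,
    v_precom_wp,
)

__all__ = [
    "DEFAULT_PRIORS",
    "DEFAULT_OPT_OUT",
    "SubjectGenerativeSpec",
    "CohortDataset",
    "draw_subject_params",
    "simulate_trial",
    "simulate_subject_task",
    "simulate_cohort",
]

# Per-task opt-out lapse defaults: observed rates in standard trials.
DEFAULT_OPT_OUT = {"effort": 0.005, "delay": 0.017}

# Prior specs: dist in {point, uniform, truncnorm}; truncated to the fitting
# bounds. Centres/spreads follow the empirical group means and (sem * sqrt(n))
# dispersions of the emulated study population.
DEFAULT_PRIORS: dict[str, dict] = {
    "epsilon": {"dist": "truncnorm", "mean": 0.21, "sd": 0.27, "low": 0.0, "high": 1.0},
    "kappa": {"dist": "truncnorm", "mean": 0.16, "sd": 0.24, "low": 0.0, "high": 1.0},
    "gamma_effort": {"dist": "truncnorm", "mean": 6.6, "sd": 6.3, "low": 0.0, "high": 100.0},
    "gamma_delay": {"dist": "truncnorm", "mean": 20.7, "sd": 22.8, "low": 0.0, "high": 100.0},
    "iota": {"dist": "truncnorm", "mean": 0.49, "sd": 0.34, "low": 0.0, "high": 1.0},
    "theta_effort": {"dist": "truncnorm", "mean": 3.7, "sd": 5.9, "low": 0.0, "high": 100.0},
    "theta_delay": {"dist": "truncnorm", "mean": 5.7, "sd": 9.5, "low": 0.0, "high": 100.0},
    "b_effort": {"dist": "truncnorm", "mean": -1.46, "sd": 2.9, "low": -5.0, "high": 5.0},
    "b_delay": {"dist": "truncnorm", "mean": -1.10, "sd": 2.9, "low": -5.0, "high": 5.0},
}
# Across-task coupling of the precommitment bias: a shared subject-level
# deviation (fraction of the prior sd) plus task-specific noise, producing
# the positive cross-task rank correlation seen empirically.
B_SHARED_FRACTION = 0.75

N_RATING_ITEMS = 400  # rating-session length emulated per subject


def _draw(prior: Mapping, rng: np.random.Generator) -> float:
    dist = prior.get("dist", "truncnorm")
    if dist == "point":
        return float(prior["value"])
    low, high = float(prior["low"]), float(prior["high"])
    if not (math.isfinite(low) and math.isfinite(high)) or low > high:
        raise ValueError(f"prior bounds must be finite with low <= high, got {prior}")
    if dist == "uniform":
        return float(rng.uniform(low, high))
    if dist == "truncnorm":
        mean, sd = float(prior["mean"]), float(prior["sd"])
        if sd <= 0:
            raise ValueError("truncnorm prior needs sd > 0 (use dist='point' for a mass)")
        a, b = (low - mean) / sd, (high - mean) / sd
        return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    raise ValueError(f"unknown prior dist {dist!r}")


@dataclass(frozen=True)
class SubjectGenerativeSpec:
    """True parameters of one simulated agent."""

    subject_id: str
    reward_set: RewardSet
    choice_params: Mapping[str, ChoiceModelParams]  # per task
    precom_params: Mapping[str, PrecomModelParams]  # per task
    generative_model: str = "mm"  # "mm" or "wp"
    opt_out_prob: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_OPT_OUT))
    achievement_failure_prob: float = 0.0
    # fixed acceptance probability replacing the model-based P(precommit);
    # 0.0 gives a never-precommitting agent (precommitment trials then run
    # exactly like standard trials), 1.0 a forced precommitter
    precommit_override: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generative_model not in ("mm", "wp"):
            raise ValueError("generative_model must be 'mm' or 'wp'")
        for p in self.opt_out_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("opt_out_prob must lie in [0, 1]")
        if not 0.0 <= self.achievement_failure_prob <= 1.0:
            raise ValueError("achievement_failure_prob must lie in [0, 1]")
        if self.generative_model == "wp":
            for cp in self.choice_params.values():
                if cp.willpower is None:
                    raise ValueError("WP agents need the willpower parameter iota")
        if self.precommit_override is not None and not 0.0 <= self.precommit_override <= 1.0:
            raise ValueError("precommit_override must lie in [0, 1]")


@dataclass
class CohortDataset:
    """Trial records for a cohort plus the generating configuration."""

    records: pd.DataFrame
    true_params: pd.DataFrame  # one row per subject x task
    provenance: dict

    def task_records(self, task: str) -> pd.DataFrame:
        return self.records[self.records["task"] == task]


def _synthetic_ratings(rng: np.random.Generator, n_items: int = N_RATING_ITEMS) -> np.ndarray:
    """Integer 0-10 enjoyment ratings: discretized normal around mid-scale."""
    raw = rng.normal(5.5, 2.2, size=n_items)
    return np.clip(np.rint(raw), 0, 10).astype(int)


def draw_subject_params(
    prior_config: Mapping | None = None,
    seed: int = 0,
    subject_id: str = "S000",
    generative_model: str = "mm",
    opt_out_prob: Mapping[str, float] | None = None,
    achievement_failure_prob: float = 0.0,
    precommit_override: float | None = None,
) -> SubjectGenerativeSpec:
    """Draw one agent's true parameters from (possibly overridden) priors.

    ``prior_config`` entries replace the defaults key-by-key; each entry is
    a dict like ``{"dist": "truncnorm", "mean": .., "sd": .., "low": ..,
    "high": ..}``, ``{"dist": "uniform", "low": .., "high": ..}`` or
    ``{"dist": "point", "value": ..}``.
    """
    priors = dict(DEFAULT_PRIORS)
    if prior_config:
        for key, val in prior_config.items():
            if key not in priors:
                raise ValueError(f"unknown prior parameter {key!r}")
            priors[key] = val
    rng = np.random.default_rng(seed)

    ratings = _synthetic_ratings(rng)
    reward_set = build_reward_set(ratings)

    eps = _draw(priors["epsilon"], rng)
    kap = _draw(priors["kappa"], rng)
    iota = _draw(priors["iota"], rng) if generative_model == "wp" else None
    choice_params = {
        "effort": ChoiceModelParams(eps, _draw(priors["gamma_effort"], rng), iota),
        "delay": ChoiceModelParams(kap, _draw(priors["gamma_delay"], rng), iota),
    }

    # Shared subject-level deviation couples b across tasks.
    shared = rng.standard_normal()
    precom_params = {}
    for task in ("effort", "delay"):
        pb = priors[f"b_{task}"]
        if pb.get("dist") == "point":
            b = float(pb["value"])
        else:
            sd = float(pb.get("sd", 1.0))
            noise = math.sqrt(max(1.0 - B_SHARED_FRACTION**2, 0.0)) * rng.standard_normal()
            b = float(pb.get("mean", 0.0)) + sd * (B_SHARED_FRACTION * shared + noise)
            b = float(np.clip(b, pb.get("low", -5.0), pb.get("high", 5.0)))
        precom_params[task] = PrecomModelParams(_draw(priors[f"theta_{task}"], rng), b)

    return SubjectGenerativeSpec(
        subject_id=subject_id,
        reward_set=reward_set,
        choice_params=choice_params,
        precom_params=precom_params,
        generative_model=generative_model,
        opt_out_prob=dict(opt_out_prob) if opt_out_prob is not None else dict(DEFAULT_OPT_OUT),
        achievement_failure_prob=achievement_failure_prob,
        precommit_override=precommit_override,
        seed=seed,
    )


def _trial_probabilities(spec: SubjectGenerativeSpec, task: str, cost: np.ndarray):
    """Closed-form P(precommit) and P(choose LR) per trial cost."""
    cp = spec.choice_params[task]
    pp = spec.precom_params[task]
    rs = spec.reward_set
    sv_lr = subjective_value(rs.m_lr, cost, cp.discount_rate)
    sv_sr = np.full_like(sv_lr, rs.m_sr)
    if spec.generative_model == "mm":
        dv = sv_lr - rs.m_sr
        v = v_precom_mm(sv_lr, sv_sr)
    else:
        dv = sv_lr - cp.willpower * rs.m_sr
        v = v_precom_wp(sv_lr, sv_sr, cp.willpower)
    p_pre = p_precommit(v, pp)
    if spec.precommit_override is not None:
        p_pre = np.full_like(p_pre, spec.precommit_override)
    return p_pre, p_choice_lr(dv, cp.inverse_temperature)


def simulate_subject_task(
    spec: SubjectGenerativeSpec, design: TaskDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate one subject's full session on one task (vectorized)."""
    task = design.task
    cost = np.array([t.cost_level for t in design.trials], dtype=float)
    is_precom_trial = np.array([t.trial_type == "precommitment" for t in design.trials])
    p_pre, p_lr = _trial_probabilities(spec, task, cost)

    n = len(design.trials)
    precommitted = is_precom_trial & (rng.random(n) < p_pre)
    chose_lr_free = rng.random(n) < p_lr  # choice when the SR is still on offer
    chose_lr = precommitted | (~precommitted & chose_lr_free)
    opt_out = (~precommitted) & chose_lr & (rng.random(n) < spec.opt_out_prob.get(task, 0.0))
    tried = chose_lr & ~opt_out
    achieved = tried & (rng.random(n) >= spec.achievement_failure_prob)

    precommit = np.where(is_precom_trial, np.where(precommitted, "yes", "no"), "")
    df = pd.DataFrame(
        {
            "subject_id": spec.subject_id,
            "task": task,
            "trial_index": [t.trial_index for t in design.trials],
            "trial_type": [t.trial_type for t in design.trials],
            "cost_level": cost,
            "precommit": precommit,
            "choice": np.where(chose_lr, "LR", "SR"),
            "opt_out": opt_out,
            "achieved_LR": achieved,
        }
    )
    return df[TRIAL_COLUMNS]


def simulate_trial(spec: SubjectGenerativeSpec, trial, rng: np.random.Generator) -> dict:
    """Simulate a single trial; returns one record as a dict."""
    design = TaskDesign(task=trial.task, trials=(trial,), seed=0)
    return simulate_subject_task(spec, design, rng).iloc[0].to_dict()


def simulate_cohort(
    n_subjects: int,
    designs: Mapping[str, TaskDesign] | None = None,
    prior_config: Mapping | None = None,
    seed: int = 0,
    generative_model: str = "mm",
    tasks: tuple[str, ...] = ("effort", "delay"),
    opt_out_prob: Mapping[str, float] | None = None,
    achievement_failure_prob: float = 0.0,
    precommit_override: float | None = None,
    shared_design: bool = False,
) -> CohortDataset:
    """Simulate a cohort: ``n_subjects`` agents, each run through every task.

    Designs default to the standard 60-trial sessions; each subject gets a
    freshly shuffled trial order (``shared_design=True`` reuses one order).
    Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence(seed)
    param_seeds, sim_seeds, design_seeds = (
        s.generate_state(n_subjects) for s in root.spawn(3)
    )

    frames, truth = [], []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        spec = draw_subject_params(
            prior_config=prior_config,
            seed=int(param_seeds[i] % 2**31),
            subject_id=sid,
            generative_model=generative_model,
            opt_out_prob=opt_out_prob,
            achievement_failure_prob=achievement_failure_prob,
            precommit_override=precommit_override,
        )
        rng = np.random.default_rng(sim_seeds[i])
        for task in tasks:
            if designs is not None and task in designs:
                design = designs[task]
            else:
                dseed = int((design_seeds[0] if shared_design else design_seeds[i]) % 2**31)
                design = generate_task_design(task, seed=dseed)
            frames.append(simulate_subject_task(spec, design, rng))
            cp, pp = spec.choice_params[task], spec.precom_params[task]
            truth.append(
                {
                    "subject_id": sid,
                    "task": task,
                    "generative_model": generative_model,
                    "m_lr": spec.reward_set.m_lr,
                    "m_sr": spec.reward_set.m_sr,
                    "discount_rate": cp.discount_rate,
                    "inverse_temperature": cp.inverse_temperature,
                    "willpower": np.nan if cp.willpower is None else cp.willpower,
                    "sensitivity": pp.sensitivity,
                    "bias": pp.bias,
                }
            )

    records = validate_trials(pd.concat(frames, ignore_index=True))
    provenance = {
        "seed": seed,
        "n_subjects": n_subjects,
        "generative_model": generative_model,
        "tasks": list(tasks),
        "opt_out_prob": dict(opt_out_prob) if opt_out_prob is not None else dict(DEFAULT_OPT_OUT),
        "achievement_failure_prob": achievement_failure_prob,
    }
    return CohortDataset(records=records, true_params=pd.DataFrame(truth), provenance=provenance)
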