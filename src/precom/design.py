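"""Task designs and subject-level reward sets.

A session of either task offers repeated choices between a free/immediate
small reward (SR) and a costly large reward (LR). Half of the trials are
*standard* (the SR stays available throughout), half offer *precommitment*
(the SR can be removed from the choice set up front). The LR's cost takes
three levels — squeezes on a dynamometer for the effort task, waiting
seconds for the delay task — each repeated a fixed number of times per
trial type, in randomized order.

Reward magnitudes are subject-specific: each subject rates a pool of items
on a 0–10 scale; ratings of 0 or 1 are discarded, items strictly above the
median of the retained ratings become large rewards, items strictly below
become small rewards, and ``M_LR``/``M_SR`` are the mean ratings of the two
sets. Items exactly at the median belong to neither set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EFFORT_COST_LEVELS = (2, 4, 6)  # squeezes
DELAY_COST_LEVELS = (4, 7, 10)  # seconds
DEFAULT_REPS = 10
TASKS = ("effort", "delay")
TRIAL_TYPES = ("standard", "precommitment")

__all__ = [
    "TrialSpec",
    "TaskDesign",
    "RewardSet",
    "DegenerateRatingError",
    "default_cost_levels",
    "generate_task_design",
    "build_reward_set",
    "design_to_frame",
]


class DegenerateRatingError(ValueError):
    """Raised when retained ratings admit no LR/SR split."""


@dataclass(frozen=True)
class TrialSpec:
    task: str
    trial_type: str
    cost_level: float
    trial_index: int


@dataclass(frozen=True)
class TaskDesign:
    task: str
    trials: tuple[TrialSpec, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class RewardSet:
    """Subject-level reward magnitudes from a rating median split."""

    m_lr: float
    m_sr: float
    n_lr: int = 0
    n_sr: int = 0

    def __post_init__(self) -> None:
        if not self.m_lr > self.m_sr:
            raise ValueError("require M_LR > M_SR")


def default_cost_levels(task: str) -> tuple[float, ...]:
    if task == "effort":
        return EFFORT_COST_LEVELS
    if task == "delay":
        return DELAY_COST_LEVELS
    raise ValueError(f"unknown task {task!r}")


def generate_task_design(
    task: str,
    cost_levels=None,
    reps_per_level_per_type: int = DEFAULT_REPS,
    seed: int = 0,
) -> TaskDesign:
    """Build a randomized session design for one task.

    The design contains ``2 * len(cost_levels) * reps`` trials: every
    (trial type, cost level) cell appears exactly ``reps`` times, and the
    full sequence is shuffled once with a seeded uniform permutation.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    if cost_levels is None:
        cost_levels = default_cost_levels(task)
    cost_levels = tuple(sorted(set(cost_levels)))
    if not cost_levels:
        raise ValueError("cost_levels must be non-empty")
    if any(c <= 0 for c in cost_levels):
        raise ValueError("cost levels must be positive")
    if reps_per_level_per_type < 1:
        raise ValueError("reps_per_level_per_type must be >= 1")

    cells = [
        (trial_type, level)
        for trial_type in TRIAL_TYPES
        for level in cost_levels
        for _ in range(reps_per_level_per_type)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    trials = tuple(
        TrialSpec(task=task, trial_type=cells[j][0], cost_level=cells[j][1], trial_index=i)
        for i, j in enumerate(order)
    )
    return TaskDesign(task=task, trials=trials, seed=seed)


def design_to_frame(design: TaskDesign, subject_id=None) -> pd.DataFrame:
    """Tabular view of a design (one row per trial)."""
    df = pd.DataFrame(
        {
            "task": [t.task for t in design.trials],
            "trial_index": [t.trial_index for t in design.trials],
            "trial_type": [t.trial_type for t in design.trials],
            "cost_level": [t.cost_level for t in design.trials],
        }
    )
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df


def build_reward_set(ratings) -> RewardSet:
    """Median-split ratings into large- and small-reward magnitudes.

    Ratings of 0 ("not enjoyable") and 1 ("neutral") are discarded. ``M_LR``
    is the mean of retained ratings strictly above their median, ``M_SR``
    the mean of those strictly below; at-median items are excluded from both.

    Raises
    ------
    DegenerateRatingError
        If, after discarding, no items lie strictly above or strictly below
        the median (e.g. all retained ratings equal).
    """
    arr = np.asarray([r[1] if isinstance(r, tuple) else r for r in ratings], dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 10)):
        raise ValueError("ratings must lie in [0, 10]")
    retained = arr[arr > 1]
    if retained.size == 0:
        raise DegenerateRatingError("all ratings discarded (everything rated 0 or 1)")
    med = np.median(retained)
    lr = retained[retained > med]
    sr = retained[retained < med]
    if lr.size == 0 or sr.size == 0:
        raise DegenerateRatingError(
            "retained ratings admit no strict median split into LR and SR sets"
        )
    return RewardSet(m_lr=float(lr.mean()), m_sr=float(sr.mean()), n_lr=int(lr.size), n_sr=int(sr.size))
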