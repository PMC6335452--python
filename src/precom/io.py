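"""Authoritative trial-level CSV schema and round-trip readers/writers.

One row per trial:

    subject_id, task, trial_index, trial_type, cost_level,
    precommit, choice, opt_out, achieved_LR

``precommit`` is ``yes``/``no`` on precommitment trials and empty on
standard trials (where precommitment is not offered). ``choice`` is
``LR``/``SR``; ``opt_out`` and ``achieved_LR`` are 0/1 flags.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "subject_id",
    "task",
    "trial_index",
    "trial_type",
    "cost_level",
    "precommit",
    "choice",
    "opt_out",
    "achieved_LR",
]

__all__ = ["TRIAL_COLUMNS", "write_trials_csv", "read_trials_csv", "validate_trials", "write_params_json", "read_params_json"]


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and record-level consistency; returns the frame.

    Enforced invariants: precommitment offered iff trial_type is
    precommitment; accepted precommitment forces an LR choice; opt-outs only
    follow an LR choice and forfeit the LR; an achieved LR requires an LR
    choice without opt-out.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    if not df["task"].isin(["effort", "delay"]).all():
        raise ValueError("task must be 'effort' or 'delay'")
    if not df["trial_type"].isin(["standard", "precommitment"]).all():
        raise ValueError("trial_type must be 'standard' or 'precommitment'")
    if not df["choice"].isin(["LR", "SR"]).all():
        raise ValueError("choice must be 'LR' or 'SR'")
    pre = df["precommit"].fillna("")
    std = df["trial_type"] == "standard"
    if not (pre[std] == "").all() or not pre[~std].isin(["yes", "no"]).all():
        raise ValueError("precommit must be empty on standard trials and yes/no otherwise")
    opt = df["opt_out"].astype(bool)
    ach = df["achieved_LR"].astype(bool)
    lr = df["choice"] == "LR"
    if ((pre == "yes") & ~lr).any():
        raise ValueError("accepted precommitment must force an LR choice")
    if (opt & (~lr | ach)).any():
        raise ValueError("opt-out requires an LR choice and forfeits the LR")
    if (ach & ~lr).any():
        raise ValueError("achieved_LR requires an LR choice")
    return df


def write_trials_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["precommit"] = out["precommit"].fillna("")
    out["opt_out"] = out["opt_out"].astype(int)
    out["achieved_LR"] = out["achieved_LR"].astype(int)
    out[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    df["precommit"] = df["precommit"].astype(str).replace("nan", "")
    df["opt_out"] = df["opt_out"].astype(int).astype(bool)
    df["achieved_LR"] = df["achieved_LR"].astype(int).astype(bool)
    df["cost_level"] = df["cost_level"].astype(float)
    df["trial_index"] = df["trial_index"].astype(int)
    return validate_trials(df)


def write_params_json(params: dict, path) -> None:
    """Sidecar with the generating (true) parameters, for recovery checks."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(params, indent=2, default=_default))


def read_params_json(path) -> dict:
    return json.loads(Path(path).read_text())
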