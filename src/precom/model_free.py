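"""Model-free behavioral statistics.

* Repeated-measures logistic regression of large-reward achievement on
  trial type (precommitment vs standard) and the LR's cost requirement,
  fitted as a GEE with subject as the cluster; the working correlation
  (independence vs exchangeable) is chosen by QIC, and Wald chi-square
  statistics plus per-cell predicted probabilities are reported.
* Empirical behavioral rates: precommitment acceptance, opt-outs (among
  standard-trial LR choices), and achievement by trial type x cost level.
* Cross-task Spearman correlations of per-subject quantities (e.g. the
  fitted precommitment bias b, or the precommitment benefit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "RegressionReport",
    "RatesReport",
    "achievement_regression",
    "behavioral_rates",
    "precommitment_benefit",
    "cross_task_correlation",
]

FORMULA = "achieved ~ C(trial_type) + C(cost_level)"
FORMULA_INTERACTION = "achieved ~ C(trial_type) * C(cost_level)"


@dataclass
class RegressionReport:
    task: str
    working_correlation: str
    qic: dict  # candidate -> QIC
    wald: pd.DataFrame  # statistic, pvalue, df per term
    cell_probabilities: pd.DataFrame  # trial_type x cost_level with SEs
    n_subjects: int
    n_trials: int

    def wald_for(self, term: str) -> tuple[float, float, int]:
        row = self.wald.loc[term]
        return float(row["statistic"]), float(row["pvalue"]), int(row["df_constraint"])


def _fit_gee(df: pd.DataFrame, cov_struct, formula: str = FORMULA):
    model = smf.gee(
        formula,
        groups="subject_id",
        data=df,
        family=sm.families.Binomial(),
        cov_struct=cov_struct,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def achievement_regression(records: pd.DataFrame, task: str,
                           include_interaction: bool = False) -> RegressionReport:
    """GEE logistic regression of LR achievement on trial type and cost.

    Cost level is categorical; subject is the repeated-measures cluster.
    Candidate working correlations {independence, exchangeable} are scored
    by QIC (scale fixed at 1 for the binomial family) and the lower-QIC
    structure is reported. ``include_interaction`` adds the trial type x
    cost interaction (used to show it worsens QIC).
    """
    df = records[records["task"] == task].copy()
    if df.empty:
        raise ValueError(f"no records for task {task!r}")
    if df["subject_id"].nunique() < 2:
        raise ValueError("repeated-measures regression needs >= 2 subjects (clusters)")
    if df["trial_type"].nunique() < 2:
        raise ValueError("both trial types must be present")
    df["achieved"] = df["achieved_LR"].astype(int)

    formula = FORMULA_INTERACTION if include_interaction else FORMULA
    candidates = {
        "independence": sm.cov_struct.Independence(),
        "exchangeable": sm.cov_struct.Exchangeable(),
    }
    fits, qic = {}, {}
    for name, cs in candidates.items():
        res = _fit_gee(df, cs, formula)
        fits[name] = res
        qic[name] = float(res.qic(scale=1.0)[0])
    chosen = min(qic, key=lambda name: qic[name])
    res = fits[chosen]

    wald = res.wald_test_terms(scalar=True).table
    wald = wald.rename(index=lambda s: s.replace("C(trial_type)", "trial_type")
                       .replace("C(cost_level)", "cost_level").replace(":", " x "))

    cells = (
        df[["trial_type", "cost_level"]]
        .drop_duplicates()
        .sort_values(["trial_type", "cost_level"])
        .reset_index(drop=True)
    )
    pred_frame = cells.copy()
    pred_frame["subject_id"] = df["subject_id"].iloc[0]  # unused by marginal prediction
    pred = res.get_prediction(pred_frame)
    cells["predicted_probability"] = pred.predicted_mean
    cells["se"] = pred.se

    return RegressionReport(
        task=task,
        working_correlation=chosen,
        qic=qic,
        wald=wald,
        cell_probabilities=cells,
        n_subjects=int(df["subject_id"].nunique()),
        n_trials=int(len(df)),
    )


@dataclass
class RatesReport:
    per_subject: pd.DataFrame  # subject x task rates
    aggregate: pd.DataFrame  # task-level rates
    achievement_by_cell: pd.DataFrame  # task x trial_type x cost_level


def behavioral_rates(records: pd.DataFrame) -> RatesReport:
    """Empirical rates with their natural denominators.

    Precommitment rate = accepted / precommitment trials; opt-out rate =
    opt-outs / standard-trial LR choices; achievement proportion by trial
    type and cost level. Undefined rates (zero denominator) are NaN.
    """
    rows = []
    for (subject, task), grp in records.groupby(["subject_id", "task"], sort=True):
        pre = grp[grp["trial_type"] == "precommitment"]
        std = grp[grp["trial_type"] == "standard"]
        std_lr = std[std["choice"] == "LR"]
        rows.append(
            {
                "subject_id": subject,
                "task": task,
                "precommit_rate": (pre["precommit"] == "yes").mean() if len(pre) else np.nan,
                "opt_out_rate": std_lr["opt_out"].mean() if len(std_lr) else np.nan,
                "achieved_precommitment": pre["achieved_LR"].mean() if len(pre) else np.nan,
                "achieved_standard": std["achieved_LR"].mean() if len(std) else np.nan,
                "n_precommitment_trials": len(pre),
                "n_standard_lr_choices": len(std_lr),
            }
        )
    per_subject = pd.DataFrame(rows)

    agg_rows = []
    for task, grp in records.groupby("task", sort=True):
        pre = grp[grp["trial_type"] == "precommitment"]
        std = grp[grp["trial_type"] == "standard"]
        std_lr = std[std["choice"] == "LR"]
        agg_rows.append(
            {
                "task": task,
                "precommit_rate": (pre["precommit"] == "yes").mean() if len(pre) else np.nan,
                "opt_out_rate": std_lr["opt_out"].mean() if len(std_lr) else np.nan,
                "achieved_overall": grp["achieved_LR"].mean(),
                "n_standard_lr_choices": len(std_lr),
            }
        )
    aggregate = pd.DataFrame(agg_rows)

    by_cell = (
        records.groupby(["task", "trial_type", "cost_level"], sort=True)["achieved_LR"]
        .mean()
        .rename("achieved_proportion")
        .reset_index()
    )
    return RatesReport(per_subject=per_subject, aggregate=aggregate, achievement_by_cell=by_cell)


def precommitment_benefit(records: pd.DataFrame) -> pd.DataFrame:
    """Per subject x task: relative increase in achieved LRs on
    precommitment vs standard trials,
    (P_achieve|precommitment - P_achieve|standard) / P_achieve|standard."""
    rep = behavioral_rates(records).per_subject
    base = rep["achieved_standard"]
    rep = rep.assign(
        precommitment_benefit=np.where(
            base > 0, (rep["achieved_precommitment"] - base) / base, np.nan
        )
    )
    return rep[["subject_id", "task", "precommitment_benefit"]]


def cross_task_correlation(values_effort, values_delay) -> tuple[float, float]:
    """Spearman rank correlation of paired per-subject values across tasks;
    returns (rho, two-tailed p). Constant input yields (NaN, NaN) with a
    warning."""
    a = np.asarray(values_effort, dtype=float)
    b = np.asarray(values_delay, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired per-subject vectors must be aligned")
    if a.size < 3:
        raise ValueError("need at least 3 paired subjects")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return (np.nan, np.nan)
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
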