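"""Fixed-effects Bayesian model comparison and parameter contrasts.

Models are compared by the Bayesian information criterion summed over
subjects (group BIC, lower is better; an absolute group difference above 2
counts as positive evidence) together with the mean McFadden pseudo R²
against a chance-prediction null. Parameter contrasts (pseudo R²,
iota_choice vs iota_reward, theta_MM vs theta_WP) use two-tailed paired
t-tests, optionally after excluding subjects who always or never accepted
precommitment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

POSITIVE_EVIDENCE_DELTA = 2.0

__all__ = [
    "ComparisonResult",
    "bic",
    "group_bic",
    "mcfadden_r2",
    "paired_ttest",
    "compare_models",
    "always_never_precommit_subjects",
]


def bic(log_likelihood: float, k_params: int, n_trials: int) -> float:
    """Bayesian information criterion ``k * ln(n) - 2 * lnL``."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return k_params * np.log(n_trials) - 2.0 * log_likelihood


def group_bic(fits: pd.DataFrame) -> float:
    """Fixed-effects group score: sum of per-subject BICs (one fit each)."""
    if fits["subject_id"].duplicated().any():
        raise ValueError("duplicate subjects in group BIC aggregation")
    return float(fits["bic"].sum())


def mcfadden_r2(log_likelihood: float, n_trials: int) -> float:
    """McFadden pseudo R² against a chance null for binary outcomes:
    ``1 - lnL / (n * ln 0.5)``. 0 = chance-level fit, 1 = perfect;
    values >= 0.2 are conventionally read as excellent."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return float(1.0 - log_likelihood / (n_trials * np.log(0.5)))


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Two-tailed paired t-test returning (t, df, p); zero-variance
    differences yield (NaN-safe) t=0 or NaN p with a warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must be aligned")
    d = a - b
    df = d.size - 1
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        warnings.warn("zero-variance paired differences; p undefined", stacklevel=2)
        return (0.0 if np.allclose(d, 0.0) else np.nan, df, np.nan)
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    per_subject_delta_bic: pd.Series
    group_bic_a: float
    group_bic_b: float
    group_delta_bic: float  # a - b; negative favours model a
    mean_pseudo_r2_a: float
    mean_pseudo_r2_b: float
    pseudo_r2_test: tuple[float, int, float]
    winner: str
    evidence: str  # "positive" if |group delta| > 2, else "weak"
    contrasts: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"model comparison: {self.model_a} vs {self.model_b}",
            f"  group BIC   {self.model_a}: {self.group_bic_a:.1f}   "
            f"{self.model_b}: {self.group_bic_b:.1f}   delta: {self.group_delta_bic:+.1f}",
            f"  mean pseudoR2   {self.model_a}: {self.mean_pseudo_r2_a:.3f}   "
            f"{self.model_b}: {self.mean_pseudo_r2_b:.3f}",
            f"  winner: {self.winner} ({self.evidence} evidence)",
        ]
        for name, (t, df, p) in self.contrasts.items():
            lines.append(f"  paired t ({name}): t({df}) = {t:.3f}, p = {p:.4f}")
        return "\n".join(lines)


def always_never_precommit_subjects(records: pd.DataFrame) -> list:
    """Subjects who always or never accepted precommitment (pooled over
    their precommitment trials); the theta contrast can exclude them."""
    pre = records[records["trial_type"] == "precommitment"]
    rate = (pre["precommit"] == "yes").groupby(pre["subject_id"]).mean()
    return sorted(rate[(rate == 0.0) | (rate == 1.0)].index.tolist())


def compare_models(fits_a: pd.DataFrame, fits_b: pd.DataFrame,
                   contrast_params: dict | None = None,
                   exclude_subjects=None) -> ComparisonResult:
    """Compare two per-subject fit tables (aligned on subject_id).

    ``contrast_params``: optional mapping of contrast name -> (column_a,
    column_b); each is run as a two-tailed paired t-test across subjects,
    e.g. ``{"theta": ("est_sensitivity", "est_sensitivity")}``.
    ``exclude_subjects`` drops subjects (e.g. always/never precommitters)
    before the parameter contrasts AND the BIC aggregation.
    """
    a = fits_a.drop_duplicates("subject_id").set_index("subject_id").sort_index()
    b = fits_b.drop_duplicates("subject_id").set_index("subject_id").sort_index()
    if not a.index.equals(b.index):
        raise ValueError("fit tables cover different subject sets")
    if exclude_subjects:
        keep = ~a.index.isin(list(exclude_subjects))
        a, b = a[keep], b[keep]
        if a.empty:
            raise ValueError("all subjects excluded")

    name_a = str(fits_a["model"].iloc[0]) if "model" in fits_a else "A"
    name_b = str(fits_b["model"].iloc[0]) if "model" in fits_b else "B"
    gbic_a = float(a["bic"].sum())
    gbic_b = float(b["bic"].sum())
    delta = gbic_a - gbic_b
    winner = name_a if delta < 0 else name_b if delta > 0 else "tie"
    result = ComparisonResult(
        model_a=name_a,
        model_b=name_b,
        per_subject_delta_bic=a["bic"] - b["bic"],
        group_bic_a=gbic_a,
        group_bic_b=gbic_b,
        group_delta_bic=delta,
        mean_pseudo_r2_a=float(a["pseudo_r2"].mean()),
        mean_pseudo_r2_b=float(b["pseudo_r2"].mean()),
        pseudo_r2_test=paired_ttest(a["pseudo_r2"], b["pseudo_r2"]),
        winner=winner,
        evidence="positive" if abs(delta) > POSITIVE_EVIDENCE_DELTA else "weak",
    )
    for name, (col_a, col_b) in (contrast_params or {}).items():
        result.contrasts[name] = paired_ttest(a[col_a], b[col_b])
    return result
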