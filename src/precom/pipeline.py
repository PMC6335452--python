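"""End-to-end orchestration: simulate (or load) a cohort, run the model-free
statistics, fit and compare the four models, correlate across tasks, and
optionally run a parameter-recovery study. Every stage derives its seed
deterministically from the global seed, so a run is reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, fitting, model_free, power, recovery
from .cohort import simulate_cohort
from .io import read_trials_csv, write_trials_csv

__all__ = ["PipelineConfig", "RunReport", "run_power_analysis", "run_pipeline", "load_config"]

run_power_analysis = power.required_sample_size


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    seed: int = 0
    n_subjects: int = 58
    tasks: tuple[str, ...] = ("effort", "delay")
    generative_model: str = "mm"
    prior_config: dict | None = None
    opt_out_prob: dict | None = None
    n_starts: int = 20
    exclude_always_never: bool = True
    run_recovery: bool = False
    recovery_n_reps: int = 10
    recovery_trials: int = 600
    dataset_csv: str | None = None  # fit a user-supplied dataset instead of simulating
    rewards_csv: str | None = None  # required with dataset_csv: subject_id, m_lr, m_sr
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**d)
        if isinstance(cfg.tasks, list):
            cfg.tasks = tuple(cfg.tasks)
        return cfg


@dataclass
class RunReport:
    config: PipelineConfig
    rates: model_free.RatesReport
    regressions: dict  # task -> RegressionReport
    fits: pd.DataFrame
    comparisons: dict  # (task, "choice"|"precom") -> ComparisonResult
    correlations: dict  # name -> (rho, p)
    recovery_report: recovery.RecoveryReport | None
    timings: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["== pipeline run =="]
        for task in self.config.tasks:
            agg = self.rates.aggregate
            row = agg[agg["task"] == task].iloc[0]
            lines.append(
                f"[{task}] precommit rate {row['precommit_rate']:.3f}, "
                f"opt-out rate {row['opt_out_rate']:.3f}"
            )
            for kind in ("choice", "precom"):
                comp = self.comparisons[(task, kind)]
                lines.append(f"[{task}] {kind} models:")
                lines.append("  " + comp.summary().replace("\n", "\n  "))
        for name, (rho, p) in self.correlations.items():
            lines.append(f"cross-task Spearman {name}: rho = {rho:.3f}, p = {p:.4f}")
        return "\n".join(lines)


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % 2**31)


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    return PipelineConfig.from_dict(data)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute simulate -> model-free -> fits -> comparison -> correlations
    (-> recovery); artifacts are written when ``output_dir`` is set."""
    timings = {}
    t0 = time.perf_counter()

    if config.dataset_csv:
        records = read_trials_csv(config.dataset_csv)
        if not config.rewards_csv:
            raise ValueError("rewards_csv (subject_id, m_lr, m_sr) is required with dataset_csv")
        rewards = pd.read_csv(config.rewards_csv)
        true_params = None
    else:
        cohort = simulate_cohort(
            n_subjects=config.n_subjects,
            prior_config=config.prior_config,
            seed=_stage_seed(config.seed, "simulate"),
            generative_model=config.generative_model,
            tasks=config.tasks,
            opt_out_prob=config.opt_out_prob,
        )
        records = cohort.records
        true_params = cohort.true_params
        rewards = true_params[["subject_id", "m_lr", "m_sr"]].drop_duplicates("subject_id")
    timings["simulate"] = time.perf_counter() - t0

    t = time.perf_counter()
    rates = model_free.behavioral_rates(records)
    regressions = {task: model_free.achievement_regression(records, task) for task in config.tasks}
    timings["model_free"] = time.perf_counter() - t

    t = time.perf_counter()
    fits = fitting.fit_cohort(
        records, rewards, tasks=config.tasks,
        n_starts=config.n_starts, seed=_stage_seed(config.seed, "fit"),
    )
    timings["fit"] = time.perf_counter() - t

    t = time.perf_counter()
    comparisons = {}
    excluded = comparison.always_never_precommit_subjects(records) if config.exclude_always_never else []
    for task in config.tasks:
        task_fits = fits[fits["task"] == task]

        def grab(model, outcome):
            return task_fits[(task_fits["model"] == model) & (task_fits["outcome"] == outcome)]

        mm, wp = grab("mm_choice", "choice"), grab("wp_choice", "choice")
        wp_ach = grab("wp_choice", "achievement")
        choice_cmp = comparison.compare_models(mm, wp)
        # iota during choice vs during the execution phase (achievement fit)
        choice_cmp.contrasts["iota_choice_vs_iota_reward"] = comparison.paired_ttest(
            wp.sort_values("subject_id")["est_willpower"].to_numpy(),
            wp_ach.sort_values("subject_id")["est_willpower"].to_numpy(),
        )
        comparisons[(task, "choice")] = choice_cmp
        comparisons[(task, "precom")] = comparison.compare_models(
            grab("mm_precom", "precommit_decision"),
            grab("wp_precom", "precommit_decision"),
            contrast_params={"theta_mm_vs_wp": ("est_sensitivity", "est_sensitivity")},
            exclude_subjects=excluded,
        )
    timings["compare"] = time.perf_counter() - t

    correlations = {}
    if set(config.tasks) >= {"effort", "delay"}:
        mm_pre = fits[(fits["model"] == "mm_precom")].pivot(
            index="subject_id", columns="task", values="est_bias"
        )
        correlations["bias_b"] = model_free.cross_task_correlation(
            mm_pre["effort"], mm_pre["delay"]
        )
        benefit = model_free.precommitment_benefit(records).pivot(
            index="subject_id", columns="task", values="precommitment_benefit"
        ).dropna()
        if len(benefit) >= 3:
            correlations["precommitment_benefit"] = model_free.cross_task_correlation(
                benefit["effort"], benefit["delay"]
            )

    recovery_report = None
    if config.run_recovery:
        t = time.perf_counter()
        recovery_report = recovery.recovery_study_uniform(
            model="mm_choice",
            trials_per_subject=config.recovery_trials,
            n_reps=config.recovery_n_reps,
            seed=_stage_seed(config.seed, "recovery"),
        )
        timings["recovery"] = time.perf_counter() - t

    report = RunReport(
        config=config,
        rates=rates,
        regressions=regressions,
        fits=fits,
        comparisons=comparisons,
        correlations=correlations,
        recovery_report=recovery_report,
        timings=timings,
    )
    if config.output_dir:
        _write_artifacts(report, records, true_params)
    return report


def _write_artifacts(report: RunReport, records: pd.DataFrame, true_params) -> None:
    out = Path(report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trials_csv(records, out / "trials.csv")
    if true_params is not None:
        true_params.to_csv(out / "true_params.csv", index=False)
    report.fits.to_csv(out / "fits.csv", index=False)
    report.rates.per_subject.to_csv(out / "rates_per_subject.csv", index=False)
    report.rates.aggregate.to_csv(out / "rates_aggregate.csv", index=False)
    report.rates.achievement_by_cell.to_csv(out / "achievement_by_cell.csv", index=False)
    for task, reg in report.regressions.items():
        reg.wald.to_csv(out / f"regression_wald_{task}.csv")
        reg.cell_probabilities.to_csv(out / f"regression_cells_{task}.csv", index=False)
    if report.recovery_report is not None:
        report.recovery_report.replicates.to_csv(out / "recovery_replicates.csv", index=False)
        report.recovery_report.summary.to_csv(out / "recovery_summary.csv", index=False)
    (out / "report.txt").write_text(report.summary() + "\n")
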