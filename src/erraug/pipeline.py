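"""End-to-end pipeline: simulate -> templates -> curve fits -> statistics.

Also hosts the "reproduce" report, which recomputes the paradigm's
benchmark quantities from scratch:

* the analytic stability limit of gain augmentation, 1/lambda;
* parameter-recovery means for the exponential fit under the control and
  offset reference parameter sets at realistic catch-trial noise;
* the pooled-SD effect sizes for learning amount and rate from the
  reference group summaries;
* the average percent error reduction across the four groups.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .config import RunConfig
from .curves import fit_all_subjects, parameter_recovery
from .io import write_manifest, write_trial_log
from .simulate import (
    GROUPS,
    LearnerState,
    make_schedule,
    simulate_experiment,
    theoretical_gain_limit,
)
from .stats import cohens_d, percent_reduction_summary, run_analysis_plan

log = logging.getLogger("erraug")

__all__ = [
    "schedule_from_config",
    "state_from_config",
    "simulate_to_dir",
    "training_catch_numbers",
    "recovery_summary",
    "reference_effect_sizes",
    "reference_percent_reduction",
    "reproduce",
]


def schedule_from_config(cfg: RunConfig):
    return make_schedule(
        cfg.seed,
        baseline_trials=cfg.baseline_trials,
        training_trials=cfg.training_trials,
        washout_trials=cfg.washout_trials,
        probe_block=cfg.probe_block,
        baseline_probe_trials=cfg.baseline_probe_trials,
        radius_m=cfg.radius_m,
    )


def state_from_config(cfg: RunConfig) -> LearnerState:
    return LearnerState(
        lambda_frac=cfg.lambda_frac,
        motor_noise_sd_deg=cfg.motor_noise_sd_deg,
        online_correction_c=cfg.online_correction_c,
        learn_on_catch=cfg.learn_on_catch,
    )


def simulate_to_dir(cfg: RunConfig, out_dir) -> pd.DataFrame:
    """Simulate the experiment and write one trial log per subject."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = schedule_from_config(cfg)
    frame = simulate_experiment(
        cfg.seed,
        group_size=cfg.group_size,
        state=state_from_config(cfg),
        schedule=schedule,
    )
    for sid, sub in frame.groupby("subject_id"):
        write_trial_log(sub, out_dir / f"{sid}_trials.csv")
    write_manifest(
        out_dir / "manifest.json",
        cfg.config_hash(),
        cfg.seed,
        {"n_subjects": frame["subject_id"].nunique(), "n_trials": len(frame)},
    )
    log.info("simulated %d trials for %d subjects", len(frame), frame["subject_id"].nunique())
    return frame


def training_catch_numbers(cfg: RunConfig) -> np.ndarray:
    """Movement numbers (1-based, within phase) of the training catch trials."""
    schedule = schedule_from_config(cfg)
    return np.array(
        [t.phase_index for t in schedule.phase("training") if t.is_catch], dtype=float
    )


def recovery_summary(cfg: RunConfig, group: str, seed_offset: int = 0) -> dict:
    """Mean recovered (A, B, C) for one reference parameter set."""
    ref = reference.GROUP_SUMMARY[group]
    recs = parameter_recovery(
        ref.amount_A_m,
        ref.time_constant_B,
        ref.steady_C_m,
        training_catch_numbers(cfg),
        noise_sd_m=cfg.noise_sd_m,
        n_replicates=cfg.recovery_replicates,
        seed=(cfg.seed + seed_offset) % (2**31),
    )
    return {
        "group": group,
        "mean_A_m": float(recs["A"].mean()),
        "mean_B_movements": float(recs["B"].mean()),
        "mean_C_m": float(recs["C"].mean()),
        "true_A_m": ref.amount_A_m,
        "true_B_movements": ref.time_constant_B,
        "true_C_m": ref.steady_C_m,
        "n_replicates": len(recs),
        "n_converged": int(recs["converged"].sum()),
    }


def reference_effect_sizes() -> dict:
    """Pooled-SD Cohen's d for learning amount and rate (reference summaries)."""
    (m1, s1), (m2, s2) = reference.AMOUNT_EFFECT["offset"], reference.AMOUNT_EFFECT["control"]
    d_amount = cohens_d(m1, s1, m2, s2)
    (m1, s1), (m2, s2) = reference.RATE_EFFECT["x2"], reference.RATE_EFFECT["control"]
    d_rate = cohens_d(m1, s1, m2, s2)
    return {"d_amount": d_amount, "d_rate": d_rate}


def reference_percent_reduction() -> float:
    """Average percent error reduction over the four reference groups."""
    order = ["control", "x2", "offset", "x3p1"]
    initial = [reference.GROUP_SUMMARY[g].initial_error_m for g in order]
    steady = [reference.GROUP_SUMMARY[g].steady_C_m for g in order]
    return percent_reduction_summary(initial, steady)


def reproduce(cfg: RunConfig, out_dir=None) -> dict:
    """Run the full pipeline and assemble the benchmark report.

    Simulates the 16-subject experiment, fits every subject's training and
    washout curves, runs the five planned group comparisons, and computes
    the analytic / recovery / worked-example benchmarks with pass-fail
    flags against the reference values.
    """
    trial_log = (
        simulate_to_dir(cfg, out_dir) if out_dir is not None else simulate_experiment(
            cfg.seed, group_size=cfg.group_size, state=state_from_config(cfg),
            schedule=schedule_from_config(cfg),
        )
    )
    fits = fit_all_subjects(trial_log)
    plan = run_analysis_plan(fits, group_order=[g for g in GROUPS])
    log.info("fitted %d curves (%d converged)", len(fits), int(fits["converged"].sum()))

    gain_limit = theoretical_gain_limit(cfg.lambda_frac)
    rec_control = recovery_summary(cfg, "control", seed_offset=0)
    rec_offset = recovery_summary(cfg, "offset", seed_offset=1)
    effects = reference_effect_sizes()
    pct = reference_percent_reduction()

    checks = {
        "gain_limit_near_3p1": abs(gain_limit - 3.1) < 0.05,
        "recovery_control_B_within_10pct": (
            abs(rec_control["mean_B_movements"] - rec_control["true_B_movements"])
            <= 0.10 * rec_control["true_B_movements"]
        ),
        "recovery_offset_A_within_10pct": (
            abs(rec_offset["mean_A_m"] - rec_offset["true_A_m"])
            <= 0.10 * rec_offset["true_A_m"]
        ),
        "cohens_d_amount_1p9": round(effects["d_amount"], 1) == 1.9,
        "cohens_d_rate_1p6": round(effects["d_rate"], 1) == 1.6,
        "percent_reduction_68": round(pct) == 68,
    }
    return {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_trials_simulated": int(len(trial_log)),
        "n_fits": int(len(fits)),
        "n_fits_converged": int(fits["converged"].sum()),
        "gain_limit": gain_limit,
        "recovery_control": rec_control,
        "recovery_offset": rec_offset,
        "effect_sizes": effects,
        "percent_reduction": pct,
        "group_comparisons": plan,
        "fits": fits,
        "checks": checks,
    }


def format_report(report: dict) -> str:
    """Human-readable summary of a reproduce() report."""
    lines = [
        "error-augmentation benchmark report",
        f"  config hash: {report['config_hash']}   seed: {report['seed']}",
        f"  simulated trials: {report['n_trials_simulated']}, "
        f"curve fits: {report['n_fits']} ({report['n_fits_converged']} converged)",
        "",
        f"  theoretical gain stability limit 1/lambda = {report['gain_limit']:.3f}",
        f"  recovery (control): mean B = {report['recovery_control']['mean_B_movements']:.1f} "
        f"movements (true {report['recovery_control']['true_B_movements']:.1f})",
        f"  recovery (offset):  mean A = {report['recovery_offset']['mean_A_m'] * 1e3:.1f} mm "
        f"(true {report['recovery_offset']['true_A_m'] * 1e3:.1f})",
        f"  Cohen's d, learning amount (offset vs control): {report['effect_sizes']['d_amount']:.2f}",
        f"  Cohen's d, time constant (x2 vs control):       {report['effect_sizes']['d_rate']:.2f}",
        f"  average percent error reduction: {report['percent_reduction']:.1f}%",
        "",
        "  planned group comparisons (simulated cohort):",
    ]
    for name, res in report["group_comparisons"].items():
        a = res["anova"]
        lines.append(
            f"    {name:12s} F({a.df_between},{a.df_within}) = {a.F:7.2f}, p = {a.p:.4f}; "
            f"Kruskal-Wallis H = {res['kruskal']['H']:.2f}, p = {res['kruskal']['p']:.4f}"
        )
    lines.append("")
    lines.append("  checks:")
    for name, ok in report["checks"].items():
        lines.append(f"    [{'PASS' if ok else 'FAIL'}] {name}")
    return "\n".join(lines)
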