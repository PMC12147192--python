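"""End-to-end orchestration: trial bundle -> per-step metrics -> summary."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort_analysis import ParticipantSummary, summarize_participant, summary_table
from .gait_events import DEFAULT_GRF_THRESHOLD_N, StepSegment, segment_steps
from .io_preprocess import GaitTrial, preprocess, read_trial
from .step_metrics import StepMetrics, compute_step_metrics, metrics_table

__all__ = ["analyze_trial", "analyze_directory", "steps_table"]


def analyze_trial(
    trial: GaitTrial, grf_threshold_n: float = DEFAULT_GRF_THRESHOLD_N
) -> tuple[list[StepSegment], list[StepMetrics]]:
    """Filter, segment and measure one trial.

    Returns all detected step segments (including excluded ones, with
    reasons) and the metrics of the included steps.
    """
    filtered = preprocess(trial)
    steps = segment_steps(filtered, grf_threshold_n)
    metrics: list[StepMetrics] = []
    for i, step in enumerate(steps):
        if step.excluded:
            continue
        m = compute_step_metrics(filtered, step, step_index=i)
        if m is not None:
            metrics.append(m)
    return steps, metrics


def steps_table(steps: list[StepSegment], participant_id: str) -> pd.DataFrame:
    """Per-step events table (``steps.tsv`` layout)."""
    rows = []
    for i, s in enumerate(steps):
        rows.append({
            "participant_id": participant_id,
            "step_index": i,
            "leading_side": s.leading_side,
            "transfer_direction": s.transfer_direction,
            "t_ic": s.t_ic,
            "t_cfo": s.t_cfo,
            "t_completion": s.t_completion,
            "t_next_ic": s.t_next_ic,
            "excluded": s.excluded,
            "reason": s.reason,
        })
    return pd.DataFrame(rows)


def analyze_directory(
    trials_dir: str | Path,
    out_dir: str | Path,
    grf_threshold_n: float = DEFAULT_GRF_THRESHOLD_N,
) -> list[ParticipantSummary]:
    """Analyze every trial bundle under ``trials_dir`` and write the
    events, step-metrics and participant-summary tables to ``out_dir``."""
    trials_dir, out_dir = Path(trials_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stems = sorted(p.with_name(p.name[: -len(".meta.json")])
                   for p in trials_dir.glob("*.meta.json"))
    if not stems:
        raise FileNotFoundError(f"no trial bundles (*.meta.json) under {trials_dir}")
    all_steps, all_metrics, summaries = [], [], []
    for stem in stems:
        trial = read_trial(stem)
        pid = trial.meta.participant_id
        steps, metrics = analyze_trial(trial, grf_threshold_n)
        all_steps.append(steps_table(steps, pid))
        all_metrics.append(metrics_table(metrics, pid))
        summaries.append(summarize_participant(pid, metrics))
    pd.concat(all_steps, ignore_index=True).to_csv(
        out_dir / "steps.tsv", sep="\t", index=False)
    pd.concat(all_metrics, ignore_index=True).to_csv(
        out_dir / "step_metrics.tsv", sep="\t", index=False)
    summary_table(summaries).to_csv(
        out_dir / "participant_summary.tsv", sep="\t", index=False)
    return summaries
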