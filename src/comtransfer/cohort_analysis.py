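"""Participant-level aggregation of per-step CoM-transfer metrics.

Builds the outcomes a gait study reports per participant: the evolution of
transfer asymmetry across the three gait events (IC, CFO, completion),
relative phase contributions to the final asymmetry, the prediction error
of the CFO projection, step-to-step control correlations, variability, and
the regression of double-support changes on trailing-limb work. Group
inference (mixed models, ANOVA, multiplicity corrections) is deliberately
left to downstream statistics software; this module emits the tidy tables
those fits consume.

Asymmetry of any transfer metric is the non-paretic-step mean minus the
paretic-step mean. Transfer magnitudes are signed negative, so a positive
asymmetry means greater CoM transfer toward the non-paretic side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .step_metrics import StepMetrics

__all__ = [
    "InsufficientDataError",
    "ParticipantSummary",
    "asymmetry_evolution",
    "phase_contributions",
    "cfo_prediction_mae",
    "stepwise_control_correlation",
    "transfer_variability",
    "work_vs_delta_regression",
    "velocity_offset_for_fp",
    "relative_increase_pct",
    "fp_share_of_final_asymmetry",
    "summarize_participant",
    "summary_table",
]

_SIDE_MEAN_FIELDS = (
    "proj_ic", "proj_cfo", "final_mag", "fp_ic", "v_ic",
    "work_ds", "avg_power_ds", "avg_mlgrf_ds", "avg_vel_ds", "ess_duration",
)


class InsufficientDataError(ValueError):
    """Raised when a participant has too few included steps on a side."""


@dataclass
class ParticipantSummary:
    participant_id: str
    n_steps_p: int
    n_steps_np: int
    means_p: dict[str, float]
    means_np: dict[str, float]
    asym_ic: float
    asym_cfo: float
    asym_final: float
    contrib_ic: float | None
    contrib_ds: float | None
    contrib_ess: float | None
    mae_p: float
    mae_np: float
    r_p: float | None
    r_np: float | None
    sd_ic_p: float
    sd_ic_np: float
    sd_final_p: float
    sd_final_np: float


def _split(steps: list[StepMetrics]) -> tuple[list[StepMetrics], list[StepMetrics]]:
    p = [s for s in steps if s.transfer_direction == "paretic"]
    np_ = [s for s in steps if s.transfer_direction == "non_paretic"]
    return p, np_


def _require(steps: list[StepMetrics], n: int, what: str) -> None:
    p, np_ = _split(steps)
    if len(p) < n or len(np_) < n:
        raise InsufficientDataError(
            f"{what} needs >= {n} included steps per side "
            f"(got paretic={len(p)}, non_paretic={len(np_)})"
        )


def asymmetry_evolution(
    steps: list[StepMetrics],
) -> tuple[float, float, float]:
    """Transfer asymmetry (non-paretic mean minus paretic mean) at IC, CFO
    and completion."""
    _require(steps, 3, "asymmetry evolution")
    p, np_ = _split(steps)
    out = []
    for fld in ("proj_ic", "proj_cfo", "final_mag"):
        m_p = float(np.mean([getattr(s, fld) for s in p]))
        m_np = float(np.mean([getattr(s, fld) for s in np_]))
        out.append(m_np - m_p)
    return tuple(out)  # type: ignore[return-value]


def phase_contributions(
    asym_ic: float, asym_cfo: float, asym_final: float
) -> tuple[float, float, float]:
    """Percent contributions of IC, double support and early single
    support to the final transfer asymmetry.

    The final asymmetry telescopes as asym_ic + (asym_cfo - asym_ic) +
    (asym_final - asym_cfo), so the three shares sum to 100% exactly.
    """
    if abs(asym_final) < 1e-6:
        raise ValueError("final asymmetry below 1e-6 m: contributions undefined")
    contrib_ic = asym_ic / asym_final * 100.0
    contrib_ds = (asym_cfo - asym_ic) / asym_final * 100.0
    contrib_ess = (asym_final - asym_cfo) / asym_final * 100.0
    return contrib_ic, contrib_ds, contrib_ess


def cfo_prediction_mae(steps: list[StepMetrics]) -> tuple[float, float]:
    """Per-side mean absolute error of the CFO projection against the
    measured final transfer magnitude (m)."""
    p, np_ = _split(steps)
    mae = lambda ss: float(np.mean([abs(s.proj_cfo - s.final_mag) for s in ss])) if ss else math.nan
    return mae(p), mae(np_)


def stepwise_control_correlation(
    steps: list[StepMetrics],
) -> tuple[float | None, float | None]:
    """Per-side Pearson r between proj_ic and its double-support change.

    A strongly negative r indicates step-to-step compensation: steps
    projected to transfer less at IC receive a larger corrective change
    during double support.
    """
    _require(steps, 5, "step-to-step control correlation")
    out = []
    for ss in _split(steps):
        x = np.array([s.proj_ic for s in ss])
        y = np.array([s.delta_ds for s in ss])
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            out.append(None)
        else:
            out.append(float(stats.pearsonr(x, y).statistic))
    return out[0], out[1]


def transfer_variability(
    steps: list[StepMetrics],
) -> tuple[float, float, float, float]:
    """Across-step sample SDs (n-1) of the IC projection and the final
    magnitude, per side: (sd_ic_p, sd_ic_np, sd_final_p, sd_final_np)."""
    _require(steps, 3, "transfer variability")
    p, np_ = _split(steps)
    sd = lambda ss, fld: float(np.std([getattr(s, fld) for s in ss], ddof=1))
    return sd(p, "proj_ic"), sd(np_, "proj_ic"), sd(p, "final_mag"), sd(np_, "final_mag")


def work_vs_delta_regression(
    steps: list[StepMetrics],
) -> dict[str, tuple[float, float, float]]:
    """OLS of the double-support projection change on trailing-limb work,
    per side: {"paretic" | "non_paretic": (slope, intercept, r_squared)}."""
    _require(steps, 5, "work regression")
    out: dict[str, tuple[float, float, float]] = {}
    for name, ss in zip(("paretic", "non_paretic"), _split(steps)):
        w = np.array([s.work_ds for s in ss])
        d = np.array([s.delta_ds for s in ss])
        if np.ptp(w) == 0.0:
            raise ValueError(f"zero work variance on {name} side: regression undefined")
        fit = stats.linregress(w, d)
        out[name] = (float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2)
    return out


def velocity_offset_for_fp(
    delta_fp: float, fp_coefficient: float, v_coefficient: float
) -> float:
    """CoM-velocity increase whose velocity-related component offsets the
    foot-placement-related component of a foot-placement increase.

    With projected magnitude = fp * c_fp + v * c_v, a widening |delta_fp|
    is cancelled by delta_v = delta_fp * c_fp / c_v. At the cohort-typical
    coefficients (c_fp ~ 1.05, c_v ~ 0.10 s) a 1 cm foot-placement change
    demands ~0.1 m/s of extra velocity — a tenfold disparity in influence.
    """
    if v_coefficient <= 0:
        raise ValueError("velocity coefficient must be positive")
    return delta_fp * fp_coefficient / v_coefficient


def relative_increase_pct(delta: float, baseline: float) -> float:
    """Percentage increase of ``delta`` over ``baseline``.

    Puts a required velocity change in context: the ~0.1 m/s needed to
    offset 1 cm of foot placement is a ~67% increase over a typical
    0.15 m/s mediolateral CoM velocity at IC.
    """
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return delta / baseline * 100.0


def fp_share_of_final_asymmetry(contrib_ic: float, influence_ratio: float) -> float:
    """Share (%) of the final asymmetry attributable to foot placement,
    given IC's contribution and the FP:velocity influence ratio.

    The IC contribution splits between its foot-placement and velocity
    components in proportion ratio : 1, so the FP share is
    contrib_ic * ratio / (ratio + 1).
    """
    if influence_ratio <= 0:
        raise ValueError("influence ratio must be positive")
    return contrib_ic * influence_ratio / (influence_ratio + 1.0)


def summarize_participant(
    participant_id: str, steps: list[StepMetrics]
) -> ParticipantSummary:
    """All participant-level outcomes from that participant's included steps."""
    p, np_ = _split(steps)
    asym_ic, asym_cfo, asym_final = asymmetry_evolution(steps)
    try:
        contribs = phase_contributions(asym_ic, asym_cfo, asym_final)
    except ValueError:
        contribs = (None, None, None)
    mae_p, mae_np = cfo_prediction_mae(steps)
    try:
        r_p, r_np = stepwise_control_correlation(steps)
    except InsufficientDataError:
        r_p = r_np = None
    sds = transfer_variability(steps)
    side_means = lambda ss: {f: float(np.mean([getattr(s, f) for s in ss])) for f in _SIDE_MEAN_FIELDS}
    return ParticipantSummary(
        participant_id=participant_id,
        n_steps_p=len(p),
        n_steps_np=len(np_),
        means_p=side_means(p),
        means_np=side_means(np_),
        asym_ic=asym_ic,
        asym_cfo=asym_cfo,
        asym_final=asym_final,
        contrib_ic=contribs[0],
        contrib_ds=contribs[1],
        contrib_ess=contribs[2],
        mae_p=mae_p,
        mae_np=mae_np,
        r_p=r_p,
        r_np=r_np,
        sd_ic_p=sds[0],
        sd_ic_np=sds[1],
        sd_final_p=sds[2],
        sd_final_np=sds[3],
    )


def summary_table(summaries: list[ParticipantSummary]) -> pd.DataFrame:
    """One-row-per-participant table (``participant_summary.tsv`` layout)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "participant_id": s.participant_id,
            "n_steps_p": s.n_steps_p,
            "n_steps_np": s.n_steps_np,
        }
        for fld in _SIDE_MEAN_FIELDS:
            row[f"{fld}_mean_p"] = s.means_p[fld]
            row[f"{fld}_mean_np"] = s.means_np[fld]
        for fld in (
            "asym_ic", "asym_cfo", "asym_final",
            "contrib_ic", "contrib_ds", "contrib_ess",
            "mae_p", "mae_np", "r_p", "r_np",
            "sd_ic_p", "sd_ic_np", "sd_final_p", "sd_final_np",
        ):
            row[fld] = getattr(s, fld)
        rows.append(row)
    return pd.DataFrame(rows)
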