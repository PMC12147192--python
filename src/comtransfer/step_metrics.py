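"""Per-step scalar metrics of frontal-plane CoM transfer.

For each included step the pipeline evaluates, in the stance-foot frame of
the leading limb: foot placement and CoM velocity at initial contact, the
LIPM-projected transfer magnitude at IC and CFO with its foot-placement /
velocity decomposition, the final (measured) transfer magnitude at
completion, the phase changes ``delta_ds = proj_cfo - proj_ic`` and
``delta_ess = final_mag - proj_cfo``, and the trailing-limb mechanical
work, power, force and velocity over double support.

Sign convention: in the stance frame the pivot-to-CoM direction is
negative, so positions are negative and the approach velocity positive,
for either leading side. The lab-to-stance mapping is ``sigma = +1`` for
right stance and ``-1`` for left (lab +x points to the participant's
right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lipm_core
from .gait_events import StepSegment
from .io_preprocess import GaitTrial, sample_at
from .lipm_core import PendulumState, ProjectionStatus, TransferProjection

__all__ = [
    "StepMetrics",
    "stance_sign",
    "stance_frame",
    "step_projections",
    "final_transfer_magnitude",
    "trailing_limb_work",
    "compute_step_metrics",
    "metrics_table",
]


def stance_sign(leading_side: str) -> float:
    """Lab-to-stance-frame mediolateral sign: +1 right stance, -1 left."""
    if leading_side not in ("left", "right"):
        raise ValueError(f"unknown side {leading_side!r}")
    return 1.0 if leading_side == "right" else -1.0


@dataclass
class StepMetrics:
    """All per-step scalars for one CoM transfer (SI units; distances
    signed negative per the stance-frame convention)."""

    step_index: int
    leading_side: str
    transfer_direction: str
    fp_ic: float
    v_ic: float
    proj_ic: float
    proj_cfo: float
    final_mag: float
    delta_ds: float
    delta_ess: float
    work_ds: float
    avg_power_ds: float
    avg_mlgrf_ds: float
    avg_vel_ds: float
    ds_duration: float
    ess_duration: float
    fp_component: float
    v_component: float
    fp_coefficient: float
    v_coefficient: float


def stance_frame(trial: GaitTrial, leading_side: str, t: float) -> PendulumState:
    """CoM state in the leading-foot stance frame at time ``t``.

    ``x0 = sigma * (com_x - foot_x)`` (negative when the CoM is medial to
    the pivot), ``v0 = sigma * com_vx`` (positive toward the pivot),
    height = instantaneous CoM height.
    """
    if not trial.filtered:
        raise ValueError("trial must be preprocessed before building stance frames")
    sigma = stance_sign(leading_side)
    kin_t = trial.kin_time
    com_x = sample_at(trial.kin["com_x"].to_numpy(), kin_t, t)
    foot_x = sample_at(trial.foot_col(leading_side, "x"), kin_t, t)
    com_vx = sample_at(trial.kin["com_vx"].to_numpy(), kin_t, t)
    height = sample_at(trial.kin["com_z"].to_numpy(), kin_t, t)
    return PendulumState(
        x0=sigma * (com_x - foot_x), v0=sigma * com_vx, height=height
    )


def step_projections(
    trial: GaitTrial, step: StepSegment
) -> tuple[TransferProjection, TransferProjection]:
    """LIPM transfer projections at IC and CFO of one step."""
    proj_ic = lipm_core.projected_transfer_magnitude(
        stance_frame(trial, step.leading_side, step.t_ic)
    )
    proj_cfo = lipm_core.projected_transfer_magnitude(
        stance_frame(trial, step.leading_side, step.t_cfo)
    )
    return proj_ic, proj_cfo


def final_transfer_magnitude(trial: GaitTrial, step: StepSegment) -> float:
    """Signed ML CoM-pivot distance at the detected transfer completion."""
    state = stance_frame(trial, step.leading_side, step.t_completion)
    return state.x0


def trailing_limb_work(
    trial: GaitTrial, step: StepSegment
) -> tuple[float, float, float, float]:
    """Trailing-limb ML work, mean power, mean ML GRF and mean CoM
    velocity over the double-support window ``[t_ic, t_cfo]``.

    Instantaneous power is the product of the trailing-belt mediolateral
    GRF and the mediolateral CoM velocity, both mapped into the
    leading-stance sign convention (positive power drives the CoM toward
    the leading pivot). Work is the trapezoidal time integral at the
    kinetic rate, with the window endpoints interpolated exactly; averages
    are time means over the window.
    """
    sigma = stance_sign(step.leading_side)
    trailing = "left" if step.leading_side == "right" else "right"
    t0, t1 = step.t_ic, step.t_cfo
    tk = trial.kinet_time
    inner = tk[(tk > t0) & (tk < t1)]
    if inner.size < 3:
        raise ValueError("double-support window shorter than 3 kinetic samples")
    tw = np.concatenate(([t0], inner, [t1]))
    grf_x = trial.grf_col(trailing, "x")
    grf_w = sigma * np.interp(tw, tk, grf_x)
    v_w = sigma * np.interp(tw, trial.kin_time, trial.kin["com_vx"].to_numpy())
    p_w = grf_w * v_w
    duration = t1 - t0
    work = float(np.trapezoid(p_w, tw))
    return (
        work,
        work / duration,
        float(np.trapezoid(grf_w, tw)) / duration,
        float(np.trapezoid(v_w, tw)) / duration,
    )


def compute_step_metrics(
    trial: GaitTrial, step: StepSegment, step_index: int = 0
) -> StepMetrics | None:
    """Assemble all per-step scalars; flags and skips invalid steps.

    Returns ``None`` (and marks the step excluded) when the LIPM
    projection at IC or CFO has no minimum (``fall_over_pivot``) or the
    double-support window is too short for work integration. By
    construction ``final_mag = proj_ic + delta_ds + delta_ess`` exactly.
    """
    ic_state = stance_frame(trial, step.leading_side, step.t_ic)
    proj_ic, proj_cfo = step_projections(trial, step)
    if (
        proj_ic.status is ProjectionStatus.FALL_OVER_PIVOT
        or proj_cfo.status is ProjectionStatus.FALL_OVER_PIVOT
    ):
        step.exclude("fall_over_pivot")
        return None
    try:
        work, avg_power, avg_grf, avg_vel = trailing_limb_work(trial, step)
    except ValueError:
        step.exclude("incomplete")
        return None
    final_mag = final_transfer_magnitude(trial, step)
    return StepMetrics(
        step_index=step_index,
        leading_side=step.leading_side,
        transfer_direction=step.transfer_direction,
        fp_ic=ic_state.x0,
        v_ic=ic_state.v0,
        proj_ic=proj_ic.magnitude,
        proj_cfo=proj_cfo.magnitude,
        final_mag=final_mag,
        delta_ds=proj_cfo.magnitude - proj_ic.magnitude,
        delta_ess=final_mag - proj_cfo.magnitude,
        work_ds=work,
        avg_power_ds=avg_power,
        avg_mlgrf_ds=avg_grf,
        avg_vel_ds=avg_vel,
        ds_duration=step.t_cfo - step.t_ic,
        ess_duration=step.t_completion - step.t_cfo,
        fp_component=proj_ic.fp_component,
        v_component=proj_ic.v_component,
        fp_coefficient=proj_ic.fp_coefficient,
        v_coefficient=proj_ic.v_coefficient,
    )


def metrics_table(metrics: list[StepMetrics], participant_id: str) -> pd.DataFrame:
    """Tidy one-row-per-step table (``step_metrics.tsv`` layout)."""
    df = pd.DataFrame([vars(m) for m in metrics])
    df.insert(0, "participant_id", participant_id)
    return df
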