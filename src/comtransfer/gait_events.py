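"""Gait event detection and step segmentation from treadmill force data.

Three events delimit each step's CoM transfer: initial contact (IC) of the
leading foot, contralateral foot off (CFO) ending double support, and
transfer completion — the instant of minimum mediolateral distance between
the CoM and the stance-foot ground projection during single support.

IC and CFO are detected from the per-belt vertical ground reaction force
with a threshold crossing (default 20 N) and a 50 ms debounce; crossing
times are linearly interpolated between samples. Steps overlapping
annotation intervals (handrail, toe drag) or showing belt crossover at IC
are flagged excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import GaitTrial, sample_at

__all__ = [
    "DEFAULT_GRF_THRESHOLD_N",
    "DEBOUNCE_S",
    "SideEvents",
    "StepSegment",
    "detect_contact_events",
    "find_transfer_completion",
    "segment_steps",
]

DEFAULT_GRF_THRESHOLD_N = 20.0
#: Minimum time the vertical GRF must persist beyond the threshold for a
#: crossing to count as a contact/off event.
DEBOUNCE_S = 0.050


@dataclass
class SideEvents:
    """Interpolated contact (IC) and foot-off times for one belt/foot."""

    side: str
    ic_times: list[float] = field(default_factory=list)
    off_times: list[float] = field(default_factory=list)


@dataclass
class StepSegment:
    """One step's event times, stance side and exclusion state.

    A *paretic* step transfers the body toward the paretic (leading) limb.
    """

    leading_side: str
    transfer_direction: str  # "paretic" | "non_paretic"
    t_ic: float
    t_cfo: float | None = None
    t_completion: float | None = None
    t_next_ic: float | None = None
    excluded: bool = False
    reason: str | None = None

    def exclude(self, reason: str) -> None:
        if not self.excluded:
            self.excluded = True
            self.reason = reason


def _threshold_crossings(
    t: np.ndarray, v: np.ndarray, threshold: float, debounce_samples: int
) -> tuple[list[float], list[float]]:
    """Debounced upward/downward threshold crossings, linearly interpolated."""
    above = v >= threshold
    rises: list[float] = []
    falls: list[float] = []
    idx = np.flatnonzero(np.diff(above.astype(int)))
    for i in idx:
        # crossing between samples i and i+1
        seg = above[i + 1 : i + 1 + debounce_samples]
        if seg.size < debounce_samples:
            continue  # too close to the trial end to qualify
        persistent = seg.all() if above[i + 1] else (~seg).all()
        if not persistent:
            continue
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        t_cross = t[i] + frac * (t[i + 1] - t[i])
        (rises if above[i + 1] else falls).append(float(t_cross))
    return rises, falls


def detect_contact_events(
    trial: GaitTrial, threshold_n: float = DEFAULT_GRF_THRESHOLD_N
) -> dict[str, SideEvents]:
    """Detect IC and foot-off events from the filtered vertical GRF.

    Returns a dict ``{"left": SideEvents, "right": SideEvents}``. An IC is
    an upward crossing of the vertical GRF through ``threshold_n`` that
    stays supra-threshold for at least 50 ms; a foot-off is the mirrored
    downward crossing.
    """
    if not trial.filtered:
        raise ValueError("trial must be preprocessed (filtered) before event detection")
    t = trial.kinet_time
    debounce = max(1, int(round(DEBOUNCE_S * trial.meta.kinet_rate_hz)))
    out: dict[str, SideEvents] = {}
    for side in ("left", "right"):
        vz = trial.grf_col(side, "z")
        rises, falls = _threshold_crossings(t, vz, threshold_n, debounce)
        if not rises and not falls:
            warnings.warn(f"no contact events found on the {side} belt", stacklevel=2)
        out[side] = SideEvents(side=side, ic_times=rises, off_times=falls)
    return out


def find_transfer_completion(
    trial: GaitTrial, step: StepSegment
) -> tuple[float | None, str | None]:
    """Locate the transfer-completion instant within single support.

    Searches the kinematic samples strictly inside ``(t_cfo, t_next_ic)``
    for the minimum of |com_x - stance-foot x| and refines the time by a
    parabolic fit through the minimum and its neighbors. Returns
    ``(t_completion, flag)`` where flag is ``"boundary_minimum"`` when the
    discrete minimum sits on the window edge (the CoM never turned around
    inside single support) or ``"incomplete"`` when the window holds fewer
    than 3 kinematic samples.
    """
    if step.t_cfo is None or step.t_next_ic is None:
        return None, "incomplete"
    t = trial.kin_time
    mask = (t > step.t_cfo) & (t < step.t_next_ic)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        return None, "incomplete"
    com_x = trial.kin["com_x"].to_numpy()[idx]
    foot_x = trial.foot_col(step.leading_side, "x")[idx]
    d = np.abs(com_x - foot_x)
    k = int(np.argmin(d))
    if k == 0 or k == idx.size - 1:
        return float(t[idx[k]]), "boundary_minimum"
    # parabolic vertex through (k-1, k, k+1) for sub-sample timing
    y0, y1, y2 = d[k - 1], d[k], d[k + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom > 0 else 0.0
    dt = t[idx[k] + 1] - t[idx[k]] if idx[k] + 1 < t.size else t[idx[k]] - t[idx[k] - 1]
    return float(t[idx[k]] + np.clip(shift, -1.0, 1.0) * dt), None


def segment_steps(
    trial: GaitTrial, threshold_n: float = DEFAULT_GRF_THRESHOLD_N
) -> list[StepSegment]:
    """Segment a trial into steps and apply exclusion rules.

    Each IC opens a step led by that foot; its CFO is the first
    contralateral foot-off after IC and the step closes at the next
    contralateral IC. Steps are flagged excluded when contacts do not
    alternate (``incomplete``), when they overlap an annotation interval
    (annotation label as reason), when the leading foot lands across the
    belt midline (``crossover``), or when no interior distance minimum
    exists (``boundary_minimum``).
    """
    events = detect_contact_events(trial, threshold_n)
    contacts = sorted(
        [(t, side) for side in ("left", "right") for t in events[side].ic_times]
    )
    steps: list[StepSegment] = []
    paretic = trial.meta.paretic_side
    for j, (t_ic, side) in enumerate(contacts):
        other = "right" if side == "left" else "left"
        step = StepSegment(
            leading_side=side,
            transfer_direction="paretic" if side == paretic else "non_paretic",
            t_ic=t_ic,
        )
        steps.append(step)
        if j + 1 >= len(contacts):
            step.exclude("incomplete")  # trial-boundary step
            continue
        t_next, side_next = contacts[j + 1]
        if side_next != other:
            step.exclude("incomplete")  # non-alternating contacts
            continue
        step.t_next_ic = t_next
        offs = [t for t in events[other].off_times if t_ic < t < t_next]
        if not offs:
            step.exclude("incomplete")
            continue
        step.t_cfo = offs[0]
        t_comp, flag = find_transfer_completion(trial, step)
        step.t_completion = t_comp
        if flag is not None:
            step.exclude(flag)
            continue
        # annotation overlap
        for ann in trial.meta.annotations:
            if ann.t_start < step.t_next_ic and ann.t_end > step.t_ic:
                step.exclude(ann.label)
                break
        if step.excluded:
            continue
        # crossover: leading foot lands on the contralateral side of the midline
        foot_x_ic = sample_at(trial.foot_col(side, "x"), trial.kin_time, t_ic)
        midline = trial.meta.belt_midline_x_m
        if (side == "right" and foot_x_ic < midline) or (
            side == "left" and foot_x_ic > midline
        ):
            step.exclude("crossover")
    return steps
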