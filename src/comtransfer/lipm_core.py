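"""Closed-form linear-inverted-pendulum (LIPM) mathematics for frontal-plane gait.

The mediolateral motion of the body center of mass (CoM) during single-limb
stance is modeled as a linear inverted pendulum pivoting about the stance
foot: ``x'' = omega^2 * x`` with eigenfrequency ``omega = sqrt(g / l)``,
where ``l`` is the CoM height. In the stance-foot frame the direction from
pivot to CoM is negative, so the CoM position ``x0`` is a negative scalar
while the CoM approaches the pivot with positive velocity ``v0``.

The central quantity is the *projected transfer magnitude*: the minimum
signed CoM-pivot distance the pendulum would reach under purely passive
dynamics from the instantaneous state. It is a function of the conserved
orbital energy ``v^2 - omega^2 x^2`` and decomposes exactly into a
foot-placement-related and a CoM-velocity-related component, each the
product of the state variable and a dimensionless (resp. time-valued)
coefficient.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "GRAVITY",
    "ProjectionStatus",
    "PendulumState",
    "TransferProjection",
    "eigenfrequency",
    "lipm_trajectory",
    "stationary_time",
    "projected_transfer_magnitude",
    "closed_form_magnitude",
    "orbital_energy",
]

#: Gravitational acceleration (m/s^2).
GRAVITY = 9.81


class ProjectionStatus(enum.Enum):
    """Outcome classification of a transfer projection."""

    VALID = "valid"
    #: The CoM state carries enough kinetic energy to cross the pivot
    #: laterally; no minimum distance exists.
    FALL_OVER_PIVOT = "fall_over_pivot"
    #: The CoM is moving away from the pivot; the minimum distance under
    #: passive dynamics is at (or before) the evaluation instant.
    RECEDING = "receding"


@dataclass(frozen=True)
class PendulumState:
    """Instantaneous frontal-plane CoM state in the stance-foot frame.

    Parameters
    ----------
    x0 : float
        Mediolateral CoM position relative to the pivot (m). Negative when
        the CoM sits on the medial side of the pivot, which is the normal
        configuration during a step.
    v0 : float
        Mediolateral CoM velocity (m/s); positive is toward the pivot.
    height : float
        Instantaneous CoM height above the walking surface (m); must be
        positive.
    """

    x0: float
    v0: float
    height: float

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"CoM height must be positive, got {self.height}")

    @property
    def omega(self) -> float:
        """Pendulum eigenfrequency sqrt(g / height), 1/s."""
        return eigenfrequency(self.height)

    @property
    def velocity_ratio(self) -> float:
        """Dimensionless v0 / (omega * |x0|); in [0, 1) for a valid transfer."""
        if self.x0 == 0.0:
            raise ValueError("degenerate state: x0 = 0 (CoM over pivot)")
        return self.v0 / (self.omega * abs(self.x0))


@dataclass(frozen=True)
class TransferProjection:
    """Projected CoM transfer and its foot-placement / velocity decomposition.

    ``magnitude`` is the projected minimum signed mediolateral CoM-pivot
    distance (m, negative); ``stationary_time`` the time until that minimum
    (s). ``fp_component = x0 * fp_coefficient`` and
    ``v_component = v0 * v_coefficient`` sum exactly to ``magnitude`` when
    the projection is valid.
    """

    status: ProjectionStatus
    magnitude: float | None = None
    stationary_time: float | None = None
    fp_component: float | None = None
    v_component: float | None = None
    fp_coefficient: float | None = None
    v_coefficient: float | None = None


def eigenfrequency(height: float) -> float:
    """Pendulum eigenfrequency omega = sqrt(g / height).

    Parameters
    ----------
    height : float
        CoM height above the surface (m), > 0.
    """
    if not height > 0:
        raise ValueError(f"CoM height must be positive, got {height}")
    return math.sqrt(GRAVITY / height)


def lipm_trajectory(state: PendulumState, t: float) -> float:
    """Passive LIPM position at time ``t`` from ``state``.

    Evaluates ``x(t) = x0 cosh(omega t) + (v0 / omega) sinh(omega t)``.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    w = state.omega
    return state.x0 * math.cosh(w * t) + (state.v0 / w) * math.sinh(w * t)


def stationary_time(state: PendulumState) -> tuple[float | None, ProjectionStatus]:
    """Time until the passive trajectory's mediolateral velocity vanishes.

    Setting ``x'(t) = 0`` gives ``tanh(omega t*) = v0 / (omega |x0|)``, so
    ``t* = artanh(u) / omega`` with ``u = v0 / (omega |x0|)``. The solution
    exists only for ``0 <= u < 1``:

    - ``u`` in [0, 1): returns ``(t*, VALID)`` (``t* = 0`` when v0 = 0 —
      the CoM is already at its minimum distance);
    - ``v0 < 0``: returns ``(None, RECEDING)``;
    - ``u >= 1``: returns ``(None, FALL_OVER_PIVOT)`` — the pendulum would
      fall laterally over the pivot and no minimum distance is defined.
    """
    u = state.velocity_ratio  # raises on x0 == 0
    if state.v0 < 0:
        return None, ProjectionStatus.RECEDING
    if u >= 1.0:
        return None, ProjectionStatus.FALL_OVER_PIVOT
    return math.atanh(u) / state.omega, ProjectionStatus.VALID


def projected_transfer_magnitude(state: PendulumState) -> TransferProjection:
    """Project the CoM state to its passive minimum pivot distance.

    For a valid state the passive trajectory is evaluated at the stationary
    time ``t*``::

        magnitude = x0 * cosh(omega t*) + (v0 / omega) * sinh(omega t*)

    reported together with its decomposition into the foot-placement-related
    component ``x0 * cosh(omega t*)`` (coefficient ``cosh(omega t*) >= 1``)
    and the velocity-related component ``v0 * sinh(omega t*) / omega``
    (coefficient in seconds). A receding state projects to its current
    position; a state with ``v0 / (omega |x0|) >= 1`` has no minimum and is
    flagged ``FALL_OVER_PIVOT``.
    """
    t_star, status = stationary_time(state)
    if status is ProjectionStatus.FALL_OVER_PIVOT:
        return TransferProjection(status=status)
    if status is ProjectionStatus.RECEDING:
        return TransferProjection(
            status=status,
            magnitude=state.x0,
            stationary_time=0.0,
            fp_component=state.x0,
            v_component=0.0,
            fp_coefficient=1.0,
            v_coefficient=0.0,
        )
    w = state.omega
    wt = w * t_star
    fp_coefficient = math.cosh(wt)
    v_coefficient = math.sinh(wt) / w
    fp_component = state.x0 * fp_coefficient
    v_component = state.v0 * v_coefficient
    return TransferProjection(
        status=ProjectionStatus.VALID,
        magnitude=fp_component + v_component,
        stationary_time=t_star,
        fp_component=fp_component,
        v_component=v_component,
        fp_coefficient=fp_coefficient,
        v_coefficient=v_coefficient,
    )


def closed_form_magnitude(state: PendulumState) -> float:
    """Projected minimum distance via the orbital-energy closed form.

    Along a passive trajectory ``v^2 - omega^2 x^2`` is conserved; at the
    minimum the velocity vanishes, so the minimum signed distance is
    ``-sqrt(x0^2 - (v0/omega)^2)``. Used as an independent check of
    :func:`projected_transfer_magnitude` (to which it is algebraically
    identical via the cosh/sinh(artanh) identities).
    """
    u = state.velocity_ratio
    if not 0.0 <= u < 1.0:
        raise ValueError(
            f"velocity ratio v0/(omega*|x0|) = {u:.4g} outside [0, 1); "
            "no passive minimum distance exists"
        )
    return -math.sqrt(state.x0**2 - (state.v0 / state.omega) ** 2)


def orbital_energy(state: PendulumState) -> float:
    """Conserved LIPM orbital energy per unit mass, (v0^2 - omega^2 x0^2)/2.

    Negative while a passive minimum distance exists; zero at the
    fall-over-pivot boundary. Injecting mechanical work W (J) into a body of
    mass m raises this quantity by W/m.
    """
    return 0.5 * (state.v0**2 - state.omega**2 * state.x0**2)
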