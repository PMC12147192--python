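"""Synthetic treadmill gait trials with exact ground truth.

Generates multi-step frontal-plane walking whose stance-phase mediolateral
CoM motion follows linear-inverted-pendulum dynamics: passive during
single support and early double support, then forced by a half-sine
trailing-limb push-off per unit mass, zero at both ends of its support and
occupying the later part of double support (where push-off peaks
physiologically), scaled so the injected mechanical work hits each step's
target. Foot placements and IC velocities are drawn from side-specific
distributions; vertical forces are modeled as complementary load-transfer
ramps (sufficient for threshold event detection, not claimed
physiological); Gaussian measurement noise is added to kinematic and
kinetic channels.

Everything is closed form. The forced oscillator ``x'' = w^2 x + A
sin(Om tau)`` has the exact solution ``x = a cosh(w tau) + b sinh(w tau)
+ C sin(Om tau)`` with ``C = -A/(Om^2 + w^2)``; because the work-energy
identity ``W/m = E(T) - E(0)`` with ``E = (v^2 - w^2 x^2)/2`` holds
exactly along this solution, the amplitude meeting a work target is the
root of a quadratic — no integration, no quadrature error. Logged ground
truth (event times, per-step states, projections, work) is therefore
exact up to floating point.

Step-to-step continuity: instead of forcing a fixed step period (which
would demand a velocity jump at initial contact), the next IC is placed at
the instant the passive fall-away velocity reaches the drawn IC velocity
for the next step, keeping the CoM trajectory C1 across steps.
``step_period`` enters only through the double-support duration
``ds_fraction * step_period``. A weak foot-placement centering gain keeps
the walker near the belt midline, mirroring the lateral-stabilization
feedback human walkers exhibit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_preprocess import Annotation, GaitTrial, KIN_COLUMNS, KINET_COLUMNS, TrialMeta, write_trial
from .lipm_core import GRAVITY, PendulumState, closed_form_magnitude, eigenfrequency

__all__ = [
    "SyntheticConfig",
    "StepTruth",
    "SyntheticGroundTruth",
    "AsymmetrySpec",
    "passive_config",
    "simulate_trial",
    "simulate_cohort",
]

_MAX_REDRAWS = 10
#: Floors on the projected transfer magnitude (m) at IC and after the
#: double-support work input; keep every step clearly short of a lateral
#: fall over the pivot.
_MIN_PROJ_M = 0.055
_MIN_PROJ_CFO_M = 0.05


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate slow hemiparetic treadmill
    walking (wider, more variable paretic foot placement; reduced
    trailing-limb work during paretic steps; ~0.15 m/s ML CoM velocity at
    initial contact; 100 Hz kinematics / 1000 Hz kinetics with ~1 mm /
    1 N measurement noise)."""

    n_steps: int = 30
    com_height: float = 0.95           # m, held exactly constant
    step_period: float = 0.65          # s, nominal; sets ds duration only
    ds_fraction: float = 0.38          # double support = ds_fraction * step_period
    fp_mean_p: float = 0.12            # m, paretic-step foot placement (wider)
    fp_mean_np: float = 0.10
    fp_sd_p: float = 0.015
    fp_sd_np: float = 0.010
    v_ic_mean: float = 0.15            # m/s toward the new pivot at IC
    v_ic_sd: float = 0.02
    work_target_p: float = 1.65        # J per paretic step (non-paretic trailing limb)
    work_target_np: float = 1.8        # J per non-paretic step
    work_sd: float = 0.15              # J, step-to-step work jitter
    compensation_gain_p: float | None = None   # overrides work targets when set
    compensation_gain_np: float | None = None
    target_magnitude: float = -0.09    # m, set point for the compensation controller
    body_mass: float = 75.0            # kg
    body_height: float = 1.72          # m
    paretic_side: str = "left"
    first_side: str = "right"
    noise_pos_sd: float = 0.001        # m, total kinematic noise sd
    #: share of the kinematic noise that is movement-correlated soft-tissue
    #: artifact (quasi-periodic at the step frequency with slowly drifting
    #: amplitude/phase); the remainder is white sensor noise
    noise_artifact_fraction: float = 0.55
    noise_artifact_drift_s: float = 1.0  # s, artifact amplitude/phase drift time
    noise_grf_sd: float = 1.0          # N, white
    kin_rate: float = 100.0            # Hz
    kinet_rate: float = 1000.0         # Hz
    fp_centering_gain: float = 0.15    # lab-frame drift feedback on placement
    push_delay_fraction: float = 0.2   # fraction of DS before the push-off half-sine
    annotations: list[Annotation] = field(default_factory=list)
    participant_id: str = "SYN01"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ds_fraction < 0.5:
            raise ValueError("ds_fraction must lie in (0, 0.5)")
        for name in ("fp_sd_p", "fp_sd_np", "v_ic_sd", "work_sd",
                     "noise_pos_sd", "noise_grf_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kin_rate <= 0 or self.kinet_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if (self.kinet_rate / self.kin_rate) % 1 != 0:
            raise ValueError("kinet_rate must be an integer multiple of kin_rate")

    @property
    def ds_duration(self) -> float:
        return self.ds_fraction * self.step_period


def passive_config(seed: int = 0, n_steps: int = 30) -> SyntheticConfig:
    """A zero-work ("ballistic") trial configuration.

    Passive double support is only dynamically consistent when the CoM's
    minimum distance would fall beyond contralateral foot off, which needs
    a faster mediolateral approach and a shorter double-support phase than
    the forced default; with these settings every step carries exactly
    zero injected trailing-limb work and the full transfer is a single
    passive pendulum arc from initial contact to completion.
    """
    return SyntheticConfig(
        seed=seed, n_steps=n_steps,
        v_ic_mean=0.26, v_ic_sd=0.01,
        fp_mean_p=0.11, fp_mean_np=0.10,
        ds_fraction=0.25,
        work_target_p=0.0, work_target_np=0.0, work_sd=0.0,
        noise_pos_sd=0.0, noise_grf_sd=0.0,
    )


@dataclass
class StepTruth:
    """Exact per-step ground truth logged by the generator."""

    step_index: int
    leading_side: str
    transfer_direction: str
    t_ic: float
    t_cfo: float
    t_completion: float
    t_next_ic: float
    fp: float               # m, signed stance-frame position at IC (negative)
    v_ic: float             # m/s toward pivot at IC
    proj_ic: float          # m, passive projection from the IC state
    proj_cfo: float         # m, projection from the CFO state
    final_mag: float        # m, true minimum distance (= proj_cfo; SS passive)
    work: float             # J, injected trailing-limb work (exact)


@dataclass
class SyntheticGroundTruth:
    steps: list[StepTruth]
    config: SyntheticConfig

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(s) for s in self.steps])
        df.insert(0, "participant_id", self.config.participant_id)
        return df


@dataclass
class _Placement:
    side: str
    position: float  # lab ML foot position
    t_on: float      # IC (or trial start for the pre-roll foot)
    t_off: float     # end of its load-bearing (CFO as trailing foot)
    sigma: float     # stance sign while this foot is the pivot
    # push-off of the double-support phase in which this foot is TRAILING:
    # lab ML force = scale * A * sin(pi (t - t_push)/T_push) on its support
    pivot_end: float | None = None  # next IC: when this foot stops being pivot
    t_push: float | None = None
    T_push: float | None = None
    trail_scale: float | None = None  # mass * sigma of the leading stance
    trail_amp: float | None = None


def _sigma(side: str) -> float:
    return 1.0 if side == "right" else -1.0


def _passive_state(tau: float, x0: float, v0: float, omega: float) -> tuple[float, float]:
    c, s = math.cosh(omega * tau), math.sinh(omega * tau)
    return x0 * c + (v0 / omega) * s, omega * x0 * s + v0 * c


def _ds_end_state(x0: float, v0: float, omega: float, T: float, t_d: float,
                  A: float) -> tuple[float, float]:
    """End state of one double-support phase.

    The phase is passive on [0, t_d] (the trailing limb still mainly bears
    load) and forced on [t_d, T] by the half-sine ``f = A sin(Om (tau -
    t_d))`` with ``Om = pi / (T - t_d)``, zero at both ends of its
    support. Closed form throughout: the forced part is ``x = a cosh + b
    sinh + C sin(Om tau2)`` with ``C = -A / (Om^2 + omega^2)``.
    """
    x1, v1 = _passive_state(t_d, x0, v0, omega)
    Tf = T - t_d
    Om = math.pi / Tf
    C = -A / (Om * Om + omega * omega)
    a = x1
    b = (v1 - C * Om) / omega
    c, s = math.cosh(omega * Tf), math.sinh(omega * Tf)
    x_T = a * c + b * s                      # sin(pi) = 0
    v_T = omega * (a * s + b * c) - C * Om   # cos(pi) = -1
    return x_T, v_T


def _solve_forcing(x0: float, v0: float, omega: float, T: float, t_d: float,
                   w_target: float) -> list[tuple[float, float, float]]:
    """Half-sine amplitudes for which the trailing-limb work over double
    support equals ``w_target`` (per unit mass).

    Work equals the orbital-energy change, which is quadratic in the
    amplitude A because the end state is affine in A; the target is met by
    up to two roots, returned as ``(A, x_end, v_end)`` ordered by |A|.
    Empty when unreachable."""
    E0 = 0.5 * (v0 * v0 - omega * omega * x0 * x0)

    def gap(A: float) -> float:
        x_T, v_T = _ds_end_state(x0, v0, omega, T, t_d, A)
        return 0.5 * (v_T * v_T - omega * omega * x_T * x_T) - E0 - w_target

    g0, gp, gm = gap(0.0), gap(1.0), gap(-1.0)
    alpha = 0.5 * (gp + gm) - g0
    beta = 0.5 * (gp - gm)
    disc = beta * beta - 4.0 * alpha * g0
    if disc < 0:
        return []
    r = math.sqrt(disc)
    roots = sorted(((-beta - r) / (2.0 * alpha), (-beta + r) / (2.0 * alpha)),
                   key=abs)
    return [(A, *_ds_end_state(x0, v0, omega, T, t_d, A)) for A in roots]


def _ds_eval(tau: np.ndarray, x0: float, v0: float, omega: float, T: float,
             t_d: float, A: float) -> np.ndarray:
    """Closed-form double-support CoM position at times ``tau`` in [0, T]."""
    tau = np.asarray(tau, dtype=float)
    out = np.empty_like(tau)
    early = tau <= t_d
    out[early] = _passive_eval(tau[early], x0, v0, omega)
    x1, v1 = _passive_state(t_d, x0, v0, omega)
    Tf = T - t_d
    Om = math.pi / Tf
    C = -A / (Om * Om + omega * omega)
    a = x1
    b = (v1 - C * Om) / omega
    t2 = tau[~early] - t_d
    out[~early] = (a * np.cosh(omega * t2) + b * np.sinh(omega * t2)
                   + C * np.sin(Om * t2))
    return out


def _passive_eval(tau: np.ndarray, x0: float, v0: float, omega: float) -> np.ndarray:
    return x0 * np.cosh(omega * tau) + (v0 / omega) * np.sinh(omega * tau)


def _passive_vel(tau: float, x0: float, v0: float, omega: float) -> float:
    return omega * x0 * math.sinh(omega * tau) + v0 * math.cosh(omega * tau)


def _smoothstep(q: np.ndarray) -> np.ndarray:
    q = np.clip(q, 0.0, 1.0)
    return q**3 * (10.0 - 15.0 * q + 6.0 * q * q)


def simulate_trial(config: SyntheticConfig) -> tuple[GaitTrial, SyntheticGroundTruth]:
    """Simulate one treadmill trial; returns the trial bundle and its
    exact ground truth.

    Steps whose draws would produce a fall-over-pivot state or a CoM that
    stops approaching the pivot before contralateral foot off are redrawn
    (up to 10 times) to keep every step inside the modeled regime; a
    persistent failure raises ``RuntimeError``.
    """
    rng = np.random.default_rng(config.seed)
    omega = eigenfrequency(config.com_height)
    T_ds = config.ds_duration
    mass = config.body_mass
    n = config.n_steps
    paretic = config.paretic_side

    def draw_step(side: str, x_lab: float) -> tuple[float, float]:
        """(fp, v_ic) draw with validity guard and drift centering."""
        mean_fp = config.fp_mean_p if side == paretic else config.fp_mean_np
        sd_fp = config.fp_sd_p if side == paretic else config.fp_sd_np
        for _ in range(_MAX_REDRAWS):
            fp = rng.normal(mean_fp, sd_fp)
            fp -= config.fp_centering_gain * _sigma(side) * x_lab
            v = rng.normal(config.v_ic_mean, config.v_ic_sd)
            # projected magnitude floor keeps steps clear of the pivot
            if fp > 0.02 and v > 0 and fp**2 - (v / omega) ** 2 >= _MIN_PROJ_M**2:
                return fp, v
        # deterministic fallback for the distribution tail: keep the chain
        # alive by shrinking the velocity until the floor is met
        fp = max(fp, 0.07)
        v = min(abs(v), 0.8 * omega * math.sqrt(fp**2 - _MIN_PROJ_M**2))
        return fp, v

    def draw_work(side: str, m_ic: float) -> float:
        gain = config.compensation_gain_p if side == paretic else config.compensation_gain_np
        if gain is not None:
            m_des = m_ic + gain * (config.target_magnitude - m_ic)
            w = 0.5 * mass * omega**2 * (m_ic**2 - m_des**2)
        else:
            w = config.work_target_p if side == paretic else config.work_target_np
        return w + rng.normal(0.0, config.work_sd) if config.work_sd > 0 else w

    # --- build the step chain ------------------------------------------------
    side0 = config.first_side
    # pre-roll single support before the first IC; generous so the first
    # step is clear of the zero-phase filter's edge transient
    t0 = 0.60
    fp0, v0 = draw_step(side0, 0.0)

    # pre-roll: previous stance foot, CoM receding toward the first placement
    pre_side = "left" if side0 == "right" else "right"
    m_pre = config.target_magnitude
    x_pre = -math.sqrt(m_pre**2 + (v0 / omega) ** 2)
    p_pre = 0.0 - _sigma(pre_side) * x_pre
    placements: list[_Placement] = [
        _Placement(side=pre_side, position=p_pre, t_on=0.0, t_off=t0 + T_ds,
                   sigma=_sigma(pre_side))
    ]

    truth: list[StepTruth] = []
    segments: list[tuple] = []  # ("pre"|"ds"|"ss", t_start, t_end, params...)
    segments.append(("pre", 0.0, t0, p_pre, _sigma(pre_side), x_pre, -v0))

    t_ic, x_lab, fp_k, v_k, side = t0, 0.0, fp0, v0, side0
    k = 0
    while k <= n:
        sig = _sigma(side)
        p_k = x_lab + sig * fp_k
        x0 = -fp_k
        m_ic = closed_form_magnitude(PendulumState(x0=x0, v0=v_k, height=config.com_height))
        t_d = config.push_delay_fraction * T_ds

        # work level that is always admissible for this geometry (shrinks the
        # projected magnitude by 20%); unlucky draws are blended toward it
        w_safe = 0.18 * mass * omega**2 * m_ic**2
        # work ceiling: never bring the CFO projection inside the floor
        # (floor softened near the IC floor so a small admissible work
        # range always remains)
        floor_cfo = min(_MIN_PROJ_CFO_M, 0.9 * abs(m_ic))
        w_cap = 0.5 * mass * omega**2 * (m_ic**2 - floor_cfo**2)
        sol = None
        for j in range(_MAX_REDRAWS):
            w_j = draw_work(side, m_ic) * (1.0 - j / _MAX_REDRAWS) \
                + w_safe * (j / _MAX_REDRAWS)
            w_j = min(w_j, w_cap)
            for A, x_cfo, v_cfo in _solve_forcing(x0, v_k, omega, T_ds, t_d, w_j / mass):
                # stay in the modeled regime: still approaching the pivot at
                # CFO, clearly short of falling over it, never crossing it
                if x_cfo >= -0.01 or v_cfo <= 1e-3 or v_cfo / (omega * -x_cfo) > 0.95:
                    continue
                if np.any(_ds_eval(np.linspace(0.0, T_ds, 25),
                                   x0, v_k, omega, T_ds, t_d, A) > -0.005):
                    continue
                sol = (A, x_cfo, v_cfo, w_j)
                break
            if sol is not None:
                break
        if sol is None:
            raise RuntimeError(
                f"step {k}: no admissible trailing-limb forcing after "
                f"{_MAX_REDRAWS} redraws"
            )
        A, x_cfo, v_cfo, w_j = sol
        t_cfo = t_ic + T_ds
        segments.append(("ds", t_ic, t_cfo, p_k, sig, x0, v_k, t_d, A, T_ds))
        placements.append(_Placement(side=side, position=p_k, t_on=t_ic,
                                     t_off=math.inf, sigma=sig))
        # the previous foot is trailing during this DS
        prev = placements[-2]
        prev.t_off = t_cfo
        prev.pivot_end = t_ic
        prev.t_push = t_ic + t_d
        prev.T_push = T_ds - t_d
        prev.trail_scale = mass * sig
        prev.trail_amp = A

        t_star = math.atanh(v_cfo / (omega * -x_cfo)) / omega
        t_comp = t_cfo + t_star
        m_final = closed_form_magnitude(
            PendulumState(x0=x_cfo, v0=v_cfo, height=config.com_height)
        )
        # exact injected work from the orbital-energy change
        work_exact = 0.5 * mass * ((v_cfo**2 - omega**2 * x_cfo**2)
                                   - (v_k**2 - omega**2 * x0**2))

        if k == n:
            # terminal step: short passive tail, no next IC
            t_end = t_comp + 0.35
            segments.append(("ss", t_cfo, t_end, p_k, sig, x_cfo, v_cfo))
            trial_end = t_end
            break

        # next IC: when the passive fall-away velocity reaches the next draw;
        # centering uses the CoM position at completion as the drift proxy
        other = "left" if side == "right" else "right"
        # drift proxy: current stride's foot midpoint (zero-mean when the
        # walker is centered, so it does not bias the placement draws)
        fp_next, v_next = draw_step(other, 0.5 * (p_k + placements[-2].position))

        def vel_gap(tau: float) -> float:
            return _passive_vel(tau, x_cfo, v_cfo, omega) + v_next

        hi = t_star + 0.05
        while vel_gap(hi) > 0:
            hi += 0.05
            if hi > t_star + 5.0:
                raise RuntimeError("fall-away never reached the drawn IC velocity")
        tau_ic = brentq(vel_gap, t_star, hi, xtol=1e-12)
        t_next = t_cfo + tau_ic
        segments.append(("ss", t_cfo, t_next, p_k, sig, x_cfo, v_cfo))

        truth.append(StepTruth(
            step_index=k,
            leading_side=side,
            transfer_direction="paretic" if side == paretic else "non_paretic",
            t_ic=t_ic, t_cfo=t_cfo, t_completion=t_comp, t_next_ic=t_next,
            fp=x0, v_ic=v_k, proj_ic=m_ic, proj_cfo=m_final,
            final_mag=m_final, work=work_exact,
        ))

        x_sf_next = float(_passive_eval(np.array([tau_ic]), x_cfo, v_cfo, omega)[0])
        x_lab = p_k + sig * x_sf_next
        t_ic, fp_k, v_k, side = t_next, fp_next, v_next, other
        k += 1

    # --- sample signals on the two timelines ---------------------------------
    dt_kinet = 1.0 / config.kinet_rate
    n_kinet = int(math.floor(trial_end / dt_kinet)) + 1
    t_kinet = np.arange(n_kinet) * dt_kinet
    ratio = int(config.kinet_rate / config.kin_rate)
    t_kin = t_kinet[::ratio].copy()

    def com_x_at(t: np.ndarray) -> np.ndarray:
        out = np.empty_like(t)
        out.fill(np.nan)
        for seg in segments:
            kind, a, b = seg[0], seg[1], seg[2]
            mask = (t >= a) & (t < b) if seg is not segments[-1] else (t >= a) & (t <= b + dt_kinet)
            if not mask.any():
                continue
            tau = t[mask] - (t0 if kind == "pre" else a)
            if kind == "pre":
                _, _, _, p, sig_s, xs, vs = seg
                out[mask] = p + sig_s * _passive_eval(t[mask] - t0, xs, vs, omega)
            elif kind == "ds":
                _, _, _, p, sig_s, xs, vs, td_s, A_s, T_s = seg
                out[mask] = p + sig_s * _ds_eval(tau, xs, vs, omega, T_s, td_s, A_s)
            else:
                _, _, _, p, sig_s, xs, vs = seg
                out[mask] = p + sig_s * _passive_eval(tau, xs, vs, omega)
        return out

    com_x_kinet = com_x_at(t_kinet)
    com_x_kin = com_x_kinet[::ratio].copy()

    # foot trajectories (kinematic timeline)
    foot_x = {"left": np.empty_like(t_kin), "right": np.empty_like(t_kin)}
    foot_z = {"left": np.zeros_like(t_kin), "right": np.zeros_like(t_kin)}
    by_side = {"left": [p for p in placements if p.side == "left"],
               "right": [p for p in placements if p.side == "right"]}
    for s, plist in by_side.items():
        x = np.full_like(t_kin, plist[0].position)
        z = np.zeros_like(t_kin)
        for i, pl in enumerate(plist):
            x[t_kin >= pl.t_on] = pl.position
            t_off = pl.t_off
            if math.isfinite(t_off) and i + 1 < len(plist):
                nxt = plist[i + 1]
                sw = (t_kin > t_off) & (t_kin < nxt.t_on)
                q = (t_kin[sw] - t_off) / (nxt.t_on - t_off)
                x[sw] = pl.position + (nxt.position - pl.position) * _smoothstep(q)
                z[sw] = 0.05 * np.sin(math.pi * np.clip(q, 0.0, 1.0))
        foot_x[s], foot_z[s] = x, z

    # ground reaction forces (kinetic timeline)
    mg = mass * GRAVITY
    grf_z = {"left": np.zeros_like(t_kinet), "right": np.zeros_like(t_kinet)}
    grf_x = {"left": np.zeros_like(t_kinet), "right": np.zeros_like(t_kinet)}
    for pl in placements:
        s = pl.side
        t_on, t_off = pl.t_on, pl.t_off if math.isfinite(pl.t_off) else trial_end + 1.0
        # vertical: ramp up over DS after landing (the pre-roll foot starts loaded)
        if pl.t_on == 0.0:
            up_end = 0.0
        else:
            up_end = t_on + T_ds
            m_up = (t_kinet >= t_on) & (t_kinet < up_end)
            grf_z[s][m_up] += mg * (t_kinet[m_up] - t_on) / T_ds
        m_full = (t_kinet >= up_end) & (t_kinet < t_off - T_ds)
        grf_z[s][m_full] += mg
        m_dn = (t_kinet >= t_off - T_ds) & (t_kinet < t_off)
        grf_z[s][m_dn] += mg * (t_off - t_kinet[m_dn]) / T_ds
        # mediolateral: pivot restoring force while leading, half-sine while trailing
        pivot_end = pl.pivot_end if pl.pivot_end is not None else t_off
        m_piv = (t_kinet >= t_on) & (t_kinet < pivot_end)
        grf_x[s][m_piv] += mass * omega**2 * (com_x_kinet[m_piv] - pl.position)
        if pl.t_push is not None and pl.trail_amp is not None:
            m_tr = (t_kinet >= pl.t_push) & (t_kinet < pl.t_push + pl.T_push)
            phase = math.pi * (t_kinet[m_tr] - pl.t_push) / pl.T_push
            grf_x[s][m_tr] += pl.trail_scale * pl.trail_amp * np.sin(phase)
    # measurement noise: kinematic channels carry white sensor noise plus
    # soft-tissue artifact — quasi-periodic at the step frequency (tissue
    # deforms with every step) with amplitude and phase drifting on the
    # scale of a stride, so it passes the kinematic low-pass filter and
    # decorrelates across the CFO-to-completion horizon; kinetic channels
    # carry white sensor noise only
    def nz(shape, sd):
        return rng.normal(0.0, sd, size=shape) if sd > 0 else np.zeros(shape)

    def _ou(n: int, tau: float) -> np.ndarray:
        rho = math.exp(-1.0 / (config.kin_rate * tau))
        scale = math.sqrt(1.0 - rho * rho)
        burn = 300  # reach the stationary distribution before the trial
        eps = rng.normal(0.0, 1.0, size=n + burn)
        from scipy.signal import lfilter

        return lfilter([scale], [1.0, -rho], eps)[burn:]

    def nz_kin(shape, sd):
        if sd <= 0:
            return np.zeros(shape)
        frac = config.noise_artifact_fraction
        white = rng.normal(0.0, 1.0, size=shape)
        if frac <= 0:
            return sd * white
        f_art = 1.0 / config.step_period  # step frequency
        drift = config.noise_artifact_drift_s
        phase = 2.0 * math.pi * f_art * t_kin
        # unit-variance quasi-periodic artifact: OU-drifting quadratures
        art = (_ou(shape[0], drift) * np.cos(phase)
               + _ou(shape[0], drift) * np.sin(phase))
        return sd * (math.sqrt(frac) * art + math.sqrt(1.0 - frac) * white)

    kin = pd.DataFrame({
        "time_s": t_kin,
        "com_x": com_x_kin + nz_kin(t_kin.shape, config.noise_pos_sd),
        "com_y": nz_kin(t_kin.shape, config.noise_pos_sd),
        "com_z": config.com_height + nz_kin(t_kin.shape, config.noise_pos_sd),
        "lfoot_x": foot_x["left"] + nz_kin(t_kin.shape, config.noise_pos_sd),
        "lfoot_y": nz_kin(t_kin.shape, config.noise_pos_sd),
        "lfoot_z": foot_z["left"] + nz_kin(t_kin.shape, config.noise_pos_sd),
        "rfoot_x": foot_x["right"] + nz_kin(t_kin.shape, config.noise_pos_sd),
        "rfoot_y": nz_kin(t_kin.shape, config.noise_pos_sd),
        "rfoot_z": foot_z["right"] + nz_kin(t_kin.shape, config.noise_pos_sd),
    })[KIN_COLUMNS]
    kinet = pd.DataFrame({
        "time_s": t_kinet,
        "grfL_x": grf_x["left"] + nz(t_kinet.shape, config.noise_grf_sd),
        "grfL_y": nz(t_kinet.shape, config.noise_grf_sd),
        "grfL_z": grf_z["left"] + nz(t_kinet.shape, config.noise_grf_sd),
        "grfR_x": grf_x["right"] + nz(t_kinet.shape, config.noise_grf_sd),
        "grfR_y": nz(t_kinet.shape, config.noise_grf_sd),
        "grfR_z": grf_z["right"] + nz(t_kinet.shape, config.noise_grf_sd),
    })[KINET_COLUMNS]

    meta = TrialMeta(
        participant_id=config.participant_id,
        paretic_side=config.paretic_side,
        body_mass_kg=config.body_mass,
        body_height_m=config.body_height,
        kin_rate_hz=config.kin_rate,
        kinet_rate_hz=config.kinet_rate,
        belt_midline_x_m=0.0,
        annotations=list(config.annotations),
    )
    trial = GaitTrial(kin=kin, kinet=kinet, meta=meta)
    return trial, SyntheticGroundTruth(steps=truth, config=config)


@dataclass
class AsymmetrySpec:
    """Prescribed hemiparetic deficits for a synthetic cohort."""

    fp_offset_p: float = 0.02       # m added to paretic-step foot placement
    work_scale_p: float = 0.7       # multiplier on paretic-step trailing work
    compensation_gain_p: float | None = None
    compensation_gain_np: float | None = None


def simulate_cohort(
    n_participants: int,
    config_template: SyntheticConfig,
    asymmetry_spec: AsymmetrySpec,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[tuple[GaitTrial, SyntheticGroundTruth]]:
    """Simulate a cohort of participants around a template config.

    Per participant, anthropometrics, baseline foot placement, IC velocity
    and work are jittered around the template, then the asymmetry spec is
    applied (paretic placement offset, paretic-step work scaling, optional
    per-side compensation gains). When ``out_dir`` is given, trial bundles
    and a pooled ``ground_truth.tsv`` are written there.
    """
    master = np.random.default_rng(seed)
    results: list[tuple[GaitTrial, SyntheticGroundTruth]] = []
    frames = []
    for i in range(n_participants):
        rng = np.random.default_rng([seed, i])
        fp_base = max(0.06, rng.normal(config_template.fp_mean_np, 0.008))
        work_base = max(0.3, rng.normal(config_template.work_target_np, 0.15))
        cfg = replace(
            config_template,
            participant_id=f"P{i + 1:02d}",
            fp_mean_np=fp_base,
            fp_mean_p=fp_base + asymmetry_spec.fp_offset_p,
            work_target_np=work_base,
            work_target_p=work_base * asymmetry_spec.work_scale_p,
            v_ic_mean=max(0.08, rng.normal(config_template.v_ic_mean, 0.015)),
            com_height=float(np.clip(rng.normal(config_template.com_height, 0.05), 0.8, 1.1)),
            body_mass=float(np.clip(rng.normal(config_template.body_mass, 8.0), 45.0, 120.0)),
            compensation_gain_p=asymmetry_spec.compensation_gain_p,
            compensation_gain_np=asymmetry_spec.compensation_gain_np,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        trial, truth = simulate_trial(cfg)
        results.append((trial, truth))
        frames.append(truth.to_frame())
        if out_dir is not None:
            write_trial(trial, Path(out_dir) / cfg.participant_id)
    if out_dir is not None:
        pd.concat(frames, ignore_index=True).to_csv(
            Path(out_dir) / "ground_truth.tsv", sep="\t", index=False
        )
    return results
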