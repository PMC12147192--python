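"""Trial I/O, filtering, differentiation and stream alignment.

A *trial bundle* is three text files sharing a stem: ``<trial>.meta.json``
(metadata), ``<trial>.kin.tsv`` (kinematic time series: CoM and per-foot
CoM positions, nominally 100 Hz) and ``<trial>.kinet.tsv`` (per-belt
ground reaction forces, nominally 1000 Hz). All quantities are SI; axes
are x = mediolateral (+ toward the participant's right), y =
anterior-posterior, z = vertical (+ up), origin on the treadmill surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Annotation",
    "TrialMeta",
    "GaitTrial",
    "read_trial",
    "write_trial",
    "butterworth_lowpass",
    "differentiate",
    "sample_at",
    "preprocess",
]

KIN_COLUMNS = [
    "time_s",
    "com_x", "com_y", "com_z",
    "lfoot_x", "lfoot_y", "lfoot_z",
    "rfoot_x", "rfoot_y", "rfoot_z",
]
KINET_COLUMNS = [
    "time_s",
    "grfL_x", "grfL_y", "grfL_z",
    "grfR_x", "grfR_y", "grfR_z",
]

#: Study filter settings: 4th-order Butterworth low-pass, zero-phase.
KINEMATIC_CUTOFF_HZ = 6.0
KINETIC_CUTOFF_HZ = 15.0
FILTER_ORDER = 4


@dataclass(frozen=True)
class Annotation:
    """A labeled time interval marking steps to exclude (handrail use,
    belt crossover, toe drag)."""

    t_start: float
    t_end: float
    label: str


@dataclass
class TrialMeta:
    participant_id: str
    paretic_side: str  # "left" | "right"
    body_mass_kg: float
    body_height_m: float
    kin_rate_hz: float
    kinet_rate_hz: float
    belt_midline_x_m: float = 0.0
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.paretic_side not in ("left", "right"):
            raise ValueError(f"paretic_side must be 'left' or 'right', got {self.paretic_side!r}")


@dataclass
class GaitTrial:
    """Synchronized kinematic/kinetic time series plus metadata for one
    treadmill walking trial.

    ``kin`` columns follow :data:`KIN_COLUMNS`, ``kinet`` columns
    :data:`KINET_COLUMNS`. After :func:`preprocess`, ``filtered`` is True
    and velocity columns ``com_vx`` (kinematic timeline) are available.
    """

    kin: pd.DataFrame
    kinet: pd.DataFrame
    meta: TrialMeta
    filtered: bool = False

    def __post_init__(self) -> None:
        _check_columns(self.kin, KIN_COLUMNS, "kinematic")
        _check_columns(self.kinet, KINET_COLUMNS, "kinetic")
        _check_uniform(self.kin["time_s"].to_numpy(), self.meta.kin_rate_hz, "kinematic")
        _check_uniform(self.kinet["time_s"].to_numpy(), self.meta.kinet_rate_hz, "kinetic")
        if self.meta.kinet_rate_hz < self.meta.kin_rate_hz:
            raise ValueError("kinetic rate must be >= kinematic rate")

    @property
    def kin_time(self) -> np.ndarray:
        return self.kin["time_s"].to_numpy()

    @property
    def kinet_time(self) -> np.ndarray:
        return self.kinet["time_s"].to_numpy()

    def foot_col(self, side: str, axis: str = "x") -> np.ndarray:
        prefix = "lfoot" if side == "left" else "rfoot"
        return self.kin[f"{prefix}_{axis}"].to_numpy()

    def grf_col(self, side: str, axis: str = "z") -> np.ndarray:
        prefix = "grfL" if side == "left" else "grfR"
        return self.kinet[f"{prefix}_{axis}"].to_numpy()


def _check_columns(df: pd.DataFrame, expected: list[str], which: str) -> None:
    # derived columns (e.g. com_vx) may follow the canonical ones
    if list(df.columns)[: len(expected)] != expected:
        raise ValueError(
            f"{which} table columns {list(df.columns)} do not match the "
            f"required schema {expected}"
        )


def _check_uniform(t: np.ndarray, rate: float, which: str) -> None:
    if t.size < 2:
        raise ValueError(f"{which} table needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{which} time vector is not strictly increasing")
    expected = 1.0 / rate
    if not np.allclose(dt, expected, rtol=1e-6, atol=1e-9):
        raise ValueError(
            f"{which} sampling is non-uniform or inconsistent with the "
            f"declared rate {rate} Hz"
        )


def read_trial(path: str | Path) -> GaitTrial:
    """Read a trial bundle given its stem (``path`` without extension) or
    any of its three component files."""
    stem = _bundle_stem(Path(path))
    meta_path = stem.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    raw = json.loads(meta_path.read_text())
    meta = TrialMeta(
        participant_id=raw["participant_id"],
        paretic_side=raw["paretic_side"],
        body_mass_kg=float(raw["body_mass_kg"]),
        body_height_m=float(raw["body_height_m"]),
        kin_rate_hz=float(raw["kin_rate_hz"]),
        kinet_rate_hz=float(raw["kinet_rate_hz"]),
        belt_midline_x_m=float(raw.get("belt_midline_x_m", 0.0)),
        annotations=[Annotation(a["t_start"], a["t_end"], a["label"])
                     for a in raw.get("annotations", [])],
    )
    kin = pd.read_csv(stem.with_suffix(".kin.tsv"), sep="\t", float_precision="round_trip")
    kinet = pd.read_csv(stem.with_suffix(".kinet.tsv"), sep="\t", float_precision="round_trip")
    return GaitTrial(kin=kin, kinet=kinet, meta=meta)


def write_trial(trial: GaitTrial, path: str | Path) -> Path:
    """Write a trial bundle; returns the bundle stem."""
    stem = _bundle_stem(Path(path))
    stem.parent.mkdir(parents=True, exist_ok=True)
    meta = trial.meta
    payload = {
        "participant_id": meta.participant_id,
        "paretic_side": meta.paretic_side,
        "body_mass_kg": meta.body_mass_kg,
        "body_height_m": meta.body_height_m,
        "kin_rate_hz": meta.kin_rate_hz,
        "kinet_rate_hz": meta.kinet_rate_hz,
        "belt_midline_x_m": meta.belt_midline_x_m,
        "annotations": [
            {"t_start": a.t_start, "t_end": a.t_end, "label": a.label}
            for a in meta.annotations
        ],
    }
    stem.with_suffix(".meta.json").write_text(json.dumps(payload, indent=1))
    # repr-precision floats so read_trial round-trips bit-exactly;
    # only canonical columns are persisted
    trial.kin[KIN_COLUMNS].to_csv(stem.with_suffix(".kin.tsv"), sep="\t", index=False,
                                  float_format=lambda v: repr(float(v)))
    trial.kinet[KINET_COLUMNS].to_csv(stem.with_suffix(".kinet.tsv"), sep="\t", index=False,
                                      float_format=lambda v: repr(float(v)))
    return stem


def _bundle_stem(path: Path) -> Path:
    name = path.name
    for suffix in (".meta.json", ".kin.tsv", ".kinet.tsv"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)])
    return path


def butterworth_lowpass(series: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass filter.

    Applied forward-backward (``filtfilt``) so event timing is not
    lag-shifted; the effective magnitude response is the squared design
    response. Length is preserved.
    """
    nyquist = rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyquist} Hz)")
    sos = signal.butter(FILTER_ORDER, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=0)


def differentiate(series: np.ndarray, rate: float) -> np.ndarray:
    """Time derivative: central differences interior, one-sided at ends."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("differentiation needs at least 3 samples")
    return np.gradient(series, 1.0 / rate, axis=0)


def sample_at(series: np.ndarray, time_vector: np.ndarray, t_query: float) -> float:
    """Linear interpolation of a sampled series at ``t_query`` (must lie
    within the sampled range)."""
    time_vector = np.asarray(time_vector)
    if not (time_vector[0] <= t_query <= time_vector[-1]):
        raise ValueError(
            f"query time {t_query} s outside sampled range "
            f"[{time_vector[0]}, {time_vector[-1]}] s"
        )
    return float(np.interp(t_query, time_vector, np.asarray(series, dtype=float)))


def preprocess(trial: GaitTrial) -> GaitTrial:
    """Filter all channels and derive CoM velocity.

    Kinematic signals are low-passed at 6 Hz and kinetic at 15 Hz (4th-order
    zero-phase Butterworth); mediolateral CoM velocity ``com_vx`` is the
    central-difference derivative of the filtered ``com_x``. Filtering
    precedes all event detection and metric computation. Returns a new
    trial; the input is not modified.
    """
    if trial.filtered:
        return trial
    kin = trial.kin.copy()
    kinet = trial.kinet.copy()
    for col in KIN_COLUMNS[1:]:
        kin[col] = butterworth_lowpass(kin[col].to_numpy(),
                                       KINEMATIC_CUTOFF_HZ, trial.meta.kin_rate_hz)
    for col in KINET_COLUMNS[1:]:
        kinet[col] = butterworth_lowpass(kinet[col].to_numpy(),
                                         KINETIC_CUTOFF_HZ, trial.meta.kinet_rate_hz)
    kin["com_vx"] = differentiate(kin["com_x"].to_numpy(), trial.meta.kin_rate_hz)
    out = GaitTrial.__new__(GaitTrial)
    out.kin = kin
    out.kinet = kinet
    out.meta = trial.meta
    out.filtered = True
    return out
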