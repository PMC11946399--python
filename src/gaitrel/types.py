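"""Shared data model for the gait-analysis pipeline.

All internal signals are SI: accelerations in m/s², angular velocities in
rad/s, time in seconds. Unit conversions happen only at the I/O boundary
(:mod:`gaitrel.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

G = 9.80665  # standard gravity, m/s²

#: Hardware full-scale ranges of the recording units (±16 g, ±2000 °/s).
ACC_RANGE_MS2 = 16.0 * G
GYRO_RANGE_RADS = np.deg2rad(2000.0)


class SensorSite(str, enum.Enum):
    """Anatomical placement of one inertial sensor."""

    HEAD = "head"
    STERNUM = "sternum"
    PELVIS = "pelvis"
    SHANK_LEFT = "shank_left"
    SHANK_RIGHT = "shank_right"


class Axis(str, enum.Enum):
    """Anatomical axes: anteroposterior, mediolateral, craniocaudal."""

    AP = "AP"
    ML = "ML"
    CC = "CC"


#: Sites whose accelerations enter the stability index (nRMS).
UPPER_BODY_SITES = (SensorSite.PELVIS, SensorSite.STERNUM, SensorSite.HEAD)

#: Canonical order of the 15 per-trial index columns.
INDEX_NAMES = (
    "nRMS_AP_pelvis",
    "nRMS_ML_pelvis",
    "nRMS_AP_trunk",
    "nRMS_ML_trunk",
    "nRMS_AP_head",
    "nRMS_ML_head",
    "iHR_AP",
    "iHR_ML",
    "iHR_CC",
    "LDLJa_AP",
    "LDLJa_ML",
    "LDLJa_CC",
    "LDLJw_AP",
    "LDLJw_ML",
    "LDLJw_CC",
)

#: nRMS column name for a (site, axis) pair; trunk is the sternum sensor.
NRMS_SITE_LABEL = {
    SensorSite.PELVIS: "pelvis",
    SensorSite.STERNUM: "trunk",
    SensorSite.HEAD: "head",
}


@dataclass
class ImuRecording:
    """Raw tri-axial recording of one sensor.

    Parameters
    ----------
    sensor_site : SensorSite
    sampling_rate_hz : float
        Nominal 128 Hz.
    acc : (T, 3) ndarray
        Accelerations, m/s², sensor frame.
    gyro : (T, 3) ndarray
        Angular velocities, rad/s, sensor frame.
    static_window : (int, int)
        Half-open sample range ``[i0, i1)`` of the initial quiet-standing
        phase used for calibration; must span at least 3 s.
    """

    sensor_site: SensorSite
    sampling_rate_hz: float
    acc: np.ndarray
    gyro: np.ndarray
    static_window: tuple[int, int]

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must be a T×3 array")
        if self.gyro.shape != self.acc.shape:
            raise ValueError("acc and gyro must have identical shape")
        T = self.acc.shape[0]
        if T < self.sampling_rate_hz * 3:
            raise ValueError("recording shorter than the 3 s static phase")
        i0, i1 = self.static_window
        if not (0 <= i0 < i1 <= T):
            raise ValueError("static_window out of bounds")
        if (i1 - i0) < 3 * self.sampling_rate_hz:
            raise ValueError("static_window must span at least 3 s")
        if not (np.all(np.isfinite(self.acc)) and np.all(np.isfinite(self.gyro))):
            raise ValueError("non-finite samples in recording")
        if np.any(np.abs(self.acc) > ACC_RANGE_MS2 * 1.001):
            raise ValueError("acceleration exceeds ±16 g sensor range")
        if np.any(np.abs(self.gyro) > GYRO_RANGE_RADS * 1.001):
            raise ValueError("angular velocity exceeds ±2000 °/s sensor range")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]


@dataclass
class TrialRecord:
    """One walking trial: synchronized recordings from up to five sites."""

    subject_id: str
    session: str  # "test" | "retest"
    recordings: dict[SensorSite, ImuRecording]
    walkway_total_m: float = 14.0
    walkway_core_m: float = 10.0

    def __post_init__(self) -> None:
        if self.session not in ("test", "retest"):
            raise ValueError(f"session must be 'test' or 'retest', got {self.session!r}")
        required = {SensorSite.PELVIS, SensorSite.STERNUM, SensorSite.HEAD}
        missing = required - set(self.recordings)
        if missing:
            raise ValueError(
                "required sensor site absent: "
                + ", ".join(sorted(s.value for s in missing))
            )
        if not ({SensorSite.SHANK_LEFT, SensorSite.SHANK_RIGHT} & set(self.recordings)):
            raise ValueError("required sensor site absent: shank_left or shank_right")
        lens = {r.n_samples for r in self.recordings.values()}
        rates = {r.sampling_rate_hz for r in self.recordings.values()}
        if len(lens) != 1 or len(rates) != 1:
            raise ValueError("recordings are not synchronized (length/rate mismatch)")

    @property
    def sampling_rate_hz(self) -> float:
        return next(iter(self.recordings.values())).sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return next(iter(self.recordings.values())).n_samples


@dataclass
class AlignedSensor:
    """One sensor after calibration, in anatomical axes (AP, ML, CC)."""

    acc_anat: np.ndarray  # T×3, m/s², gravity removed from CC
    gyro_anat: np.ndarray  # T×3, rad/s, bias removed
    rotation: np.ndarray  # 3×3 sensor→anatomical
    gyro_bias: np.ndarray  # 3-vector, rad/s, sensor frame


@dataclass
class AlignedTrial:
    """A trial after the full calibration chain (bias, rotation, gravity,
    low-pass filtering)."""

    subject_id: str
    session: str
    sampling_rate_hz: float
    static_window: tuple[int, int]
    sensors: dict[SensorSite, AlignedSensor]
    filter_meta: dict = field(default_factory=dict)


@dataclass
class StrideTable:
    """Per-leg stride boundaries detected from shank angular velocity.

    ``boundaries`` are sample indices of terminal-contact proxies; stride i
    spans ``[boundaries[i], boundaries[i+1])``. ``steady`` flags which
    strides enter index computation.
    """

    leg: SensorSite
    sampling_rate_hz: float
    boundaries: np.ndarray  # (n+1,) int sample indices, strictly increasing
    steady: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.boundaries.size:
            if np.any(np.diff(self.boundaries) <= 0):
                raise ValueError("stride boundaries must be strictly increasing")
        n = max(self.boundaries.size - 1, 0)
        self.steady = np.asarray(self.steady, dtype=bool)
        if self.steady.size != n:
            raise ValueError("steady flags must match stride count")

    @property
    def n_strides(self) -> int:
        return max(self.boundaries.size - 1, 0)

    @property
    def durations_s(self) -> np.ndarray:
        return np.diff(self.boundaries) / self.sampling_rate_hz

    @property
    def n_steady(self) -> int:
        return int(self.steady.sum())

    @property
    def usable(self) -> bool:
        """At least 3 steady-state strides are required for index computation."""
        return self.n_steady >= 3


@dataclass
class TrialIndexSet:
    """The 15 per-trial gait index values (Table-2 row structure)."""

    subject_id: str
    session: str
    values: dict[str, float]
    n_strides_used: int

    def __post_init__(self) -> None:
        missing = set(INDEX_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing index values: {sorted(missing)}")

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id, "session": self.session}
        row.update({k: self.values[k] for k in INDEX_NAMES})
        row["n_strides_used"] = self.n_strides_used
        return row
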