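"""Per-stride gait indices: stability (nRMS), symmetry (iHR), smoothness (LDLJ).

* **nRMS** — per-stride RMS of the AP or ML acceleration divided by the CC
  RMS. The craniocaudal normalization removes inter-individual differences
  in overall acceleration magnitude due to walking speed; higher values mean
  larger horizontal accelerations relative to vertical, i.e. reduced
  stability.

* **iHR** — improved harmonic ratio. A stride contains two steps, so in a
  bilaterally symmetric gait the AP and CC pelvis accelerations concentrate
  power at even stride-frequency harmonics and the ML acceleration at odd
  ones (the *intrinsic* harmonics for each axis). iHR is the percentage of
  stride-harmonic power in the intrinsic set: 100 % = perfect symmetry,
  0 % = complete asymmetry.

* **LDLJ** — log dimensionless jerk,
  ``−ln[ (t2−t1)³ / max|s|² · ∫ (ds/dt)² dt ]``, computed per axis on the
  acceleration (LDLJa) or angular velocity (LDLJw) segment of one stride.
  Derivative: central differences; integral: trapezoidal rule.

All three are computed per steady-state stride and averaged (configurable
to median) into one value per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import (
    INDEX_NAMES,
    NRMS_SITE_LABEL,
    UPPER_BODY_SITES,
    AlignedTrial,
    Axis,
    SensorSite,
    StrideTable,
    TrialIndexSet,
)
from .segmentation import slice_strides

log = logging.getLogger(__name__)

#: Harmonic parity consistent with bilateral symmetry, per axis.
DEFAULT_PARITY = {Axis.AP: "even", Axis.ML: "odd", Axis.CC: "even"}


@dataclass
class IndexConfig:
    n_harmonics: int = 20  # harmonics per parity set (intrinsic and extrinsic)
    parity: dict = field(default_factory=lambda: dict(DEFAULT_PARITY))
    resample_len: int = 256
    aggregate: str = "mean"  # or "median"


def stride_rms(values: np.ndarray) -> float:
    """Root mean square √(Σv²/N) of one stride's samples."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("stride segment needs at least 2 samples")
    return float(np.sqrt(np.mean(v**2)))


def nrms(rms_x: float, rms_y: float) -> float:
    """Normalized RMS: horizontal (AP or ML) RMS over craniocaudal RMS."""
    if rms_y <= 0:
        raise ValueError("degenerate CC signal (zero RMS)")
    return rms_x / rms_y


def harmonic_powers(x: np.ndarray, resample_len: int = 256) -> np.ndarray:
    """Stride-frequency harmonic powers |X_h|² of one demeaned stride.

    The stride is resampled to a fixed length so its harmonics fall exactly
    on DFT bins (no leakage from non-integer alignment); entry ``h`` of the
    result (1-based) is the power at harmonic ``h`` of the stride frequency.
    """
    x = np.asarray(x, float)
    x = x - x.mean()
    n = x.size
    # linear resampling over the stride period (endpoint-exclusive phase grid)
    phase_src = np.arange(n) / n
    phase_dst = np.arange(resample_len) / resample_len
    xr = np.interp(phase_dst, phase_src, x, period=1.0)
    spec = np.fft.rfft(xr) / resample_len
    amp = np.abs(spec)
    return amp[1:] ** 2  # drop DC; index 0 ↔ harmonic 1


def ihr(
    stride_signal: np.ndarray,
    axis: Axis,
    n_harmonics: int = 20,
    parity: dict | None = None,
    resample_len: int = 256,
) -> float:
    """Improved harmonic ratio (%) of one stride's acceleration component.

    Considers the first ``n_harmonics`` intrinsic-parity and the first
    ``n_harmonics`` extrinsic-parity stride harmonics; returns
    ``100 · ΣP_intrinsic / (ΣP_intrinsic + ΣP_extrinsic)``.
    """
    par = (parity or DEFAULT_PARITY)[axis]
    powers = harmonic_powers(stride_signal, resample_len)
    available = powers.size
    if available < 2 * n_harmonics:
        log.warning(
            "segment supports only %d harmonics (< %d); using available ones",
            available,
            2 * n_harmonics,
        )
    h = np.arange(1, available + 1)
    even = h % 2 == 0
    intrinsic_mask = even if par == "even" else ~even
    p_int = powers[intrinsic_mask][:n_harmonics].sum()
    p_ext = powers[~intrinsic_mask][:n_harmonics].sum()
    total = p_int + p_ext
    if total <= 0:
        raise ValueError("degenerate stride: no harmonic power")
    return float(100.0 * p_int / total)


def ldlj(s: np.ndarray, fs_hz: float) -> float:
    """Log dimensionless jerk of one per-axis stride segment.

    ``−ln[ T³ / max|s|² · ∫ ṡ² dt ]`` with ``T = t2 − t1`` the segment
    duration, central-difference derivative and trapezoidal integration.
    Scale-invariant by construction (the amplitude cancels).
    """
    s = np.asarray(s, float)
    if s.ndim != 1:
        raise ValueError("ldlj operates on a single-axis segment")
    if s.size < 3:
        raise ValueError("segment too short for a derivative")
    peak = np.max(np.abs(s))
    if peak == 0:
        raise ValueError("degenerate segment (identically zero)")
    dt = 1.0 / fs_hz
    T = (s.size - 1) * dt
    ds = np.gradient(s, dt)
    integral = np.trapezoid(ds**2, dx=dt)
    return float(-np.log(T**3 / peak**2 * integral))


def aggregate_strides(values: list[float], how: str = "mean") -> float:
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("no stride values to aggregate")
    return float(np.median(arr)) if how == "median" else float(np.mean(arr))


def compute_trial_indices(
    aligned: AlignedTrial,
    strides: StrideTable,
    config: IndexConfig | None = None,
) -> TrialIndexSet:
    """All 15 per-trial indices from an aligned trial and its stride table.

    nRMS (AP, ML) at pelvis, trunk (sternum) and head; iHR (AP, ML, CC) and
    LDLJ of acceleration and angular velocity (AP, ML, CC) at the pelvis.
    Per-stride values are aggregated across steady-state strides.
    """
    cfg = config or IndexConfig()
    if strides.n_steady < 3:
        raise ValueError(
            f"trial unusable: {strides.n_steady} steady-state strides (< 3)"
        )
    fs = aligned.sampling_rate_hz
    per_stride: dict[str, list[float]] = {name: [] for name in INDEX_NAMES}

    axis_col = {Axis.AP: 0, Axis.ML: 1, Axis.CC: 2}
    for site in UPPER_BODY_SITES:
        label = NRMS_SITE_LABEL[site]
        for seg in slice_strides(aligned, strides, site, "acc"):
            rms_cc = stride_rms(seg[:, 2])
            for ax in (Axis.AP, Axis.ML):
                per_stride[f"nRMS_{ax.value}_{label}"].append(
                    nrms(stride_rms(seg[:, axis_col[ax]]), rms_cc)
                )

    pelvis_acc = slice_strides(aligned, strides, SensorSite.PELVIS, "acc")
    for seg in pelvis_acc:
        for ax in Axis:
            per_stride[f"iHR_{ax.value}"].append(
                ihr(seg[:, axis_col[ax]], ax, cfg.n_harmonics, cfg.parity, cfg.resample_len)
            )
    # the jerk integral runs from boundary to boundary: inclusive segments
    pelvis_acc_cl = slice_strides(aligned, strides, SensorSite.PELVIS, "acc", inclusive_end=True)
    pelvis_gyro_cl = slice_strides(aligned, strides, SensorSite.PELVIS, "gyro", inclusive_end=True)
    for seg in pelvis_acc_cl:
        for ax in Axis:
            per_stride[f"LDLJa_{ax.value}"].append(ldlj(seg[:, axis_col[ax]], fs))
    for seg in pelvis_gyro_cl:
        for ax in Axis:
            per_stride[f"LDLJw_{ax.value}"].append(ldlj(seg[:, axis_col[ax]], fs))

    values = {k: aggregate_strides(v, cfg.aggregate) for k, v in per_stride.items()}
    return TrialIndexSet(
        subject_id=aligned.subject_id,
        session=aligned.session,
        values=values,
        n_strides_used=strides.n_steady,
    )
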