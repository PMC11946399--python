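"""Sensor calibration chain: gyroscope bias removal, gravity alignment to
anatomical axes, gravity removal from the craniocaudal axis, and zero-phase
Butterworth low-pass filtering.

The chain is applied in a fixed order — bias removal → rotation → gravity
removal (CC) → filtering — so that the static calibration quantities are
estimated on raw signals. Filtering is zero-phase (forward-backward) by
default because the per-stride indices are phase-sensitive; a single-pass
variant is available via :class:`FilterConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import AlignedSensor, AlignedTrial, SensorSite, TrialRecord, G


@dataclass
class FilterConfig:
    """Low-pass filter settings (second-order Butterworth)."""

    acc_cutoff_hz: float = 10.0
    gyro_cutoff_hz: float = 6.0
    order: int = 2
    zero_phase: bool = True


#: Nominal forward (anteroposterior) axis of each sensor in its own frame,
#: used to complete the horizontal plane after gravity alignment.
DEFAULT_FORWARD_AXES: dict[SensorSite, tuple[float, float, float]] = {
    site: (1.0, 0.0, 0.0) for site in SensorSite
}


def estimate_static_bias(gyro: np.ndarray, static_window: tuple[int, int]) -> np.ndarray:
    """Per-axis mean angular velocity over the quiet-standing window.

    Subtracting this constant from the full stream removes the gyroscope
    static bias.
    """
    gyro = np.asarray(gyro, float)
    i0, i1 = static_window
    if i1 - i0 < 2:
        raise ValueError("static window too short for bias estimation")
    return gyro[i0:i1].mean(axis=0)


def gravity_alignment(
    acc: np.ndarray,
    static_window: tuple[int, int],
    forward_axis: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> np.ndarray:
    """Rotation matrix taking sensor coordinates to anatomical (AP, ML, CC).

    The craniocaudal axis is the direction of the mean static-phase
    acceleration (gravity). Gravity fixes only the vertical; the horizontal
    pair is completed by projecting the sensor's nominal forward axis onto
    the horizontal plane (AP) and closing the right-handed triad
    (ML = CC × AP). Rows of the returned matrix are the AP, ML, CC axes in
    sensor coordinates, so ``R @ v_sensor`` yields (AP, ML, CC) components.
    """
    acc = np.asarray(acc, float)
    i0, i1 = static_window
    mean_acc = acc[i0:i1].mean(axis=0)
    mag = np.linalg.norm(mean_acc)
    if not (0.8 * G <= mag <= 1.2 * G):
        raise ValueError(
            f"sensor not quasi-static or miscalibrated: static |acc| = {mag:.3f} m/s² "
            f"outside [{0.8 * G:.2f}, {1.2 * G:.2f}]"
        )
    cc = mean_acc / mag
    # Complete the horizontal plane; fall back to basis vectors if the
    # forward hint is (near) parallel to gravity.
    candidates = [np.asarray(forward_axis, float)] + [np.eye(3)[i] for i in range(3)]
    ap = None
    for f in candidates:
        h = f - np.dot(f, cc) * cc
        norm = np.linalg.norm(h)
        if norm > 1e-6:
            ap = h / norm
            break
    ml = np.cross(cc, ap)
    return np.vstack([ap, ml, cc])


def remove_gravity_cc(acc_anat: np.ndarray, static_window: tuple[int, int]) -> np.ndarray:
    """Subtract the static-window mean from the CC column only.

    Mean subtraction (rather than a hard-coded 9.81) is robust to residual
    misalignment of the gravity estimate.
    """
    acc_anat = np.asarray(acc_anat, float)
    i0, i1 = static_window
    out = acc_anat.copy()
    out[:, 2] -= acc_anat[i0:i1, 2].mean()
    return out


def lowpass_filter(
    x: np.ndarray, cutoff_hz: float, fs_hz: float, order: int = 2, zero_phase: bool = True
) -> np.ndarray:
    """Butterworth low-pass, zero-phase (forward-backward) by default."""
    x = np.asarray(x, float)
    if not 0 < cutoff_hz < fs_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz not in (0, Nyquist={fs_hz / 2}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def filtfilt_gain(freqs_hz: np.ndarray, cutoff_hz: float, fs_hz: float, order: int = 2) -> np.ndarray:
    """Exact amplitude gain of the zero-phase digital filter at ``freqs_hz``.

    Forward-backward filtering applies the squared magnitude response; used
    by the synthetic generator to state band-limited analytic truths.
    """
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs_hz) * 2 * np.pi / fs_hz)
    return np.abs(h) ** 2


def align_trial(
    trial: TrialRecord,
    filter_config: FilterConfig | None = None,
    forward_axes: dict[SensorSite, tuple[float, float, float]] | None = None,
) -> AlignedTrial:
    """Run the full calibration chain on every sensor of a trial."""
    cfg = filter_config or FilterConfig()
    fwd = dict(DEFAULT_FORWARD_AXES)
    if forward_axes:
        fwd.update(forward_axes)
    fs = trial.sampling_rate_hz
    sensors: dict[SensorSite, AlignedSensor] = {}
    for site, rec in trial.recordings.items():
        win = rec.static_window
        bias = estimate_static_bias(rec.gyro, win)
        R = gravity_alignment(rec.acc, win, fwd[site])
        acc_anat = rec.acc @ R.T
        gyro_anat = (rec.gyro - bias) @ R.T
        acc_anat = remove_gravity_cc(acc_anat, win)
        acc_f = lowpass_filter(acc_anat, cfg.acc_cutoff_hz, fs, cfg.order, cfg.zero_phase)
        gyro_f = lowpass_filter(gyro_anat, cfg.gyro_cutoff_hz, fs, cfg.order, cfg.zero_phase)
        sensors[site] = AlignedSensor(
            acc_anat=acc_f, gyro_anat=gyro_f, rotation=R, gyro_bias=bias
        )
    any_rec = next(iter(trial.recordings.values()))
    return AlignedTrial(
        subject_id=trial.subject_id,
        session=trial.session,
        sampling_rate_hz=fs,
        static_window=any_rec.static_window,
        sensors=sensors,
        filter_meta={
            "acc_cutoff_hz": cfg.acc_cutoff_hz,
            "gyro_cutoff_hz": cfg.gyro_cutoff_hz,
            "order": cfg.order,
            "zero_phase": cfg.zero_phase,
        },
    )
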