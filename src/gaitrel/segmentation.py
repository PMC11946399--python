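"""Stride segmentation from shank angular velocity.

Mid-swing produces a prominent positive peak in the sagittal-plane
(mediolateral-axis) angular velocity of the shank. Stride boundaries are
placed at the local minimum preceding each mid-swing peak — a terminal
contact proxy — and consecutive boundaries delimit strides. The first and
last detected stride of each leg are excluded from index computation as a
proxy for the walkway's 2 m acceleration/deceleration sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .types import AlignedTrial, SensorSite, StrideTable

log = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    prominence_rad_s: float = 1.0
    min_separation_s: float = 0.6
    stride_band_s: tuple[float, float] = (0.6, 2.5)
    anchor_leg: SensorSite = SensorSite.SHANK_LEFT
    drop_edge_strides: int = 1


def detect_strides(
    gyro_ml_shank: np.ndarray,
    fs_hz: float,
    leg: SensorSite = SensorSite.SHANK_LEFT,
    config: SegmentationConfig | None = None,
) -> StrideTable:
    """Detect stride boundaries on one leg from ML shank angular velocity.

    Returns an empty table (with a warning) when no swing peaks are found;
    strides with implausible durations are discarded.
    """
    cfg = config or SegmentationConfig()
    w = np.asarray(gyro_ml_shank, float)
    if w.ndim != 1:
        raise ValueError("expected a single-axis signal")
    peaks, _ = find_peaks(
        w,
        prominence=cfg.prominence_rad_s,
        distance=max(int(round(cfg.min_separation_s * fs_hz)), 1),
    )
    if peaks.size == 0:
        log.warning("no mid-swing peaks found; returning empty stride table")
        return StrideTable(leg=leg, sampling_rate_hz=fs_hz, boundaries=np.array([], int), steady=np.array([], bool))

    # boundary = minimum in the window from the previous peak to this peak;
    # the first peak searches one typical period back.
    if peaks.size >= 2:
        first_lo = max(0, 2 * peaks[0] - peaks[1])
    else:
        first_lo = max(0, peaks[0] - int(round(fs_hz)))
    boundaries = []
    prev = first_lo
    for p in peaks:
        lo = prev
        if p - lo < 2:
            lo = max(0, p - 2)
        boundaries.append(lo + int(np.argmin(w[lo:p])) if p > lo else p)
        prev = p
    boundaries = np.array(sorted(set(boundaries)), int)

    # enforce the stride-duration plausibility band
    keep = [boundaries[0]]
    for b in boundaries[1:]:
        if (b - keep[-1]) / fs_hz >= cfg.stride_band_s[0]:
            keep.append(b)
    boundaries = np.array(keep, int)
    durations = np.diff(boundaries) / fs_hz
    ok = durations <= cfg.stride_band_s[1]
    if not np.all(ok):
        log.warning("discarding %d strides outside plausibility band", int((~ok).sum()))
    # keep the longest run of consecutive plausible strides
    if boundaries.size >= 2 and not np.all(ok):
        best, cur, start, best_start = 0, 0, 0, 0
        for i, good in enumerate(ok):
            if good:
                cur += 1
                if cur > best:
                    best, best_start = cur, start
            else:
                cur, start = 0, i + 1
        boundaries = boundaries[best_start : best_start + best + 1] if best else boundaries[:1]
    n = max(boundaries.size - 1, 0)
    return StrideTable(
        leg=leg,
        sampling_rate_hz=fs_hz,
        boundaries=boundaries,
        steady=np.ones(n, bool),
    )


def select_steady_state(strides: StrideTable, drop_edge_strides: int = 1) -> StrideTable:
    """Flag the first/last ``drop_edge_strides`` strides as non-steady-state.

    The remaining strides approximate the 10 m core of the walkway. The
    returned table is ``unusable`` when fewer than 3 steady strides remain.
    """
    n = strides.n_strides
    steady = np.zeros(n, bool)
    if n > 2 * drop_edge_strides:
        steady[drop_edge_strides : n - drop_edge_strides] = True
    table = StrideTable(
        leg=strides.leg,
        sampling_rate_hz=strides.sampling_rate_hz,
        boundaries=strides.boundaries,
        steady=steady,
    )
    if not table.usable:
        log.warning(
            "only %d steady-state strides (< 3): trial flagged unusable", table.n_steady
        )
    return table


def slice_strides(
    aligned: AlignedTrial,
    strides: StrideTable,
    site: SensorSite,
    kind: str = "acc",
    inclusive_end: bool = False,
) -> list[np.ndarray]:
    """Per-stride T_i×3 segments of one site's signal (steady strides only).

    With ``inclusive_end`` each segment includes the closing boundary sample,
    so its first and last samples sit exactly at the stride boundaries — the
    integration limits t1, t2 of the smoothness index. Half-open segments
    (the default) partition the covered span and suit the per-stride RMS and
    harmonic decompositions, where the closing sample belongs to the next
    stride.
    """
    sensor = aligned.sensors[site]
    sig = sensor.acc_anat if kind == "acc" else sensor.gyro_anat
    T = sig.shape[0]
    extra = 1 if inclusive_end else 0
    segments = []
    for i in range(strides.n_strides):
        if not strides.steady[i]:
            continue
        b0, b1 = strides.boundaries[i], strides.boundaries[i + 1]
        if b0 < 0 or b1 + extra > T:
            raise ValueError(f"stride [{b0}, {b1}] outside signal bounds (T={T})")
        segments.append(sig[b0 : b1 + extra])
    return segments
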