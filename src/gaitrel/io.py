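"""CSV interchange for trials, cohort manifests and index tables.

Trial CSV layout::

    # units: acc=m/s2 gyro=rad/s
    time_s,pelvis_acc_x,pelvis_acc_y,...,shank_left_gyro_z[,phase]

The leading comment line declaring units is mandatory — accelerometer export
units vary between ``g`` and ``m/s2`` across tools and silent guessing is a
real failure mode, so the reader refuses files without a declaration.
Signals are converted to SI (m/s², rad/s) on ingest.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import INDEX_NAMES, SensorSite, TrialIndexSet, TrialRecord, ImuRecording, G

_UNIT_RE = re.compile(r"#\s*units:\s*acc=(\S+)\s+gyro=(\S+)")

_ACC_FACTORS = {"m/s2": 1.0, "m/s^2": 1.0, "g": G}
_GYRO_FACTORS = {"rad/s": 1.0, "deg/s": np.pi / 180.0, "dps": np.pi / 180.0}

#: Optional per-subject metadata columns of the cohort manifest.
MANIFEST_META_COLS = (
    "age",
    "sex",
    "months_since_trauma",
    "leg_length_cm",
    "bmi",
    "walking_speed_mps",
    "bbs",
    "dgi",
)


def _parse_units(path: Path) -> tuple[float, float]:
    with open(path) as fh:
        first = fh.readline()
    m = _UNIT_RE.match(first.strip())
    if not m:
        raise ValueError(
            f"{path}: missing unit declaration (expected leading "
            "'# units: acc=<m/s2|g> gyro=<rad/s|deg/s>' line)"
        )
    acc_u, gyro_u = m.group(1), m.group(2)
    if acc_u not in _ACC_FACTORS:
        raise ValueError(f"{path}: unknown acceleration unit {acc_u!r}")
    if gyro_u not in _GYRO_FACTORS:
        raise ValueError(f"{path}: unknown angular-velocity unit {gyro_u!r}")
    return _ACC_FACTORS[acc_u], _GYRO_FACTORS[gyro_u]


def read_trial_csv(
    path: str | Path,
    subject_id: str | None = None,
    session: str = "test",
    static_window_s: tuple[float, float] = (0.0, 3.0),
) -> TrialRecord:
    """Read one trial CSV into a :class:`TrialRecord` with SI units.

    The static window is taken from a ``phase`` column (initial contiguous
    run of ``static`` rows) when present, else from ``static_window_s``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    acc_f, gyro_f = _parse_units(path)
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: non-monotonic time column")
    fs = 1.0 / np.median(dt)

    if "phase" in df.columns:
        static_mask = (df["phase"].astype(str).str.strip() == "static").to_numpy()
        if not static_mask[0]:
            raise ValueError(f"{path}: phase column present but trial does not start static")
        i1 = int(np.argmin(static_mask)) if not static_mask.all() else len(df)
        window = (0, i1)
    else:
        window = (int(round(static_window_s[0] * fs)), int(round(static_window_s[1] * fs)))

    recordings: dict[SensorSite, ImuRecording] = {}
    for site in SensorSite:
        acc_cols = [f"{site.value}_acc_{ax}" for ax in "xyz"]
        gyro_cols = [f"{site.value}_gyro_{ax}" for ax in "xyz"]
        have_acc = all(c in df.columns for c in acc_cols)
        have_gyro = all(c in df.columns for c in gyro_cols)
        if not (have_acc or have_gyro):
            continue
        if not (have_acc and have_gyro):
            raise ValueError(f"{path}: incomplete channel set for site {site.value}")
        recordings[site] = ImuRecording(
            sensor_site=site,
            sampling_rate_hz=fs,
            acc=df[acc_cols].to_numpy(float) * acc_f,
            gyro=df[gyro_cols].to_numpy(float) * gyro_f,
            static_window=window,
        )
    return TrialRecord(
        subject_id=subject_id if subject_id is not None else path.stem,
        session=session,
        recordings=recordings,
    )


def write_trial_csv(trial: TrialRecord, path: str | Path) -> Path:
    """Write a trial to the canonical CSV layout (SI units declared)."""
    path = Path(path)
    n = trial.n_samples
    fs = trial.sampling_rate_hz
    data = {"time_s": np.arange(n) / fs}
    for site in sorted(trial.recordings, key=lambda s: s.value):
        rec = trial.recordings[site]
        for j, ax in enumerate("xyz"):
            data[f"{site.value}_acc_{ax}"] = rec.acc[:, j]
        for j, ax in enumerate("xyz"):
            data[f"{site.value}_gyro_{ax}"] = rec.gyro[:, j]
    i0, i1 = next(iter(trial.recordings.values())).static_window
    phase = np.full(n, "walk", dtype=object)
    phase[i0:i1] = "static"
    data["phase"] = phase
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write("# units: acc=m/s2 gyro=rad/s\n")
        df.to_csv(fh, index=False, float_format="%.9g")
    return path


def write_index_table(sets: list[TrialIndexSet], path: str | Path) -> Path:
    """Write per-trial index values, one row per (subject, session)."""
    if not sets:
        raise ValueError("empty index set list")
    rows = [s.as_row() for s in sets]
    keys = [(r["subject_id"], r["session"]) for r in rows]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (subject, session) rows: {dupes}")
    df = pd.DataFrame(rows, columns=["subject_id", "session", *INDEX_NAMES, "n_strides_used"])
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_index_table(path: str | Path) -> list[TrialIndexSet]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            TrialIndexSet(
                subject_id=str(row["subject_id"]),
                session=str(row["session"]),
                values={k: float(row[k]) for k in INDEX_NAMES},
                n_strides_used=int(row["n_strides_used"]),
            )
        )
    return out


def index_table_frame(sets: list[TrialIndexSet]) -> pd.DataFrame:
    """Index sets as a DataFrame keyed by (subject_id, session)."""
    df = pd.DataFrame([s.as_row() for s in sets])
    return df.set_index(["subject_id", "session"]).sort_index()


def read_manifest(path: str | Path, require_pairs: bool = True) -> pd.DataFrame:
    """Read the cohort manifest CSV (subject_id, session, path + metadata).

    With ``require_pairs`` each subject must appear with exactly one test and
    one retest row, as the paired reliability design requires.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "session", "path"):
        if col not in df.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    df["subject_id"] = df["subject_id"].astype(str)
    bad = set(df["session"]) - {"test", "retest"}
    if bad:
        raise ValueError(f"manifest contains unknown sessions: {sorted(bad)}")
    if require_pairs:
        counts = df.groupby(["subject_id", "session"]).size().unstack(fill_value=0)
        offenders = counts.index[
            (counts.get("test", 0) != 1) | (counts.get("retest", 0) != 1)
        ].tolist()
        if offenders:
            raise ValueError(
                f"subjects without exactly one test and one retest entry: {offenders}"
            )
    return df
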