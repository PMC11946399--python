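"""End-to-end orchestration: preprocess → segment → indices → reliability.

Outputs are a pure function of (input files, RunConfig). Subjects with an
unusable trial (fewer than 3 steady-state strides in either session) are
excluded pairwise, matching the paired reliability design.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .indices import compute_trial_indices
from .io import index_table_frame, read_manifest, read_trial_csv, write_index_table
from .preprocess import align_trial
from .reliability import agreement_frame, descriptives_frame, reliability_table
from .segmentation import detect_strides, select_steady_state
from .types import SensorSite, TrialIndexSet, TrialRecord

log = logging.getLogger(__name__)


def process_trial(trial: TrialRecord, config: RunConfig | None = None):
    """Run one trial through alignment, segmentation and index computation.

    Returns ``(TrialIndexSet | None, qc_dict)``; the index set is None when
    the trial is unusable (too few steady-state strides).
    """
    cfg = config or RunConfig()
    aligned = align_trial(trial, cfg.filter)
    anchor = cfg.segmentation.anchor_leg
    if anchor not in aligned.sensors:
        anchor = (
            SensorSite.SHANK_RIGHT
            if anchor == SensorSite.SHANK_LEFT
            else SensorSite.SHANK_LEFT
        )
    gyro_ml = aligned.sensors[anchor].gyro_anat[:, 1]
    strides = detect_strides(gyro_ml, aligned.sampling_rate_hz, anchor, cfg.segmentation)
    strides = select_steady_state(strides, cfg.segmentation.drop_edge_strides)
    qc = {
        "subject_id": trial.subject_id,
        "session": trial.session,
        "anchor_leg": anchor.value,
        "strides_detected": strides.n_strides,
        "strides_used": strides.n_steady,
        "usable": strides.usable,
    }
    if not strides.usable:
        log.warning(
            "trial %s/%s unusable: %d steady strides",
            trial.subject_id,
            trial.session,
            strides.n_steady,
        )
        return None, qc
    return compute_trial_indices(aligned, strides, cfg.index), qc


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict:
    """Process a cohort manifest into index and reliability tables.

    Writes ``index_table.csv``, ``table2.csv`` (descriptives + paired
    comparison), ``table3.csv`` (ICC/SEM/MDC), ``qc.csv`` and
    ``run_metadata.json`` under ``out_dir``.
    """
    cfg = config or RunConfig()
    manifest_path = Path(manifest_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent

    index_sets: list[TrialIndexSet] = []
    qc_rows = []
    for _, row in manifest.iterrows():
        trial = read_trial_csv(
            base / row["path"],
            subject_id=row["subject_id"],
            session=row["session"],
            static_window_s=cfg.static_window_s,
        )
        idx, qc = process_trial(trial, cfg)
        qc_rows.append(qc)
        if idx is not None:
            index_sets.append(idx)
    qc_df = pd.DataFrame(qc_rows)
    if not qc_df["usable"].all() and cfg.strict:
        raise RuntimeError(
            "unusable trials under --strict: "
            + ", ".join(
                f"{r.subject_id}/{r.session}"
                for r in qc_df[~qc_df["usable"]].itertuples()
            )
        )

    frame = index_table_frame(index_sets).reset_index()
    test_df = frame[frame["session"] == "test"].drop(columns=["session", "n_strides_used"])
    retest_df = frame[frame["session"] == "retest"].drop(columns=["session", "n_strides_used"])
    if cfg.drop_incomplete:
        complete = sorted(set(test_df["subject_id"]) & set(retest_df["subject_id"]))
        dropped = sorted(
            (set(test_df["subject_id"]) | set(retest_df["subject_id"])) - set(complete)
        )
        if dropped:
            log.warning("excluding subjects without both usable sessions: %s", dropped)
        test_df = test_df[test_df["subject_id"].isin(complete)]
        retest_df = retest_df[retest_df["subject_id"].isin(complete)]

    records = reliability_table(test_df, retest_df, cfg.reliability)
    table2 = descriptives_frame(records)
    table3 = agreement_frame(records)

    write_index_table(index_sets, out / "index_table.csv")
    table2.to_csv(out / "table2.csv", index=False, float_format="%.6g")
    table3.to_csv(out / "table3.csv", index=False, float_format="%.6g")
    qc_df.to_csv(out / "qc.csv", index=False)
    metadata = {
        "gaitrel_version": __version__,
        "n_trials": int(len(manifest)),
        "n_subjects_analyzed": int(test_df["subject_id"].nunique()),
        "config": cfg.to_dict(),
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2)
    return {
        "index_sets": index_sets,
        "records": records,
        "table2": table2,
        "table3": table3,
        "qc": qc_df,
        "metadata": metadata,
    }
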