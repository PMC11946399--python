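"""Synthetic test/retest gait cohorts with known ground truth.

The generator emulates the study protocol this package targets: a 3 s quiet
stance followed by a short straight-path walk (~8 strides of the 10 m core
at a slow self-selected speed, stride time ≈ 1.27 s), recorded at 128 Hz by
five sensors (head, sternum, pelvis, both shanks), repeated twice per
subject within one visit.

Signal model
------------
Upper-body accelerations and pelvis angular velocities are finite sums of
stride-frequency harmonics — the minimal model under which the harmonic
symmetry index is exact and the stability index has a Parseval closed form.
Each axis carries a target symmetry (iHR) and RMS level realized *exactly*
in the harmonic amplitudes, so every index has an analytic truth. Shank
angular velocity is a periodic swing template (positive mid-swing peak,
negative pre-swing trough) whose extremum times provide ground-truth stride
events. Raw sensor frames are tilted by a known pitch rotation to exercise
gravity alignment; heading is assumed calibrated (a yaw offset is
unidentifiable from gravity alone and would mix AP into ML).

Test-retest dependence is induced by a subject-level random effect on the
index-determining parameters plus additive session noise, so the true
intraclass correlation of each index family is controlled exactly:
ICC = σ²_between / (σ²_between + σ²_within).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .preprocess import FilterConfig, filtfilt_gain
from .types import ImuRecording, SensorSite, TrialRecord, G, INDEX_NAMES
from .io import write_trial_csv

#: Population means and between+within SDs of the index targets
#: (cohort-level walking characteristics of slow ambulators).
NRMS_TARGETS = {  # (site label, axis) -> (mean, sd)
    ("pelvis", "AP"): (0.82, 0.20),
    ("pelvis", "ML"): (0.85, 0.25),
    ("trunk", "AP"): (0.61, 0.20),
    ("trunk", "ML"): (0.71, 0.25),
    ("head", "AP"): (0.68, 0.30),
    ("head", "ML"): (0.68, 0.28),
}
IHR_TARGETS = {"AP": (75.0, 12.0), "ML": (71.0, 10.0), "CC": (78.0, 11.0)}
#: Vertical (CC) acceleration RMS scale per site, m/s².
CC_RMS_TARGETS = {"pelvis": (1.3, 0.25), "trunk": (1.1, 0.2), "head": (0.9, 0.18)}

_SITE_LABEL = {SensorSite.PELVIS: "pelvis", SensorSite.STERNUM: "trunk", SensorSite.HEAD: "head"}
_HARMONICS = np.array([1, 2, 3, 4])  # stride harmonics carrying power
_AX_COL = {"AP": 0, "ML": 1, "CC": 2}


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort."""

    n_subjects: int = 49
    n_strides: int = 8
    fs_hz: float = 128.0
    static_s: float = 3.0
    stride_time_mean_s: float = 1.27
    stride_time_sd_s: float = 0.08
    stride_jitter_cv: float = 0.02
    noise_sigma_acc: float = 0.03  # m/s², white, sensor frame
    noise_sigma_gyro: float = 0.005  # rad/s
    tilt_deg: float = 10.0  # injected pitch tilt of each sensor frame
    true_icc: dict = dc_field(
        default_factory=lambda: {"nRMS": 0.95, "iHR": 0.90, "LDLJ": 0.65}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for fam, icc in self.true_icc.items():
            if not 0 <= icc < 1:
                raise ValueError(f"true_icc[{fam!r}] must lie in [0, 1)")


@dataclass
class SessionParams:
    """Realized per-session signal parameters with analytic index truths."""

    stride_time_s: float
    #: (site label, axis) -> harmonic amplitude array over _HARMONICS
    acc_amps: dict
    acc_phases: dict
    #: axis -> amplitude/phase arrays for pelvis angular velocity
    gyro_amps: dict
    gyro_phases: dict
    targets: dict  # index name -> target value (iHR %, nRMS ratio)


@dataclass
class SubjectProfile:
    """Subject-level latent parameters; sessions derive from it."""

    spec: CohortSpec
    subject_index: int
    stride_time_s: float
    tilt_rad: float
    shank_peak_rad_s: float
    gyro_bias: np.ndarray
    subject_effects: dict  # index/param name -> between-subject effect
    phases: dict
    gyro_phase: dict
    age: float = 40.0
    sex: str = "M"

    @property
    def subject_id(self) -> str:
        return f"sub{self.subject_index:03d}"

    def session_params(self, session: str) -> SessionParams:
        return _session_params(self, session)


def _rng(spec: CohortSpec, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, *keys]))


def _split_amplitudes(
    ihr_target: float, rms_target: float, parity: str, tilt: float
) -> np.ndarray:
    """Harmonic amplitudes over _HARMONICS realizing exact iHR and RMS.

    Within each parity set amplitudes decay as h^(−tilt); the sets are
    scaled so intrinsic power / total power = iHR/100 and Σ A²/2 = RMS².
    """
    if not 0 <= ihr_target <= 100:
        raise ValueError("iHR target outside [0, 100]")
    if rms_target <= 0:
        raise ValueError("RMS target must be positive")
    even = _HARMONICS % 2 == 0
    intr = even if parity == "even" else ~even
    w = _HARMONICS.astype(float) ** (-tilt)
    total_power = 2.0 * rms_target**2  # Σ A² (Parseval: RMS² = Σ A²/2)
    amps = np.zeros_like(w)
    for mask, share in ((intr, ihr_target / 100.0), (~intr, 1.0 - ihr_target / 100.0)):
        denom = np.sum(w[mask] ** 2)
        if share > 0 and denom == 0:
            raise ValueError("infeasible target: no harmonics available for parity set")
        if denom > 0:
            amps[mask] = w[mask] * np.sqrt(share * total_power / denom)
    return amps


def make_profile(spec: CohortSpec, subject_index: int) -> SubjectProfile:
    """Deterministic subject profile for (spec.seed, subject_index)."""
    rng = _rng(spec, subject_index, 0)
    stride_time = float(
        np.clip(rng.normal(spec.stride_time_mean_s, spec.stride_time_sd_s), 1.0, 1.6)
    )
    effects: dict[str, float] = {}
    # between-subject component of each index target (variance icc·σ²)
    for (site, ax), (_, sd) in NRMS_TARGETS.items():
        effects[f"nRMS_{ax}_{site}"] = rng.normal(0.0, sd * np.sqrt(spec.true_icc["nRMS"]))
    for ax, (_, sd) in IHR_TARGETS.items():
        effects[f"iHR_{ax}"] = rng.normal(0.0, sd * np.sqrt(spec.true_icc["iHR"]))
    for site, (_, sd) in CC_RMS_TARGETS.items():
        effects[f"ccrms_{site}"] = rng.normal(0.0, sd)
    # spectral tilt drives the smoothness indices
    effects["tilt_acc"] = rng.normal(0.0, 0.35 * np.sqrt(spec.true_icc["LDLJ"]))
    effects["tilt_gyro"] = rng.normal(0.0, 0.35 * np.sqrt(spec.true_icc["LDLJ"]))
    for ax in ("AP", "ML", "CC"):
        effects[f"wrms_{ax}"] = rng.normal(0.0, 0.08)
    phases = {
        (site, ax): rng.uniform(0, 2 * np.pi, _HARMONICS.size)
        for site in ("pelvis", "trunk", "head")
        for ax in ("AP", "ML", "CC")
    }
    gyro_phase = {ax: rng.uniform(0, 2 * np.pi, _HARMONICS.size) for ax in ("AP", "ML", "CC")}
    return SubjectProfile(
        spec=spec,
        subject_index=subject_index,
        stride_time_s=stride_time,
        tilt_rad=np.deg2rad(spec.tilt_deg) + rng.normal(0.0, np.deg2rad(2.0)),
        shank_peak_rad_s=float(np.clip(rng.normal(4.8, 0.5), 3.0, 7.0)),
        gyro_bias=rng.normal(0.0, 0.01, 3),
        subject_effects=effects,
        phases=phases,
        gyro_phase=gyro_phase,
        age=float(np.clip(rng.normal(36.7, 13.2), 17, 67)),
        sex="F" if rng.uniform() < 17 / 49 else "M",
    )


def _session_params(profile: SubjectProfile, session: str) -> SessionParams:
    spec = profile.spec
    s_idx = {"test": 1, "retest": 2}[session]
    rng = _rng(spec, profile.subject_index, s_idx)
    eff = profile.subject_effects

    def within(family: str, sd: float) -> float:
        return rng.normal(0.0, sd * np.sqrt(1.0 - spec.true_icc[family]))

    targets: dict[str, float] = {}
    for ax, (mu, sd) in IHR_TARGETS.items():
        targets[f"iHR_{ax}"] = float(
            np.clip(mu + eff[f"iHR_{ax}"] + within("iHR", sd), 5.0, 99.0)
        )
    for (site, ax), (mu, sd) in NRMS_TARGETS.items():
        targets[f"nRMS_{ax}_{site}"] = float(
            np.clip(mu + eff[f"nRMS_{ax}_{site}"] + within("nRMS", sd), 0.15, 2.5)
        )
    cc_rms = {
        site: float(np.clip(mu + eff[f"ccrms_{site}"], 0.4, 3.0))
        for site, (mu, _) in CC_RMS_TARGETS.items()
    }
    tilt_acc = 0.6 + eff["tilt_acc"] + within("LDLJ", 0.35)
    tilt_gyro = 0.6 + eff["tilt_gyro"] + within("LDLJ", 0.35)

    acc_amps, acc_phases = {}, {}
    for site in ("pelvis", "trunk", "head"):
        for ax in ("AP", "ML", "CC"):
            parity = "odd" if ax == "ML" else "even"
            if ax == "CC":
                rms_t = cc_rms[site]
            else:
                rms_t = targets[f"nRMS_{ax}_{site}"] * cc_rms[site]
            if site == "pelvis":
                ihr_t = targets[f"iHR_{ax}"]
            else:
                ihr_t = 70.0  # symmetry is only scored at the pelvis
            acc_amps[(site, ax)] = _split_amplitudes(ihr_t, rms_t, parity, tilt_acc)
            acc_phases[(site, ax)] = profile.phases[(site, ax)]
    gyro_amps, gyro_phases = {}, {}
    for ax in ("AP", "ML", "CC"):
        wrms = float(np.clip(0.45 + eff[f"wrms_{ax}"], 0.15, 1.2))
        gyro_amps[ax] = _split_amplitudes(70.0, wrms, "even" if ax != "ML" else "odd", tilt_gyro)
        gyro_phases[ax] = profile.gyro_phase[ax]
    return SessionParams(
        stride_time_s=profile.stride_time_s,
        acc_amps=acc_amps,
        acc_phases=acc_phases,
        gyro_amps=gyro_amps,
        gyro_phases=gyro_phases,
        targets=targets,
    )


# ---------------------------------------------------------------------------
# shank swing template and event ground truth

_PEAK_PHASE, _PEAK_WIDTH = 0.75, 0.08  # stride-phase units
_TROUGH_PHASE, _TROUGH_WIDTH = 0.55, 0.09
_TROUGH_FRACTION = 0.35  # trough depth relative to the mid-swing peak


def _shank_template(phase: np.ndarray, peak_amp: float) -> np.ndarray:
    """Periodic sagittal shank angular velocity over stride phase."""
    out = np.zeros_like(phase, dtype=float)
    for k in (-1.0, 0.0, 1.0):
        out += peak_amp * np.exp(-(((phase % 1.0) - _PEAK_PHASE + k) / _PEAK_WIDTH) ** 2)
        out -= (
            _TROUGH_FRACTION
            * peak_amp
            * np.exp(-(((phase % 1.0) - _TROUGH_PHASE + k) / _TROUGH_WIDTH) ** 2)
        )
    return out


def boundary_phase(peak_amp: float = 4.8) -> float:
    """Stride phase of the template minimum between successive swing peaks
    (the terminal-contact proxy the detector locks onto)."""
    grid = np.linspace(_PEAK_PHASE + 0.02, _PEAK_PHASE + 0.98, 20001)
    return float(grid[np.argmin(_shank_template(grid, peak_amp))] % 1.0)


def synthesize_trial(
    profile: SubjectProfile, session: str, noiseless: bool = False
) -> tuple[TrialRecord, dict]:
    """Materialize one trial from a profile.

    Returns the trial plus a ground-truth dict: per-index analytic truths on
    the band-limited signal, true stride-boundary sample times of the left
    shank, and the injected rotation.
    """
    spec = profile.spec
    params = profile.session_params(session)
    fs, tau = spec.fs_hz, params.stride_time_s
    s_idx = {"test": 1, "retest": 2}[session]
    rng = _rng(spec, profile.subject_index, s_idx, 1)

    n_periods = spec.n_strides + 1  # n+1 swing peaks bracket n full strides
    n_static = int(round(spec.static_s * fs))
    t_walk = n_periods * tau
    n_total = n_static + int(round((t_walk + 0.8) * fs))
    t = np.arange(n_total) / fs
    walk_start = spec.static_s + 0.2
    phase = (t - walk_start) / tau
    in_walk = (phase >= 0) & (phase <= n_periods)
    # smooth half-cosine on/off ramps confined to the edge strides
    ramp = np.zeros(n_total)
    ramp[in_walk] = 1.0
    edge = 0.3  # seconds
    rise = (t >= walk_start) & (t < walk_start + edge)
    fall = (t > walk_start + t_walk - edge) & (t <= walk_start + t_walk)
    ramp[rise] = 0.5 - 0.5 * np.cos(np.pi * (t[rise] - walk_start) / edge)
    ramp[fall] = 0.5 - 0.5 * np.cos(np.pi * (walk_start + t_walk - t[fall]) / edge)

    def harmonic_series(amps: np.ndarray, phases: np.ndarray) -> np.ndarray:
        sig = np.zeros(n_total)
        for A, h, ph in zip(amps, _HARMONICS, phases):
            sig += A * np.cos(2 * np.pi * h * phase + ph)
        return sig * ramp

    # pitch tilt about the ML axis: anatomical -> sensor is R0.T
    c, s = np.cos(profile.tilt_rad), np.sin(profile.tilt_rad)
    R0 = np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])

    sigma_a = 0.0 if noiseless else spec.noise_sigma_acc
    sigma_w = 0.0 if noiseless else spec.noise_sigma_gyro
    recordings: dict[SensorSite, ImuRecording] = {}

    for site_enum, site in _SITE_LABEL.items():
        acc_anat = np.zeros((n_total, 3))
        for ax in ("AP", "ML", "CC"):
            acc_anat[:, _AX_COL[ax]] = harmonic_series(
                params.acc_amps[(site, ax)], params.acc_phases[(site, ax)]
            )
        acc_anat[:, 2] += G
        gyro_anat = np.zeros((n_total, 3))
        if site == "pelvis":
            for ax in ("AP", "ML", "CC"):
                gyro_anat[:, _AX_COL[ax]] = harmonic_series(
                    params.gyro_amps[ax], params.gyro_phases[ax]
                )
        acc_raw = acc_anat @ R0 + rng.normal(0.0, sigma_a, (n_total, 3))
        gyro_raw = gyro_anat @ R0 + profile.gyro_bias + rng.normal(0.0, sigma_w, (n_total, 3))
        recordings[site_enum] = ImuRecording(
            sensor_site=site_enum,
            sampling_rate_hz=fs,
            acc=acc_raw,
            gyro=gyro_raw,
            static_window=(0, n_static),
        )

    jitter = 0.0 if noiseless else spec.stride_jitter_cv
    for leg, leg_shift in ((SensorSite.SHANK_LEFT, 0.0), (SensorSite.SHANK_RIGHT, 0.5)):
        leg_phase = phase - leg_shift
        if jitter > 0:
            # slow phase wobble emulating stride-to-stride timing variation
            leg_phase = leg_phase + jitter * np.sin(
                2 * np.pi * t / (3.7 * tau) + rng.uniform(0, 2 * np.pi)
            )
        wav = _shank_template(leg_phase, profile.shank_peak_rad_s) * ramp
        gyro_anat = np.zeros((n_total, 3))
        gyro_anat[:, 1] = wav  # sagittal-plane rotation = ML axis
        acc_anat = np.zeros((n_total, 3))
        acc_anat[:, 2] = G + 0.4 * np.cos(2 * np.pi * leg_phase) * ramp
        acc_raw = acc_anat @ R0 + rng.normal(0.0, sigma_a, (n_total, 3))
        gyro_raw = gyro_anat @ R0 + profile.gyro_bias + rng.normal(0.0, sigma_w, (n_total, 3))
        recordings[leg] = ImuRecording(
            sensor_site=leg,
            sampling_rate_hz=fs,
            acc=acc_raw,
            gyro=gyro_raw,
            static_window=(0, n_static),
        )

    trial = TrialRecord(
        subject_id=profile.subject_id, session=session, recordings=recordings
    )
    bphase = boundary_phase(profile.shank_peak_rad_s)
    truth = {
        "indices": analytic_truth(params, fs),
        "targets": dict(params.targets),
        "boundary_times_s": walk_start + (bphase + np.arange(spec.n_strides + 1)) * tau,
        "stride_time_s": tau,
        "rotation": R0,  # sensor -> anatomical, what gravity alignment recovers
    }
    return trial, truth


def analytic_truth(
    params: SessionParams, fs_hz: float, filter_config: FilterConfig | None = None
) -> dict[str, float]:
    """Closed-form index truths on the band-limited (filtered) signal.

    The measurement chain low-pass filters before computing indices, so the
    truths apply the exact zero-phase Butterworth gain to each harmonic
    amplitude: iHR from the intrinsic/total power ratio, nRMS from Parseval
    RMS, LDLJ from the harmonic-series jerk integral with a densely sampled
    amplitude maximum.
    """
    cfg = filter_config or FilterConfig()
    tau = params.stride_time_s
    freqs = _HARMONICS / tau
    g_acc = filtfilt_gain(freqs, cfg.acc_cutoff_hz, fs_hz, cfg.order)
    g_gyro = filtfilt_gain(freqs, cfg.gyro_cutoff_hz, fs_hz, cfg.order)
    if not cfg.zero_phase:  # single-pass: amplitude gain is |H|, not |H|²
        g_acc, g_gyro = np.sqrt(g_acc), np.sqrt(g_gyro)

    def rms_of(amps: np.ndarray) -> float:
        return float(np.sqrt(np.sum(amps**2) / 2.0))

    def ihr_of(amps: np.ndarray, parity: str) -> float:
        even = _HARMONICS % 2 == 0
        intr = even if parity == "even" else ~even
        p = amps**2
        return float(100.0 * p[intr].sum() / p.sum())

    def ldlj_of(amps: np.ndarray, phases: np.ndarray) -> float:
        integral = float(np.sum(amps**2 * (2 * np.pi * _HARMONICS / tau) ** 2) * tau / 2.0)
        tt = np.linspace(0.0, tau, 8192, endpoint=False)
        sig = np.zeros_like(tt)
        for A, h, ph in zip(amps, _HARMONICS, phases):
            sig += A * np.cos(2 * np.pi * h * tt / tau + ph)
        peak = float(np.max(np.abs(sig)))
        return float(-np.log(tau**3 / peak**2 * integral))

    out: dict[str, float] = {}
    filt = {k: v * g_acc for k, v in params.acc_amps.items()}
    for site in ("pelvis", "trunk", "head"):
        cc = rms_of(filt[(site, "CC")])
        for ax in ("AP", "ML"):
            out[f"nRMS_{ax}_{site}"] = rms_of(filt[(site, ax)]) / cc
    for ax in ("AP", "ML", "CC"):
        parity = "odd" if ax == "ML" else "even"
        out[f"iHR_{ax}"] = ihr_of(filt[("pelvis", ax)], parity)
        out[f"LDLJa_{ax}"] = ldlj_of(filt[("pelvis", ax)], params.acc_phases[("pelvis", ax)])
        out[f"LDLJw_{ax}"] = ldlj_of(params.gyro_amps[ax] * g_gyro, params.gyro_phases[ax])
    return out


def generate_paired_values(
    n: int,
    true_icc: float,
    mean: float = 0.0,
    sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired test/retest values with exact variance-component structure.

    subject ~ N(mean, icc·sd²); each session adds N(0, (1−icc)·sd²), giving
    a population ICC of exactly ``true_icc`` and total variance ``sd²``.
    """
    if not 0 <= true_icc < 1:
        raise ValueError("true_icc must lie in [0, 1)")
    rng = rng or np.random.default_rng()
    subj = rng.normal(mean, sd * np.sqrt(true_icc), n)
    wsd = sd * np.sqrt(1.0 - true_icc)
    return subj + rng.normal(0.0, wsd, n), subj + rng.normal(0.0, wsd, n)


def generate_cohort(
    spec: CohortSpec, out_dir=None, noiseless: bool = False
) -> tuple[list[tuple[TrialRecord, TrialRecord]], pd.DataFrame]:
    """Full cohort: n subjects × (test, retest), plus a ground-truth table.

    With ``out_dir`` set, trial CSVs, a cohort manifest and the ground-truth
    CSV are written there. Fully deterministic for a fixed spec.
    """
    pairs = []
    truth_rows = []
    manifest_rows = []
    for i in range(spec.n_subjects):
        profile = make_profile(spec, i)
        session_trials = {}
        for session in ("test", "retest"):
            trial, truth = synthesize_trial(profile, session, noiseless=noiseless)
            session_trials[session] = trial
            row = {"subject_id": profile.subject_id, "session": session}
            row.update(truth["indices"])
            row["stride_time_s"] = truth["stride_time_s"]
            truth_rows.append(row)
            manifest_rows.append(
                {
                    "subject_id": profile.subject_id,
                    "session": session,
                    "path": f"{profile.subject_id}_{session}.csv",
                    "age": round(profile.age, 1),
                    "sex": profile.sex,
                    "walking_speed_mps": round(1.0 / profile.stride_time_s, 3),
                }
            )
        pairs.append((session_trials["test"], session_trials["retest"]))
    truth_df = pd.DataFrame(truth_rows, columns=["subject_id", "session", *INDEX_NAMES, "stride_time_s"])
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for test, retest in pairs:
            write_trial_csv(test, out / f"{test.subject_id}_test.csv")
            write_trial_csv(retest, out / f"{retest.subject_id}_retest.csv")
        pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
        truth_df.to_csv(out / "ground_truth.csv", index=False, float_format="%.9g")
    return pairs, truth_df
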