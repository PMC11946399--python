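"""Test-retest reliability surface: normality gating, paired comparison with
effect size, ICC with 95 % CI, SEM, MDC, and demographic subgroup analysis.

The intraclass correlation comes from the two-way mean squares of the
subject × session table (single-measure, fixed sessions). Two forms are
provided: *consistency* (the classical ICC(3,1)) and *absolute agreement*
(ICC(A,1) under the two-way model), with F-distribution 95 % confidence
intervals. SEM = SD·√(1−ICC); MDC = SEM·1.96·m with the multiplier m either
2 (as-printed convention) or √2 (the conventional MDC95) — both are exposed
because published SEM→MDC pairs in this literature mix the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import INDEX_NAMES

log = logging.getLogger(__name__)

ALPHA = 0.05
MDC_MULTIPLIERS = {"printed_2": 2.0, "sqrt2": np.sqrt(2.0)}


@dataclass
class ReliabilityConfig:
    icc_form: str = "absolute_agreement"  # or "consistency"
    mdc_convention: str = "printed_2"  # or "sqrt2"
    sem_sd: str = "pooled"  # "pooled" | "test" | "diff"
    aggregate_alpha: float = ALPHA


@dataclass
class ReliabilityRecord:
    """Per-index test/retest summary (one row of the reliability tables)."""

    index: str
    n: int
    test_mean: float
    test_ci: tuple[float, float]
    retest_mean: float
    retest_ci: tuple[float, float]
    diff_mean: float
    diff_ci: tuple[float, float]
    normal: bool
    test_used: str
    p: float
    d: float
    d_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    icc_form: str
    sd: float
    sem: float
    sem_ci: tuple[float, float]
    mdc: float
    mdc_ci: tuple[float, float]
    mdc_multiplier: float
    degenerate: bool = False


def normality_test(differences: np.ndarray, alpha: float = ALPHA):
    """Shapiro–Wilk on paired differences; gates the paired-test choice.

    Returns ``(statistic, p, is_normal)``; a constant vector is degenerate
    (statistic/p are NaN, ``is_normal`` False) and callers fall back to a
    sign-based convention.
    """
    d = np.asarray(differences, float)
    if d.size < 3:
        raise ValueError("need at least 3 paired differences")
    if np.ptp(d) == 0:
        return np.nan, np.nan, False
    stat, p = stats.shapiro(d)
    return float(stat), float(p), bool(p > alpha)


def cohens_d(differences: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Paired Cohen's d = mean(diff)/SD(diff) with an approximate 95 % CI."""
    d = np.asarray(differences, float)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, (0.0, 0.0)
    eff = d.mean() / sd
    se = np.sqrt(1.0 / n + eff**2 / (2.0 * n))
    z = stats.norm.ppf(1 - ALPHA / 2)
    return float(eff), (float(eff - z * se), float(eff + z * se))


def paired_comparison(test: np.ndarray, retest: np.ndarray):
    """Paired t-test when the differences pass normality, Wilcoxon otherwise.

    Returns ``(p, d, d_ci, test_used, is_normal)``. Zero-variance
    differences yield the degenerate convention p = 1, d = 0.
    """
    test = np.asarray(test, float)
    retest = np.asarray(retest, float)
    if test.shape != retest.shape or test.size < 3:
        raise ValueError("paired samples must match and have n ≥ 3")
    diff = retest - test
    if np.ptp(diff) == 0:
        if np.all(diff == 0):
            log.info("identical sessions: degenerate paired comparison")
            return 1.0, 0.0, (0.0, 0.0), "degenerate", False
        # constant nonzero shift: sign test is the defensible fallback
        p = float(stats.binomtest(int(np.sum(diff > 0)), diff.size).pvalue)
        return p, np.inf if diff[0] > 0 else -np.inf, (np.nan, np.nan), "sign", False
    _, _, normal = normality_test(diff)
    if normal:
        p = float(stats.ttest_rel(retest, test).pvalue)
        used = "t"
    else:
        p = float(stats.wilcoxon(retest, test).pvalue)
        used = "wilcoxon"
    d, d_ci = cohens_d(diff)
    return p, d, d_ci, used, normal


def _mean_squares(data: np.ndarray):
    """Two-way mean squares (rows = subjects, cols = sessions)."""
    n, k = data.shape
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    resid = data - row_m[:, None] - col_m[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_3_1(
    test: np.ndarray,
    retest: np.ndarray,
    form: str = "absolute_agreement",
    alpha: float = ALPHA,
) -> tuple[float, tuple[float, float]]:
    """Single-measure ICC from the two-way model, with a 95 % CI.

    ``form='consistency'`` gives the classical ICC(3,1)
    (MSR−MSE)/(MSR+(k−1)MSE); ``form='absolute_agreement'`` additionally
    penalizes a systematic session shift via the session mean square.
    Confidence limits follow the F-distribution constructions of the
    McGraw–Wong framework.
    """
    data = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    n, k = data.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    msr, msc, mse = _mean_squares(data)
    if msr <= 1e-30:
        raise ValueError("degenerate table: zero between-subject variance")

    if form == "consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse <= 1e-30:
            return 1.0, (1.0, 1.0)
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif form == "absolute_agreement":
        est = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        if mse <= 1e-30 and abs(msc - mse) <= 1e-30:
            return 1.0, (1.0, 1.0)
        a = k * est / (n * (1 - est)) if est < 1 else np.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
        if not np.isfinite(a):
            return 1.0, (1.0, 1.0)
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    est = float(est)
    return est, (float(min(lo, est)), float(max(hi, est)))


def sem(sd: float, icc: float) -> float:
    """Standard error of measurement, SD·√(1−ICC)."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if sd < 0:
        raise ValueError("SD must be non-negative")
    return float(sd * np.sqrt(1.0 - icc))


def mdc(sem_value: float, convention: str = "printed_2") -> float:
    """Minimal detectable change, SEM·1.96·m (m = 2 or √2 by convention)."""
    if sem_value < 0:
        raise ValueError("SEM must be non-negative")
    return float(sem_value * 1.96 * MDC_MULTIPLIERS[convention])


def subgroup_compare(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney U between two subgroups of per-subject values.

    Used on absolute test-retest differences split by age (<40 vs >40) or
    sex, to check whether measurement reliability differs between subgroups.
    Returns ``(U, two-sided p)``.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two non-empty groups required")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("one subgroup is empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _mean_ci(x: np.ndarray, alpha: float = ALPHA) -> tuple[float, tuple[float, float]]:
    m = float(np.mean(x))
    se = stats.sem(x)
    if se == 0:
        return m, (m, m)
    half = float(se * stats.t.ppf(1 - alpha / 2, x.size - 1))
    return m, (m - half, m + half)


def reliability_table(
    test_table: pd.DataFrame,
    retest_table: pd.DataFrame,
    config: ReliabilityConfig | None = None,
) -> list[ReliabilityRecord]:
    """One ReliabilityRecord per index from matched test/retest index tables.

    Inputs are DataFrames with a ``subject_id`` index (or column) and the 15
    index columns; rows are matched by subject_id, so row order is
    irrelevant. SEM/MDC confidence limits are obtained by propagating the
    ICC confidence limits through the formulas.
    """
    cfg = config or ReliabilityConfig()

    def _prep(df: pd.DataFrame) -> pd.DataFrame:
        if "subject_id" in df.columns:
            df = df.set_index("subject_id")
        return df.sort_index()

    t, r = _prep(test_table), _prep(retest_table)
    unmatched = sorted(set(t.index).symmetric_difference(r.index))
    if unmatched:
        raise ValueError(f"subjects without both sessions: {unmatched}")
    r = r.loc[t.index]

    records = []
    for name in INDEX_NAMES:
        x = t[name].to_numpy(float)
        y = r[name].to_numpy(float)
        n = x.size
        diff = y - x
        tm, tci = _mean_ci(x)
        rm, rci = _mean_ci(y)
        dm, dci = _mean_ci(diff)
        p, d, d_ci, used, normal = paired_comparison(x, y)
        degenerate = used in ("degenerate", "sign")
        try:
            icc_est, icc_ci = icc_3_1(x, y, cfg.icc_form)
        except ValueError:
            icc_est, icc_ci, degenerate = np.nan, (np.nan, np.nan), True
        if cfg.sem_sd == "pooled":
            sd_val = float(np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0))
        elif cfg.sem_sd == "test":
            sd_val = float(x.std(ddof=1))
        elif cfg.sem_sd == "diff":
            sd_val = float(diff.std(ddof=1))
        else:
            raise ValueError(f"unknown sem_sd {cfg.sem_sd!r}")
        if np.isnan(icc_est):
            sem_v, sem_ci_v, mdc_v, mdc_ci_v = np.nan, (np.nan, np.nan), np.nan, (np.nan, np.nan)
        else:
            sem_v = sem(sd_val, icc_est)
            # ICC CI endpoints propagate inversely: higher ICC → lower SEM
            sem_ci_v = (sem(sd_val, min(icc_ci[1], 1.0)), sem(sd_val, icc_ci[0]))
            mdc_v = mdc(sem_v, cfg.mdc_convention)
            mdc_ci_v = tuple(mdc(s, cfg.mdc_convention) for s in sem_ci_v)
        records.append(
            ReliabilityRecord(
                index=name,
                n=n,
                test_mean=tm,
                test_ci=tci,
                retest_mean=rm,
                retest_ci=rci,
                diff_mean=dm,
                diff_ci=dci,
                normal=normal,
                test_used=used,
                p=p,
                d=d,
                d_ci=d_ci,
                icc=icc_est,
                icc_ci=icc_ci,
                icc_form=cfg.icc_form,
                sd=sd_val,
                sem=sem_v,
                sem_ci=sem_ci_v,
                mdc=mdc_v,
                mdc_ci=mdc_ci_v,
                mdc_multiplier=MDC_MULTIPLIERS[cfg.mdc_convention],
                degenerate=degenerate,
            )
        )
    return records


def descriptives_frame(records: list[ReliabilityRecord]) -> pd.DataFrame:
    """Descriptive/paired-comparison table (means, difference, p, d)."""
    return pd.DataFrame(
        {
            "index": r.index,
            "n": r.n,
            "test_mean": r.test_mean,
            "test_ci_low": r.test_ci[0],
            "test_ci_high": r.test_ci[1],
            "retest_mean": r.retest_mean,
            "retest_ci_low": r.retest_ci[0],
            "retest_ci_high": r.retest_ci[1],
            "diff_mean": r.diff_mean,
            "diff_ci_low": r.diff_ci[0],
            "diff_ci_high": r.diff_ci[1],
            "normal": r.normal,
            "test_used": r.test_used,
            "p": r.p,
            "d": r.d,
            "d_ci_low": r.d_ci[0],
            "d_ci_high": r.d_ci[1],
        }
        for r in records
    )


def agreement_frame(records: list[ReliabilityRecord]) -> pd.DataFrame:
    """Reliability table (ICC, SEM, MDC, each with 95 % CI)."""
    return pd.DataFrame(
        {
            "index": r.index,
            "n": r.n,
            "icc": r.icc,
            "icc_ci_low": r.icc_ci[0],
            "icc_ci_high": r.icc_ci[1],
            "icc_form": r.icc_form,
            "sd": r.sd,
            "sem": r.sem,
            "sem_ci_low": r.sem_ci[0],
            "sem_ci_high": r.sem_ci[1],
            "mdc": r.mdc,
            "mdc_ci_low": r.mdc_ci[0],
            "mdc_ci_high": r.mdc_ci[1],
            "mdc_multiplier": r.mdc_multiplier,
            "degenerate": r.degenerate,
        }
        for r in records
    )
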