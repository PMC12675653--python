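"""Statistical layer: paired comparisons, Bonferroni adjustment, Cohen's d.

One value per participant x condition enters each test.  Zero-variance
difference scores yield a flagged degenerate result (t and p are NaN) rather
than an exception or a silent zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, InsufficientData

log = logging.getLogger(__name__)

METRIC_COLUMNS = ("accuracy", "std", "rms_s2s", "data_loss")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


@dataclass
class EffectSize:
    d: float
    interpretation: str
    degenerate: bool = False


@dataclass
class ComparisonResult:
    """One device x metric row of the summary table."""

    metric_name: str
    device: str
    kind: str                 # 'paired' or 'one_sample'
    n: int
    mean_bright: float
    sd_bright: float
    mean_dark: float
    sd_dark: float
    median_bright: float
    median_dark: float
    iqr_bright: float
    iqr_dark: float
    t_statistic: float
    df: int
    p_raw: float
    p_adjusted: float
    cohens_d: float
    d_interpretation: str
    degenerate: bool = False


def _t_from_values(values: np.ndarray) -> TTestResult:
    n = len(values)
    if n < 2:
        raise InsufficientData("t test needs at least 2 observations")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return TTestResult(t=math.nan, df=n - 1, p=math.nan, degenerate=True)
    t = float(np.mean(values) / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TTestResult(t=t, df=n - 1, p=p)


def paired_t(bright, dark) -> TTestResult:
    """Two-sided paired-sample t test on differences dark - bright."""
    b = np.asarray(bright, dtype=float)
    d = np.asarray(dark, dtype=float)
    if b.shape != d.shape:
        raise InsufficientData("paired samples must have equal length")
    return _t_from_values(d - b)


def one_sample_t_vs_zero(values) -> TTestResult:
    """Two-sided one-sample t test of the values against zero."""
    return _t_from_values(np.asarray(values, dtype=float))


def bonferroni(p_values, m: int | None = None):
    """Multiply each p by the family size and cap at 1.0.

    ``m`` defaults to the number of p values supplied.
    """
    ps = np.asarray(p_values, dtype=float)
    finite = np.isfinite(ps)
    if np.any((ps[finite] < 0) | (ps[finite] > 1)):
        raise DomainError("p values must lie in [0, 1]")
    m = len(ps) if m is None else int(m)
    if m < 1:
        raise DomainError("family size must be >= 1")
    return np.minimum(ps * m, 1.0)


def interpret_d(d: float) -> str:
    """Effect-size bins on |d|: <0.2 negligible, <0.5 small, <0.8 medium, else large."""
    a = abs(d)
    if not np.isfinite(a):
        return "degenerate"
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def cohens_d_paired(bright, dark, method: str = "difference") -> EffectSize:
    """Paired Cohen's d.

    ``difference`` (default): mean of difference scores over their SD
    (sample denominator), the form satisfying d = t / sqrt(n).
    ``average_sd``: mean difference over the pooled per-condition SD.
    """
    b = np.asarray(bright, dtype=float)
    d = np.asarray(dark, dtype=float)
    if b.shape != d.shape or len(b) < 2:
        raise InsufficientData("paired effect size needs >= 2 aligned pairs")
    diff = d - b
    if method == "difference":
        denom = float(np.std(diff, ddof=1))
    elif method == "average_sd":
        denom = math.sqrt((np.var(b, ddof=1) + np.var(d, ddof=1)) / 2.0)
    else:
        raise DomainError(f"unknown method {method!r}")
    if denom == 0.0:
        return EffectSize(d=math.nan, interpretation="degenerate", degenerate=True)
    val = float(np.mean(diff) / denom)
    return EffectSize(d=val, interpretation=interpret_d(val))


def cohens_d_one_sample(values) -> EffectSize:
    """d for a one-sample-vs-zero comparison: mean / SD."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InsufficientData("effect size needs >= 2 observations")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return EffectSize(d=math.nan, interpretation="degenerate", degenerate=True)
    val = float(np.mean(v) / sd)
    return EffectSize(d=val, interpretation=interpret_d(val))


def _iqr(v: np.ndarray) -> float:
    return float(np.percentile(v, 75) - np.percentile(v, 25))


def summarize(trial_metrics: pd.DataFrame, shifts: pd.DataFrame | None = None,
              metrics=METRIC_COLUMNS, d_method: str = "difference",
              family: str = "per-metric", family_size: int | None = None):
    """Per-device bright-vs-dark comparisons plus shift-vs-zero tests.

    ``trial_metrics`` needs columns participant, device, condition and the
    metric columns (trial-level rows are averaged per participant and
    condition first).  ``shifts`` needs columns participant, device, shift.
    The Bonferroni family defaults to one metric across all devices
    (``family='per-metric'``); ``family_size`` overrides it.

    Returns (list of ComparisonResult, tidy DataFrame).
    """
    df = trial_metrics.copy()
    agg = df.groupby(["participant", "device", "condition"], as_index=False)[
        list(metrics)
    ].mean()
    results: list[ComparisonResult] = []
    devices = sorted(agg["device"].unique())
    for metric in metrics:
        rows = []
        for device in devices:
            sub = agg[agg["device"] == device]
            wide = sub.pivot(index="participant", columns="condition", values=metric)
            if not {"bright", "dark"} <= set(wide.columns):
                log.warning("device %s lacks a condition for metric %s", device, metric)
                continue
            dropped = wide[wide.isna().any(axis=1)]
            if len(dropped):
                log.warning("dropping %d participant(s) missing a condition for %s/%s",
                            len(dropped), device, metric)
            wide = wide.dropna()
            if len(wide) < 2:
                log.warning("device %s has <2 complete participants for %s", device, metric)
                continue
            b = wide["bright"].to_numpy()
            d = wide["dark"].to_numpy()
            tt = paired_t(b, d)
            es = cohens_d_paired(b, d, method=d_method)
            rows.append(ComparisonResult(
                metric_name=metric, device=device, kind="paired", n=len(wide),
                mean_bright=float(b.mean()), sd_bright=float(b.std(ddof=1)),
                mean_dark=float(d.mean()), sd_dark=float(d.std(ddof=1)),
                median_bright=float(np.median(b)), median_dark=float(np.median(d)),
                iqr_bright=_iqr(b), iqr_dark=_iqr(d),
                t_statistic=tt.t, df=tt.df, p_raw=tt.p, p_adjusted=math.nan,
                cohens_d=es.d, d_interpretation=es.interpretation,
                degenerate=tt.degenerate or es.degenerate,
            ))
        m = family_size if family_size is not None else max(len(rows), 1)
        adj = bonferroni([r.p_raw if np.isfinite(r.p_raw) else 1.0 for r in rows], m=m)
        for r, pa in zip(rows, adj):
            r.p_adjusted = float(pa) if not r.degenerate else math.nan
        results.extend(rows)

    if shifts is not None:
        rows = []
        for device in sorted(shifts["device"].unique()):
            v = (shifts[shifts["device"] == device]
                 .groupby("participant")["shift"].mean().to_numpy())
            if len(v) < 2:
                log.warning("device %s has <2 participants with shifts", device)
                continue
            tt = one_sample_t_vs_zero(v)
            es = cohens_d_one_sample(v)
            rows.append(ComparisonResult(
                metric_name="apparent_gaze_shift", device=device, kind="one_sample",
                n=len(v),
                mean_bright=float(v.mean()), sd_bright=float(v.std(ddof=1)),
                mean_dark=math.nan, sd_dark=math.nan,
                median_bright=float(np.median(v)), median_dark=math.nan,
                iqr_bright=_iqr(v), iqr_dark=math.nan,
                t_statistic=tt.t, df=tt.df, p_raw=tt.p, p_adjusted=math.nan,
                cohens_d=es.d, d_interpretation=es.interpretation,
                degenerate=tt.degenerate or es.degenerate,
            ))
        m = family_size if family_size is not None else max(len(rows), 1)
        adj = bonferroni([r.p_raw if np.isfinite(r.p_raw) else 1.0 for r in rows], m=m)
        for r, pa in zip(rows, adj):
            r.p_adjusted = float(pa) if not r.degenerate else math.nan
        results.extend(rows)

    table = pd.DataFrame([vars(r) for r in results])
    return results, table


def format_report(results) -> str:
    """Plain-text summary table of ComparisonResult records."""
    lines = [
        f"{'metric':<20}{'device':<14}{'n':>4}{'bright':>16}{'dark':>16}"
        f"{'t (df)':>14}{'adj. p':>9}{'d':>12}",
    ]
    for r in results:
        if r.degenerate:
            stat = "degenerate"
            dtxt = "degenerate"
            ptxt = "-"
        else:
            stat = f"{r.t_statistic:.2f} ({r.df})"
            ptxt = f"{r.p_adjusted:.3f}"
            dtxt = f"{r.cohens_d:.2f} {r.d_interpretation}"
        bright = f"{r.mean_bright:.2f} ± {r.sd_bright:.2f}"
        dark = ("-" if not np.isfinite(r.mean_dark)
                else f"{r.mean_dark:.2f} ± {r.sd_dark:.2f}")
        lines.append(
            f"{r.metric_name:<20}{r.device:<14}{r.n:>4}{bright:>16}{dark:>16}"
            f"{stat:>14}{ptxt:>9}{dtxt:>12}"
        )
    return "\n".join(lines)
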