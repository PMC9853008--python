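"""Shared statistical kernel and the pre/post psychometric analysis.

Textbook estimators only: Student t tests (pooled variance), one-way and
repeated-measures ANOVA, Kolmogorov-Smirnov normality, Benjamini-Hochberg
step-up FDR, and the pooled-SD standardized pre/post effect size.  The
effect-size helper has a "printed precision" mode that truncates toward zero
at a fixed number of decimals, which is the convention needed to reproduce
published tables computed that way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "EffectSizeResult",
    "paired_t",
    "two_sample_t",
    "oneway_anova",
    "rm_anova",
    "ks_normality",
    "bh_fdr",
    "cohens_d_pooled",
    "cohens_d_samples",
    "truncate_toward_zero",
    "psych_report",
]


class DegenerateDataError(ValueError):
    """Zero variance (or otherwise degenerate input) where a test needs spread."""


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    q: float | None = None
    decision: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    convention: str = "pooled-sd"
    printed: float | None = None


def _asarray(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise ValueError(f"{name} needs at least 2 observations")
    return arr


def paired_t(before, after) -> TestResult:
    """Paired Student t test; df = n - 1."""
    b = _asarray(before, "before")
    a = _asarray(after, "after")
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("paired differences have zero variance")
    n = diff.size
    t = diff.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult("paired-t", t, n - 1, p)


def two_sample_t(a, b) -> TestResult:
    """Pooled-variance two-sample t test; df = n1 + n2 - 2."""
    x = _asarray(a, "a")
    y = _asarray(b, "b")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        raise DegenerateDataError("pooled variance is zero")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("two-sample-t", t, df, p)


def oneway_anova(*groups) -> TestResult:
    """One-way fixed-effects ANOVA; df = (k - 1, N - k)."""
    arrs = [_asarray(g, f"group{i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        raise DegenerateDataError("within-group variance is zero")
    f = (ss_between / df1) / (ss_within / df2)
    p = sps.f.sf(f, df1, df2)
    return TestResult("oneway-anova", f, (df1, df2), p)


def rm_anova(matrix) -> TestResult:
    """Classical repeated-measures ANOVA on a subjects x conditions matrix.

    Subject effects are removed from the error term; df = (k-1, (n-1)(k-1)).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with n, k >= 2")
    n, k = m.shape
    grand = m.mean()
    ss_cond = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if ss_err <= 0:
        raise DegenerateDataError("repeated-measures error sum of squares is zero")
    f = (ss_cond / df1) / (ss_err / df2)
    p = sps.f.sf(f, df1, df2)
    return TestResult("rm-anova", f, (df1, df2), p)


def ks_normality(x) -> TestResult:
    """Kolmogorov-Smirnov test of the standardized sample against N(0, 1)."""
    arr = _asarray(x, "x")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("sample has zero variance")
    z = (arr - arr.mean()) / sd
    stat, p = sps.kstest(z, "norm")
    return TestResult("ks-normality", float(stat), float(arr.size), float(p))


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, q_values)`` where ``q_values`` are the monotone
    adjusted p values (``p * m / rank`` cummin from the largest rank down).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    reject = qvals <= q
    return reject, qvals


def truncate_toward_zero(x: float, decimals: int) -> float:
    """Drop digits beyond ``decimals`` without rounding (-0.0586 -> -0.058)."""
    scale = 10.0**decimals
    # round at 9 decimals first so float noise cannot flip the truncation
    return math.trunc(round(x * scale, 9)) / scale


def cohens_d_pooled(
    mean_before: float,
    sd_before: float,
    mean_after: float,
    sd_after: float,
    printed_decimals: int | None = None,
) -> EffectSizeResult:
    """Standardized pre/post change: (m2 - m1) / sqrt((s1^2 + s2^2) / 2).

    With ``printed_decimals`` set, the ``printed`` field carries the value
    truncated toward zero at that many decimals.
    """
    if sd_before <= 0 or sd_after <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = math.sqrt((sd_before**2 + sd_after**2) / 2.0)
    d = (mean_after - mean_before) / pooled
    printed = None
    if printed_decimals is not None:
        printed = truncate_toward_zero(d, printed_decimals)
    return EffectSizeResult(d=d, printed=printed)


def cohens_d_samples(before, after, printed_decimals: int | None = None) -> EffectSizeResult:
    """Same convention as :func:`cohens_d_pooled` from raw paired samples."""
    b = _asarray(before, "before")
    a = _asarray(after, "after")
    return cohens_d_pooled(
        b.mean(), b.std(ddof=1), a.mean(), a.std(ddof=1), printed_decimals=printed_decimals
    )


def psych_report(scores: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Pre/post analysis of a long score table.

    ``scores`` columns: subject, group, scale, before, after.  Per group and
    scale: paired t, pooled-SD d; per scale: pooled two-sample t comparing
    change scores between the two groups (df = n1 + n2 - 2).  Incomplete
    pairs are dropped with a warning.
    """
    required = {"subject", "group", "scale", "before", "after"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table missing columns {required - set(scores.columns)}")
    frame = scores.copy()
    n_missing = frame[["before", "after"]].isna().any(axis=1).sum()
    if n_missing:
        import warnings

        warnings.warn(f"dropping {n_missing} incomplete score pairs", stacklevel=2)
        frame = frame.dropna(subset=["before", "after"])

    rows = []
    groups = sorted(frame["group"].unique())
    for scale, sub in frame.groupby("scale", sort=False):
        changes = {}
        for group in groups:
            g = sub[sub["group"] == group]
            if len(g) < 2:
                continue
            res = paired_t(g["before"], g["after"])
            eff = cohens_d_samples(g["before"], g["after"], printed_decimals=2)
            changes[group] = (g["after"] - g["before"]).to_numpy()
            rows.append(
                {
                    "scale": scale,
                    "group": group,
                    "test": "paired-t",
                    "n": len(g),
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                    "d": eff.d,
                    "d_printed": eff.printed,
                }
            )
        if len(changes) == 2:
            (g1, c1), (g2, c2) = sorted(changes.items())
            res = two_sample_t(c1, c2)
            rows.append(
                {
                    "scale": scale,
                    "group": f"{g1}-vs-{g2}",
                    "test": "two-sample-t-change",
                    "n": c1.size + c2.size,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                    "d": np.nan,
                    "d_printed": np.nan,
                }
            )
    report = pd.DataFrame(rows)
    if not report.empty:
        reject, qvals = bh_fdr(report["p"].to_numpy(), q=q)
        report["q_value"] = qvals
        report["significant"] = reject
    return report
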