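"""Offline EEG preprocessing, group asymmetry statistics, and HRV per block."""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .feedback import ALPHA_BAND, asymmetry_series
from .paradigm import ANALYSIS_LABELS, REST, UPREGULATION, VIEW, ExperimentSchedule
from .recording import EEGRecording
from .stats import DegenerateDataError, bh_fdr, ks_normality, oneway_anova, rm_anova, two_sample_t

__all__ = [
    "preprocess",
    "block_asymmetry_table",
    "asymmetry_group_stats",
    "detect_r_peaks",
    "hrv_by_block",
]

TARGET_RATE = 250.0
NOTCH_FREQS = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0)


def preprocess(
    recording: EEGRecording,
    lowpass_hz: float = 100.0,
    notch_freqs=NOTCH_FREQS,
    notch_halfwidth: float = 1.0,
) -> EEGRecording:
    """Downsample to 250 samples/s, low-pass at 100 Hz and notch the slice
    harmonics (15..90 Hz, +-1 Hz), all zero-phase."""
    if recording.rate < TARGET_RATE:
        raise ValueError(f"input rate {recording.rate} < {TARGET_RATE}")
    data = recording.data
    if recording.rate != TARGET_RATE:
        frac = Fraction(TARGET_RATE / recording.rate).limit_denominator(10000)
        data = spsig.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    nyq = TARGET_RATE / 2.0
    sos = spsig.butter(4, lowpass_hz / nyq, btype="lowpass", output="sos")
    data = spsig.sosfiltfilt(sos, data, axis=1)
    for f0 in notch_freqs:
        lo, hi = (f0 - notch_halfwidth) / nyq, (f0 + notch_halfwidth) / nyq
        sos = spsig.butter(2, [lo, hi], btype="bandstop", output="sos")
        data = spsig.sosfiltfilt(sos, data, axis=1)
    from dataclasses import replace

    return replace(recording, data=data, rate=TARGET_RATE)


def block_asymmetry_table(
    recordings,
    schedule: ExperimentSchedule,
    win_s: float = 2.0,
    step_s: float = 1.0,
    band=ALPHA_BAND,
) -> pd.DataFrame:
    """Per subject x run x block mean windowed asymmetry (Buffer excluded).

    ``recordings`` iterates over ``(subject_id, group, EEGRecording)``.
    Returns columns subject, group, run, block, mean_asym.
    """
    rows = []
    for subject, group, rec in recordings:
        windows = asymmetry_series(rec, schedule, win_s, step_s, band)
        frame = pd.DataFrame(
            [
                {"run": w.run, "block": w.block, "asym": w.asym}
                for w in windows
                if w.valid and w.block in ANALYSIS_LABELS
            ]
        )
        grouped = frame.groupby(["run", "block"])["asym"].mean().reset_index()
        for _, row in grouped.iterrows():
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "run": int(row["run"]),
                    "block": row["block"],
                    "mean_asym": float(row["asym"]),
                }
            )
    return pd.DataFrame(rows)


def _runblock_pivot(table: pd.DataFrame) -> pd.DataFrame:
    return table.pivot_table(
        index=["subject", "run"], columns="block", values="mean_asym"
    ).reset_index()


def asymmetry_group_stats(
    table: pd.DataFrame, q: float = 0.05, mode: str = "pooled"
) -> pd.DataFrame:
    """Condition and group statistics on run-block asymmetry values.

    Per the reproduction-mode default the omnibus and pairwise condition
    tests pool all run-blocks of the experimental group into a one-way
    ANOVA (error df = N - k, e.g. F(2, 537) for 180 run-blocks per
    condition); ``mode='rm'`` instead blocks on run-block units
    (classical repeated measures).  Between-group two-sample t tests
    compare run-block Up-View and Up-Rest differences (pooled variance,
    df = n1 + n2 - 2), BH-FDR corrected as a family at ``q``.
    """
    if mode not in ("pooled", "rm"):
        raise ValueError(f"unknown mode {mode!r}")
    exp = table[table["group"] == "experimental"]
    rows = []

    for label in ANALYSIS_LABELS:
        vals = exp.loc[exp["block"] == label, "mean_asym"]
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            raise DegenerateDataError(f"degenerate asymmetry cell: {label}")
        res = ks_normality(vals)
        rows.append(
            {"test": f"ks-normality[{label}]", "statistic": res.statistic,
             "df1": res.df, "df2": np.nan, "p": res.p}
        )

    conds = {
        lab: exp.loc[exp["block"] == lab, "mean_asym"].to_numpy()
        for lab in ANALYSIS_LABELS
    }
    if mode == "pooled":
        omni = oneway_anova(conds[REST], conds[VIEW], conds[UPREGULATION])
        pair_uv = oneway_anova(conds[UPREGULATION], conds[VIEW])
        pair_ur = oneway_anova(conds[UPREGULATION], conds[REST])
    else:
        piv = _runblock_pivot(exp)
        mat = piv[[REST, VIEW, UPREGULATION]].to_numpy()
        omni = rm_anova(mat)
        pair_uv = rm_anova(piv[[UPREGULATION, VIEW]].to_numpy())
        pair_ur = rm_anova(piv[[UPREGULATION, REST]].to_numpy())
    for name, res in (
        ("anova[Rest,View,Upregulation]", omni),
        ("anova[Upregulation,View]", pair_uv),
        ("anova[Upregulation,Rest]", pair_ur),
    ):
        rows.append(
            {"test": name, "statistic": res.statistic,
             "df1": res.df[0], "df2": res.df[1], "p": res.p}
        )

    ctl = table[table["group"] == "control"]
    between = []
    if not ctl.empty:
        piv_exp = _runblock_pivot(exp)
        piv_ctl = _runblock_pivot(ctl)
        for ref, name in ((VIEW, "Upregulation-View"), (REST, "Upregulation-Rest")):
            d_exp = (piv_exp[UPREGULATION] - piv_exp[ref]).to_numpy()
            d_ctl = (piv_ctl[UPREGULATION] - piv_ctl[ref]).to_numpy()
            res = two_sample_t(d_exp, d_ctl)
            between.append(
                {"test": f"group-t[{name}]", "statistic": res.statistic,
                 "df1": res.df, "df2": np.nan, "p": res.p}
            )

    report = pd.DataFrame(rows + between)
    report["q_value"] = np.nan
    report["significant"] = pd.NA
    if between:
        idx = report["test"].str.startswith("group-t")
        reject, qvals = bh_fdr(report.loc[idx, "p"].to_numpy(), q=q)
        report.loc[idx, "q_value"] = qvals
        report.loc[idx, "significant"] = reject
    return report


def detect_r_peaks(
    ecg: np.ndarray, rate: float, refractory_s: float = 0.25
) -> np.ndarray:
    """R-peak times (s) via smoothed squared-derivative thresholding.

    Threshold-on-derivative with a refractory period; peak positions are
    refined to the local maximum of the raw signal.  A flat signal returns
    an empty array with a warning.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < int(rate):
        warnings.warn("ECG too short for peak detection", stacklevel=2)
        return np.array([])
    if np.ptp(x) == 0:
        warnings.warn("flat ECG signal; no peaks detected", stacklevel=2)
        return np.array([])
    deriv = np.gradient(x)
    energy = deriv**2
    win = max(3, int(0.12 * rate))
    energy = np.convolve(energy, np.ones(win) / win, mode="same")
    thr = 0.25 * np.percentile(energy, 99.9)
    if thr <= 0:
        warnings.warn("no derivative energy above threshold", stacklevel=2)
        return np.array([])
    locs, _ = spsig.find_peaks(energy, height=thr, distance=int(refractory_s * rate))
    half = int(0.06 * rate)
    refined = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(x.size, loc + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    times = np.unique(np.asarray(refined)) / rate
    # enforce refractory period after refinement
    keep = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            keep.append(t)
            last = t
    return np.asarray(keep)


def hrv_by_block(
    peak_times: np.ndarray, schedule: ExperimentSchedule, alpha: float = 0.05
):
    """SDNN/RMSSD per block label (pooled over runs) + across-block ANOVA.

    RR intervals are assigned to the block containing their midpoint;
    Buffer intervals are dropped.  Blocks with fewer than 2 intervals are
    flagged missing.  Returns ``(records DataFrame, TestResult | None)``.
    """
    times = np.asarray(peak_times, dtype=float)
    rr = np.diff(times) * 1000.0  # ms
    mids = (times[:-1] + times[1:]) / 2.0
    per_block: dict[str, list[float]] = {lab: [] for lab in ANALYSIS_LABELS}
    for _, lab, start, end in schedule.blocks():
        if lab not in per_block:
            continue
        sel = (mids >= start) & (mids < end)
        per_block[lab].extend(rr[sel])
    rows = []
    for lab in ANALYSIS_LABELS:
        vals = np.asarray(per_block[lab])
        if vals.size < 2:
            rows.append(
                {"block": lab, "sdnn": np.nan, "rmssd": np.nan,
                 "n_beats": int(vals.size), "missing": True}
            )
            continue
        rows.append(
            {
                "block": lab,
                "sdnn": float(vals.std(ddof=1)),
                "rmssd": float(np.sqrt(np.mean(np.diff(vals) ** 2))),
                "n_beats": int(vals.size),
                "missing": False,
            }
        )
    records = pd.DataFrame(rows)
    test = None
    groups = [np.asarray(per_block[lab]) for lab in ANALYSIS_LABELS]
    if all(g.size >= 2 for g in groups):
        try:
            test = oneway_anova(*groups)
        except DegenerateDataError:
            test = None
    return records, test
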