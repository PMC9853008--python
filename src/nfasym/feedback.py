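"""Closed-loop feedback engine: windowed alpha log-power asymmetry.

The displayed bar during an Upregulation block is the mean of the last (up
to) three baseline-relative asymmetry values, where the asymmetry of a 2-s
window is ``ln P(F4) - ln P(F3)`` of alpha-band power and the baseline is
the mean asymmetry of the preceding View block.  The bar is blue when it
maintains or increases relative to the previous bar, red otherwise.  Sham
mode replaces the asymmetry stream with a bounded random walk that is
independent of the EEG input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import UPREGULATION, VIEW, ExperimentSchedule
from .recording import EEGRecording

__all__ = [
    "AsymmetryWindow",
    "FeedbackState",
    "FeedbackTrace",
    "window_band_power",
    "asymmetry_series",
    "view_baseline",
    "feedback_bar",
    "sham_feedback",
    "run_closed_loop",
    "template_subtract",
    "BaselineUnavailableError",
]

ALPHA_BAND = (8.0, 12.0)


class BaselineUnavailableError(ValueError):
    """No valid View window available to set the feedback baseline."""


@dataclass(frozen=True)
class AsymmetryWindow:
    run: int
    block: str
    t_start: float
    ln_p_f4: float
    ln_p_f3: float
    asym: float
    valid: bool = True


@dataclass
class FeedbackState:
    """Mutable per-block feedback state (baseline, smoothing history)."""

    baseline: float
    win_s: float = 2.0
    step_s: float = 1.0
    history: list = field(default_factory=list)
    prev_bar: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.win_s):
            raise ValueError("require 0 < step_s <= win_s")


@dataclass(frozen=True)
class FeedbackTrace:
    """Per-update feedback records for one recording (Upregulation only)."""

    records: pd.DataFrame  # columns: run, time, bar, color, raw_asym, relative_asym
    mode: str
    seed: int | None = None

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def window_band_power(segment: np.ndarray, rate: float, band=ALPHA_BAND) -> float:
    """Total periodogram power (mean-square units) in ``band``.

    Rectangular summation of FFT periodogram bins whose center frequencies
    fall inside ``[low, high]``; Parseval-normalized so a unit-amplitude
    in-band sinusoid yields ~0.5.
    """
    x = np.asarray(segment, dtype=float)
    low, high = band
    if not (0 < low < high < rate / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={rate / 2})")
    n = x.size
    spec = np.fft.rfft(x)
    ms = np.abs(spec) ** 2 / n**2
    ms[1 : (n + 1) // 2] *= 2.0  # one-sided doubling (not DC / Nyquist)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= low) & (freqs <= high)
    return float(ms[mask].sum())


def asymmetry_series(
    recording: EEGRecording,
    schedule: ExperimentSchedule,
    win_s: float = 2.0,
    step_s: float = 1.0,
    band=ALPHA_BAND,
) -> list[AsymmetryWindow]:
    """Sliding-window ``ln P(F4) - ln P(F3)`` aligned to block starts.

    Windows advance by ``step_s`` within each block; a 40-s View block at
    the 2 s / 1 s defaults yields 39 windows and a 60-s Upregulation block
    yields 59.  Windows with non-positive power are flagged invalid.
    """
    f3 = recording.channel("F3")
    f4 = recording.channel("F4")
    rate = recording.rate
    wlen = int(round(win_s * rate))
    step = int(round(step_s * rate))
    out: list[AsymmetryWindow] = []
    for run, label, sl in schedule.sample_slices(rate):
        start, stop = sl.start, min(sl.stop, recording.n_samples)
        for i0 in range(start, stop - wlen + 1, step):
            seg3 = f3[i0 : i0 + wlen]
            seg4 = f4[i0 : i0 + wlen]
            p3 = window_band_power(seg3, rate, band)
            p4 = window_band_power(seg4, rate, band)
            t0 = i0 / rate
            if p3 <= 0 or p4 <= 0:
                out.append(AsymmetryWindow(run, label, t0, np.nan, np.nan, np.nan, False))
                continue
            l3, l4 = np.log(p3), np.log(p4)
            out.append(AsymmetryWindow(run, label, t0, l4, l3, l4 - l3))
    return out


def view_baseline(windows: list[AsymmetryWindow]) -> float:
    """Mean asymmetry of the valid View windows handed in."""
    vals = [w.asym for w in windows if w.valid and w.block == VIEW]
    if not vals:
        raise BaselineUnavailableError("no valid View windows for baseline")
    return float(np.mean(vals))


def feedback_bar(state: FeedbackState, new_asym: float) -> tuple[float, str]:
    """One feedback update: baseline-relative, 3-window smoothed, colored.

    Mutates ``state``; returns ``(bar_height, color)``.  Color is blue when
    the bar maintains or increases, red when it drops; the first bar of a
    block is blue.
    """
    relative = new_asym - state.baseline
    state.history.append(relative)
    if len(state.history) > 3:
        state.history.pop(0)
    bar = float(np.mean(state.history))
    color = "blue" if state.prev_bar is None or bar >= state.prev_bar else "red"
    state.prev_bar = bar
    return bar, color


def _n_updates(block_s: float, win_s: float, step_s: float) -> int:
    return int(np.floor((block_s - win_s) / step_s + 1e-9)) + 1


def sham_feedback(
    schedule: ExperimentSchedule,
    seed: int,
    step_sd: float = 0.2,
    bound: float = 2.0,
    win_s: float = 2.0,
    step_s: float = 1.0,
) -> FeedbackTrace:
    """Random bar trace independent of any EEG input.

    A Gaussian random walk (step SD ``step_sd``) reflected at ``+-bound``
    restarts for every Upregulation block; colors follow the same
    maintain-or-increase rule as real feedback.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for run, label, start, end in schedule.blocks():
        if label != UPREGULATION:
            continue
        n = _n_updates(end - start, win_s, step_s)
        bar = 0.0
        prev = None
        for k in range(n):
            bar = bar + rng.normal(0.0, step_sd)
            # reflect into [-bound, bound]
            while abs(bar) > bound:
                bar = np.sign(bar) * (2 * bound) - bar
            color = "blue" if prev is None or bar >= prev else "red"
            prev = bar
            rows.append(
                {
                    "run": run,
                    "time": start + k * step_s + win_s,
                    "bar": bar,
                    "color": color,
                    "raw_asym": np.nan,
                    "relative_asym": np.nan,
                }
            )
    return FeedbackTrace(records=pd.DataFrame(rows), mode="sham", seed=seed)


def run_closed_loop(
    recording: EEGRecording,
    schedule: ExperimentSchedule,
    mode: str = "real",
    seed: int | None = None,
    win_s: float = 2.0,
    step_s: float = 1.0,
    band=ALPHA_BAND,
) -> FeedbackTrace:
    """Chain windowing -> View baseline -> bar updates causally per run.

    Every update at time t is a pure function of samples at or before t;
    in sham mode the EEG is ignored entirely.
    """
    if mode == "sham":
        if seed is None:
            raise ValueError("sham mode requires a seed")
        return sham_feedback(schedule, seed, win_s=win_s, step_s=step_s)
    if mode != "real":
        raise ValueError(f"unknown mode {mode!r}")

    windows = asymmetry_series(recording, schedule, win_s, step_s, band)
    by_run: dict[int, list[AsymmetryWindow]] = {}
    for w in windows:
        by_run.setdefault(w.run, []).append(w)

    rows = []
    for run in sorted(by_run):
        run_windows = by_run[run]
        baseline = view_baseline([w for w in run_windows if w.block == VIEW])
        state = FeedbackState(baseline=baseline, win_s=win_s, step_s=step_s)
        for w in run_windows:
            if w.block != UPREGULATION or not w.valid:
                continue
            bar, color = feedback_bar(state, w.asym)
            rows.append(
                {
                    "run": run,
                    "time": w.t_start + win_s,
                    "bar": bar,
                    "color": color,
                    "raw_asym": w.asym,
                    "relative_asym": w.asym - baseline,
                }
            )
    return FeedbackTrace(records=pd.DataFrame(rows), mode="real")


def template_subtract(
    recording: EEGRecording,
    period_s: float,
    n_average: int = 10,
    channels: tuple[str, ...] | None = None,
) -> EEGRecording:
    """Moving-average template subtraction of a periodic artifact.

    Splits each channel into consecutive epochs of ``period_s`` and
    subtracts from every epoch the mean of the ``n_average`` preceding
    epochs (the first epochs use the earliest available ones, self
    excluded).  Trailing samples shorter than one period pass through.  If
    the recording holds fewer than ``n_average`` full epochs the input is
    returned unchanged with a warning.
    """
    if period_s <= 0:
        raise ValueError("period_s must be positive")
    plen = int(round(period_s * recording.rate))
    n_epochs = recording.n_samples // plen
    if n_epochs < n_average:
        warnings.warn(
            f"only {n_epochs} epochs < n_average={n_average}; passthrough", stacklevel=2
        )
        return recording
    if channels is None:
        channels = tuple(c for c in recording.channels if c.upper() != "ECG")
    data = recording.data.copy()
    for name in channels:
        ci = recording.channels.index(name)
        sig = data[ci]
        epochs = sig[: n_epochs * plen].reshape(n_epochs, plen)
        cleaned = epochs.copy()
        for i in range(n_epochs):
            if i >= n_average:
                template = epochs[i - n_average : i].mean(axis=0)
            else:
                # warm-up: earliest n_average epochs excluding the current one
                pool = [j for j in range(n_average + 1) if j != i][:n_average]
                template = epochs[pool].mean(axis=0)
            cleaned[i] = epochs[i] - template
        data[ci, : n_epochs * plen] = cleaned.ravel()
    return recording.with_data(data)
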