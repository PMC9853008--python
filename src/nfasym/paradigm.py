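"""Block timeline of the experiment and its mapping to sample/volume grids.

The paradigm is a fixed sequence of runs, each composed of Rest, View and
Upregulation blocks plus a short Buffer segment (instruction/transition time
that closes the gap between the analysed blocks and the run length; it is
excluded from every analysis).  All intervals are half-open ``[start, end)``
and 0-based; boundaries are floored onto the sample grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REST",
    "VIEW",
    "UPREGULATION",
    "BUFFER",
    "BLOCK_LABELS",
    "BlockSpec",
    "ExperimentSchedule",
    "build_schedule",
    "block_labels",
    "write_events",
    "read_events",
]

REST = "Rest"
VIEW = "View"
UPREGULATION = "Upregulation"
BUFFER = "Buffer"

#: Closed set of block labels; Buffer is analysis-excluded padding.
BLOCK_LABELS = (REST, VIEW, UPREGULATION, BUFFER)

#: Labels that take part in analyses (Buffer never does).
ANALYSIS_LABELS = (REST, VIEW, UPREGULATION)


class ScheduleError(ValueError):
    """Invalid schedule parameters or malformed events file."""


@dataclass(frozen=True)
class BlockSpec:
    """One block of one run: a label and a duration in seconds."""

    label: str
    duration: float

    def __post_init__(self) -> None:
        if self.label not in BLOCK_LABELS:
            raise ScheduleError(f"unknown block label {self.label!r}")
        if self.duration < 0:
            raise ScheduleError(f"negative duration {self.duration} for {self.label}")
        if self.label != BUFFER and self.duration <= 0:
            raise ScheduleError(f"{self.label} block must have positive duration")


@dataclass(frozen=True)
class ExperimentSchedule:
    """Ordered runs of blocks plus the two sampling grids (BOLD TR, EEG rate)."""

    runs: tuple[tuple[BlockSpec, ...], ...]
    tr: float
    eeg_rate: float

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def run_duration(self) -> float:
        return sum(b.duration for b in self.runs[0])

    @property
    def total_duration(self) -> float:
        return sum(b.duration for run in self.runs for b in run)

    @property
    def n_volumes(self) -> int:
        return int(math.floor(self.total_duration / self.tr + 1e-9))

    def blocks(self):
        """Yield ``(run_index, label, start_s, end_s)`` in temporal order."""
        t = 0.0
        for r, run in enumerate(self.runs):
            for block in run:
                if block.duration > 0:
                    yield r, block.label, t, t + block.duration
                t += block.duration

    def sample_slices(self, rate: float, label: str | None = None):
        """Yield ``(run_index, label, slice)`` of sample indices at ``rate``.

        Half-open block intervals are floored onto the sample grid, so the
        slices partition ``range(floor(total_duration * rate))``.
        """
        if rate <= 0:
            raise ScheduleError("rate must be positive")
        for r, lab, start, end in self.blocks():
            if label is not None and lab != label:
                continue
            i0 = int(math.floor(start * rate + 1e-9))
            i1 = int(math.floor(end * rate + 1e-9))
            yield r, lab, slice(i0, i1)

    def volume_slices(self, label: str | None = None):
        """Block slices on the BOLD volume grid (one sample per TR)."""
        return self.sample_slices(1.0 / self.tr, label=label)


def build_schedule(
    n_runs: int = 10,
    rest_s: float = 20.0,
    view_s: float = 40.0,
    up_s: float = 60.0,
    buffer_s: float = 10.0,
    tr: float = 2.0,
    eeg_rate: float = 250.0,
) -> ExperimentSchedule:
    """Build the default Rest -> View -> Upregulation (-> Buffer) paradigm.

    Defaults reproduce the 10-run design: 130 s per run, 1300 s total and
    650 volumes at TR = 2 s.
    """
    if tr <= 0:
        raise ScheduleError("tr must be positive")
    if eeg_rate <= 0:
        raise ScheduleError("eeg_rate must be positive")
    if n_runs < 1:
        raise ScheduleError("n_runs must be >= 1")
    for name, dur in (("rest_s", rest_s), ("view_s", view_s), ("up_s", up_s)):
        if dur <= 0:
            raise ScheduleError(f"{name} must be positive")
    if buffer_s < 0:
        raise ScheduleError("buffer_s must be >= 0")
    run = [
        BlockSpec(REST, rest_s),
        BlockSpec(VIEW, view_s),
        BlockSpec(UPREGULATION, up_s),
    ]
    if buffer_s > 0:
        run.append(BlockSpec(BUFFER, buffer_s))
    return ExperimentSchedule(
        runs=tuple(tuple(run) for _ in range(n_runs)), tr=tr, eeg_rate=eeg_rate
    )


def block_labels(schedule: ExperimentSchedule, rate: float) -> np.ndarray:
    """One label per sample at ``rate`` samples/s over the whole experiment."""
    n = int(math.floor(schedule.total_duration * rate + 1e-9))
    out = np.empty(n, dtype=object)
    for _, lab, sl in schedule.sample_slices(rate):
        out[sl] = lab
    return out


def write_events(schedule: ExperimentSchedule, path) -> None:
    """Serialize to a BIDS-style events TSV (onset, duration, trial_type, run).

    TR and EEG rate are carried in ``# key=value`` header comments so the
    file round-trips to an identical schedule.
    """
    rows = [
        {"onset": start, "duration": end - start, "trial_type": lab, "run": r}
        for r, lab, start, end in schedule.blocks()
    ]
    frame = pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "run"])
    with open(path, "w") as fh:
        fh.write(f"# tr={schedule.tr}\n# eeg_rate={schedule.eeg_rate}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_events(path) -> ExperimentSchedule:
    """Inverse of :func:`write_events`; validates ordering and overlap."""
    meta = {"tr": 2.0, "eeg_rate": 250.0}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, val = line.lstrip("#").strip().partition("=")
        if key.strip() in meta:
            meta[key.strip()] = float(val)
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    required = {"onset", "duration", "trial_type", "run"}
    if not required.issubset(frame.columns):
        raise ScheduleError(f"events file missing columns {required - set(frame.columns)}")
    frame = frame.sort_values(["onset"]).reset_index(drop=True)
    runs: dict[int, list[BlockSpec]] = {}
    prev_end = 0.0
    for idx, row in frame.iterrows():
        onset, duration = float(row["onset"]), float(row["duration"])
        if onset < prev_end - 1e-9:
            raise ScheduleError(
                f"row {idx}: onset {onset} overlaps previous block ending at {prev_end}"
            )
        if onset > prev_end + 1e-9:
            # implicit gap is treated as buffer time of the current run
            runs.setdefault(int(row["run"]), []).append(BlockSpec(BUFFER, onset - prev_end))
        try:
            block = BlockSpec(str(row["trial_type"]), duration)
        except ScheduleError as exc:
            raise ScheduleError(f"row {idx}: {exc}") from exc
        runs.setdefault(int(row["run"]), []).append(block)
        prev_end = onset + duration
    ordered = tuple(tuple(runs[k]) for k in sorted(runs))
    return ExperimentSchedule(runs=ordered, tr=meta["tr"], eeg_rate=meta["eeg_rate"])
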