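"""Multichannel sampled-signal container with TSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["EEGRecording", "ChannelNotFoundError"]


class ChannelNotFoundError(KeyError):
    pass


@dataclass(frozen=True, eq=False)
class EEGRecording:
    """Channels-by-samples signal matrix with a sampling rate.

    ``data`` has shape ``(n_channels, n_samples)``; ``channels`` names the
    rows (e.g. F3, F4, ECG).  ``meta`` carries generator ground truth
    (planted R-peak times, artifact templates) and is never serialized.
    """

    data: np.ndarray
    rate: float
    channels: tuple[str, ...]
    meta: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channels", tuple(self.channels))
        if data.ndim != 2 or data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {data.shape} does not match {len(self.channels)} channels"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {name!r} not in {list(self.channels)}"
            ) from None
        return self.data[idx]

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        return replace(self, data=np.asarray(data, dtype=float))

    def truncated(self, t: float) -> "EEGRecording":
        """Keep only samples strictly before time ``t`` (causality checks)."""
        n = int(np.floor(t * self.rate + 1e-9))
        return self.with_data(self.data[:, :n])

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(self.data.T, columns=list(self.channels))
        with open(path, "w") as fh:
            fh.write(f"# rate={self.rate}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "EEGRecording":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# rate="):
                raise ValueError(f"{path}: missing '# rate=' header")
            rate = float(first.split("=", 1)[1])
            frame = pd.read_csv(fh, sep="\t")
        return cls(data=frame.to_numpy().T, rate=rate, channels=tuple(frame.columns))
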