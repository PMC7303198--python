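"""Core in-memory containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns of the event table attached to continuous recordings.
EVENT_COLUMNS = ["sample", "index", "stimulus", "role", "condition", "onset_ms", "token"]


@dataclass
class RawEEG:
    """Continuous multichannel EEG in microvolts.

    data : (n_channels, n_samples) float array, µV
    srate : sampling rate, Hz
    ch_names / ch_types : per-channel name and kind ('scalp'|'mastoid'|'eog')
    events : trial event table with sample indices into ``data``
    reference : label of the recording reference
    """

    data: np.ndarray
    srate: float
    ch_names: list[str]
    ch_types: list[str]
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))
    reference: str = "Fpz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.ch_names) or len(self.ch_names) != len(self.ch_types):
            raise ValueError("channel metadata length does not match data")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if len(self.events):
            s = np.asarray(self.events["sample"], dtype=int)
            if np.any(np.diff(s) <= 0):
                raise ValueError("event sample indices must be strictly increasing")
            if s[0] < 0 or s[-1] >= self.n_samples:
                raise ValueError("event sample indices out of data bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def picks(self, kind: str) -> np.ndarray:
        """Indices of channels of a given type."""
        return np.array([i for i, t in enumerate(self.ch_types) if t == kind], dtype=int)

    def copy(self) -> "RawEEG":
        return RawEEG(
            data=self.data.copy(),
            srate=self.srate,
            ch_names=list(self.ch_names),
            ch_types=list(self.ch_types),
            events=self.events.copy(),
            reference=self.reference,
        )
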