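"""In-memory container for multichannel PSG signals."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: EEG channels used throughout the package, with their contralateral
#: mastoid reference.
EEG_CHANNELS = ("F3", "F4", "C3", "C4", "O1", "O2")
CONTRALATERAL_MASTOID = {
    "F3": "M2", "C3": "M2", "O1": "M2",
    "F4": "M1", "C4": "M1", "O2": "M1",
}


@dataclass
class Recording:
    """Multichannel signal in microvolts with sampling metadata.

    Attributes
    ----------
    channels : list of str
        Ordered channel names.
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling frequency in Hz.
    reference : dict
        Per-channel reference token (e.g. "M2", or "raw").
    """

    channels: list
    data: np.ndarray
    fs: float
    reference: dict = field(default_factory=dict)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count does not match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def get(self, channel: str) -> np.ndarray:
        return self.data[self.channels.index(channel)]

    def copy(self) -> "Recording":
        return Recording(list(self.channels), self.data.copy(), self.fs,
                         dict(self.reference), self.start_time)
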