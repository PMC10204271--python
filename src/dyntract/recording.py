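"""In-memory container for a multi-channel voltage recording (iEEG + EOG)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """Multi-channel voltage time series.

    Attributes
    ----------
    data : numpy.ndarray
        (n_channels, n_samples) voltages in microvolts.
    sampling_rate : float
        Hz.
    channels : list of str
        Channel (site) identifiers, row-aligned with ``data``.
    eog_channel : str or None
        Name of the electro-oculography channel, if present.
    """

    data: np.ndarray
    sampling_rate: float
    channels: list[str]
    eog_channel: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel list does not match data rows")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.eog_channel is not None and self.eog_channel not in self.channels:
            raise ValueError(f"eog_channel {self.eog_channel!r} not in channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def eog(self) -> np.ndarray:
        if self.eog_channel is None:
            raise ValueError("recording has no EOG channel")
        return self.channel(self.eog_channel)
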