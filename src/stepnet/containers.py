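"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import ChannelGeometry


@dataclass
class EpochedEEG:
    """Stimulus-locked EEG epochs for one subject × task.

    data
        ``(n_epochs, n_channels, n_times)`` voltages in μV.
    sfreq
        Sampling rate in Hz (the study recorded at 250 Hz).
    tmin_ms
        Time of sample 0 relative to stimulus onset; −200 ms throughout
        this package. Windows are half-open ``[tmin, tmax)``.
    conditions
        Per-epoch condition label (``Frequent``/``Target``/``Novel`` or
        ``Go``/``NoGo``).
    """

    data: np.ndarray
    sfreq: float
    tmin_ms: float
    montage: ChannelGeometry
    conditions: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("one condition label per epoch required")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel axis does not match montage")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.tmin_ms + np.arange(self.n_times) * 1000.0 / self.sfreq

    @property
    def ch_names(self) -> tuple[str, ...]:
        return self.montage.ch_names

    def select(self, condition: str) -> "EpochedEEG":
        """Epochs of a single condition."""
        mask = self.conditions == condition
        return replace(self, data=self.data[mask], conditions=self.conditions[mask])

    def subset(self, epoch_idx: np.ndarray) -> "EpochedEEG":
        idx = np.asarray(epoch_idx)
        return replace(self, data=self.data[idx], conditions=self.conditions[idx])

    def copy(self) -> "EpochedEEG":
        return replace(self, data=self.data.copy(), conditions=self.conditions.copy())
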