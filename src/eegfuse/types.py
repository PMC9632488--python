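"""Core data container for one subject's continuous multichannel EEG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultichannelRecord:
    """One subject's continuous EEG.

    Parameters
    ----------
    data
        Channel-major matrix, shape ``(n_channels, n_samples)``, in microvolts.
    sampling_rate
        Samples per second (Hz).
    channel_names
        Ordered, unique electrode labels (e.g. ``["Fp1", "Fpz", "Fp2"]``).
    subject_id
        Stable identifier; used to prevent subject leakage across splits.
    label
        Class index in ``0..k-1`` (e.g. 0 = healthy control, 1 = depressed).
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    subject_id: str
    label: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(
                f"record data must be 2-D (channels x samples), got shape {self.data.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names must be unique: {self.channel_names}")
        if not np.isfinite(self.data).all():
            raise ValueError("record data contains NaN or infinite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_subset(self, names: list[str]) -> "MultichannelRecord":
        """Return a copy restricted to ``names``, in the requested order."""
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(
                f"channels {missing} not in record (available: {self.channel_names})"
            )
        idx = [self.channel_names.index(n) for n in names]
        return MultichannelRecord(
            data=self.data[idx].copy(),
            sampling_rate=self.sampling_rate,
            channel_names=list(names),
            subject_id=self.subject_id,
            label=self.label,
        )
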