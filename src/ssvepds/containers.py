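"""In-memory containers for multichannel EEG recordings and labelled trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """A multichannel signal: ``data`` is channels x samples at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    ch_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.ch_names is not None and len(self.ch_names) != self.n_channels:
            raise ValueError("ch_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrialSet:
    """Labelled fixed-length trials: ``data`` is trials x channels x samples.

    ``labels`` are 1-based class indices.  ``sequence`` optionally records
    which stimulation sequence each trial belongs to (one visit of every
    target forms a sequence); cross-validation folds split on sequences so
    that class balance is preserved.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    sequence: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("TrialSet data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length does not match trial count")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.sequence is not None:
            self.sequence = np.asarray(self.sequence, dtype=int)
            if len(self.sequence) != self.n_trials:
                raise ValueError("sequence length does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def trial(self, i: int) -> Recording:
        return Recording(self.data[i], self.fs)

    def subset(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        seq = None if self.sequence is None else self.sequence[idx]
        return TrialSet(self.data[idx], self.labels[idx], self.fs, seq, dict(self.meta))
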