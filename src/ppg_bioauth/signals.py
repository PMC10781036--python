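"""Core signal containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class SignalRecord:
    """A single-channel PPG time series.

    Parameters
    ----------
    samples : 1-D float array, arbitrary amplitude units.
    fs : sampling rate in Hz, > 0.
    subject_id : identity label (int or str), or None when unknown.
    source_tag : free-text provenance, e.g. ``"synthetic"`` or ``"RW-PPG"``.
    record_id : unique id of the recording, used to group segments so that
        windows cut from the same recording never straddle a train/test split.
    """

    samples: np.ndarray
    fs: float
    subject_id: object = None
    source_tag: str = ""
    record_id: object = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "SignalRecord":
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       fs=self.fs if fs is None else fs)


@dataclass
class Segment:
    """One fixed-duration window of a preprocessed signal."""

    samples: np.ndarray
    fs: float
    start_time_s: float
    subject_id: object = None
    record_id: object = None
    snr_db: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs
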