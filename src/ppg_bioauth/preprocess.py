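"""PPG preprocessing: filter, detrend, de-artifact, normalize, resample,
segment, and quality-screen.

The stages run in a fixed order (the order of :func:`preprocess_record`):

1. zero-phase Butterworth band-pass in the cardiac band,
2. moving-average baseline subtraction,
3. PCA-based motion-artifact suppression on an epoch-stacked matrix,
4. peak normalization,
5. cubic-spline resampling to a common rate,
6. overlapping fixed-length windowing,
7. per-window spectral SNR estimation and thresholding.

Each stage is individually addressable and the chained pipeline equals
their composition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .signals import Segment, SignalRecord

__all__ = [
    "PreprocessConfig", "bandpass_filter", "remove_baseline",
    "remove_motion_artifacts_pca", "normalize", "resample", "segment",
    "estimate_snr", "quality_screen", "preprocess_record", "PipelineStageError",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters (all rates in Hz, times in s)."""

    band_low_hz: float = 0.5
    band_high_hz: float = 8.0
    filter_order: int = 4
    baseline_window_s: float = 1.0
    pca_epoch_s: float = 1.0
    pca_variance_keep: float = 0.9
    target_fs: float = 250.0
    window_s: float = 5.0
    overlap: float = 0.5
    snr_min_db: float = 5.0
    cardiac_band_hz: tuple[float, float] = (0.7, 3.5)

    def __post_init__(self):
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.band_high_hz >= self.target_fs / 2:
            raise ValueError("band_high_hz must be below the target Nyquist rate")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if not (0 < self.pca_variance_keep <= 1):
            raise ValueError("pca_variance_keep must be in (0, 1]")


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def bandpass_filter(record: SignalRecord, cfg: PreprocessConfig) -> SignalRecord:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    if cfg.band_high_hz >= record.fs / 2:
        raise ValueError(
            f"band_high_hz={cfg.band_high_hz} is not below Nyquist {record.fs / 2}"
        )
    sos = sps.butter(cfg.filter_order, [cfg.band_low_hz, cfg.band_high_hz],
                     btype="bandpass", fs=record.fs, output="sos")
    return record.with_samples(sps.sosfiltfilt(sos, record.samples))


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average with reflection padding at the edges."""
    win = max(int(win), 1)
    half = win // 2
    padded = np.pad(x, (half, win - 1 - half), mode="reflect")
    kernel = np.full(win, 1.0 / win)
    return np.convolve(padded, kernel, mode="valid")


def remove_baseline(record: SignalRecord, cfg: PreprocessConfig) -> SignalRecord:
    """Subtract a centered moving-average baseline."""
    win = int(round(cfg.baseline_window_s * record.fs))
    if win < 2:
        raise ValueError("baseline window must span at least 2 samples")
    return record.with_samples(record.samples - _moving_average(record.samples, win))


def remove_motion_artifacts_pca(record: SignalRecord, cfg: PreprocessConfig) -> SignalRecord:
    """Suppress transient artifacts via PCA on an epoch-stacked matrix.

    The signal is cut into consecutive non-overlapping epochs (rows of a
    matrix) and decomposed by SVD of the uncentered matrix (equivalently,
    eigen-decomposition of the epochs' second-moment matrix); the
    reconstruction keeps the leading components whose cumulative captured
    energy first reaches ``pca_variance_keep``.  The repeating pulse shape
    shared by all epochs dominates the leading component, while a
    transient burst confined to one epoch loads on trailing components
    and is discarded.  The matrix is deliberately not column-centered:
    centering would move the common pulse into the restored mean and
    leave the burst as the dominant component, defeating the removal.
    The output is truncated to a whole number of epochs.
    """
    epoch_len = int(round(cfg.pca_epoch_s * record.fs))
    n_epochs = record.samples.size // epoch_len
    if n_epochs < 2:
        raise ValueError("signal must span at least two PCA epochs")
    X = record.samples[: n_epochs * epoch_len].reshape(n_epochs, epoch_len)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        keep = 1
    else:
        cum = np.cumsum(var) / total
        keep = int(np.searchsorted(cum, cfg.pca_variance_keep - 1e-12) + 1)
    recon = (U[:, :keep] * s[:keep]) @ Vt[:keep]
    return record.with_samples(recon.ravel())


def normalize(record: SignalRecord, cfg: PreprocessConfig | None = None) -> SignalRecord:
    """Center to zero mean, then scale so the absolute peak is 1.

    A constant record maps to all zeros rather than dividing by zero.
    """
    x = record.samples - record.samples.mean()
    peak = np.abs(x).max()
    return record.with_samples(x / peak if peak > 0 else x)


def resample(record: SignalRecord, target_fs: float) -> SignalRecord:
    """Cubic-spline resampling onto a uniform grid at ``target_fs``."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    n_out = int(round(record.duration_s * target_fs))
    t_in = np.arange(record.samples.size) / record.fs
    t_out = np.arange(n_out) / target_fs
    if record.samples.size < 4:
        y = np.interp(t_out, t_in, record.samples)
    else:
        spline = CubicSpline(t_in, record.samples)
        y = spline(np.clip(t_out, t_in[0], t_in[-1]))
    return record.with_samples(y, fs=float(target_fs))


def segment(record: SignalRecord, cfg: PreprocessConfig) -> list[Segment]:
    """Cut into overlapping windows; trailing partial windows are dropped."""
    W = int(round(cfg.window_s * record.fs))
    S = int(round(W * (1.0 - cfg.overlap)))
    S = max(S, 1)
    L = record.samples.size
    if L < W:
        return []
    n = (L - W) // S + 1
    return [
        Segment(
            samples=record.samples[i * S : i * S + W].copy(),
            fs=record.fs,
            start_time_s=i * S / record.fs,
            subject_id=record.subject_id,
            record_id=record.record_id,
        )
        for i in range(n)
    ]


def estimate_snr(seg: Segment, cfg: PreprocessConfig) -> float:
    """In-band / out-of-band periodogram power ratio in dB.

    Power inside ``cardiac_band_hz`` (DC excluded) is treated as signal,
    everything else as noise.  Returns ``+inf`` when the out-of-band power
    is exactly zero.  The value is also stored on the segment.
    """
    lo, hi = cfg.cardiac_band_hz
    freqs, pxx = sps.periodogram(seg.samples, fs=seg.fs)
    nz = freqs > 0
    in_band = nz & (freqs >= lo) & (freqs <= hi)
    out_band = nz & ~in_band
    p_in = pxx[in_band].sum()
    p_out = pxx[out_band].sum()
    if p_out == 0:
        snr = np.inf
    elif p_in == 0:
        snr = -np.inf
    else:
        snr = 10.0 * np.log10(p_in / p_out)
    seg.snr_db = float(snr)
    return seg.snr_db


def quality_screen(segments: list[Segment], cfg: PreprocessConfig) -> list[Segment]:
    """Keep segments whose SNR meets the threshold, preserving order."""
    return [s for s in segments if s.snr_db is not None and s.snr_db >= cfg.snr_min_db]


_STAGES = ("bandpass_filter", "remove_baseline", "remove_motion_artifacts_pca",
           "normalize", "resample", "segment", "estimate_snr", "quality_screen")


def preprocess_record(record: SignalRecord, cfg: PreprocessConfig) -> list[Segment]:
    """Run the full preprocessing chain and return the surviving segments."""
    x = record
    try:
        stage = "bandpass_filter"
        x = bandpass_filter(x, cfg)
        stage = "remove_baseline"
        x = remove_baseline(x, cfg)
        stage = "remove_motion_artifacts_pca"
        x = remove_motion_artifacts_pca(x, cfg)
        stage = "normalize"
        x = normalize(x, cfg)
        stage = "resample"
        x = resample(x, cfg.target_fs)
        stage = "segment"
        segs = segment(x, cfg)
        stage = "estimate_snr"
        for s in segs:
            estimate_snr(s, cfg)
        stage = "quality_screen"
        return quality_screen(segs, cfg)
    except ValueError as exc:
        raise PipelineStageError(stage, exc) from exc
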