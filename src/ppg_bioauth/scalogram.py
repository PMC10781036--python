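"""Morlet continuous-wavelet-transform scalogram images.

The transform evaluates, on the sample grid with spacing dt = 1/fs,

    W(s, tau) = (1 / sqrt(s)) * sum_t x(t) * conj(psi((t - tau) / s)) * dt

with the (non-admissibility-corrected) Morlet mother wavelet

    psi(t) = pi**(-1/4) * exp(i * omega0 * t) * exp(-t**2 / 2)

and zero extension beyond the signal boundaries.  The fast path computes
the same Riemann sum with FFT convolutions; :func:`cwt_bruteforce_oracle`
evaluates the double sum literally and exists purely as an independent
cross-check.

Scalogram magnitudes |W| over a frequency-by-time grid are resized to
square images and min-max scaled to [0, 1] before entering the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .signals import Segment

__all__ = [
    "WaveletSpec", "ScalogramConfig", "Scalogram", "morlet_wavelet",
    "scale_for_frequency", "cwt", "cwt_bruteforce_oracle", "to_image",
    "segment_to_image", "build_image_matrix",
]

# wavelet envelope support, in units of the scaled Gaussian sigma; the
# envelope at 8 sigma is exp(-32) ~ 1e-14, far below the 1e-6 oracle band
_SUPPORT_SIGMAS = 8.0


@dataclass(frozen=True)
class WaveletSpec:
    """Mother-wavelet choice; only the Morlet family is supported."""

    family: str = "morlet"
    omega0: float = 6.0

    def __post_init__(self):
        if self.family != "morlet":
            raise ValueError(f"unsupported wavelet family '{self.family}'")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")


@dataclass(frozen=True)
class ScalogramConfig:
    n_freq_bins: int = 128
    freq_min_hz: float = 0.5
    freq_max_hz: float = 100.0
    desired_length: int | None = None  # zero-pad segments shorter than this
    image_side: int = 128

    def __post_init__(self):
        if not (0 < self.freq_min_hz < self.freq_max_hz):
            raise ValueError("need 0 < freq_min_hz < freq_max_hz")
        if self.n_freq_bins < 2 or self.image_side < 2:
            raise ValueError("n_freq_bins and image_side must be >= 2")


@dataclass
class Scalogram:
    magnitudes: np.ndarray        # (n_scales, n_times), >= 0
    freqs_hz: np.ndarray
    scales: np.ndarray
    times_s: np.ndarray
    segment_ref: object = None


def morlet_wavelet(t, spec: WaveletSpec = WaveletSpec()):
    """psi(t) = pi^(-1/4) exp(i omega0 t) exp(-t^2/2), vectorized over t."""
    t = np.asarray(t, dtype=np.float64)
    return np.pi ** (-0.25) * np.exp(1j * spec.omega0 * t) * np.exp(-0.5 * t**2)


def scale_for_frequency(f_hz, spec: WaveletSpec = WaveletSpec()):
    """Scale whose oscillation matches frequency f: s = omega0 / (2 pi f)."""
    f_hz = np.asarray(f_hz, dtype=np.float64)
    if np.any(f_hz <= 0):
        raise ValueError("frequencies must be positive")
    s = spec.omega0 / (2.0 * np.pi * f_hz)
    return float(s) if s.ndim == 0 else s


def _freq_grid(cfg: ScalogramConfig) -> np.ndarray:
    return np.linspace(cfg.freq_min_hz, cfg.freq_max_hz, cfg.n_freq_bins)


def _cwt_matrix(x: np.ndarray, fs: float, scales: np.ndarray,
                spec: WaveletSpec) -> np.ndarray:
    """|W(s, tau)| for a batch of equal-length signals x (n, N)."""
    x = np.atleast_2d(x)
    n_sig, N = x.shape
    dt = 1.0 / fs
    mags = np.empty((n_sig, scales.size, N))
    for i, s in enumerate(scales):
        half = min(N - 1, int(np.ceil(_SUPPORT_SIGMAS * s / dt)))
        m = np.arange(-half, half + 1)
        # h[j] = conj(psi(-(j*dt)/s)) * dt / sqrt(s)  => convolution computes
        # sum_t x[t] conj(psi((t - tau) dt / s)) dt / sqrt(s)
        h = np.conj(morlet_wavelet(-m * dt / s, spec)) * dt / np.sqrt(s)
        full = fftconvolve(x, h[None, :], mode="full", axes=1)
        mags[:, i, :] = np.abs(full[:, half : half + N])
    return mags


def cwt(seg: Segment, cfg: ScalogramConfig, spec: WaveletSpec = WaveletSpec()) -> Scalogram:
    """Morlet CWT magnitudes of one segment on the configured frequency grid."""
    if seg.samples.size == 0:
        raise ValueError("segment is empty")
    if cfg.freq_max_hz > seg.fs / 2 + 1e-12:
        raise ValueError(
            f"freq_max_hz={cfg.freq_max_hz} exceeds Nyquist {seg.fs / 2}"
        )
    freqs = _freq_grid(cfg)
    scales = scale_for_frequency(freqs, spec)
    mags = _cwt_matrix(seg.samples, seg.fs, scales, spec)[0]
    times = np.arange(seg.samples.size) / seg.fs
    return Scalogram(magnitudes=mags, freqs_hz=freqs, scales=scales,
                     times_s=times, segment_ref=seg)


def cwt_bruteforce_oracle(seg: Segment, scales: np.ndarray,
                          spec: WaveletSpec = WaveletSpec()) -> Scalogram:
    """Literal double-loop evaluation of the CWT Riemann sum (test oracle).

    Intended for short segments only (<= 512 samples); the fast path must
    agree with this elementwise.
    """
    x = seg.samples
    N = x.size
    if N > 512:
        raise ValueError("oracle is restricted to segments of <= 512 samples")
    dt = 1.0 / seg.fs
    t = np.arange(N) * dt
    scales = np.asarray(scales, dtype=np.float64)
    W = np.empty((scales.size, N), dtype=np.complex128)
    for i, s in enumerate(scales):
        for j in range(N):
            tau = t[j]
            W[i, j] = (1.0 / np.sqrt(s)) * np.sum(
                x * np.conj(morlet_wavelet((t - tau) / s, spec)) * dt
            )
    freqs = spec.omega0 / (2.0 * np.pi * scales)
    return Scalogram(magnitudes=np.abs(W), freqs_hz=freqs, scales=scales,
                     times_s=t, segment_ref=seg)


def _bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize on an align-corners grid; identity when sizes match."""
    h, w = img.shape
    if (h, w) == (out_h, out_w):
        return img.copy()
    ys = np.linspace(0, h - 1, out_h)
    xs = np.linspace(0, w - 1, out_w)
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 2) if h > 1 else np.zeros(out_h, int)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 2) if w > 1 else np.zeros(out_w, int)
    wy = (ys - y0) if h > 1 else np.zeros(out_h)
    wx = (xs - x0) if w > 1 else np.zeros(out_w)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    top = img[np.ix_(y0, x0)] * (1 - wx) + img[np.ix_(y0, x1)] * wx
    bot = img[np.ix_(y1, x0)] * (1 - wx) + img[np.ix_(y1, x1)] * wx
    return top * (1 - wy[:, None]) + bot * wy[:, None]


def to_image(scal: Scalogram, cfg: ScalogramConfig) -> np.ndarray:
    """Resize |W| to (image_side, image_side) and min-max scale to [0, 1].

    A constant-magnitude scalogram maps to an all-zero image.
    """
    img = _bilinear_resize(scal.magnitudes, cfg.image_side, cfg.image_side)
    lo, hi = img.min(), img.max()
    if hi > lo:
        return (img - lo) / (hi - lo)
    return np.zeros_like(img)


def segment_to_image(seg: Segment, cfg: ScalogramConfig,
                     spec: WaveletSpec = WaveletSpec()) -> np.ndarray:
    """Zero-pad (if shorter than desired_length), transform, and image one segment."""
    samples = seg.samples
    if cfg.desired_length is not None and samples.size < cfg.desired_length:
        samples = np.pad(samples, (0, cfg.desired_length - samples.size))
        seg = Segment(samples=samples, fs=seg.fs, start_time_s=seg.start_time_s,
                      subject_id=seg.subject_id, record_id=seg.record_id,
                      snr_db=seg.snr_db)
    return to_image(cwt(seg, cfg, spec), cfg)


def build_image_matrix(segments: list[Segment], cfg: ScalogramConfig,
                       spec: WaveletSpec = WaveletSpec()):
    """One image per segment (input order) plus a stacked flattened matrix.

    Returns ``(images, matrix)`` where ``images`` is a list of
    (image_side, image_side) arrays and ``matrix`` has one flattened image
    per row.
    """
    if not segments:
        return [], np.zeros((0, cfg.image_side * cfg.image_side))
    lengths = {s.samples.size for s in segments}
    fss = {s.fs for s in segments}
    freqs = _freq_grid(cfg)
    spec_scales = scale_for_frequency(freqs, spec)
    images = []
    if len(lengths) == 1 and len(fss) == 1:
        # batched fast path: shared kernels across equal-length segments
        fs = segments[0].fs
        if cfg.freq_max_hz > fs / 2 + 1e-12:
            raise ValueError(f"freq_max_hz={cfg.freq_max_hz} exceeds Nyquist {fs / 2}")
        X = np.stack([s.samples for s in segments])
        if cfg.desired_length is not None and X.shape[1] < cfg.desired_length:
            X = np.pad(X, ((0, 0), (0, cfg.desired_length - X.shape[1])))
        mags = _cwt_matrix(X, fs, spec_scales, spec)
        for m in mags:
            scal = Scalogram(m, freqs, spec_scales, np.arange(m.shape[1]) / fs)
            images.append(to_image(scal, cfg))
    else:
        images = [segment_to_image(s, cfg, spec) for s in segments]
    matrix = np.stack([im.ravel() for im in images])
    return images, matrix
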