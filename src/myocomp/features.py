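"""Surface-EMG feature extraction.

The control chain converts a multi-channel EMG stream into a sequence of
band-power feature vectors: a zero-lag digital high-pass removes motion
artefact and mains-adjacent low-frequency content, each channel is cut into
Hann-windowed frames, the frame spectrum is computed by FFT, and the
magnitude-squared spectrum is averaged inside equal-width frequency bands
(8 bands over 0-400 Hz by default).  With 3 electrode channels the default
configuration yields 24 features per frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass
class EmgStream:
    """Multi-channel raw EMG at a fixed sampling rate.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz.
    samples : ndarray, shape (n_channels, n_samples)
        Signal in amplifier output units.
    labels : ndarray of str, optional
        Per-sample motion label track aligned with ``samples``.
    """

    sample_rate: float
    samples: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a (n_channels, n_samples) array")
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive and finite")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.samples.shape[1]:
                raise ValueError("label track length must match sample count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class FeatureConfig:
    """Framing and band-partition parameters.

    frame_size is the analysis window in samples (power of two), hop the
    frame advance, and the band partition divides [0, f_max) into n_bands
    equal-width bands.  ``log_compress`` applies log(1+x) to the band powers.
    """

    frame_size: int = 256
    hop: int = 128
    n_bands: int = 8
    f_max: float = 400.0
    highpass_cutoff: float = 50.0
    log_compress: bool = False

    def __post_init__(self) -> None:
        if self.frame_size < 2 or (self.frame_size & (self.frame_size - 1)) != 0:
            raise ValueError("frame_size must be a power of two >= 2")
        if not 0 < self.hop <= self.frame_size:
            raise ValueError("hop must satisfy 0 < hop <= frame_size")
        if self.n_bands < 1 or self.f_max <= 0:
            raise ValueError("n_bands >= 1 and f_max > 0 required")
        if self.highpass_cutoff < 0:
            raise ValueError("highpass_cutoff must be >= 0")

    @property
    def band_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.f_max, self.n_bands + 1)


@dataclass
class FeatureFrame:
    """One timestamped band-power vector (channels x bands, bands fastest)."""

    frame_time: float
    values: np.ndarray
    band_edges: np.ndarray


def highpass_filter(stream: EmgStream, cutoff: float = 50.0, order: int = 4) -> EmgStream:
    """Zero-lag Butterworth high-pass applied forward-backward per channel.

    Output length equals input length; DC and sub-cutoff drift are rejected
    without phase distortion, which suits offline feature extraction.
    """
    nyquist = stream.sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    sos = signal.butter(order, cutoff, btype="highpass", fs=stream.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, stream.samples, axis=1)
    return EmgStream(stream.sample_rate, filtered, stream.labels)


def spectral_frame(frame: np.ndarray, sample_rate: float, window: np.ndarray | None = None) -> np.ndarray:
    """Hann-windowed magnitude-squared spectrum of one frame.

    Returns |X_k|^2 for k = 0..frame_size/2 (non-negative frequencies);
    the bin width is sample_rate / frame_size.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 1:
        raise ValueError("frame must be one-dimensional")
    n = frame.shape[0]
    if window is None:
        window = signal.windows.hann(n, sym=False)
    elif window.shape[0] != n:
        raise ValueError("window length must match frame length")
    spectrum = np.fft.rfft(frame * window)
    return np.abs(spectrum) ** 2


def band_powers(
    spectrum: np.ndarray,
    sample_rate: float,
    n_bands: int = 8,
    f_max: float = 400.0,
    statistic: str = "mean",
) -> np.ndarray:
    """Average magnitude-squared power in equal-width bands over [0, f_max).

    Band j covers [j*f_max/n_bands, (j+1)*f_max/n_bands); a bin belongs to
    the band containing its centre frequency, and bins at or above f_max are
    discarded.  ``statistic`` selects the per-band reduction ("mean" keeps
    values comparable across bands with unequal bin counts; "sum" preserves
    total in-band power).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if f_max > sample_rate / 2.0:
        raise ValueError("f_max must not exceed the Nyquist frequency")
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    frame_size = 2 * (spectrum.shape[0] - 1)
    freqs = np.arange(spectrum.shape[0]) * sample_rate / frame_size
    width = f_max / n_bands
    out = np.empty(n_bands)
    for j in range(n_bands):
        mask = (freqs >= j * width) & (freqs < (j + 1) * width)
        if not mask.any():
            raise ValueError(
                f"band {j} ([{j * width}, {(j + 1) * width}) Hz) contains no FFT bins"
            )
        out[j] = spectrum[mask].mean() if statistic == "mean" else spectrum[mask].sum()
    return out


def extract_feature_stream(stream: EmgStream, config: FeatureConfig = FeatureConfig()) -> list[FeatureFrame]:
    """Run the full chain: high-pass, frame, window+FFT, band powers.

    Per frame the per-channel band-power vectors are concatenated in channel
    order with bands varying fastest, so 3 channels x 8 bands gives a
    24-dimensional feature.  Frame times are frame centres.  The frame count
    is floor((n_samples - frame_size)/hop) + 1.
    """
    if stream.n_samples < config.frame_size:
        raise ValueError("stream shorter than one analysis frame")
    if config.highpass_cutoff > 0:
        stream = highpass_filter(stream, config.highpass_cutoff)
    window = signal.windows.hann(config.frame_size, sym=False)
    n_frames = (stream.n_samples - config.frame_size) // config.hop + 1
    edges = config.band_edges
    frames: list[FeatureFrame] = []
    for i in range(n_frames):
        start = i * config.hop
        chunk = stream.samples[:, start : start + config.frame_size]
        vec = np.concatenate(
            [
                band_powers(
                    spectral_frame(chunk[c], stream.sample_rate, window),
                    stream.sample_rate,
                    config.n_bands,
                    config.f_max,
                )
                for c in range(stream.n_channels)
            ]
        )
        if config.log_compress:
            vec = np.log1p(vec)
        t = (start + config.frame_size / 2.0) / stream.sample_rate
        frames.append(FeatureFrame(frame_time=t, values=vec, band_edges=edges))
    return frames


def feature_matrix(frames: list[FeatureFrame]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a feature-frame list into (times, X) arrays for model fitting."""
    if not frames:
        raise ValueError("empty feature-frame list")
    times = np.array([f.frame_time for f in frames])
    X = np.vstack([f.values for f in frames])
    return times, X
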