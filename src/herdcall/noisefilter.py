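"""Stationary-noise removal by STFT spectral gating with mask smoothing.

The gate follows the classic spectral-gating recipe: estimate, per frequency
bin, the mean and standard deviation of the noise magnitude in dB over time;
set a per-bin threshold ``mean + n_std * std``; keep only time-frequency
cells whose magnitude exceeds the threshold of their bin; smooth the
resulting binary mask with a small normalized 2 (frequency) x 4 (time)
kernel to suppress musical-noise artifacts; multiply and invert.

The analysis frame convention is non-centered: column ``l`` of the STFT is
the windowed DFT of samples ``[l*hop, l*hop + win_length)``.  With the
default Hann window, 2048-sample window and 256-sample hop the geometry
satisfies constant overlap-add, so the inverse transform reconstructs
interior samples essentially exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d, get_window

from .audio_io import AudioSegment
from .config import (
    DEFAULT_HOP,
    DEFAULT_N_FFT,
    DEFAULT_N_STD,
    DEFAULT_SMOOTHING_KERNEL_SHAPE,
    DEFAULT_WIN_LENGTH,
)
from .exceptions import ConfigError, DataError, ShapeError

__all__ = [
    "STFTConfig",
    "STFTMatrix",
    "NoiseProfile",
    "TimeFrequencyMask",
    "stft",
    "istft",
    "estimate_noise_profile",
    "compute_mask",
    "smooth_mask",
    "denoise",
]

_DB_FLOOR = 1e-12  # added to |X| before taking logs


@dataclass(frozen=True)
class STFTConfig:
    """STFT geometry: FFT size, window length, hop, and taper."""

    n_fft: int = DEFAULT_N_FFT
    win_length: int = DEFAULT_WIN_LENGTH
    hop: int = DEFAULT_HOP
    window_fn: str = "hann"

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.win_length <= self.n_fft):
            raise ConfigError("require 0 < hop <= win_length <= n_fft")

    @property
    def n_bins(self) -> int:
        return self.n_fft // 2 + 1

    def window(self) -> np.ndarray:
        # periodic ('fftbins') taper: required for constant overlap-add
        return get_window(self.window_fn, self.win_length, fftbins=True)


@dataclass
class STFTMatrix:
    """One-sided complex time-frequency matrix (rows = bins, cols = frames)."""

    values: np.ndarray
    config: STFTConfig
    sample_rate: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ShapeError("STFT values must be a 2-D matrix")
        if self.values.shape[0] != self.config.n_bins:
            raise ShapeError(
                f"expected {self.config.n_bins} frequency bins, got {self.values.shape[0]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("STFT matrix contains non-finite entries")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def magnitude_db(self) -> np.ndarray:
        return 20.0 * np.log10(np.abs(self.values) + _DB_FLOOR)

    def frequencies(self) -> np.ndarray:
        return np.fft.rfftfreq(self.config.n_fft, d=1.0 / self.sample_rate)


@dataclass
class NoiseProfile:
    """Per-bin noise statistics in dB and the derived gate threshold."""

    mean_power_db: np.ndarray
    std_power_db: np.ndarray
    threshold_db: np.ndarray
    n_std: float = DEFAULT_N_STD

    def __post_init__(self) -> None:
        if not (
            len(self.mean_power_db) == len(self.std_power_db) == len(self.threshold_db)
        ):
            raise ShapeError("noise profile vectors must have equal length")


def _uniform_kernel(shape: tuple[int, int]) -> np.ndarray:
    k = np.ones(shape, dtype=np.float64)
    return k / k.sum()


@dataclass
class TimeFrequencyMask:
    """Soft gate mask in [0, 1], same shape as the STFT it multiplies."""

    values: np.ndarray
    smoothing_kernel: np.ndarray = field(
        default_factory=lambda: _uniform_kernel(DEFAULT_SMOOTHING_KERNEL_SHAPE)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.smoothing_kernel = np.asarray(self.smoothing_kernel, dtype=np.float64)
        if np.any(self.values < -1e-12) or np.any(self.values > 1.0 + 1e-12):
            raise DataError("mask entries must lie in [0, 1]")
        if np.any(self.smoothing_kernel < 0):
            raise DataError("kernel weights must be non-negative")
        if abs(self.smoothing_kernel.sum() - 1.0) > 1e-9:
            raise DataError("kernel weights must sum to 1")
        self.values = np.clip(self.values, 0.0, 1.0)


def stft(segment: AudioSegment, config: STFTConfig | None = None) -> STFTMatrix:
    """Short-time Fourier transform with non-centered frames.

    X(l, k) = sum_n w(n) x(n + l*H) e^{-2 pi i k n / N}, one-sided in k.
    """
    config = config or STFTConfig()
    x = segment.samples
    if x.size < config.win_length:
        raise DataError(
            f"clip of {x.size} samples shorter than one window ({config.win_length})"
        )
    n_frames = 1 + (x.size - config.win_length) // config.hop
    w = config.window()
    idx = np.arange(config.win_length)[None, :] + config.hop * np.arange(n_frames)[:, None]
    frames = x[idx] * w[None, :]
    spec = np.fft.rfft(frames, n=config.n_fft, axis=1).T  # (bins, frames)
    return STFTMatrix(values=spec, config=config, sample_rate=segment.sample_rate)


def istft(matrix: STFTMatrix, length: int | None = None) -> AudioSegment:
    """Inverse STFT by weighted overlap-add.

    Frames are inverse-transformed, re-windowed, and summed; the sum of
    squared windows normalizes the overlap.  Requires the window/hop pair to
    satisfy constant overlap-add (NOLA), which the default Hann/2048/256
    geometry does.
    """
    cfg = matrix.config
    w = cfg.window()
    n_frames = matrix.n_frames
    frames = np.fft.irfft(matrix.values.T, n=cfg.n_fft, axis=1)[:, : cfg.win_length]
    out_len = cfg.win_length + cfg.hop * (n_frames - 1)
    y = np.zeros(out_len)
    wsum = np.zeros(out_len)
    w2 = w * w
    for l in range(n_frames):
        s = l * cfg.hop
        y[s : s + cfg.win_length] += frames[l] * w
        wsum[s : s + cfg.win_length] += w2
    if wsum.max() <= 0:
        raise ConfigError("window/hop pair does not satisfy overlap-add (all-zero weight)")
    # Only samples with at least half the interior window coverage are
    # reconstructed; the under-covered edge ramps are zeroed.  Dividing them
    # by their near-zero weights would be exact for an untouched spectrum but
    # amplifies edge leakage arbitrarily once a mask has been applied.
    covered = wsum >= 0.5 * wsum.max()
    y[covered] /= wsum[covered]
    y[~covered] = 0.0
    if length is not None:
        if length <= out_len:
            y = y[:length]
        else:
            y = np.pad(y, (0, length - out_len))
    return AudioSegment(samples=y, sample_rate=matrix.sample_rate)


def estimate_noise_profile(noise_stft: STFTMatrix, n_std: float = DEFAULT_N_STD) -> NoiseProfile:
    """Per-bin mean/std of the noise magnitude (dB) and the gate threshold.

    Statistics are taken over time on dB magnitudes (population std);
    threshold = mean + n_std * std per frequency bin.
    """
    if noise_stft.n_frames < 2:
        raise DataError("need at least 2 time columns to estimate noise statistics")
    mag_db = noise_stft.magnitude_db()
    mean = mag_db.mean(axis=1)
    std = mag_db.std(axis=1)  # population (ddof=0)
    return NoiseProfile(
        mean_power_db=mean,
        std_power_db=std,
        threshold_db=mean + n_std * std,
        n_std=n_std,
    )


def compute_mask(signal_stft: STFTMatrix, profile: NoiseProfile) -> TimeFrequencyMask:
    """Raw binary gate: 1 where the bin magnitude (dB) exceeds its threshold."""
    if len(profile.threshold_db) != signal_stft.n_bins:
        raise ShapeError(
            f"profile has {len(profile.threshold_db)} bins, STFT has {signal_stft.n_bins}"
        )
    mag_db = signal_stft.magnitude_db()
    raw = (mag_db > np.asarray(profile.threshold_db)[:, None]).astype(np.float64)
    return TimeFrequencyMask(values=raw)


def smooth_mask(mask: TimeFrequencyMask) -> TimeFrequencyMask:
    """Smooth the gate with the normalized kernel (zero-padded 2-D convolution).

    The kernel averages over 2 frequency x 4 time cells by default, turning
    the hard gate into a graded attenuation and removing isolated one-cell
    openings that would ring as musical noise.
    """
    k = mask.smoothing_kernel
    if k.shape[0] > mask.values.shape[0] or k.shape[1] > mask.values.shape[1]:
        raise ShapeError("smoothing kernel larger than the mask")
    smoothed = convolve2d(mask.values, k, mode="same", boundary="fill", fillvalue=0.0)
    return TimeFrequencyMask(values=np.clip(smoothed, 0.0, 1.0), smoothing_kernel=k)


def _quietest_window(segment: AudioSegment, window_seconds: float, min_samples: int) -> AudioSegment:
    """Lowest-energy stretch of the clip, used as the noise reference."""
    n = max(int(round(window_seconds * segment.sample_rate)), min_samples)
    x = segment.samples
    if x.size <= n:
        return segment
    # cumulative-sum sliding energy, stepped at 10 ms granularity
    step = max(1, segment.sample_rate // 100)
    csum = np.concatenate([[0.0], np.cumsum(x * x)])
    starts = np.arange(0, x.size - n + 1, step)
    energies = csum[starts + n] - csum[starts]
    s = int(starts[np.argmin(energies)])
    return segment.with_samples(x[s : s + n])


def denoise(
    segment: AudioSegment,
    noise_reference: AudioSegment | None = None,
    config: STFTConfig | None = None,
    n_std: float = DEFAULT_N_STD,
    kernel_shape: tuple[int, int] = DEFAULT_SMOOTHING_KERNEL_SHAPE,
) -> AudioSegment:
    """End-to-end spectral gate: STFT -> profile -> mask -> smooth -> ISTFT.

    When no dedicated noise recording is supplied, the quietest 0.5 s of the
    clip itself serves as the noise reference.  Output length equals input
    length; metadata is preserved.
    """
    config = config or STFTConfig()
    spec = stft(segment, config)
    ref = noise_reference if noise_reference is not None else _quietest_window(
        segment, 0.5, 2 * config.win_length
    )
    profile = estimate_noise_profile(stft(ref, config), n_std=n_std)
    raw = compute_mask(spec, profile)
    raw.smoothing_kernel = _uniform_kernel(kernel_shape)
    soft = smooth_mask(raw)
    gated = STFTMatrix(
        values=spec.values * soft.values, config=config, sample_rate=spec.sample_rate
    )
    out = istft(gated, length=segment.samples.size)
    return AudioSegment(
        samples=out.samples,
        sample_rate=segment.sample_rate,
        start_time=segment.start_time,
        sensor_id=segment.sensor_id,
        zone_id=segment.zone_id,
        calibration_offset_db=segment.calibration_offset_db,
    )
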