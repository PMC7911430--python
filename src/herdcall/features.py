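"""Mel-filter-bank / MFCC feature extraction to a fixed-size matrix.

A clip is framed and Fourier-transformed (same non-centered convention as
the noise filter), the per-frame power spectrum is pooled through a bank of
M triangular filters spaced evenly on the Mel scale, log-compressed, and
cosine-transformed:

    B(m, k):  triangular weight of filter m at frequency bin k
    E(m)   =  sum_k B(m, k) P(k)            (filter-bank energy)
    Elog(m) = log(E(m) + eps)
    MFCC(n) = sum_m Elog(m) cos(n (m - 1/2) pi / M),  n = 1..M

All M coefficients are retained and the time axis is padded with zeros (or
truncated) on the right to a fixed frame count so every clip maps to an
identically shaped matrix for the classifiers.  The Mel mapping is
m = 2595 * log10(1 + f/700).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import AudioSegment
from .config import DEFAULT_LOG_FLOOR, DEFAULT_N_MELS, DEFAULT_T_FIXED
from .exceptions import ConfigError, DataError, ShapeError
from .noisefilter import STFTConfig, stft

__all__ = [
    "MelFilterBank",
    "MFCCMatrix",
    "mel_scale",
    "inv_mel_scale",
    "build_filter_bank",
    "filter_bank_energies",
    "dct_coefficients",
    "mfcc_pipeline",
]


def mel_scale(hz):
    """Hz -> Mel, m = 2595 log10(1 + f/700). Strictly increasing, mel(0)=0."""
    hz = np.asarray(hz, dtype=np.float64)
    if np.any(hz < 0):
        raise DataError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + hz / 700.0)
    return float(out) if out.ndim == 0 else out


def inv_mel_scale(mel):
    """Mel -> Hz, inverse of :func:`mel_scale`."""
    mel = np.asarray(mel, dtype=np.float64)
    if np.any(mel < 0):
        raise DataError("mel value must be non-negative")
    out = 700.0 * (10.0 ** (mel / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class MelFilterBank:
    """Bank of M triangular filters over one-sided FFT bins.

    ``weights[m, k]`` rises linearly from boundary m to a peak of 1 at
    boundary m+1 and falls to zero at boundary m+2 (boundaries are the M+2
    Mel-equally-spaced edge frequencies in bin units).
    """

    weights: np.ndarray
    boundaries: np.ndarray  # M+2 boundary positions, fractional FFT bins
    M: int
    sample_rate: int
    n_fft: int


@dataclass
class MFCCMatrix:
    """Fixed-width cepstral feature matrix (M coefficients x T_fixed frames)."""

    coefficients: np.ndarray
    t_fixed: int
    n_valid_frames: int
    log_energies: np.ndarray | None = None
    power_spectrum_source: str = "stft"

    def __post_init__(self) -> None:
        if self.coefficients.shape[1] != self.t_fixed:
            raise ShapeError("coefficient matrix width must equal t_fixed")


def build_filter_bank(
    M: int = DEFAULT_N_MELS,
    n_fft: int = 2048,
    sample_rate: int = 16_000,
    f_min: float = 0.0,
    f_max: float | None = None,
) -> MelFilterBank:
    """Triangular filters with apexes equally spaced on the Mel scale."""
    if M < 1:
        raise ConfigError("M must be >= 1")
    nyquist = sample_rate / 2.0
    if f_max is None:
        f_max = nyquist
    if not (0 <= f_min < f_max <= nyquist):
        raise ConfigError("require 0 <= f_min < f_max <= Nyquist")
    n_bins = n_fft // 2 + 1
    mel_pts = np.linspace(mel_scale(f_min), mel_scale(f_max), M + 2)
    hz_pts = inv_mel_scale(mel_pts)
    # boundary positions in (fractional) bin units
    bounds = hz_pts * n_fft / sample_rate
    if np.any(np.diff(bounds) < 1e-9):
        raise ConfigError(
            f"M={M} filters collide on {n_bins} bins; reduce M or raise n_fft"
        )
    k = np.arange(n_bins, dtype=np.float64)
    w = np.zeros((M, n_bins))
    for m in range(M):
        left, center, right = bounds[m], bounds[m + 1], bounds[m + 2]
        rise = (k - left) / (center - left)
        fall = (right - k) / (right - center)
        w[m] = np.clip(np.minimum(rise, fall), 0.0, 1.0)
    if np.any(w.max(axis=1) <= 0.0):
        raise ConfigError(
            f"M={M} filters leave some with no supporting bin on {n_bins} bins; "
            "reduce M or raise n_fft"
        )
    return MelFilterBank(weights=w, boundaries=bounds, M=M, sample_rate=sample_rate, n_fft=n_fft)


def filter_bank_energies(
    power_frames: np.ndarray,
    bank: MelFilterBank,
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool power spectra through the bank: E = B @ P, Elog = log(E + eps).

    ``power_frames`` is (n_bins, n_frames) and must be non-negative.
    Returns (E, Elog), both (M, n_frames).
    """
    P = np.asarray(power_frames, dtype=np.float64)
    if P.ndim == 1:
        P = P[:, None]
    if np.any(P < 0):
        raise DataError("power spectrum must be non-negative")
    if P.shape[0] != bank.weights.shape[1]:
        raise ShapeError(
            f"power spectrum has {P.shape[0]} bins, bank expects {bank.weights.shape[1]}"
        )
    E = bank.weights @ P
    return E, np.log(E + log_floor)


def dct_coefficients(elog: np.ndarray) -> np.ndarray:
    """Unnormalized cosine transform of the log filter-bank energies.

    MFCC(n) = sum_{m=1..M} Elog(m) cos(n (m - 1/2) pi / M) for n = 1..M
    (a DCT-II without the DC row, so a constant Elog maps to all zeros).
    """
    elog = np.asarray(elog, dtype=np.float64)
    if elog.ndim == 1:
        elog = elog[:, None]
    M = elog.shape[0]
    n = np.arange(1, M + 1)[:, None]
    m = np.arange(1, M + 1)[None, :]
    C = np.cos(n * (m - 0.5) * np.pi / M)  # (n, m)
    return C @ elog


def _pad_or_truncate(mat: np.ndarray, t_fixed: int) -> np.ndarray:
    if mat.shape[1] >= t_fixed:
        return mat[:, :t_fixed]
    return np.pad(mat, ((0, 0), (0, t_fixed - mat.shape[1])))


def mfcc_pipeline(
    segment: AudioSegment,
    M: int = DEFAULT_N_MELS,
    t_fixed: int = DEFAULT_T_FIXED,
    stft_config: STFTConfig | None = None,
    representation: str = "mfcc",
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> MFCCMatrix:
    """Clip -> fixed-size feature matrix.

    STFT power -> Mel-bank energies -> log -> DCT, then right-pad with zeros
    (or right-truncate) to exactly ``t_fixed`` frames.  With
    ``representation='logmel'`` the DCT step is skipped and the log energies
    themselves are returned.
    """
    if representation not in ("mfcc", "logmel"):
        raise ConfigError("representation must be 'mfcc' or 'logmel'")
    stft_config = stft_config or STFTConfig()
    spec = stft(segment, stft_config)
    P = np.abs(spec.values) ** 2
    bank = build_filter_bank(M=M, n_fft=stft_config.n_fft, sample_rate=segment.sample_rate)
    _, elog = filter_bank_energies(P, bank, log_floor=log_floor)
    feats = dct_coefficients(elog) if representation == "mfcc" else elog
    n_valid = min(feats.shape[1], t_fixed)
    return MFCCMatrix(
        coefficients=_pad_or_truncate(feats, t_fixed),
        t_fixed=t_fixed,
        n_valid_frames=n_valid,
        log_energies=_pad_or_truncate(elog, t_fixed),
        power_spectrum_source="stft",
    )
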