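"""Synthetic cattle-call and farm-noise generator.

Labeled audio with the structure the pipeline assumes, so every stage is
testable without field recordings.  Four call classes with distinct
acoustic signatures are embedded 2-3 s into 5 s clips:

* class 0 (estrus-like):   long call with a rising fundamental sweep
* class 1 (food-anticipating-like): train of short repeated pulses
* class 2 (cough-like):    short broadband burst with noisy excitation
* class 3 (normal-like):   flat-fundamental moderate call

Noise kinds mirror a barn: broadband microphone white noise, continuous
low-frequency hum concentrated below ~400 Hz, transient metallic clangs,
and speech-like chirp sequences.  The default fundamentals (80-300 Hz, up
to 12 harmonics) are plausibility conventions of this generator, not
measurements of real cattle; a ``hard`` mode narrows inter-class contrasts
for stress testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioSegment, write_wav
from .config import DEFAULT_SAMPLE_RATE
from .exceptions import ConfigError, DataError, SilentSegmentError

__all__ = [
    "CallSpec",
    "NoiseSpec",
    "generate_call",
    "add_noise",
    "generate_nonvocal",
    "generate_dataset",
    "make_dataset",
    "TABLE2_CLASS_COUNTS",
]

#: Per-class sample counts of the behavioral corpus the generator can mirror.
TABLE2_CLASS_COUNTS = (207, 178, 56, 456)

_CLASS_F0_RANGES = {0: (120.0, 220.0), 1: (150.0, 280.0), 2: (80.0, 160.0), 3: (90.0, 180.0)}


@dataclass
class CallSpec:
    """Recipe for one synthetic cattle call."""

    class_index: int
    f0_range: tuple[float, float] | None = None
    n_harmonics: int = 10
    duration_range: tuple[float, float] | None = None
    clip_seconds: float = 5.0
    sample_rate: int = DEFAULT_SAMPLE_RATE
    amplitude: float = 0.7
    hard: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_index not in (0, 1, 2, 3):
            raise ConfigError("class_index must be 0..3")
        if self.f0_range is None:
            self.f0_range = _CLASS_F0_RANGES[self.class_index]
        lo, hi = self.f0_range
        if not (50.0 < lo <= hi < 1000.0):
            raise ConfigError("f0_range must lie within (50, 1000) Hz")


@dataclass
class NoiseSpec:
    """Recipe for additive noise at a target signal-to-noise ratio."""

    kind: str = "white"
    snr_db: float = 10.0
    band_limit: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "low_band_hum", "transient_clang", "speech_like"):
            raise ConfigError(f"unknown noise kind {self.kind!r}")
        if not math.isfinite(self.snr_db):
            raise ConfigError("snr_db must be finite (omit noise for a clean clip)")


def _envelope(n: int, kind: str) -> np.ndarray:
    """Rise-fall amplitude envelope over n samples."""
    t = np.linspace(0.0, 1.0, n)
    if kind == "rise_fall":
        return np.sin(np.pi * t) ** 0.8
    if kind == "sharp_attack":
        return np.exp(-4.0 * t) * np.minimum(t / 0.02, 1.0)
    raise ConfigError(f"unknown envelope {kind!r}")


def _harmonic_stack(f0_curve: np.ndarray, n_harmonics: int, sample_rate: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Sum of harmonics of a (possibly time-varying) fundamental."""
    phase = 2.0 * np.pi * np.cumsum(f0_curve) / sample_rate
    out = np.zeros_like(f0_curve)
    nyq = sample_rate / 2.0
    for h in range(1, n_harmonics + 1):
        if np.max(f0_curve) * h >= 0.95 * nyq:
            break
        out += (1.0 / h) * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    return out


def generate_call(spec: CallSpec) -> tuple[AudioSegment, int]:
    """One labeled clip with a class-distinct call embedded 2-3 s in.

    Deterministic for a fixed spec (same seed -> bit-identical audio).
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    n_clip = int(round(spec.clip_seconds * sr))
    clip = np.zeros(n_clip)
    f0 = rng.uniform(*spec.f0_range)
    contrast = 0.35 if spec.hard else 1.0

    if spec.class_index == 0:  # long rising sweep
        dur = rng.uniform(*(spec.duration_range or (0.9, 1.5)))
        n = int(dur * sr)
        sweep = f0 * (1.0 + 0.5 * contrast * np.linspace(0.0, 1.0, n))
        call = _harmonic_stack(sweep, spec.n_harmonics, sr, rng) * _envelope(n, "rise_fall")
    elif spec.class_index == 1:  # repeated short pulses
        n_pulses = rng.integers(4, 7)
        pulse_dur = rng.uniform(0.12, 0.18)
        gap = rng.uniform(0.08, 0.14)
        n_p = int(pulse_dur * sr)
        pieces = []
        for _ in range(n_pulses):
            f0_p = np.full(n_p, f0 * rng.uniform(0.95, 1.05))
            pieces.append(_harmonic_stack(f0_p, spec.n_harmonics, sr, rng)
                          * _envelope(n_p, "rise_fall"))
            pieces.append(np.zeros(int(gap * sr)))
        call = np.concatenate(pieces[:-1])
        n = call.size
    elif spec.class_index == 2:  # broadband noisy burst
        dur = rng.uniform(*(spec.duration_range or (0.2, 0.4)))
        n = int(dur * sr)
        noise = rng.standard_normal(n)
        lo = 1500.0 * (1.0 if not spec.hard else 0.4)
        hi = min(6000.0, 0.45 * sr)
        sos = butter(4, [lo, hi], btype="bandpass", fs=sr, output="sos")
        burst = sosfiltfilt(sos, noise)
        f0_c = np.full(n, f0)
        tonal = 0.25 * _harmonic_stack(f0_c, 4, sr, rng)
        call = (burst / (np.std(burst) + 1e-12) + tonal) * _envelope(n, "sharp_attack")
    else:  # flat-fundamental moderate call
        dur = rng.uniform(*(spec.duration_range or (0.5, 1.0)))
        n = int(dur * sr)
        f0_c = np.full(n, f0) * (1.0 + 0.01 * np.sin(2 * np.pi * 5.0 * np.arange(n) / sr))
        call = _harmonic_stack(f0_c, spec.n_harmonics, sr, rng) * _envelope(n, "rise_fall")

    if n > n_clip:
        raise DataError("call duration exceeds clip length")
    onset = int(rng.uniform(2.0, 3.0) * sr)
    onset = min(onset, n_clip - n)
    call = spec.amplitude * call / (np.max(np.abs(call)) + 1e-12)
    clip[onset : onset + n] += call
    seg = AudioSegment(samples=clip, sample_rate=sr, start_time=0.0)
    return seg, spec.class_index


def generate_nonvocal(kind: str = "transient_clang", sample_rate: int = DEFAULT_SAMPLE_RATE,
                      clip_seconds: float = 5.0, amplitude: float = 0.7,
                      seed: int = 0) -> AudioSegment:
    """A clip containing only a non-cattle transient (clang or speech-like)."""
    rng = np.random.default_rng(seed)
    n_clip = int(round(clip_seconds * sample_rate))
    base = np.zeros(n_clip)
    noise = _make_noise(kind, n_clip, sample_rate, rng, band_limit=400.0)
    peak = np.max(np.abs(noise)) + 1e-12
    base += amplitude * noise / peak
    return AudioSegment(samples=base, sample_rate=sample_rate)


def _make_noise(kind: str, n: int, sr: int, rng: np.random.Generator,
                band_limit: float) -> np.ndarray:
    if kind == "white":
        return rng.standard_normal(n)
    if kind == "low_band_hum":
        if band_limit >= sr / 2:
            raise ConfigError("band_limit must be below Nyquist")
        sos = butter(8, 0.75 * band_limit, btype="lowpass", fs=sr, output="sos")
        return sosfiltfilt(sos, rng.standard_normal(n))
    if kind == "transient_clang":
        out = np.zeros(n)
        for _ in range(int(rng.integers(1, 4))):
            start = int(rng.uniform(0.1, 0.8) * n)
            dur = int(rng.uniform(0.05, 0.25) * sr)
            dur = min(dur, n - start)
            t = np.arange(dur) / sr
            clang = np.zeros(dur)
            for _p in range(5):  # inharmonic metallic partials
                fp = rng.uniform(800.0, min(7000.0, 0.45 * sr))
                clang += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * fp * t)
            out[start : start + dur] += clang * np.exp(-12.0 * t)
        return out
    if kind == "speech_like":
        out = np.zeros(n)
        pos = int(rng.uniform(0.05, 0.2) * n)
        while pos < n - sr // 10:
            dur = int(rng.uniform(0.06, 0.15) * sr)
            dur = min(dur, n - pos)
            t = np.arange(dur) / sr
            f = rng.uniform(300.0, min(3000.0, 0.4 * sr))
            out[pos : pos + dur] += np.sin(2 * np.pi * f * t) * np.hanning(dur)
            pos += dur + int(rng.uniform(0.02, 0.3) * sr)
        return out
    raise ConfigError(f"unknown noise kind {kind!r}")


def add_noise(segment: AudioSegment, spec: NoiseSpec) -> AudioSegment:
    """Mix noise into a clip at the requested SNR (RMS over the whole clip)."""
    x = segment.samples
    sig_rms = float(np.sqrt(np.mean(x * x)))
    if sig_rms == 0.0:
        raise SilentSegmentError("cannot target an SNR against a silent clip")
    rng = np.random.default_rng(spec.seed)
    noise = _make_noise(spec.kind, x.size, segment.sample_rate, rng, spec.band_limit)
    noise_rms = float(np.sqrt(np.mean(noise * noise))) + 1e-300
    target_rms = sig_rms / (10.0 ** (spec.snr_db / 20.0))
    return segment.with_samples(x + noise * (target_rms / noise_rms))


def generate_dataset(
    n_per_class: int,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    include_nonvocal: bool = True,
    noise_kinds: tuple[str, ...] = ("white",),
    snr_db_range: tuple[float, float] = (8.0, 20.0),
    imbalance: bool = False,
    hard: bool = False,
    seed: int = 0,
) -> tuple[list[AudioSegment], np.ndarray, np.ndarray]:
    """In-memory labeled dataset.

    Returns (segments, binary_labels, behavior_labels) where binary label 1
    means cattle voice and behavior label is 0..3 for calls, -1 for
    non-vocal clips.  ``imbalance=True`` ignores ``n_per_class`` for the
    call classes and mirrors the behavioral corpus exactly: per-class
    counts 207/178/56/456 (total 897).
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    counts = TABLE2_CLASS_COUNTS if imbalance else (n_per_class,) * 4
    segments: list[AudioSegment] = []
    binary: list[int] = []
    behavior: list[int] = []
    for cls, n_cls in enumerate(counts):
        for _ in range(n_cls):
            call_seed = int(rng.integers(0, 2**31 - 1))
            seg, label = generate_call(CallSpec(
                class_index=cls, sample_rate=sample_rate, hard=hard, seed=call_seed
            ))
            kind = noise_kinds[int(rng.integers(0, len(noise_kinds)))]
            seg = add_noise(seg, NoiseSpec(
                kind=kind, snr_db=float(rng.uniform(*snr_db_range)),
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
            segments.append(seg)
            binary.append(1)
            behavior.append(label)
    if include_nonvocal:
        n_nonvocal = n_per_class
        for i in range(n_nonvocal):
            kind = ("transient_clang", "speech_like")[i % 2]
            seg = generate_nonvocal(kind=kind, sample_rate=sample_rate,
                                    seed=int(rng.integers(0, 2**31 - 1)))
            seg = add_noise(seg, NoiseSpec(
                kind="white", snr_db=float(rng.uniform(*snr_db_range)),
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
            segments.append(seg)
            binary.append(0)
            behavior.append(-1)
    return segments, np.asarray(binary), np.asarray(behavior)


def make_dataset(
    out_dir: str | Path,
    n_per_class: int = 100,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    include_nonvocal: bool = True,
    noise_kinds: tuple[str, ...] = ("white",),
    snr_db_range: tuple[float, float] = (8.0, 20.0),
    imbalance: bool = False,
    hard: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Write WAV clips plus a CSV manifest; returns the manifest frame.

    Manifest columns: file, is_cattle, behavior_class, sensor_id, zone_id,
    timestamp, seed.  ``imbalance=True`` mirrors the behavioral corpus
    exactly (per-class counts 207/178/56/456, total 897 call clips);
    ``include_nonvocal`` adds ``n_per_class`` non-cattle transient clips.
    Two runs with the same arguments produce identical audio and manifest.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out_dir}: {exc}") from exc
    segments, binary, behavior = generate_dataset(
        n_per_class=n_per_class, sample_rate=sample_rate,
        include_nonvocal=include_nonvocal, noise_kinds=noise_kinds,
        snr_db_range=snr_db_range, imbalance=imbalance, hard=hard, seed=seed,
    )
    rows = []
    for i, seg in enumerate(segments):
        name = f"clip_{i:05d}.wav"
        write_wav(seg, out_dir / name)
        rows.append({
            "file": name,
            "is_cattle": int(binary[i]),
            "behavior_class": int(behavior[i]),
            "sensor_id": f"sensor-{i % 4}",
            "zone_id": f"zone-{i % 3}",
            "timestamp": float(i * 10.0),
            "seed": seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
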