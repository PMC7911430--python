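"""WAV I/O, dB-triggered event capture, and cross-sensor deduplication.

The capture model mirrors a barn monitoring rig: each sensor watches its own
audio stream and saves a fixed-length clip whenever the short-window level
rises above a trigger threshold (default 60 dB).  Co-located sensors in one
zone will all capture the same loud call, so coincident events within a zone
are collapsed to the single loudest recording.

A digital clip carries no absolute sound-pressure level; the level metric
used throughout is ``20*log10(max|amplitude|) + calibration_offset`` with a
default offset of 60 dB so that a full-scale clip sits exactly at the 60 dB
trigger level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .config import (
    DEFAULT_CALIBRATION_OFFSET_DB,
    DEFAULT_RECORD_SECONDS,
    DEFAULT_TRIGGER_DB,
    DEFAULT_TRIGGER_HOP,
    DEFAULT_TRIGGER_WINDOW,
    DEFAULT_COINCIDENCE_WINDOW,
)
from .exceptions import ConfigError, DataError, SilentSegmentError, WavFormatError

__all__ = [
    "AudioSegment",
    "SensorEvent",
    "measure_db",
    "detect_events",
    "deduplicate_zone",
    "read_wav",
    "write_wav",
]


@dataclass(eq=False)
class AudioSegment:
    """A timestamped mono PCM clip with sensor metadata and peak level.

    ``samples`` are real amplitudes in [-1, 1]; ``peak_db`` is recomputable
    via :func:`measure_db` (it is filled in automatically when left as None).
    """

    samples: np.ndarray
    sample_rate: int
    start_time: float = 0.0
    sensor_id: str = "sensor-0"
    zone_id: str = "zone-0"
    peak_db: float | None = None
    calibration_offset_db: float = DEFAULT_CALIBRATION_OFFSET_DB

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise DataError("samples must be a non-empty 1-D sequence")
        if self.sample_rate <= 0:
            raise DataError("sample_rate must be positive")
        if self.peak_db is None:
            if np.any(self.samples != 0.0):
                self.peak_db = measure_db(self.samples, self.calibration_offset_db)
            else:
                self.peak_db = -np.inf

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "AudioSegment":
        """Copy of this segment with new samples (peak level recomputed)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64), peak_db=None)


@dataclass(eq=False)
class SensorEvent:
    """A triggered recording: the captured clip plus trigger bookkeeping."""

    segment: AudioSegment
    trigger_time: float
    threshold_db: float = DEFAULT_TRIGGER_DB

    def __post_init__(self) -> None:
        if self.segment.peak_db < self.threshold_db:
            raise DataError(
                f"event peak {self.segment.peak_db:.2f} dB below "
                f"threshold {self.threshold_db:.2f} dB"
            )


def measure_db(
    samples: np.ndarray, calibration_offset: float = DEFAULT_CALIBRATION_OFFSET_DB
) -> float:
    """Peak level of a clip in calibrated decibels.

    dB = 20*log10(max|amplitude|) + calibration_offset.  Monotonically
    non-decreasing in the peak amplitude; raises on an all-zero clip where
    the level is undefined.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise DataError("cannot measure level of an empty clip")
    peak = float(np.max(np.abs(samples)))
    if peak == 0.0:
        raise SilentSegmentError("all-zero (silent) segment has no defined level")
    return 20.0 * np.log10(peak) + calibration_offset


def detect_events(
    samples: np.ndarray,
    sample_rate: int,
    threshold_db: float = DEFAULT_TRIGGER_DB,
    record_seconds: float = DEFAULT_RECORD_SECONDS,
    calibration_offset: float = DEFAULT_CALIBRATION_OFFSET_DB,
    window_seconds: float = DEFAULT_TRIGGER_WINDOW,
    hop_seconds: float = DEFAULT_TRIGGER_HOP,
    sensor_id: str = "sensor-0",
    zone_id: str = "zone-0",
) -> list[SensorEvent]:
    """Scan a stream with short sliding windows and capture loud events.

    Whenever the window peak level strictly exceeds ``threshold_db``, a clip
    of exactly ``record_seconds`` starting at that window is captured
    (zero-padded if the stream ends early).  Triggers that fall inside an
    active recording are absorbed by it, so events never overlap.
    """
    if record_seconds <= 0:
        raise ConfigError("record_seconds must be positive")
    if window_seconds <= 0 or hop_seconds <= 0:
        raise ConfigError("trigger window and hop must be positive")
    samples = np.asarray(samples, dtype=np.float64)
    win = max(1, int(round(window_seconds * sample_rate)))
    hop = max(1, int(round(hop_seconds * sample_rate)))
    if samples.size < win:
        raise DataError("stream shorter than one analysis window")
    record_n = int(round(record_seconds * sample_rate))

    events: list[SensorEvent] = []
    guard_end = -1  # last sample index covered by the active recording
    for start in range(0, samples.size - win + 1, hop):
        if start <= guard_end:
            continue
        frame = samples[start : start + win]
        peak = np.max(np.abs(frame))
        if peak == 0.0:
            continue
        level = 20.0 * np.log10(peak) + calibration_offset
        if level > threshold_db:
            clip = samples[start : start + record_n]
            if clip.size < record_n:
                clip = np.pad(clip, (0, record_n - clip.size))
            t0 = start / sample_rate
            seg = AudioSegment(
                samples=clip,
                sample_rate=sample_rate,
                start_time=t0,
                sensor_id=sensor_id,
                zone_id=zone_id,
                calibration_offset_db=calibration_offset,
            )
            events.append(SensorEvent(segment=seg, trigger_time=t0, threshold_db=threshold_db))
            guard_end = start + record_n - 1
    return events


def deduplicate_zone(
    events: list[SensorEvent],
    coincidence_window: float = DEFAULT_COINCIDENCE_WINDOW,
) -> list[SensorEvent]:
    """Collapse coincident same-zone recordings to the loudest one.

    Events in the same zone whose trigger times fall in the same coincidence
    bucket (``floor(trigger_time / coincidence_window)``) are the same
    physical sound heard by several sensors; only the event with the highest
    peak level survives.  Events in different zones never collapse.
    Idempotent; survivors are a subset of the input.
    """
    if coincidence_window <= 0:
        raise ConfigError("coincidence_window must be positive")
    best: dict[tuple[str, int], SensorEvent] = {}
    for ev in events:
        bucket = int(np.floor(ev.trigger_time / coincidence_window))
        key = (ev.segment.zone_id, bucket)
        cur = best.get(key)
        if cur is None or ev.segment.peak_db > cur.segment.peak_db:
            best[key] = ev
    return sorted(best.values(), key=lambda e: (e.trigger_time, e.segment.zone_id))


def read_wav(path: str | Path, **segment_kwargs) -> AudioSegment:
    """Read a RIFF/WAVE file into an :class:`AudioSegment`.

    PCM integer dialects are rescaled to [-1, 1]; multichannel audio is
    downmixed to mono by averaging channels.
    """
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, EOFError) as exc:
        raise WavFormatError(f"cannot read {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32 / float64 IEEE dialects
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if x.size == 0:
        raise WavFormatError(f"{path} contains no samples")
    return AudioSegment(samples=x, sample_rate=int(rate), **segment_kwargs)


def write_wav(segment: AudioSegment, path: str | Path, subtype: str = "PCM_16") -> None:
    """Write a segment to disk as 16-bit PCM (default) or IEEE float WAV."""
    x = np.clip(segment.samples, -1.0, 1.0)
    if subtype == "PCM_16":
        q = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(str(path), segment.sample_rate, q)
    elif subtype == "FLOAT":
        wavfile.write(str(path), segment.sample_rate, x.astype(np.float32))
    else:
        raise ConfigError(f"unknown WAV subtype {subtype!r} (use PCM_16 or FLOAT)")
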