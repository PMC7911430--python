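"""End-to-end monitoring flow: capture -> dedup -> denoise -> features ->
binary gate -> behavioral classification -> per-event report.

Each post-deduplication event yields exactly one :class:`PredictionRecord`.
Behavioral fields are present only when the gate accepts the clip as cattle
voice; classes 0-2 (estrus, food-anticipating, cough) raise the alert flag
that tells the farmer the event needs attention.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio_io import AudioSegment, SensorEvent, deduplicate_zone, read_wav
from .config import PipelineConfig
from .exceptions import ConfigError, DataError
from .features import mfcc_pipeline
from .metrics import BEHAVIOR_CLASSES
from .models import SequentialCNN, predict
from .noisefilter import STFTConfig, denoise

__all__ = ["PredictionRecord", "run_pipeline", "export_report", "import_report"]

logger = logging.getLogger("herdcall.monitor")

#: Behavioral classes that raise the management alert.
ALERT_CLASSES = (0, 1, 2)


@dataclass
class PredictionRecord:
    """One monitored event: provenance, gate decision, behavioral class."""

    timestamp: float
    sensor_id: str
    zone_id: str
    wav_path: str
    is_cattle: bool
    cattle_probability: float
    behavior_class: int | None = None
    behavior_probability: float | None = None
    alert: bool = False

    def __post_init__(self) -> None:
        if self.is_cattle and self.behavior_class is None:
            raise DataError("cattle events must carry a behavioral class")
        if not self.is_cattle and self.behavior_class is not None:
            raise DataError("non-cattle events must not carry behavioral fields")

    @property
    def behavior_name(self) -> str | None:
        if self.behavior_class is None:
            return None
        return BEHAVIOR_CLASSES[self.behavior_class]

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "sensor_id": self.sensor_id,
            "zone_id": self.zone_id,
            "wav_path": self.wav_path,
            "is_cattle": self.is_cattle,
            "cattle_probability": self.cattle_probability,
            "behavior_class": self.behavior_class,
            "behavior_name": self.behavior_name,
            "behavior_probability": self.behavior_probability,
            "alert": self.alert,
        }


def _classify_event(
    event: SensorEvent,
    wav_path: str,
    binary_model: SequentialCNN,
    behavior_model: SequentialCNN,
    config: PipelineConfig,
) -> PredictionRecord:
    t0 = time.perf_counter()
    stft_cfg = STFTConfig(n_fft=config.n_fft, win_length=config.win_length, hop=config.hop)
    clean = denoise(event.segment, config=stft_cfg, n_std=config.n_std)
    feature_cfg = STFTConfig(n_fft=config.n_fft, win_length=config.win_length,
                             hop=config.feature_hop or config.hop)
    feats = mfcc_pipeline(
        clean,
        M=config.n_mels,
        t_fixed=config.t_fixed,
        stft_config=feature_cfg,
        representation=config.representation,
    )
    gate_class, gate_probs = predict(binary_model, feats)
    is_cattle = gate_class == 1
    if is_cattle:
        beh_class, beh_probs = predict(behavior_model, feats)
        record = PredictionRecord(
            timestamp=event.trigger_time,
            sensor_id=event.segment.sensor_id,
            zone_id=event.segment.zone_id,
            wav_path=wav_path,
            is_cattle=True,
            cattle_probability=float(gate_probs[1]),
            behavior_class=beh_class,
            behavior_probability=float(beh_probs[beh_class]),
            alert=beh_class in ALERT_CLASSES,
        )
    else:
        record = PredictionRecord(
            timestamp=event.trigger_time,
            sensor_id=event.segment.sensor_id,
            zone_id=event.segment.zone_id,
            wav_path=wav_path,
            is_cattle=False,
            cattle_probability=float(gate_probs[1]),
        )
    logger.info(
        "event t=%.2fs sensor=%s stage=classify duration=%.3fs cattle=%s class=%s",
        event.trigger_time, event.segment.sensor_id,
        time.perf_counter() - t0, record.is_cattle, record.behavior_name,
    )
    return record


def run_pipeline(
    wav_paths: list[str | Path],
    binary_model: SequentialCNN | str | Path,
    behavior_model: SequentialCNN | str | Path,
    config: PipelineConfig | None = None,
    manifest: dict | None = None,
) -> list[PredictionRecord]:
    """Classify captured clips into per-event prediction records.

    Each WAV file is treated as one captured sensor event (its manifest
    entry, if given, supplies sensor/zone/timestamp metadata); coincident
    same-zone events are deduplicated to the loudest, then each surviving
    event is denoised, featurized, gated, and (if cattle) behaviorally
    classified.  Deterministic for fixed inputs, config, and checkpoints.
    """
    config = config or PipelineConfig()
    if isinstance(binary_model, (str, Path)):
        if not Path(binary_model).exists():
            raise ConfigError(f"missing binary model checkpoint {binary_model}")
        binary_model = SequentialCNN.load(binary_model)
    if isinstance(behavior_model, (str, Path)):
        if not Path(behavior_model).exists():
            raise ConfigError(f"missing behavior model checkpoint {behavior_model}")
        behavior_model = SequentialCNN.load(behavior_model)

    events: list[tuple[SensorEvent, str]] = []
    for i, p in enumerate(wav_paths):
        meta = (manifest or {}).get(str(p), {})
        seg = read_wav(
            p,
            sensor_id=meta.get("sensor_id", f"sensor-{i}"),
            zone_id=meta.get("zone_id", f"zone-{i}"),
            start_time=float(meta.get("timestamp", float(i))),
            calibration_offset_db=config.calibration_offset_db,
        )
        ev = SensorEvent(
            segment=seg, trigger_time=seg.start_time, threshold_db=-np.inf
        )
        events.append((ev, str(p)))
    paths_by_id = {id(ev): path for ev, path in events}
    surviving = deduplicate_zone([ev for ev, _ in events], config.coincidence_window)
    records = [
        _classify_event(ev, paths_by_id[id(ev)], binary_model, behavior_model, config)
        for ev in surviving
    ]
    logger.info("pipeline complete: %d events in, %d records out", len(events), len(records))
    return records


_CSV_FIELDS = [
    "timestamp", "sensor_id", "zone_id", "wav_path", "is_cattle",
    "cattle_probability", "behavior_class", "behavior_name",
    "behavior_probability", "alert",
]


def export_report(records: list[PredictionRecord], path: str | Path,
                  format: str = "json") -> None:
    """Serialize records losslessly as JSON (default) or CSV."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps([r.to_dict() for r in records], indent=2))
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            for r in records:
                writer.writerow(r.to_dict())
    else:
        raise ConfigError(f"unknown report format {format!r}")


def import_report(path: str | Path) -> list[PredictionRecord]:
    """Read back a JSON report written by :func:`export_report`."""
    data = json.loads(Path(path).read_text())
    records = []
    for d in data:
        d = dict(d)
        d.pop("behavior_name", None)
        records.append(PredictionRecord(**d))
    return records
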