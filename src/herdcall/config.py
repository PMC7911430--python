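"""Pipeline configuration with the monitoring system's default constants.

Every constant of the monitoring flow lives here rather than inline in the
stage code: the 60 dB capture threshold, the 5 s record length, the STFT
geometry (n_fft 2048, window 2048, hop 256), the gate width n_std, the
128-band / 2000-frame feature target, and the Adadelta hyperparameters
(gamma 0.95, epsilon 1e-7).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import ConfigError

#: Default sampling rate (Hz) for synthesis and capture.
DEFAULT_SAMPLE_RATE = 16_000
#: Capture trigger level (dB); clips are saved when the level exceeds this.
DEFAULT_TRIGGER_DB = 60.0
#: Length of a captured clip in seconds.
DEFAULT_RECORD_SECONDS = 5.0
#: Digital full scale maps to this dB level (see audio_io.measure_db).
DEFAULT_CALIBRATION_OFFSET_DB = 60.0
#: Sliding trigger window / hop in seconds.
DEFAULT_TRIGGER_WINDOW = 0.100
DEFAULT_TRIGGER_HOP = 0.050
#: Cross-sensor deduplication coincidence window (seconds).
DEFAULT_COINCIDENCE_WINDOW = 1.0

#: STFT geometry.
DEFAULT_N_FFT = 2048
DEFAULT_WIN_LENGTH = 2048
DEFAULT_HOP = 256
#: Spectral-gate threshold multiplier (threshold = mean + n_std * std, in dB).
DEFAULT_N_STD = 1.5
#: Mask smoothing kernel: 2 frequency rows x 4 time columns, equal weights.
DEFAULT_SMOOTHING_KERNEL_SHAPE = (2, 4)

#: Feature target: Mel bands x fixed time frames.
DEFAULT_N_MELS = 128
DEFAULT_T_FIXED = 2000
#: Floor added inside log() on filter-bank energies.
DEFAULT_LOG_FLOOR = 1e-10

#: Adadelta hyperparameters.
DEFAULT_ADADELTA_GAMMA = 0.95
DEFAULT_ADADELTA_EPSILON = 1e-7

#: Training defaults.
DEFAULT_EPOCHS = 60
DEFAULT_BATCH_SIZE = 32
DEFAULT_VALIDATION_FRACTION = 0.2


@dataclass
class PipelineConfig:
    """Declarative configuration for the end-to-end monitoring pipeline."""

    sample_rate: int = DEFAULT_SAMPLE_RATE
    trigger_db: float = DEFAULT_TRIGGER_DB
    record_seconds: float = DEFAULT_RECORD_SECONDS
    calibration_offset_db: float = DEFAULT_CALIBRATION_OFFSET_DB
    coincidence_window: float = DEFAULT_COINCIDENCE_WINDOW
    n_fft: int = DEFAULT_N_FFT
    win_length: int = DEFAULT_WIN_LENGTH
    hop: int = DEFAULT_HOP
    n_std: float = DEFAULT_N_STD
    n_mels: int = DEFAULT_N_MELS
    t_fixed: int = DEFAULT_T_FIXED
    #: hop for feature framing; None reuses the denoising hop
    feature_hop: int | None = None
    representation: str = "mfcc"  # "mfcc" (post-DCT) or "logmel"
    adadelta_gamma: float = DEFAULT_ADADELTA_GAMMA
    adadelta_epsilon: float = DEFAULT_ADADELTA_EPSILON
    epochs: int = DEFAULT_EPOCHS
    batch_size: int = DEFAULT_BATCH_SIZE
    seed: int = 0
    binary_model_path: str | None = None
    behavior_model_path: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.record_seconds <= 0:
            raise ConfigError("record_seconds must be positive")
        if not (0 < self.hop <= self.win_length <= self.n_fft):
            raise ConfigError("require 0 < hop <= win_length <= n_fft")
        if self.representation not in ("mfcc", "logmel"):
            raise ConfigError("representation must be 'mfcc' or 'logmel'")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))
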