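"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: ConfigError -> 1, DataError -> 2.
"""


class HerdcallError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(HerdcallError):
    """Invalid configuration (bad STFT geometry, thresholds, model spec...)."""


class DataError(HerdcallError):
    """Invalid or malformed input data."""


class SilentSegmentError(DataError):
    """An all-zero clip where a level measurement or SNR target is required."""


class WavFormatError(DataError):
    """File is not readable RIFF/WAVE PCM or IEEE-float audio."""


class ShapeError(DataError):
    """Matrix/bin-count mismatch between pipeline stages."""


class UndefinedRateError(DataError):
    """A confusion-matrix rate whose denominator is zero."""
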