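"""Shared fixtures: synthetic datasets and session-scoped trained models.

The trained-model fixture runs the full desk-scale benchmark once per
session (seed 7, 100 clips per class, 32 Mel bands x 64 frames, 40 epochs)
and is shared by the end-to-end classification tests.
"""

import numpy as np
import pytest
from hypothesis import settings

import herdcall as h
from herdcall.noisefilter import STFTConfig

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# Desk-scale study conditions shared by tests and the acceptance benchmark.
BENCH_SEED = 7
BENCH_N_PER_CLASS = 100
BENCH_MELS = 32
BENCH_FRAMES = 64
BENCH_EPOCHS = 40
# hop chosen so a whole 5 s / 16 kHz clip fits in 64 frames
BENCH_STFT = dict(n_fft=2048, win_length=2048, hop=1280)


def snr_db(x: np.ndarray, reference: np.ndarray) -> float:
    err = x - reference
    return 10.0 * np.log10(np.sum(reference**2) / np.sum(err**2))


def featurize_segments(segments, mels=BENCH_MELS, frames=BENCH_FRAMES,
                       denoise_first=True):
    """Noise-filter then featurize, as the monitoring flow does."""
    cfg = STFTConfig(**BENCH_STFT)
    out = []
    for s in segments:
        if denoise_first:
            s = h.denoise(s)  # default 2048/2048/256 gating geometry
        out.append(
            h.mfcc_pipeline(s, M=mels, t_fixed=frames, stft_config=cfg).coefficients
        )
    return np.stack(out)


@pytest.fixture(scope="session")
def bench_dataset():
    """Seed-7 synthetic corpus: 100 clips per call class plus non-vocal."""
    segments, binary, behavior = h.synthetic.generate_dataset(
        n_per_class=BENCH_N_PER_CLASS, seed=BENCH_SEED
    )
    features = featurize_segments(segments)
    return segments, features, binary, behavior


@pytest.fixture(scope="session")
def trained_models(bench_dataset):
    """Binary gate and behavior model trained on the seed-7 corpus."""
    _, X, yb, ybeh = bench_dataset
    tconf = h.TrainConfig(epochs=BENCH_EPOCHS, batch_size=32, seed=BENCH_SEED)
    binary_model, binary_hist = h.train(
        h.build_binary_cnn((BENCH_MELS, BENCH_FRAMES), seed=BENCH_SEED), X, yb, tconf
    )
    call = ybeh >= 0
    behavior_model, behavior_hist = h.train(
        h.build_behavior_cnn((BENCH_MELS, BENCH_FRAMES), seed=BENCH_SEED),
        X[call], ybeh[call], tconf,
    )
    return {
        "binary": binary_model,
        "binary_history": binary_hist,
        "behavior": behavior_model,
        "behavior_history": behavior_hist,
    }
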