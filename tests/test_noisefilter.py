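"""STFT analysis/synthesis, noise-profile statistics, gating, smoothing."""

import numpy as np
import pytest
from scipy.signal import convolve2d, get_window, periodogram

import herdcall as h
from herdcall.exceptions import ConfigError, DataError, ShapeError
from herdcall.noisefilter import (
    NoiseProfile,
    STFTConfig,
    STFTMatrix,
    TimeFrequencyMask,
    _uniform_kernel,
)

SR = 16000


def _segment(x, sr=SR):
    return h.AudioSegment(samples=x, sample_rate=sr)


def snr_db(x, ref):
    return 10 * np.log10(np.sum(ref**2) / np.sum((x - ref) ** 2))


class TestStft:
    def test_bin_centered_sine_concentrates_in_its_row(self):
        cfg = STFTConfig(n_fft=1024, win_length=1024, hop=256, window_fn="boxcar")
        k = 40
        f = k * SR / cfg.n_fft
        x = np.sin(2 * np.pi * f * np.arange(SR) / SR)
        S = h.stft(_segment(x), cfg)
        power = np.abs(S.values) ** 2
        assert np.all(power[k] / power.sum(axis=0) >= 0.90)

    def test_all_zero_clip_gives_zero_matrix(self):
        S = h.stft(_segment(np.zeros(8192)))
        assert np.all(S.values == 0)

    def test_column_power_matches_windowed_frame_power(self):
        # Parseval with one-sided correction against a direct framing oracle
        rng = np.random.default_rng(11)
        x = rng.standard_normal(SR)
        cfg = STFTConfig()
        S = h.stft(_segment(x), cfg)
        w = get_window("hann", cfg.win_length, fftbins=True)
        for col in (0, 3, S.n_frames - 1):
            frame = x[col * cfg.hop : col * cfg.hop + cfg.win_length] * w
            X = S.values[:, col]
            one_sided = np.abs(X[0]) ** 2 + np.abs(X[-1]) ** 2 + 2 * np.sum(np.abs(X[1:-1]) ** 2)
            assert one_sided / cfg.n_fft == pytest.approx(np.sum(frame**2), rel=1e-6)

    def test_frame_count_convention(self):
        # 5 s at 16 kHz, window 2048, hop 256: 1 + (80000-2048)//256 frames
        S = h.stft(_segment(np.random.default_rng(0).standard_normal(80000)))
        assert S.n_frames == 1 + (80000 - 2048) // 256

    def test_short_clip_rejected(self):
        with pytest.raises(DataError):
            h.stft(_segment(np.ones(100)))

    def test_bad_geometry_rejected(self):
        with pytest.raises(ConfigError):
            STFTConfig(n_fft=512, win_length=1024, hop=256)


class TestIstft:
    def test_round_trip_reproduces_interior(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40000)
        cfg = STFTConfig()
        y = h.istft(h.stft(_segment(x), cfg), length=x.size)
        core = slice(cfg.win_length, -cfg.win_length)
        assert np.max(np.abs(y.samples[core] - x[core])) <= 1e-6

    def test_all_pass_mask_preserves_signal(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40000)
        S = h.stft(_segment(x))
        ones = TimeFrequencyMask(values=np.ones_like(S.values, dtype=float))
        gated = STFTMatrix(values=S.values * ones.values, config=S.config, sample_rate=SR)
        y = h.istft(gated, length=x.size)
        core = slice(2048, -2048)
        assert np.max(np.abs(y.samples[core] - x[core])) <= 1e-6

    def test_zero_mask_gives_silence(self):
        S = h.stft(_segment(np.random.default_rng(7).standard_normal(40000)))
        gated = STFTMatrix(values=S.values * 0.0, config=S.config, sample_rate=SR)
        assert np.all(h.istft(gated).samples == 0.0)


class TestNoiseProfile:
    def test_constant_magnitude_gives_zero_std(self):
        cfg = STFTConfig(n_fft=64, win_length=64, hop=32)
        vals = np.full((33, 10), 2.0, dtype=complex)
        prof = h.estimate_noise_profile(STFTMatrix(values=vals, config=cfg, sample_rate=SR))
        assert np.allclose(prof.std_power_db, 0.0, atol=1e-9)
        assert np.allclose(prof.threshold_db, prof.mean_power_db)

    def test_two_column_hand_computation(self):
        cfg = STFTConfig(n_fft=64, win_length=64, hop=32)
        a, b = 1.0, 4.0
        vals = np.column_stack([np.full(33, a), np.full(33, b)]).astype(complex)
        prof = h.estimate_noise_profile(STFTMatrix(values=vals, config=cfg, sample_rate=SR))
        da, db = 20 * np.log10(a), 20 * np.log10(b)
        assert prof.mean_power_db[0] == pytest.approx((da + db) / 2, abs=1e-6)
        assert prof.std_power_db[0] == pytest.approx(abs(da - db) / 2, abs=1e-6)

    def test_white_noise_threshold_is_flat(self):
        rng = np.random.default_rng(42)
        noise = _segment(0.1 * rng.standard_normal(SR))
        prof = h.estimate_noise_profile(h.stft(noise))
        cv = prof.threshold_db.std() / abs(prof.threshold_db.mean())
        assert cv < 0.2

    def test_single_column_rejected(self):
        cfg = STFTConfig(n_fft=64, win_length=64, hop=32)
        vals = np.ones((33, 1), dtype=complex)
        with pytest.raises(DataError):
            h.estimate_noise_profile(STFTMatrix(values=vals, config=cfg, sample_rate=SR))


class TestComputeMask:
    def _profile(self, n_bins, level_db):
        return NoiseProfile(
            mean_power_db=np.full(n_bins, level_db),
            std_power_db=np.zeros(n_bins),
            threshold_db=np.full(n_bins, level_db),
        )

    def test_signal_above_threshold_passes_everywhere(self):
        S = h.stft(_segment(np.random.default_rng(0).standard_normal(8192)))
        mask = h.compute_mask(S, self._profile(S.n_bins, -200.0))
        assert np.all(mask.values == 1.0)

    def test_signal_below_threshold_blocked_everywhere(self):
        S = h.stft(_segment(np.random.default_rng(0).standard_normal(8192)))
        mask = h.compute_mask(S, self._profile(S.n_bins, 200.0))
        assert np.all(mask.values == 0.0)

    def test_hum_band_passes_less_than_call_band(self):
        seg, _ = h.generate_call(h.CallSpec(class_index=0, f0_range=(500, 600), seed=4))
        noisy = h.add_noise(seg, h.NoiseSpec(kind="low_band_hum", snr_db=5, seed=4))
        S = h.stft(noisy)
        ref = h.add_noise(_segment(np.full(80000, 1e-6)),
                          h.NoiseSpec(kind="low_band_hum", snr_db=-40, seed=5))
        prof = h.estimate_noise_profile(h.stft(ref))
        mask = h.compute_mask(S, prof)
        freqs = S.frequencies()
        below = mask.values[freqs < 400].mean()
        call_band = mask.values[(freqs >= 450) & (freqs < 4000)].mean()
        assert below < call_band

    def test_bin_mismatch_rejected(self):
        S = h.stft(_segment(np.random.default_rng(0).standard_normal(8192)))
        with pytest.raises(ShapeError):
            h.compute_mask(S, self._profile(S.n_bins - 1, 0.0))


class TestSmoothMask:
    def test_all_ones_keeps_interior_at_one(self):
        mask = TimeFrequencyMask(values=np.ones((20, 40)))
        out = h.smooth_mask(mask)
        assert np.all(out.values <= 1.0 + 1e-12)
        assert np.allclose(out.values[2:-2, 3:-3], 1.0)

    def test_isolated_cell_spreads_with_unit_mass(self):
        vals = np.zeros((20, 40))
        vals[10, 20] = 1.0
        out = h.smooth_mask(TimeFrequencyMask(values=vals))
        assert out.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(out.values) == 8  # 2x4 neighborhood

    def test_checkerboard_matches_direct_convolution(self):
        vals = np.indices((16, 24)).sum(axis=0) % 2.0
        mask = TimeFrequencyMask(values=vals)
        out = h.smooth_mask(mask)
        oracle = convolve2d(vals, _uniform_kernel((2, 4)), mode="same", boundary="fill")
        assert np.allclose(out.values, oracle, atol=1e-12)

    def test_kernel_weights_validated(self):
        with pytest.raises(DataError):
            TimeFrequencyMask(values=np.zeros((4, 4)), smoothing_kernel=np.ones((2, 4)))


class TestDenoise:
    def test_clean_tone_passes_nearly_unchanged(self):
        # 1 s tone burst in an otherwise quiet clip: the gate passes it
        x = np.zeros(80000)
        n = SR
        x[2 * SR : 3 * SR] = 0.5 * np.sin(2 * np.pi * 1000 * np.arange(n) / SR) * np.hanning(n)
        out = h.denoise(_segment(x))
        core = slice(8000, -8000)
        assert snr_db(out.samples[core], x[core]) >= 30.0

    def test_improves_snr_on_noisy_call(self):
        seg, _ = h.generate_call(h.CallSpec(class_index=0, seed=3))
        noisy = h.add_noise(seg, h.NoiseSpec(kind="white", snr_db=0, seed=1))
        out = h.denoise(noisy)
        assert snr_db(out.samples, seg.samples) - snr_db(noisy.samples, seg.samples) >= 6.0

    def test_pure_noise_with_self_reference_mostly_removed(self):
        rng = np.random.default_rng(1)
        noise = _segment(0.1 * rng.standard_normal(80000))
        out = h.denoise(noise, noise_reference=noise)
        # with the default gate width (mean + 1.5 sd) the loudest ~7% of
        # noise cells pass by construction, carrying a few percent of energy
        assert np.sqrt(np.mean(out.samples**2)) <= 0.2 * np.sqrt(np.mean(noise.samples**2))

    def test_masking_is_a_contraction(self):
        seg, _ = h.generate_call(h.CallSpec(class_index=1, seed=9))
        noisy = h.add_noise(seg, h.NoiseSpec(kind="white", snr_db=5, seed=2))
        S = h.stft(noisy)
        prof = h.estimate_noise_profile(S)
        soft = h.smooth_mask(h.compute_mask(S, prof))
        assert np.all(np.abs(S.values * soft.values) <= np.abs(S.values) + 1e-12)

    def test_denoise_is_idempotent_in_rms(self):
        seg, _ = h.generate_call(h.CallSpec(class_index=0, seed=3))
        noisy = h.add_noise(seg, h.NoiseSpec(kind="white", snr_db=0, seed=1))
        d1 = h.denoise(noisy)
        d2 = h.denoise(d1)
        r1 = np.sqrt(np.mean(d1.samples**2))
        r2 = np.sqrt(np.mean(d2.samples**2))
        assert abs(r2 - r1) / r1 < 0.05

    def test_gate_width_extremes(self):
        seg, _ = h.generate_call(h.CallSpec(class_index=2, seed=8))
        noisy = h.add_noise(seg, h.NoiseSpec(kind="white", snr_db=10, seed=3))
        wide_open = h.denoise(noisy, n_std=-1e6)
        core = slice(4096, -4096)
        rel = (np.max(np.abs(wide_open.samples[core] - noisy.samples[core]))
               / np.max(np.abs(noisy.samples)))
        assert rel < 0.01  # identity up to reconstruction/border smoothing
        assert np.all(h.denoise(noisy, n_std=1e6).samples == 0.0)

    def test_output_length_and_metadata_preserved(self):
        seg, _ = h.generate_call(h.CallSpec(class_index=3, seed=2))
        seg.sensor_id, seg.zone_id = "s9", "z9"
        out = h.denoise(seg)
        assert out.samples.size == seg.samples.size
        assert (out.sensor_id, out.zone_id) == ("s9", "z9")
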