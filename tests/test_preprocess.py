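import numpy as np
import pytest

import pulsegrip as pg
from pulsegrip.preprocess import (
    PreprocessConfig,
    moving_average,
    preprocess_dataset,
    split_dataset,
    wavelet_denoise,
    zscore,
)
from pulsegrip.synthetic import ForceSignal


def _sig(x, fs=100.0):
    return ForceSignal(samples=np.asarray(x, dtype=float), fs=fs)


class TestWaveletDenoise:
    def test_zero_signal_stays_zero(self):
        out = wavelet_denoise(_sig(np.zeros(256)))
        assert np.allclose(out.samples, 0.0)
        assert out.samples.size == 256

    def test_zero_threshold_is_perfect_reconstruction(self, rng):
        x = rng.normal(size=777)
        out = wavelet_denoise(_sig(x), threshold=0.0)
        np.testing.assert_allclose(out.samples, x, atol=1e-8)

    def test_clean_pulse_train_almost_unchanged(self):
        spec = pg.make_preset("porcine_I", "artery", amplitude_cv=0.0, noise_sd=0.0)
        sig = pg.simulate_grip_trial(spec, fs=100, seed=0)
        out = wavelet_denoise(sig)
        rmse = np.sqrt(np.mean((out.samples - sig.samples) ** 2))
        assert rmse < 0.02 * spec.pulse_amplitude

    def test_removes_more_noise_than_signal(self, rng):
        spec = pg.make_preset("porcine_I", "artery", amplitude_cv=0.0, noise_sd=0.0)
        clean = pg.simulate_grip_trial(spec, fs=100, seed=0)
        noise = rng.normal(0.0, 0.01, clean.samples.size)
        noisy = _sig(clean.samples + noise)
        out = wavelet_denoise(noisy)
        residual = out.samples - clean.samples
        assert np.var(residual) / np.var(noise) < 1.0

    def test_short_signal_error_names_maximum_level(self):
        with pytest.raises(ValueError, match="maximum usable level"):
            wavelet_denoise(_sig(np.arange(8.0)), PreprocessConfig())

    def test_length_preserved_for_odd_input(self, rng):
        x = rng.normal(size=301)
        assert wavelet_denoise(_sig(x)).samples.size == 301


class TestZscore:
    def test_worked_example(self):
        out = zscore(_sig([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.samples, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_output_standardized(self, rng):
        out = zscore(_sig(rng.normal(3.0, 7.0, 500)))
        assert abs(out.samples.mean()) < 1e-10
        assert abs(np.std(out.samples, ddof=1) - 1.0) < 1e-10

    def test_twice_is_stable(self, rng):
        once = zscore(_sig(rng.normal(size=100)))
        twice = zscore(once)
        assert abs(np.std(twice.samples, ddof=1) - np.std(once.samples, ddof=1)) < 1e-10

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore(_sig([5.0, 5.0, 5.0]))


class TestMovingAverage:
    def test_constant_invariance(self):
        out = moving_average(_sig([1.0, 1.0, 1.0]), 3)
        np.testing.assert_allclose(out.samples, [1.0, 1.0, 1.0])

    def test_shrunk_edges(self):
        out = moving_average(_sig([0.0, 3.0, 0.0]), 3)
        np.testing.assert_allclose(out.samples, [1.5, 1.0, 1.5])

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(moving_average(_sig(x), 1).samples, x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_average(_sig(np.arange(10.0)), 4)

    def test_matches_direct_windowed_mean(self, rng):
        x = rng.normal(size=31)
        out = moving_average(_sig(x), 5).samples
        # oracle: direct mean over the clipped window at every position
        expected = [
            np.mean(x[max(0, i - 2) : min(31, i + 3)]) for i in range(31)
        ]
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestSplitDataset:
    def test_balanced_three_class_622(self):
        ds = pg.generate_dataset("phantom_III", 80, 20, 0)
        out = split_dataset(ds, (6, 2, 2), seed=1)
        split = np.asarray(out.split)
        assert (split == "train").sum() == 144
        assert (split == "val").sum() == 48
        assert (split == "test").sum() == 48

    def test_per_class_counts_within_one_of_targets(self):
        ds = pg.generate_dataset("porcine_I", 13, 20, 0)
        out = split_dataset(ds, (6, 2, 2), seed=0)
        split = np.asarray(out.split)
        for c in range(2):
            mask = out.labels == c
            for part, frac in [("train", 0.6), ("val", 0.2), ("test", 0.2)]:
                n = ((split == part) & mask).sum()
                assert abs(n - 13 * frac) <= 1

    def test_deterministic_and_exhaustive(self):
        ds = pg.generate_dataset("porcine_I", 5, 20, 2)
        a = split_dataset(ds, seed=7)
        b = split_dataset(ds, seed=7)
        assert a.split == b.split
        assert set(a.split) == {"train", "val", "test"}

    def test_small_class_rejected(self):
        ds = pg.generate_dataset("porcine_I", 2, 20, 0)
        with pytest.raises(ValueError, match="need >= 3"):
            split_dataset(ds)


class TestPreprocessDataset:
    def test_global_normalization_preserves_amplitude_ordering(self, tiny_dataset):
        # artery trials must keep larger spread than vein trials after the
        # train-split-fitted normalization
        spread = np.array([np.std(s.samples) for s in tiny_dataset.sequences])
        artery = spread[tiny_dataset.labels == 0].mean()
        vein = spread[tiny_dataset.labels == 1].mean()
        assert artery > 1.5 * vein

    def test_per_signal_normalization_standardizes_each(self):
        ds = pg.generate_dataset("porcine_I", 3, 20, 1)
        out = preprocess_dataset(
            ds, PreprocessConfig(normalization="per_signal", smoothing_window=1)
        )
        for s in out.sequences:
            assert abs(s.samples.mean()) < 1e-8
            assert abs(np.std(s.samples, ddof=1) - 1.0) < 1e-8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(smoothing_window=4)
        with pytest.raises(ValueError):
            PreprocessConfig(decomposition_level=0)
        with pytest.raises(ValueError):
            PreprocessConfig(normalization="other")
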