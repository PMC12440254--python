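"""Signal conditioning and dataset splitting.

The conditioning chain, in fixed order, is wavelet soft-threshold denoising,
Z-score normalization and a short moving-average smoothing; datasets are
split 6:2:2 into train/validation/test, stratified by class.

Denoising decomposes the signal into wavelet sub-bands, shrinks every detail
coefficient toward zero by a threshold (soft thresholding) and reconstructs.
The default threshold is the universal rule sigma * sqrt(2 ln N) with sigma
estimated from the finest detail band via the median absolute deviation.

Two normalization flavours are provided: the per-signal :func:`zscore` (each
sequence to mean 0, sd 1), and a dataset-level variant used by the
classification pipeline which fits one mean/sd on the training split so that
between-sequence amplitude differences — the physically discriminative
feature — survive normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .synthetic import ForceSignal, LabeledDataset

__all__ = [
    "PreprocessConfig",
    "wavelet_denoise",
    "zscore",
    "moving_average",
    "split_dataset",
    "preprocess_signal",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    wavelet_family: str = "db4"
    decomposition_level: int = 4
    threshold_rule: str = "universal"
    smoothing_window: int = 3
    split_ratios: tuple[float, float, float] = (6.0, 2.0, 2.0)
    split_seed: int = 0
    # "global" fits one mean/sd on the training split; "per_signal" applies
    # zscore() independently to every sequence.
    normalization: str = "global"

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        if not sum(self.split_ratios) > 0:
            raise ValueError("split_ratios must sum to > 0")
        if self.threshold_rule != "universal":
            raise ValueError("threshold_rule must be 'universal'")
        if self.normalization not in ("global", "per_signal", "none"):
            raise ValueError("normalization must be global|per_signal|none")


def wavelet_denoise(
    signal: ForceSignal,
    config: PreprocessConfig | None = None,
    threshold: float | None = None,
) -> ForceSignal:
    """Soft-threshold wavelet denoising; output length equals input length.

    ``threshold`` overrides the universal rule (0 reproduces the input up to
    transform round-off).
    """
    config = config or PreprocessConfig()
    x = signal.samples
    n = x.size
    if n < 2**config.decomposition_level:
        max_level = max(1, int(np.floor(np.log2(max(n, 2)))))
        raise ValueError(
            f"signal of length {n} too short for decomposition level "
            f"{config.decomposition_level}; maximum usable level ~{max_level}"
        )
    coeffs = pywt.wavedec(x, config.wavelet_family, level=config.decomposition_level)
    if threshold is None:
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        threshold = sigma * np.sqrt(2.0 * np.log(n))
    if threshold > 0:
        denoised = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]
        ]
    else:  # nothing to shrink (e.g. noise-free signal)
        denoised = coeffs
    y = pywt.waverec(denoised, config.wavelet_family)[:n]
    return ForceSignal(samples=y, fs=signal.fs, t0=signal.t0)


def zscore(signal: ForceSignal) -> ForceSignal:
    """Per-signal standardization to mean 0, sd 1 (ddof=1 convention)."""
    x = signal.samples
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("constant signal: standard deviation is zero")
    return ForceSignal(samples=(x - np.mean(x)) / sd, fs=signal.fs, t0=signal.t0)


def moving_average(signal: ForceSignal, window: int = 3) -> ForceSignal:
    """Centered moving average; the window shrinks at the edges.

    Length is preserved and no values are fabricated beyond the signal ends.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    x = signal.samples
    if window > x.size:
        raise ValueError("window exceeds signal length")
    if window == 1:
        return ForceSignal(samples=x.copy(), fs=signal.fs, t0=signal.t0)
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, x.size)
    y = (csum[hi] - csum[lo]) / (hi - lo)
    return ForceSignal(samples=y, fs=signal.fs, t0=signal.t0)


def split_dataset(
    dataset: LabeledDataset,
    ratios: tuple[float, float, float] = (6.0, 2.0, 2.0),
    seed: int = 0,
) -> LabeledDataset:
    """Stratified random train/val/test split, deterministic per seed.

    Within each class of size n the counts are round(n*r_train),
    round(n*r_val) and the remainder for test.
    """
    total = float(sum(ratios))
    r_train, r_val = ratios[0] / total, ratios[1] / total
    labels = dataset.labels
    split = np.empty(len(labels), dtype=object)
    rng = np.random.default_rng(seed)
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(labels == c)
        if idx.size < 3:
            raise ValueError(
                f"class {dataset.class_names[c]!r} has {idx.size} sequences; "
                "need >= 3 to split"
            )
        idx = rng.permutation(idx)
        n_train = int(round(idx.size * r_train))
        n_val = int(round(idx.size * r_val))
        split[idx[:n_train]] = "train"
        split[idx[n_train : n_train + n_val]] = "val"
        split[idx[n_train + n_val :]] = "test"
    return LabeledDataset(
        sequences=dataset.sequences,
        labels=dataset.labels,
        class_names=dataset.class_names,
        split=list(split),
        seed=dataset.seed,
        trial_seeds=dataset.trial_seeds,
    )


def preprocess_signal(
    signal: ForceSignal, config: PreprocessConfig | None = None
) -> ForceSignal:
    """Denoise -> per-signal zscore -> smooth, the fixed per-signal chain."""
    config = config or PreprocessConfig()
    out = wavelet_denoise(signal, config)
    out = zscore(out)
    return moving_average(out, config.smoothing_window)


def preprocess_dataset(
    dataset: LabeledDataset, config: PreprocessConfig | None = None
) -> LabeledDataset:
    """Condition every sequence of a dataset for the classifier.

    Chain per sequence: wavelet denoise, normalization, moving average.
    With ``normalization="global"`` a single mean/sd is fitted on the
    training split (all sequences if the dataset is unsplit) and applied
    everywhere, so relative amplitudes between sequences are preserved.
    """
    config = config or PreprocessConfig()
    denoised = [wavelet_denoise(s, config) for s in dataset.sequences]
    if config.normalization == "per_signal":
        normed = [zscore(s) for s in denoised]
    elif config.normalization == "global":
        if dataset.split is not None:
            fit_idx = dataset.indices("train")
        else:
            fit_idx = np.arange(len(denoised))
        pooled = np.concatenate([denoised[i].samples for i in fit_idx])
        mu = float(np.mean(pooled))
        sd = float(np.std(pooled, ddof=1))
        if sd == 0.0:
            raise ValueError("training split is constant; cannot normalize")
        normed = [
            ForceSignal(samples=(s.samples - mu) / sd, fs=s.fs, t0=s.t0)
            for s in denoised
        ]
    else:
        normed = denoised
    smoothed = [moving_average(s, config.smoothing_window) for s in normed]
    return LabeledDataset(
        sequences=smoothed,
        labels=dataset.labels,
        class_names=dataset.class_names,
        split=dataset.split,
        seed=dataset.seed,
        trial_seeds=dataset.trial_seeds,
    )
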