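"""Peak clamping force fluctuation (PCFF) statistics and group comparison.

During a steady grasp of a pulsating vessel, each pressure pulse shows up as
a transient peak in the gripping force.  The PCFF is the height of those
peaks above the static clamp component; the spacing between consecutive
peaks gives the pulse frequency.  The clamp baseline is estimated by the
signal's lower quartile: the pulse can occupy close to half of each cycle,
which pushes the median measurably above the clamp force (by about one
noise standard deviation under additive sensor noise), while any quantile
safely below the pulse duty cycle sits on the flat clamp-only segments and
is unbiased.

Group comparison follows the usual battery for force-statistic contrasts:
independent-samples t-test for two normal, equal-variance groups;
Mann-Whitney U otherwise for two groups; Kruskal-Wallis for three or more
groups.  Normality is screened with Shapiro-Wilk, variance homogeneity with
Levene's test.  p < 0.05 is flagged significant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy import stats

from .synthetic import ForceSignal, LabeledDataset

__all__ = [
    "PulseSummary",
    "GroupComparison",
    "detect_peaks",
    "compute_pcff",
    "pulse_frequency",
    "extract_pulse_summary",
    "compare_groups",
    "dataset_pcff",
    "write_pcff_report",
]

DEFAULT_PROMINENCE_FRACTION = 0.3
MIN_SEPARATION_PERIOD_FRACTION = 0.5
ALPHA = 0.05
BASELINE_QUANTILE = 0.25  # below any plausible pulse duty cycle


@dataclass
class PulseSummary:
    """Detected pulsation peaks and their PCFF statistics for one trial."""

    peak_indices: np.ndarray
    peak_forces: np.ndarray
    baseline: float
    pcff_values: np.ndarray
    mean_pcff: float
    pulse_rate_bpm: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak_indices must be strictly increasing")
        if self.pulse_rate_bpm < 0:
            raise ValueError("pulse_rate_bpm must be >= 0")


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # "t" | "mann_whitney" | "kruskal_wallis"
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def detect_peaks(
    signal: ForceSignal,
    expected_rate_bpm: float = 90.0,
    prominence_frac: float = DEFAULT_PROMINENCE_FRACTION,
) -> np.ndarray:
    """Locate pulsation peaks.

    Local maxima with minimum separation half the expected period and
    prominence at least ``prominence_frac`` of the signal's range.  A flat
    signal yields no peaks.
    """
    x = signal.samples
    span = float(np.ptp(x))
    if span == 0.0:
        return np.asarray([], dtype=int)
    distance = max(
        1,
        int(
            round(
                MIN_SEPARATION_PERIOD_FRACTION
                * (60.0 / expected_rate_bpm)
                * signal.fs
            )
        ),
    )
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence_frac * span)
    return peaks


def compute_pcff(
    signal: ForceSignal, peaks: np.ndarray, baseline: float | None = None
) -> PulseSummary:
    """PCFF per peak (peak force minus the clamp baseline) and mean.

    ``baseline`` defaults to the lower quartile of ``signal``; callers may
    supply a baseline taken from a denoised copy instead.  The pulse rate is
    derived from the median inter-peak interval; a single peak yields
    rate 0.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 1:
        raise ValueError("no pulsation peaks: cannot compute PCFF")
    if baseline is None:
        baseline = float(np.quantile(signal.samples, BASELINE_QUANTILE))
    peak_forces = signal.samples[peaks].astype(float)
    pcff = peak_forces - baseline
    rate = pulse_frequency(peaks, signal.fs) if peaks.size >= 2 else 0.0
    return PulseSummary(
        peak_indices=peaks,
        peak_forces=peak_forces,
        baseline=baseline,
        pcff_values=pcff,
        mean_pcff=float(np.mean(pcff)),
        pulse_rate_bpm=rate,
    )


def pulse_frequency(peaks: np.ndarray, fs: float) -> float:
    """Pulses per minute from the median inter-peak sample interval."""
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        raise ValueError("need >= 2 peaks to estimate pulse frequency")
    return float(60.0 * fs / np.median(np.diff(peaks)))


def extract_pulse_summary(
    signal: ForceSignal,
    expected_rate_bpm: float = 90.0,
    prominence_frac: float = DEFAULT_PROMINENCE_FRACTION,
    detection_signal: ForceSignal | None = None,
) -> PulseSummary:
    """Detect peaks then compute the PCFF summary.

    When ``detection_signal`` is given (typically a denoised and smoothed
    copy), peaks are located on it and the clamp baseline is its lower
    quartile (noise is suppressed there), while peak forces are read from
    ``signal`` itself: soft-threshold shrinkage attenuates the pulse crest
    and would bias PCFF low if heights were measured on the conditioned
    copy.
    """
    where = detection_signal if detection_signal is not None else signal
    peaks = detect_peaks(where, expected_rate_bpm, prominence_frac)
    baseline = (
        float(np.quantile(detection_signal.samples, BASELINE_QUANTILE))
        if detection_signal is not None
        else None
    )
    return compute_pcff(signal, peaks, baseline=baseline)


def compare_groups(
    groups: list[np.ndarray], normality_alpha: float = ALPHA
) -> GroupComparison:
    """Select and run the appropriate two-or-more-group location test.

    Two groups passing Shapiro-Wilk normality and Levene variance screening
    get the independent t-test; two groups otherwise get Mann-Whitney U;
    three or more groups get Kruskal-Wallis.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < 3:
            raise ValueError(f"group {i} has {g.size} values; need >= 3")
    if len(groups) == 2:
        a, b = groups
        normal = all(stats.shapiro(g).pvalue > normality_alpha for g in groups)
        if normal:
            equal_var = stats.levene(a, b).pvalue > normality_alpha
            if equal_var:
                res = stats.ttest_ind(a, b)
                return GroupComparison("t", float(res.statistic), float(res.pvalue))
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison("mann_whitney", float(res.statistic), float(res.pvalue))
    res = stats.kruskal(*groups)
    return GroupComparison("kruskal_wallis", float(res.statistic), float(res.pvalue))


def _condition_for_detection(signal: ForceSignal) -> ForceSignal:
    # Local import: preprocess imports synthetic, not pcff, so no cycle.
    from .preprocess import moving_average, wavelet_denoise

    return moving_average(wavelet_denoise(signal), 3)


def dataset_pcff(
    dataset: LabeledDataset,
    expected_rate_bpm: float = 90.0,
    condition_detection: bool = True,
) -> dict:
    """Per-condition PCFF samples and summaries for a labeled dataset.

    By default each trial is denoised and smoothed for peak localisation
    (heights are still measured on the trial itself; see
    :func:`extract_pulse_summary`).  Returns a mapping condition name ->
    dict with the per-trial mean PCFF array, its group mean, and the mean
    estimated pulse rate.
    """
    out: dict[str, dict] = {}
    for c, name in enumerate(dataset.class_names):
        idx = np.flatnonzero(dataset.labels == c)
        values, rates = [], []
        for i in idx:
            sig = dataset.sequences[i]
            det = _condition_for_detection(sig) if condition_detection else None
            summary = extract_pulse_summary(
                sig, expected_rate_bpm, detection_signal=det
            )
            values.append(summary.mean_pcff)
            if summary.pulse_rate_bpm > 0:
                rates.append(summary.pulse_rate_bpm)
        values = np.asarray(values)
        out[name] = {
            "pcff": values,
            "mean_pcff": float(np.mean(values)),
            "n": int(values.size),
            "mean_pulse_rate_bpm": float(np.mean(rates)) if rates else 0.0,
        }
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def write_pcff_report(dataset: LabeledDataset, path) -> Path:
    """Write a per-condition PCFF comparison table as CSV.

    One row per condition (n, mean PCFF) and one per condition pair
    (test name, statistic, p-value, significance marker).
    """
    stats_by_cond = dataset_pcff(dataset)
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["condition", "n", "mean_pcff_n"])
        for name, s in stats_by_cond.items():
            w.writerow([name, s["n"], f"{s['mean_pcff']:.4f}"])
        w.writerow([])
        w.writerow(["group_a", "group_b", "test", "statistic", "p_value", "marker"])
        names = list(stats_by_cond)
        for a, b in combinations(names, 2):
            cmpres = compare_groups(
                [stats_by_cond[a]["pcff"], stats_by_cond[b]["pcff"]]
            )
            w.writerow(
                [
                    a,
                    b,
                    cmpres.test_name,
                    f"{cmpres.statistic:.4f}",
                    f"{cmpres.p_value:.3e}",
                    _stars(cmpres.p_value),
                ]
            )
    return path
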