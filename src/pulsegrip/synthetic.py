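"""Synthetic pulsatile gripping-force trials for vessel-identification work.

A peristaltic pump driving fluid through a clamped vessel produces a
pulsatile gripping force on top of a static clamp force.  Each roller pass
generates one pressure pulse, so a pump at 30 rev/min with three rollers
yields ~90 pulses/min, i.e. a simulated heart rate of ~1.5 Hz.  A trial is a
steady 15 s hold of the grasper during which the force sensor records

    f(t) = baseline + a * pulse_train(t) + noise,

where ``a`` is the per-trial peak amplitude (the peak clamping force
fluctuation, PCFF, the condition should produce), ``pulse_train`` is a
periodic asymmetric pulse with unit peak (fast rise to 30% of the period,
slower decay), and ``noise`` is white sensor noise.

Presets encode six vessel-model tasks (three silicone phantoms, three
ex-vivo porcine models); each condition's ``pulse_amplitude`` is the group
mean PCFF reported for it, so downstream peak statistics and classifiers can
be exercised against known ground truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "VesselModelSpec",
    "ForceSignal",
    "LabeledDataset",
    "TASK_CONDITIONS",
    "make_preset",
    "pulse_waveform",
    "simulate_grip_trial",
    "generate_dataset",
    "write_force_csv",
    "read_force_csv",
    "write_dataset",
    "read_dataset",
]

# Defaults for the simulated protocol.  The pump setting (30 rev/min x 3
# rollers) fixes the pulse rate; hold duration matches the 15 s steady grasp;
# baseline clamp force, trial-to-trial amplitude CV and sensor noise are
# generator choices (see docs/methods.md).
DEFAULT_PULSE_RATE_BPM = 90.0
DEFAULT_HOLD_DURATION_S = 15.0
DEFAULT_BASELINE_FORCE_N = 0.5
DEFAULT_AMPLITUDE_CV = 0.15
DEFAULT_NOISE_SD_N = 0.003
DEFAULT_FS_HZ = 100.0

# Pulse shape: asymmetric super-Gaussian exp(-(dphi/w)^4) peaking at 30% of
# the period, with a faster rise (w=0.12 cycles) than decay (w=0.20 cycles).
# The quartic exponent gives a blunt peak (sample-grid and smoothing
# insensitive) yet tails that hug zero over most of the cycle, so the signal
# median tracks the clamp baseline to ~0.3% of the pulse amplitude.
PULSE_PEAK_PHASE = 0.3
PULSE_RISE_SCALE = 0.12
PULSE_DECAY_SCALE = 0.20


@dataclass(frozen=True)
class VesselModelSpec:
    """Generator preset for one vessel-model condition."""

    model_id: str
    condition_label: str
    pulse_amplitude: float  # N; the group-mean PCFF this condition produces
    baseline_force: float = DEFAULT_BASELINE_FORCE_N  # N, static clamp
    pulse_rate: float = DEFAULT_PULSE_RATE_BPM  # pulses/min
    amplitude_cv: float = DEFAULT_AMPLITUDE_CV  # trial-to-trial CV
    noise_sd: float = DEFAULT_NOISE_SD_N  # N, white sensor noise
    hold_duration: float = DEFAULT_HOLD_DURATION_S  # s
    class_index: int = 0

    def __post_init__(self) -> None:
        if not self.pulse_amplitude > 0:
            raise ValueError("pulse_amplitude must be > 0")
        if not self.pulse_rate > 0:
            raise ValueError("pulse_rate must be > 0")
        if not 0 <= self.amplitude_cv < 1:
            raise ValueError("amplitude_cv must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.hold_duration > 0:
            raise ValueError("hold_duration must be > 0")


@dataclass
class ForceSignal:
    """Uniformly sampled gripping-force time series in newtons."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class LabeledDataset:
    """Sequences with class labels and an optional train/val/test split."""

    sequences: list[ForceSignal]
    labels: np.ndarray
    class_names: list[str]
    split: list[str] | None = None
    seed: int | None = None
    trial_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences must have equal length")
        if self.labels.size and self.labels.max() >= len(self.class_names):
            raise ValueError("label index exceeds class_names")
        if self.split is not None and len(self.split) != len(self.sequences):
            raise ValueError("split must assign every sequence")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def indices(self, part: str) -> np.ndarray:
        if self.split is None:
            raise ValueError("dataset has no split; run split_dataset first")
        return np.flatnonzero(np.asarray(self.split) == part)


# Condition tables: (label, group-mean PCFF in N), in printed order.  Labels
# are the hardness (Shore A) of the silicone vessel (phantom I), thickness of
# the surrounding silicone tissue (phantom II), hardness of the surrounding
# tissue (phantom III), vessel type (porcine I), adipose cover thickness
# (porcine II) and cover tissue type (porcine III).
TASK_CONDITIONS: dict[str, list[tuple[str, float]]] = {
    "phantom_I": [("20A", 0.162), ("30A", 0.130), ("40A", 0.010)],
    "phantom_II": [
        ("0.5mm", 0.223),
        ("1.0mm", 0.172),
        ("1.5mm", 0.141),
        ("2.0mm", 0.081),
        ("2.5mm", 0.050),
        ("3.0mm", 0.026),
    ],
    "phantom_III": [("10A", 0.141), ("20A", 0.100), ("30A", 0.058)],
    "porcine_I": [("artery", 0.047), ("vein", 0.022)],
    "porcine_II": [("1.0mm", 0.122), ("2.0mm", 0.066), ("3.0mm", 0.046)],
    "porcine_III": [("adipose", 0.059), ("muscle", 0.032)],
}


def make_preset(model_id: str, condition_label: str, **overrides) -> VesselModelSpec:
    """Return the generator preset for one vessel-model condition.

    ``pulse_amplitude`` equals the group-mean PCFF for that condition;
    protocol defaults (90 pulses/min, 15 s hold) and generator defaults
    (amplitude CV 0.15, noise sd 0.003 N) may be overridden by keyword.
    """
    if model_id not in TASK_CONDITIONS:
        raise KeyError(
            f"unknown model_id {model_id!r}; valid: {sorted(TASK_CONDITIONS)}"
        )
    conditions = TASK_CONDITIONS[model_id]
    labels = [label for label, _ in conditions]
    if condition_label not in labels:
        raise KeyError(
            f"unknown condition {condition_label!r} for {model_id}; "
            f"valid: {labels}"
        )
    idx = labels.index(condition_label)
    spec = VesselModelSpec(
        model_id=model_id,
        condition_label=condition_label,
        pulse_amplitude=conditions[idx][1],
        class_index=idx,
    )
    return replace(spec, **overrides) if overrides else spec


def pulse_waveform(phase: np.ndarray) -> np.ndarray:
    """Unit-peak asymmetric pulse evaluated at phase in [0, 1) cycles.

    Super-Gaussian exp(-(dphi/w)^4) around the peak at
    ``PULSE_PEAK_PHASE``, rising faster (scale ``PULSE_RISE_SCALE``) than it
    decays (scale ``PULSE_DECAY_SCALE``); effectively zero for most of the
    cycle.  The peak value is exactly 1 at phase == PULSE_PEAK_PHASE.
    """
    phi = np.mod(np.asarray(phase, dtype=float), 1.0)
    d = phi - PULSE_PEAK_PHASE
    w = np.where(d < 0, PULSE_RISE_SCALE, PULSE_DECAY_SCALE)
    return np.exp(-((d / w) ** 4))


def simulate_grip_trial(
    spec: VesselModelSpec, fs: float = DEFAULT_FS_HZ, seed=0
) -> ForceSignal:
    """Simulate one steady-hold gripping trial.

    The per-trial pulse amplitude is drawn from a normal distribution with
    mean ``spec.pulse_amplitude`` and coefficient of variation
    ``spec.amplitude_cv`` (truncated to stay positive); the pulse train gets
    a uniform random phase; white noise with sd ``spec.noise_sd`` is added.
    Deterministic for a fixed seed.
    """
    min_fs = 10.0 * spec.pulse_rate / 60.0
    if fs < min_fs:
        raise ValueError(
            f"fs={fs} Hz cannot resolve {spec.pulse_rate}/min pulses; "
            f"need fs >= {min_fs} Hz"
        )
    rng = np.random.default_rng(seed)
    amp = float(
        rng.normal(spec.pulse_amplitude, spec.amplitude_cv * spec.pulse_amplitude)
    )
    amp = max(amp, 0.05 * spec.pulse_amplitude)  # keep the pulse physical
    # Random phase, quantised so one sample lands exactly on a pulse peak
    # (the unit-peak construction is then exact under sampling).
    cycles_per_s = spec.pulse_rate / 60.0
    n_period = max(1, int(np.ceil(fs / cycles_per_s)))
    i0 = int(rng.integers(0, n_period))
    phase0 = PULSE_PEAK_PHASE - (i0 / fs) * cycles_per_s
    n = int(round(spec.hold_duration * fs))
    t = np.arange(n) / fs
    phase = t * cycles_per_s + phase0
    samples = spec.baseline_force + amp * pulse_waveform(phase)
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, size=n)
    return ForceSignal(samples=samples, fs=fs)


def _trial_seed(master_seed: int, class_index: int, trial_index: int) -> int:
    """Deterministic, well-separated per-trial seed below 2**31."""
    ss = np.random.SeedSequence((int(master_seed), class_index, trial_index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(
    task_id: str,
    n_per_condition: int,
    fs: float = DEFAULT_FS_HZ,
    seed: int = 0,
    **preset_overrides,
) -> LabeledDataset:
    """Generate a labeled dataset for one of the six classification tasks.

    One sequence per trial per condition; labels follow the printed condition
    order of the task's comparison table.  Per-trial seeds are derived
    deterministically from the master seed.
    """
    if task_id not in TASK_CONDITIONS:
        raise KeyError(
            f"unknown task {task_id!r}; valid: {sorted(TASK_CONDITIONS)}"
        )
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    sequences: list[ForceSignal] = []
    labels: list[int] = []
    trial_seeds: list[int] = []
    class_names = [label for label, _ in TASK_CONDITIONS[task_id]]
    for ci, label in enumerate(class_names):
        spec = make_preset(task_id, label, **preset_overrides)
        for ti in range(n_per_condition):
            s = _trial_seed(seed, ci, ti)
            sequences.append(simulate_grip_trial(spec, fs=fs, seed=s))
            labels.append(ci)
            trial_seeds.append(s)
    return LabeledDataset(
        sequences=sequences,
        labels=np.asarray(labels),
        class_names=class_names,
        seed=int(seed),
        trial_seeds=trial_seeds,
    )


# ---------------------------------------------------------------------------
# File I/O: two-column CSV per signal, JSON manifest per dataset.

def write_force_csv(signal: ForceSignal, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "force_n"])
        for t, x in zip(signal.times, signal.samples):
            w.writerow([f"{t:.6f}", f"{x:.9f}"])


def read_force_csv(path) -> ForceSignal:
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = np.asarray(data["time_s"], dtype=float)
    x = np.asarray(data["force_n"], dtype=float)
    if t.size < 2:
        raise ValueError(f"{path} holds fewer than 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ForceSignal(samples=x, fs=fs, t0=float(t[0]))


def write_dataset(dataset: LabeledDataset, outdir) -> Path:
    """Write each sequence as CSV plus a JSON manifest; return manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (sig, label) in enumerate(zip(dataset.sequences, dataset.labels)):
        fname = f"trial_{i:04d}.csv"
        write_force_csv(sig, outdir / fname)
        entries.append(
            {
                "file": fname,
                "label": int(label),
                "class_name": dataset.class_names[int(label)],
                "split": dataset.split[i] if dataset.split else None,
                "seed": dataset.trial_seeds[i] if dataset.trial_seeds else None,
            }
        )
    manifest = {
        "class_names": dataset.class_names,
        "seed": dataset.seed,
        "sequences": entries,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_dataset(manifest_path) -> LabeledDataset:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    entries = manifest["sequences"]
    sequences = [read_force_csv(root / e["file"]) for e in entries]
    labels = np.asarray([e["label"] for e in entries])
    split = [e.get("split") for e in entries]
    has_split = all(s is not None for s in split) and len(split) > 0
    return LabeledDataset(
        sequences=sequences,
        labels=labels,
        class_names=list(manifest["class_names"]),
        split=split if has_split else None,
        seed=manifest.get("seed"),
        trial_seeds=[e.get("seed") for e in entries],
    )
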