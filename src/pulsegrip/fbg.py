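"""Fiber Bragg grating (FBG) force-sensor model.

An FBG reflects a narrow band centred at the Bragg wavelength
``lambda_B = 2 * n_eff * Lambda`` (effective index times grating period).
Force applied to the grating strains it and shifts the reflected wavelength
linearly:

    d_lambda_B = 2 * n_eff * Lambda * (1 + P_e) * eta * F = sensitivity * F,

with ``P_e`` the photo-elastic coefficient and ``eta`` the force-to-strain
transfer factor.  Only the lumped slope matters for interrogation, so the
model is constructed from a calibration ``sensitivity`` in nm/N (0.082 nm/N
for the grasper-tip sensor this package emulates); the four physical
constants are optional and, when all given, validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ForceSignal

__all__ = [
    "DEFAULT_SENSITIVITY_NM_PER_N",
    "FBGSensorModel",
    "WavelengthTrace",
    "bragg_wavelength",
    "force_to_shift",
    "shift_to_force",
    "interrogate",
    "trace_to_force",
]

DEFAULT_SENSITIVITY_NM_PER_N = 0.082
DEFAULT_BASE_WAVELENGTH_NM = 1550.0  # telecom C band; metadata only


def bragg_wavelength(n_eff: float, grating_period_nm: float) -> float:
    """Bragg wavelength 2 * n_eff * Lambda in nm."""
    if not n_eff > 0 or not grating_period_nm > 0:
        raise ValueError("n_eff and grating_period_nm must be > 0")
    return 2.0 * n_eff * grating_period_nm


@dataclass(frozen=True)
class FBGSensorModel:
    """Lumped linear FBG force sensor: shift = sensitivity * force."""

    sensitivity: float = DEFAULT_SENSITIVITY_NM_PER_N  # nm/N
    n_eff: float | None = None
    grating_period: float | None = None  # nm
    photo_elastic: float | None = None
    force_to_strain: float | None = None

    def __post_init__(self) -> None:
        if not self.sensitivity > 0:
            raise ValueError("sensitivity must be > 0")
        consts = (
            self.n_eff,
            self.grating_period,
            self.photo_elastic,
            self.force_to_strain,
        )
        if all(c is not None for c in consts):
            implied = (
                2.0
                * self.n_eff
                * self.grating_period
                * (1.0 + self.photo_elastic)
                * self.force_to_strain
            )
            if abs(implied - self.sensitivity) > 1e-9 * abs(self.sensitivity):
                raise ValueError(
                    "physical constants imply sensitivity "
                    f"{implied:.6g} nm/N, inconsistent with "
                    f"{self.sensitivity:.6g} nm/N"
                )


@dataclass
class WavelengthTrace:
    """Bragg wavelength-shift time series in nm."""

    shifts: np.ndarray
    fs: float
    base_wavelength: float = DEFAULT_BASE_WAVELENGTH_NM

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if not self.base_wavelength > 0:
            raise ValueError("base_wavelength must be > 0")


def force_to_shift(force, model: FBGSensorModel):
    """Wavelength shift in nm for a force (N); linear and sign-preserving."""
    force = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(force)):
        raise ValueError("force must be finite")
    out = model.sensitivity * force
    return float(out) if out.ndim == 0 else out


def shift_to_force(delta_lambda, model: FBGSensorModel):
    """Inverse of :func:`force_to_shift` (force in N for a shift in nm)."""
    if not model.sensitivity > 0:
        raise ValueError("sensitivity must be > 0")
    delta_lambda = np.asarray(delta_lambda, dtype=float)
    out = delta_lambda / model.sensitivity
    return float(out) if out.ndim == 0 else out


def interrogate(
    signal: ForceSignal,
    model: FBGSensorModel,
    wavelength_noise_sd: float = 0.0,
    seed=0,
) -> WavelengthTrace:
    """Render a force signal as the interrogator's wavelength-shift trace.

    Elementwise force-to-shift conversion plus optional white wavelength
    noise (sd in nm); sampling rate preserved, reproducible per seed.
    """
    shifts = force_to_shift(signal.samples, model)
    if wavelength_noise_sd > 0:
        rng = np.random.default_rng(seed)
        shifts = shifts + rng.normal(0.0, wavelength_noise_sd, size=shifts.size)
    return WavelengthTrace(shifts=shifts, fs=signal.fs)


def trace_to_force(trace: WavelengthTrace, model: FBGSensorModel) -> ForceSignal:
    """Demodulate a wavelength trace back to a force signal."""
    return ForceSignal(samples=shift_to_force(trace.shifts, model), fs=trace.fs)


def write_trace_csv(trace: WavelengthTrace, path) -> None:
    """Write a wavelength-shift trace as two-column CSV."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "delta_lambda_nm"])
        for i, s in enumerate(trace.shifts):
            w.writerow([f"{i / trace.fs:.6f}", f"{s:.9f}"])
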