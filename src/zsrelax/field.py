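"""Sample geometry, static-field inhomogeneity, and ZS slice selection.

The sample is a column of length ``coil_length_cm`` along z, discretized
into ``n_z`` equally weighted isochromats.  Field inhomogeneity is a linear
frequency ramp ``inhom_slope_hz_per_cm * z`` by default (matching a
deshimmed z1 shim); an arbitrary profile callable can be supplied instead.

Slice selection follows the Zangger-Sterk scheme: under a weak z gradient
G4 the resonance frequency becomes position dependent, so a frequency
selective pulse addresses only the thin slice where a given site is on
resonance.  Coherence-selection gradients are treated as an ideal pathway
filter and are not simulated explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional

import numpy as np

__all__ = [
    "FieldModel",
    "SlicePulse",
    "SliceGeometry",
    "z_grid",
    "inhomogeneity_offset",
    "slice_geometry",
]


@dataclass
class FieldModel:
    """Spectrometer field, sample geometry, and ZS gradient.

    Parameters
    ----------
    spectrometer_mhz : float
        Proton carrier frequency in MHz (default 500).
    coil_length_cm : float
        Effective RF-coil / sample length along z (default 1.5 cm).
    n_z : int
        Number of z isochromats (>= 1); a convergence knob, not physics.
    inhom_slope_hz_per_cm : float
        Linear field-inhomogeneity coefficient.  The full-sample frequency
        spread is ``slope * coil_length_cm``.
    gamma_hz_per_gauss : float
        Gyromagnetic conversion for 1H (default 4257.7 Hz/G).
    g4_gauss_per_cm : float
        Weak ZS slice-selection gradient amplitude (>= 0).
    carrier_ppm : float
        Transmitter position; offsets in the simulated FID (and slice
        positions under G4) are measured from here.  Place it mid-spectrum
        so all sites fall inside the +/- sw/2 detection window.
    inhom_profile : callable, optional
        Arbitrary offset profile z (cm) -> Hz; overrides the linear slope.
    """

    spectrometer_mhz: float = 500.0
    coil_length_cm: float = 1.5
    n_z: int = 101
    inhom_slope_hz_per_cm: float = 0.0
    gamma_hz_per_gauss: float = 4257.7
    g4_gauss_per_cm: float = 0.56
    carrier_ppm: float = 0.0
    inhom_profile: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if not self.coil_length_cm > 0:
            raise ValueError("coil_length_cm must be > 0")
        if int(self.n_z) != self.n_z or self.n_z < 1:
            raise ValueError("n_z must be an integer >= 1")
        if self.g4_gauss_per_cm < 0:
            raise ValueError("g4_gauss_per_cm must be >= 0")
        if not self.spectrometer_mhz > 0:
            raise ValueError("spectrometer_mhz must be > 0")


@dataclass
class SlicePulse:
    """Frequency-selective inversion pulse used for slice selection.

    The shaped pulse is idealized as a top-hat inversion band of width
    ``bandwidth_factor / duration_s`` (Hz).  The default factor 0.84 is the
    Gaussian-envelope FWHM heuristic; the convention is configurable because
    effective bandwidth definitions vary between instruments.
    """

    duration_s: float = 0.0162
    bandwidth_factor: float = 0.84

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not self.bandwidth_factor > 0:
            raise ValueError("bandwidth_factor must be > 0")

    @property
    def bandwidth_hz(self) -> float:
        return self.bandwidth_factor / self.duration_s


class SliceGeometry(NamedTuple):
    center_cm: float
    width_cm: float
    fraction: float


def z_grid(fieldmodel: FieldModel) -> np.ndarray:
    """Isochromat z positions: n_z points spanning [-L/2, +L/2] inclusive."""
    L = fieldmodel.coil_length_cm
    if fieldmodel.n_z == 1:
        return np.array([0.0])
    return np.linspace(-L / 2.0, L / 2.0, fieldmodel.n_z)


def inhomogeneity_offset(fieldmodel: FieldModel, z) -> np.ndarray | float:
    """Static-field frequency offset (Hz) at position(s) z within the sample."""
    z_arr = np.asarray(z, dtype=float)
    half = fieldmodel.coil_length_cm / 2.0
    if np.any(np.abs(z_arr) > half * (1 + 1e-12)):
        raise ValueError(f"z outside the sample (|z| <= {half} cm)")
    if fieldmodel.inhom_profile is not None:
        out = np.vectorize(fieldmodel.inhom_profile, otypes=[float])(z_arr)
    else:
        out = fieldmodel.inhom_slope_hz_per_cm * z_arr
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def slice_geometry(
    fieldmodel: FieldModel, pulse: SlicePulse, site_offset_hz: float
) -> SliceGeometry:
    """Position, thickness, and volume fraction of a site's ZS slice.

    Under gradient G4 a site with offset nu (Hz from the carrier) is on
    resonance at ``z = nu / (gamma * G4)``; the selective pulse inverts a
    band of width ``BW / (gamma * G4)`` cm around it.  The center is
    clipped into the sample, the fraction is slice width over sample
    length, capped at 1.
    """
    g4 = fieldmodel.g4_gauss_per_cm
    if g4 <= 0:
        raise ValueError("slice selection requires g4_gauss_per_cm > 0")
    hz_per_cm = fieldmodel.gamma_hz_per_gauss * g4
    L = fieldmodel.coil_length_cm
    center = float(np.clip(site_offset_hz / hz_per_cm, -L / 2.0, L / 2.0))
    width = pulse.bandwidth_hz / hz_per_cm
    fraction = min(width, L) / L
    return SliceGeometry(center_cm=center, width_cm=width, fraction=fraction)


def slice_in_sample(fieldmodel: FieldModel, pulse: SlicePulse, site_offset_hz: float) -> bool:
    """Whether any part of the (unclipped) slice overlaps the sample column."""
    hz_per_cm = fieldmodel.gamma_hz_per_gauss * fieldmodel.g4_gauss_per_cm
    c0 = site_offset_hz / hz_per_cm
    half_w = 0.5 * pulse.bandwidth_hz / hz_per_cm
    half_L = fieldmodel.coil_length_cm / 2.0
    return (c0 - half_w) <= half_L and (c0 + half_w) >= -half_L
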