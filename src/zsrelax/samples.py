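"""Built-in demo spin systems, acquisition bundles, and the noise model.

Three samples of increasing complexity are provided: 1-bromobutane (a
simple four-site coupled chain), quinine (a crowded 16-proton aromatic /
aliphatic system), and azithromycin (a macrolide with dozens of sites).
Relaxation times and chemical shifts marked ``"reported"`` in the fixture
metadata are experimentally measured values used as simulation ground
truth; values marked ``"invented"`` are plausible placeholders (notably
all J-coupling networks for quinine/azithromycin, which default to zero so
the relaxation tables are exercised on clean singlets).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import FieldModel, SlicePulse
from .sequence import CPMGScheme, IRScheme, ZSAcquisition
from .spin_system import Coupling, Spin, SpinSystem

__all__ = [
    "NoiseModel",
    "add_noise",
    "bromobutane_like",
    "quinine_like",
    "azithromycin_like",
    "SchemeBundle",
    "reference_schemes",
]


@dataclass
class NoiseModel:
    """Additive complex Gaussian noise, relative to the series maximum.

    ``sigma`` is the per-point standard deviation on each of the real and
    imaginary channels, in units of max|fid| over the series.  The same
    seed always reproduces the same realization.
    """

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def add_noise(fids: np.ndarray, model: NoiseModel) -> np.ndarray:
    """Return a noisy copy of a FID (1D) or FID series (2D)."""
    fids = np.asarray(fids, dtype=complex)
    if model.sigma == 0:
        return fids.copy()
    scale = model.sigma * np.max(np.abs(fids))
    rng = np.random.default_rng(model.seed)
    noise = rng.normal(scale=scale, size=fids.shape) + 1j * rng.normal(
        scale=scale, size=fids.shape
    )
    return fids + noise


def bromobutane_like() -> SpinSystem:
    """Four-site coupled chain emulating 1-bromobutane (CH2Br-CH2-CH2-CH3).

    The 3.42 ppm methylene carries the reported T1 = 4.99 s / T2 = 2.77 s;
    the remaining shifts and relaxation times, and the 7 Hz vicinal
    couplings along the chain, are invented but chemically plausible.
    """
    spins = [
        Spin("CH2Br", 3.42, 4.99, 2.77, n_equivalent=2),
        Spin("CH2_b", 1.85, 4.20, 2.40, n_equivalent=2),
        Spin("CH2_c", 1.45, 4.50, 2.60, n_equivalent=2),
        Spin("CH3", 0.92, 5.50, 3.00, n_equivalent=3),
    ]
    couplings = [
        Coupling("CH2Br", "CH2_b", 7.0),
        Coupling("CH2_b", "CH2_c", 7.0),
        Coupling("CH2_c", "CH3", 7.0),
    ]
    provenance = {
        "CH2Br": {"shift_ppm": "reported", "t1_s": "reported", "t2_s": "reported"},
        "CH2_b": {"shift_ppm": "invented", "t1_s": "invented", "t2_s": "invented"},
        "CH2_c": {"shift_ppm": "invented", "t1_s": "invented", "t2_s": "invented"},
        "CH3": {"shift_ppm": "invented", "t1_s": "invented", "t2_s": "invented"},
        "couplings": "invented",
    }
    return SpinSystem(spins, couplings, name="bromobutane", metadata={"provenance": provenance})


# (label, shift_ppm, T1_s, T2_s) -- real-time well-shimmed measurements.
_QUININE_SITES = [
    ("H3", 7.60, 1.69, 0.89),
    ("H2", 7.06, 1.84, 1.08),
    ("H4", 6.65, 1.05, 0.67),
    ("H1_5", 6.45, 1.36, 0.87),
    ("H15", 4.92, 1.45, 0.73),
    ("H7", 4.70, 0.54, 0.12),
    ("H16a", 4.15, 1.24, 0.73),
    ("H16b", 4.11, 1.30, 0.71),
    ("H6", 3.10, 0.84, 0.62),
    ("H8", 2.68, 0.38, 0.22),
    ("H13", 2.29, 0.57, 0.31),
    ("H12", 2.26, 0.43, 0.28),
    ("H14", 1.83, 0.40, 0.26),
    ("H10", 1.46, 0.83, 0.36),
    ("H9a", 1.00, 0.66, 0.31),
    ("H9b", 0.96, 0.42, 0.26),
    ("H11a", 0.94, 0.42, 0.26),
    ("H11b", 0.69, 0.39, 0.24),
]

# Conventional-experiment values where they were measured separately.
_QUININE_CONVENTIONAL = {"H6": (0.84, 0.58), "H7": (0.52, 0.16)}


def quinine_like(variant: str = "realtime", couplings: list[Coupling] | None = None) -> SpinSystem:
    """Crowded 16-proton system emulating quinine, singlet-mode by default.

    ``variant="realtime"`` (default) uses the real-time well-shimmed
    relaxation measurements as ground truth; ``variant="conventional"``
    substitutes the conventional-experiment values for the sites where a
    separate conventional measurement exists (protons 6 and 7).  All J
    couplings default to zero (the relaxation tables are measured on
    decoupled singlets); pass ``couplings`` for a coupled variant.
    """
    if variant not in ("realtime", "conventional"):
        raise ValueError("variant must be 'realtime' or 'conventional'")
    spins = []
    provenance = {}
    for label, shift, t1, t2 in _QUININE_SITES:
        if variant == "conventional" and label in _QUININE_CONVENTIONAL:
            t1, t2 = _QUININE_CONVENTIONAL[label]
        n_eq = 2 if label == "H1_5" else 1
        spins.append(Spin(label, shift, t1, t2, n_equivalent=n_eq))
        provenance[label] = {"shift_ppm": "reported", "t1_s": "reported", "t2_s": "reported"}
    return SpinSystem(
        spins,
        couplings or [],
        name=f"quinine-{variant}",
        metadata={"provenance": provenance, "variant": variant},
    )


# (label, shift_ppm, T1_s, T2_s) -- real-time measurements under the
# unshimmed field; starred sites also have conventional well-shimmed values.
_AZITHROMYCIN_SITES = [
    ("H2", 2.76, 0.62, 0.40),
    ("H3", 4.30, 0.48, 0.33),
    ("H4", 1.99, 0.39, 0.30),
    ("H5", 3.65, 0.41, 0.30),
    ("H7", 1.80, 0.37, 0.21),
    ("H9", 2.55, 0.28, 0.22),
    ("H10", 2.70, 0.39, 0.26),
    ("H11", 3.70, 0.37, 0.23),
    ("H17", 1.05, 0.36, 0.29),
    ("H19", 0.92, 0.68, 0.45),
    ("H22", 1.09, 0.33, 0.28),
    ("H1p", 4.47, 0.44, 0.31),
    ("H2p", 3.23, 0.70, 0.33),
    ("H3p", 2.48, 0.51, 0.26),
    ("H4p", 1.69, 0.36, 0.22),
    ("H5p", 3.52, 0.51, 0.29),
    ("H6p", 1.21, 0.40, 0.32),
    ("H7p", 2.32, 0.43, 0.31),
    ("H8p", 2.30, 0.41, 0.28),
    ("H2pp", 2.39, 0.36, 0.26),
    ("H4pp", 2.07, 0.79, 0.34),
    ("H5pp", 4.12, 0.49, 0.31),
    ("H6pp", 1.34, 0.45, 0.32),
    ("H7pp", 1.27, 0.46, 0.32),
    ("H8pp", 3.34, 0.67, 0.40),
]

_AZITHROMYCIN_CONVENTIONAL = {
    "H7p": (0.43, 0.32),
    "H8p": (0.41, 0.30),
    "H7pp": (0.45, 0.35),
    "H8pp": (0.66, 0.45),
}


def azithromycin_like(variant: str = "realtime") -> SpinSystem:
    """Macrolide-sized singlet system emulating azithromycin (25 sites)."""
    if variant not in ("realtime", "conventional"):
        raise ValueError("variant must be 'realtime' or 'conventional'")
    spins = []
    provenance = {}
    for label, shift, t1, t2 in _AZITHROMYCIN_SITES:
        if variant == "conventional" and label in _AZITHROMYCIN_CONVENTIONAL:
            t1, t2 = _AZITHROMYCIN_CONVENTIONAL[label]
        spins.append(Spin(label, shift, t1, t2))
        provenance[label] = {"shift_ppm": "reported", "t1_s": "reported", "t2_s": "reported"}
    return SpinSystem(
        spins, [], name=f"azithromycin-{variant}",
        metadata={"provenance": provenance, "variant": variant},
    )


@dataclass
class SchemeBundle:
    """Acquisition + relaxation parameter set for one demo sample."""

    name: str
    ir: IRScheme
    cpmg: CPMGScheme
    zs: ZSAcquisition
    pulse: SlicePulse
    field: FieldModel
    deshimmed_width_hz: float = 0.0
    system_factory: object = None

    def system(self) -> SpinSystem:
        return self.system_factory()

    def deshimmed_field(self, n_z: int | None = None) -> FieldModel:
        """Copy of the field model with the linear slope calibrated so the
        full-sample spread equals the deshimmed line width."""
        f = self.field
        return FieldModel(
            spectrometer_mhz=f.spectrometer_mhz,
            coil_length_cm=f.coil_length_cm,
            n_z=n_z or f.n_z,
            inhom_slope_hz_per_cm=self.deshimmed_width_hz / f.coil_length_cm,
            gamma_hz_per_gauss=f.gamma_hz_per_gauss,
            g4_gauss_per_cm=f.g4_gauss_per_cm,
            carrier_ppm=f.carrier_ppm,
        )


def reference_schemes() -> dict[str, SchemeBundle]:
    """The three demo acquisition bundles, matching the instrument settings
    the fixtures emulate (delay grids, chunk counts, gradients, pulses)."""
    bromobutane = SchemeBundle(
        name="bromobutane",
        ir=IRScheme([0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0]),
        cpmg=CPMGScheme([0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8], tau2_s=200e-6),
        zs=ZSAcquisition(n_chunks=40, spectral_width_hz=2000.0, chunk_duration_s=0.02),
        pulse=SlicePulse(duration_s=0.0162),
        field=FieldModel(
            spectrometer_mhz=500.0, coil_length_cm=1.5, g4_gauss_per_cm=0.56,
            carrier_ppm=2.2,
        ),
        deshimmed_width_hz=177.35,
        system_factory=bromobutane_like,
    )
    quinine = SchemeBundle(
        name="quinine",
        ir=IRScheme([0.04, 0.1, 0.32, 0.84, 1.6, 3.2, 5.0]),
        cpmg=CPMGScheme([0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64, 1.40], tau2_s=200e-6),
        zs=ZSAcquisition(n_chunks=30, spectral_width_hz=4000.0, chunk_duration_s=0.02),
        pulse=SlicePulse(duration_s=0.0166),
        field=FieldModel(
            spectrometer_mhz=500.0, coil_length_cm=1.5, g4_gauss_per_cm=0.47,
            carrier_ppm=4.0,
        ),
        deshimmed_width_hz=182.23,
        system_factory=quinine_like,
    )
    azithromycin = SchemeBundle(
        name="azithromycin",
        ir=IRScheme([0.0625, 0.125, 0.25, 0.5, 1.0, 2.5]),
        cpmg=CPMGScheme([0.01, 0.015, 0.05, 0.09, 0.15, 0.25, 0.4, 0.7], tau2_s=200e-6),
        zs=ZSAcquisition(n_chunks=30, spectral_width_hz=2000.0, chunk_duration_s=0.02),
        pulse=SlicePulse(duration_s=0.0171),
        field=FieldModel(
            spectrometer_mhz=500.0, coil_length_cm=1.5, g4_gauss_per_cm=0.56,
            carrier_ppm=2.7,
        ),
        deshimmed_width_hz=29.3,
        system_factory=azithromycin_like,
    )
    return {b.name: b for b in (bromobutane, quinine, azithromycin)}
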