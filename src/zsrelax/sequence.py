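"""Closed-form synthesis of conventional and real-time ZS pure-shift signals.

Two acquisition modes are generated on a shared complex time grid:

* **conventional** -- the full sample volume precesses freely; every site
  contributes its first-order multiplet, each line dephased by the
  z-inhomogeneity distribution and damped by T2.

* **zs** (real-time pure shift) -- the FID is acquired in ``n`` chunks with
  an instantaneous decoupling element (hard pi + slice-selective pi +
  gradients) between chunks.  The element inverts every spin outside the
  active slice, so J evolution is refocused at each chunk midpoint while
  the chemical-shift phase runs on undisturbed.  Each site therefore
  appears as a singlet at its shift, amplitude-modulated within each chunk
  by cos(pi J (t - t_mid))^n_partner, which is what produces the familiar
  chunking sidebands at multiples of 1/chunk_duration.  Only the thin
  slice selected for each site contributes, scaling the amplitude by the
  slice fraction and collapsing the inhomogeneity to its value at the
  slice center.

Relaxation-delay weighting (inversion recovery or CPMG echo train) enters
as a per-site scalar computed by :func:`ir_recovery_factor` /
:func:`cpmg_decay_factor`; the synthesis itself is deterministic and
noise-free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import FieldModel, SlicePulse, inhomogeneity_offset, slice_geometry, slice_in_sample, z_grid
from .spin_system import SpinSystem, multiplet_pattern, resonance_offset_hz

__all__ = [
    "IRScheme",
    "CPMGScheme",
    "ZSAcquisition",
    "RelaxationSeries",
    "ir_recovery_factor",
    "cpmg_decay_factor",
    "simulate_conventional_fid",
    "simulate_zs_pureshift_fid",
    "run_ir_experiment",
    "run_cpmg_experiment",
]


@dataclass
class IRScheme:
    """Inversion-recovery delay grid.

    ``inversion_efficiency`` generalizes the ideal factor
    ``1 - 2 exp(-tau/T1)``: an imperfect pi pulse inverts only a fraction
    ``w`` of the equilibrium magnetization, giving ``1 - (1+w) exp(-tau/T1)``.
    """

    tau1_list: list[float]
    inversion_efficiency: float = 1.0

    def __post_init__(self) -> None:
        taus = list(self.tau1_list)
        if not taus:
            raise ValueError("tau1_list must be nonempty")
        if any(t <= 0 for t in taus):
            raise ValueError("all tau1 delays must be > 0")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("tau1_list must be strictly increasing")
        if not (0 < self.inversion_efficiency <= 1):
            raise ValueError("inversion_efficiency must be in (0, 1]")
        self.tau1_list = taus


@dataclass
class CPMGScheme:
    """CPMG echo-train delays: total spin-echo delays Delta = m * tau2."""

    delta_list: list[float]
    tau2_s: float = 200e-6

    def __post_init__(self) -> None:
        deltas = list(self.delta_list)
        if not deltas:
            raise ValueError("delta_list must be nonempty")
        if any(b <= a for a, b in zip(deltas, deltas[1:])):
            raise ValueError("delta_list must be strictly increasing")
        if not self.tau2_s > 0:
            raise ValueError("tau2_s must be > 0")
        for d in deltas:
            m = d / self.tau2_s
            if abs(m - round(m)) > 1e-9 * max(1.0, m):
                raise ValueError(
                    f"delta {d} s is not an integer multiple of tau2 = {self.tau2_s} s"
                )
        self.delta_list = deltas

    def echo_counts(self) -> list[int]:
        return [int(round(d / self.tau2_s)) for d in self.delta_list]


@dataclass
class ZSAcquisition:
    """Chunked real-time acquisition parameters.

    Total acquisition time is ``n_chunks * chunk_duration_s``; the first and
    last chunks are half-length so that the J-refocusing midpoints fall at
    t=0 and t=t_max.  ``per_element_loss`` is a multiplicative amplitude
    penalty per decoupling element (pulse imperfections, relaxation during
    the element); 1 means lossless.
    """

    n_chunks: int
    spectral_width_hz: float
    chunk_duration_s: float = 0.02
    per_element_loss: float = 1.0

    def __post_init__(self) -> None:
        if int(self.n_chunks) != self.n_chunks or self.n_chunks < 2:
            raise ValueError("n_chunks must be an integer >= 2")
        if not self.chunk_duration_s > 0:
            raise ValueError("chunk_duration_s must be > 0")
        if not self.spectral_width_hz > 0:
            raise ValueError("spectral_width_hz must be > 0")
        if not (0 < self.per_element_loss <= 1):
            raise ValueError("per_element_loss must be in (0, 1]")
        pts = self.chunk_duration_s * self.spectral_width_hz
        if abs(pts - round(pts)) > 1e-9 * max(1.0, pts):
            raise ValueError("dwell time must divide chunk_duration_s exactly")

    @property
    def total_time_s(self) -> float:
        return self.n_chunks * self.chunk_duration_s

    @property
    def n_points(self) -> int:
        return int(round(self.total_time_s * self.spectral_width_hz))


@dataclass
class RelaxationSeries:
    """Arrayed FIDs versus relaxation delay on a shared time grid."""

    delays: np.ndarray
    fids: np.ndarray  # shape (n_delays, n_points), complex
    mode: str  # "conventional" | "zs"
    experiment: str  # "IR" | "CPMG"
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.fids = np.asarray(self.fids, dtype=complex)
        if self.fids.ndim != 2 or len(self.delays) != self.fids.shape[0]:
            raise ValueError("need one FID per delay, all the same length")

    @property
    def spectral_width_hz(self) -> float:
        return float(self.metadata["spectral_width_hz"])

    @property
    def spectrometer_mhz(self) -> float:
        return float(self.metadata["spectrometer_mhz"])

    @property
    def carrier_ppm(self) -> float:
        return float(self.metadata.get("carrier_ppm", 0.0))


def ir_recovery_factor(tau1: float, t1_relax: float, efficiency: float = 1.0) -> float:
    """Longitudinal recovery weight ``1 - (1+w) exp(-tau1/T1)``.

    With perfect inversion (w=1) this is the textbook ``1 - 2 exp(-tau1/T1)``:
    -1 right after inversion, 0 at the null point tau1 = T1 ln 2, -> 1 at
    full recovery.
    """
    if not t1_relax > 0:
        raise ValueError("t1_relax must be > 0")
    if tau1 < 0:
        raise ValueError("tau1 must be >= 0")
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must be in (0, 1]")
    return 1.0 - (1.0 + efficiency) * math.exp(-tau1 / t1_relax)


def cpmg_decay_factor(delta: float, t2_relax: float) -> float:
    """Echo-train decay weight ``exp(-Delta/T2)``.

    Static offsets (chemical shift and field inhomogeneity) are refocused
    by the pi-pulse train, and J modulation is suppressed in the short
    interpulse limit tau2 << 1/J, so only T2 decay survives.
    """
    if not t2_relax > 0:
        raise ValueError("t2_relax must be > 0")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return math.exp(-delta / t2_relax)


def _as_weight_map(system: SpinSystem, weight) -> dict[str, float]:
    if isinstance(weight, dict):
        return {s.label: float(weight[s.label]) for s in system.spins}
    return {s.label: float(weight) for s in system.spins}


def _carrier_offset_hz(spin, fieldmodel: FieldModel) -> float:
    """Site offset in Hz relative to the transmitter (carrier_ppm)."""
    return resonance_offset_hz(spin, fieldmodel.spectrometer_mhz) - (
        fieldmodel.carrier_ppm * fieldmodel.spectrometer_mhz
    )


def simulate_conventional_fid(
    system: SpinSystem,
    fieldmodel: FieldModel,
    weight,
    duration: float,
    spectral_width: float,
) -> np.ndarray:
    """Full-volume multiplet FID.

    ``weight`` is a scalar or a per-site-label dict of relaxation factors.
    Every site contributes its multiplet lines, averaged over all z
    isochromats (each shifted by the local inhomogeneity offset), damped by
    its own T2.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if not spectral_width > 0:
        raise ValueError("spectral_width must be > 0")
    wmap = _as_weight_map(system, weight)
    n = int(round(duration * spectral_width))
    t = np.arange(n) / spectral_width
    zs = z_grid(fieldmodel)
    dz = np.asarray(inhomogeneity_offset(fieldmodel, zs), dtype=float).reshape(-1)
    fid = np.zeros(n, dtype=complex)
    for spin in system.spins:
        nu = _carrier_offset_hz(spin, fieldmodel)
        lines = multiplet_pattern(spin, system)
        offs = np.array([nu + lo for lo, _ in lines])
        amps = np.array([a for _, a in lines])
        # (n_lines * n_z) complex exponentials, equally weighted isochromats
        freqs = (offs[:, None] + dz[None, :]).ravel()
        w_lines = (amps[:, None] * np.ones_like(dz)[None, :]).ravel() / len(dz)
        phase = np.exp(2j * np.pi * np.outer(freqs, t))
        site_sig = w_lines @ phase
        fid += spin.n_equivalent * wmap[spin.label] * site_sig * np.exp(-t / spin.t2_s)
    return fid


def _chunk_index(t: np.ndarray, chunk: float, n_chunks: int) -> np.ndarray:
    """Index k of the chunk (with midpoint k*chunk) containing each time.

    Chunk 0 and chunk n are the half-length first/last chunks; boundaries at
    (k - 1/2) * chunk belong to the later chunk.
    """
    k = np.floor(t / chunk + 0.5).astype(int)
    return np.clip(k, 0, n_chunks)


def _site_pureshift_modulation(
    system: SpinSystem,
    spin_label: str,
    zs: ZSAcquisition,
) -> np.ndarray:
    """Unit-amplitude chunked J-modulation envelope for one site.

    Product over coupling partners of cos(pi J (t - t_mid))^n_partner with
    t_mid the midpoint of the chunk containing t, times the per-element
    amplitude loss.  Excludes chemical-shift phase, T2 decay, and slice
    scaling.
    """
    t = np.arange(zs.n_points) / zs.spectral_width_hz
    k = _chunk_index(t, zs.chunk_duration_s, zs.n_chunks)
    t_mid = k * zs.chunk_duration_s
    env = np.ones_like(t)
    for partner, j in system.partners_of(spin_label):
        if j == 0:
            continue
        env = env * np.cos(np.pi * j * (t - t_mid)) ** partner.n_equivalent
    if zs.per_element_loss < 1:
        env = env * zs.per_element_loss**k
    return env


def simulate_zs_pureshift_fid(
    system: SpinSystem,
    fieldmodel: FieldModel,
    zs: ZSAcquisition,
    pulse: SlicePulse,
    weight,
) -> np.ndarray:
    """Real-time ZS pure-shift FID (homodecoupled, slice-selected).

    Each site rings at its bare chemical shift (plus the inhomogeneity
    offset at its slice center), scaled by its slice fraction, with J
    evolution refocused at every chunk midpoint.  A site whose slice falls
    entirely outside the sample contributes nothing (warning).
    """
    wmap = _as_weight_map(system, weight)
    t = np.arange(zs.n_points) / zs.spectral_width_hz
    fid = np.zeros(zs.n_points, dtype=complex)
    for spin in system.spins:
        nu = _carrier_offset_hz(spin, fieldmodel)
        if not slice_in_sample(fieldmodel, pulse, nu):
            warnings.warn(
                f"site {spin.label!r} at {spin.shift_ppm} ppm: slice falls outside "
                "the sample; contributes zero signal",
                stacklevel=2,
            )
            continue
        geom = slice_geometry(fieldmodel, pulse, nu)
        nu_eff = nu + float(inhomogeneity_offset(fieldmodel, geom.center_cm))
        env = _site_pureshift_modulation(system, spin.label, zs)
        fid += (
            geom.fraction
            * spin.n_equivalent
            * wmap[spin.label]
            * env
            * np.exp((2j * np.pi * nu_eff - 1.0 / spin.t2_s) * t)
        )
    return fid


def _series_metadata(system, fieldmodel, mode, experiment, spectral_width, duration, extra):
    md = {
        "system": system.name,
        "mode": mode,
        "experiment": experiment,
        "spectral_width_hz": spectral_width,
        "duration_s": duration,
        "spectrometer_mhz": fieldmodel.spectrometer_mhz,
        "carrier_ppm": fieldmodel.carrier_ppm,
    }
    md.update(extra)
    return md


def _resolve_acq(mode, zs, pulse, duration, spectral_width):
    if mode == "zs":
        if zs is None:
            raise ValueError("zs acquisition parameters are required for mode='zs'")
        pulse = pulse if pulse is not None else SlicePulse()
        return zs, pulse, zs.total_time_s, zs.spectral_width_hz
    if mode == "conventional":
        # default to the ZS time grid so spectra are comparable bin-for-bin
        if duration is None:
            if zs is None:
                raise ValueError("duration (or a ZS acquisition) is required")
            duration = zs.total_time_s
        if spectral_width is None:
            if zs is None:
                raise ValueError("spectral_width (or a ZS acquisition) is required")
            spectral_width = zs.spectral_width_hz
        return zs, pulse, duration, spectral_width
    raise ValueError(f"unknown mode {mode!r}; expected 'conventional' or 'zs'")


def run_ir_experiment(
    system: SpinSystem,
    fieldmodel: FieldModel,
    scheme: IRScheme,
    mode: str = "zs",
    zs: ZSAcquisition | None = None,
    pulse: SlicePulse | None = None,
    duration: float | None = None,
    spectral_width: float | None = None,
) -> RelaxationSeries:
    """Arrayed inversion-recovery experiment: one FID per tau1 delay."""
    zs, pulse, duration, spectral_width = _resolve_acq(mode, zs, pulse, duration, spectral_width)
    fids = []
    for tau1 in scheme.tau1_list:
        weights = {
            s.label: ir_recovery_factor(tau1, s.t1_s, scheme.inversion_efficiency)
            for s in system.spins
        }
        if mode == "zs":
            fids.append(simulate_zs_pureshift_fid(system, fieldmodel, zs, pulse, weights))
        else:
            fids.append(simulate_conventional_fid(system, fieldmodel, weights, duration, spectral_width))
    md = _series_metadata(
        system, fieldmodel, mode, "IR", spectral_width, duration,
        {"inversion_efficiency": scheme.inversion_efficiency},
    )
    return RelaxationSeries(np.array(scheme.tau1_list), np.array(fids), mode, "IR", md)


def run_cpmg_experiment(
    system: SpinSystem,
    fieldmodel: FieldModel,
    scheme: CPMGScheme,
    mode: str = "zs",
    zs: ZSAcquisition | None = None,
    pulse: SlicePulse | None = None,
    duration: float | None = None,
    spectral_width: float | None = None,
) -> RelaxationSeries:
    """Arrayed CPMG experiment: one FID per total spin-echo delay Delta."""
    zs, pulse, duration, spectral_width = _resolve_acq(mode, zs, pulse, duration, spectral_width)
    fids = []
    for delta in scheme.delta_list:
        weights = {s.label: cpmg_decay_factor(delta, s.t2_s) for s in system.spins}
        if mode == "zs":
            fids.append(simulate_zs_pureshift_fid(system, fieldmodel, zs, pulse, weights))
        else:
            fids.append(simulate_conventional_fid(system, fieldmodel, weights, duration, spectral_width))
    md = _series_metadata(
        system, fieldmodel, mode, "CPMG", spectral_width, duration,
        {"tau2_s": scheme.tau2_s},
    )
    return RelaxationSeries(np.array(scheme.delta_list), np.array(fids), mode, "CPMG", md)
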