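"""Weakly coupled proton spin systems and first-order multiplet expansion.

A :class:`SpinSystem` collects proton sites (:class:`Spin`) and scalar
couplings (:class:`Coupling`) and can expand each site into its first-order
multiplet line list.  Only the weak-coupling (first-order) regime is
modelled: a coupling partner with ``n`` equivalent protons splits a site
into an ``n+1``-line binomial multiplet of spacing *J*, and patterns from
independent partners combine by convolution.  Second-order effects
(roofing, AB patterns) are out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spin",
    "Coupling",
    "SpinSystem",
    "WeakCouplingWarning",
    "resonance_offset_hz",
    "multiplet_pattern",
    "DEFAULT_SPECTROMETER_MHZ",
]

#: Default proton carrier frequency (MHz); a 500 MHz instrument.
DEFAULT_SPECTROMETER_MHZ = 500.0


class WeakCouplingWarning(UserWarning):
    """Emitted when a coupled pair violates the weak-coupling condition."""


@dataclass(frozen=True)
class Spin:
    """One proton site.

    Parameters
    ----------
    label : str
        Unique site name.
    shift_ppm : float
        Chemical shift relative to the 0-ppm carrier.
    t1_s : float
        Longitudinal relaxation time (s), > 0.
    t2_s : float
        Transverse relaxation time (s), > 0.  ``t1_s >= t2_s`` is *not*
        enforced; both merely have to be positive.
    n_equivalent : int
        Number of magnetically equivalent protons at the site (>= 1).
        Scales the site amplitude and the splitting it imposes on partners.
    """

    label: str
    shift_ppm: float
    t1_s: float
    t2_s: float
    n_equivalent: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift_ppm):
            raise ValueError(f"spin {self.label!r}: shift_ppm must be finite")
        if not (self.t1_s > 0 and math.isfinite(self.t1_s)):
            raise ValueError(f"spin {self.label!r}: t1_s must be positive")
        if not (self.t2_s > 0 and math.isfinite(self.t2_s)):
            raise ValueError(f"spin {self.label!r}: t2_s must be positive")
        if int(self.n_equivalent) != self.n_equivalent or self.n_equivalent < 1:
            raise ValueError(f"spin {self.label!r}: n_equivalent must be an integer >= 1")


@dataclass(frozen=True)
class Coupling:
    """Scalar (J) coupling between two sites, in Hz."""

    site_a: str
    site_b: str
    j_hz: float

    def __post_init__(self) -> None:
        if self.site_a == self.site_b:
            raise ValueError("coupling must join two distinct sites")
        if not (self.j_hz >= 0 and math.isfinite(self.j_hz)):
            raise ValueError("j_hz must be finite and >= 0")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.site_a, self.site_b))


@dataclass
class SpinSystem:
    """A named collection of spins and their scalar couplings.

    On construction every coupling label must resolve to a spin, each
    unordered pair may appear at most once, and the weak-coupling condition
    |Δν| >= 5·J is checked at the default spectrometer frequency (violations
    warn, they do not raise).
    """

    spins: list[Spin]
    couplings: list[Coupling] = field(default_factory=list)
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.spins]
        if len(set(labels)) != len(labels):
            raise ValueError("spin labels must be unique")
        known = set(labels)
        seen_pairs = set()
        for c in self.couplings:
            if c.site_a not in known or c.site_b not in known:
                raise ValueError(f"coupling {c.site_a!r}-{c.site_b!r}: unknown site label")
            if c.pair in seen_pairs:
                raise ValueError(f"duplicate coupling for pair {sorted(c.pair)}")
            seen_pairs.add(c.pair)
        self.check_weak_coupling(DEFAULT_SPECTROMETER_MHZ)

    def spin(self, label: str) -> Spin:
        for s in self.spins:
            if s.label == label:
                return s
        raise KeyError(label)

    def partners_of(self, label: str) -> list[tuple[Spin, float]]:
        """Coupling partners of a site as ``(partner_spin, j_hz)`` pairs."""
        out = []
        for c in self.couplings:
            if c.site_a == label:
                out.append((self.spin(c.site_b), c.j_hz))
            elif c.site_b == label:
                out.append((self.spin(c.site_a), c.j_hz))
        return out

    def check_weak_coupling(self, spectrometer_mhz: float) -> bool:
        """Warn for each coupled pair with |Δν| < 5·J at this field.

        Returns True when every coupling satisfies the condition.
        """
        ok = True
        for c in self.couplings:
            if c.j_hz == 0:
                continue
            dnu = abs(
                resonance_offset_hz(self.spin(c.site_a), spectrometer_mhz)
                - resonance_offset_hz(self.spin(c.site_b), spectrometer_mhz)
            )
            if dnu < 5.0 * c.j_hz:
                ok = False
                warnings.warn(
                    f"pair {c.site_a!r}-{c.site_b!r}: shift difference {dnu:.2f} Hz "
                    f"< 5 x J = {5 * c.j_hz:.2f} Hz; first-order treatment is "
                    "inaccurate for this pair",
                    WeakCouplingWarning,
                    stacklevel=2,
                )
        return ok

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "spins": [
                {
                    "label": s.label,
                    "shift_ppm": s.shift_ppm,
                    "t1_s": s.t1_s,
                    "t2_s": s.t2_s,
                    "n_equivalent": s.n_equivalent,
                }
                for s in self.spins
            ],
            "couplings": [
                {"site_a": c.site_a, "site_b": c.site_b, "j_hz": c.j_hz}
                for c in self.couplings
            ],
        }
        if self.metadata:
            d["metadata"] = self.metadata
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystem":
        spins = [Spin(**s) for s in d.get("spins", [])]
        couplings = [Coupling(**c) for c in d.get("couplings", [])]
        return cls(
            spins=spins,
            couplings=couplings,
            name=d.get("name", ""),
            metadata=d.get("metadata", {}),
        )


def resonance_offset_hz(spin: Spin, spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ) -> float:
    """Resonance offset of a site in Hz relative to the 0-ppm carrier.

    One ppm corresponds to ``spectrometer_mhz`` Hz (1e-6 of the carrier in
    MHz expressed in Hz), so the offset is simply shift_ppm x frequency_MHz.
    """
    if not (math.isfinite(spectrometer_mhz) and spectrometer_mhz > 0):
        raise ValueError("spectrometer_mhz must be finite and > 0")
    return spin.shift_ppm * spectrometer_mhz


def _binomial_pattern(n_p: int, j_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """(n_p+1)-line binomial multiplet from n_p equivalent partner protons."""
    k = np.arange(n_p + 1)
    offsets = (k - n_p / 2.0) * j_hz
    weights = np.array([math.comb(n_p, int(i)) for i in k], dtype=float)
    return offsets, weights / weights.sum()


def multiplet_pattern(spin: Spin, system: SpinSystem) -> list[tuple[float, float]]:
    """First-order multiplet of a site as ``(offset_hz, intensity)`` lines.

    Offsets are relative to the site's own resonance; intensities sum to 1.
    Each coupling partner contributes a binomial sub-pattern; independent
    partners combine by convolution.  Lines that coincide (to 1e-6 Hz) are
    merged.  A site with no couplings is a singlet ``[(0.0, 1.0)]``.
    """
    offsets = np.array([0.0])
    weights = np.array([1.0])
    for partner, j in system.partners_of(spin.label):
        if j == 0:
            continue
        p_off, p_w = _binomial_pattern(partner.n_equivalent, j)
        offsets = (offsets[:, None] + p_off[None, :]).ravel()
        weights = (weights[:, None] * p_w[None, :]).ravel()
    # merge coincident lines
    order = np.argsort(offsets)
    offsets, weights = offsets[order], weights[order]
    merged_off: list[float] = []
    merged_w: list[float] = []
    for o, w in zip(offsets, weights):
        if merged_off and abs(o - merged_off[-1]) <= 1e-6:
            merged_w[-1] += w
        else:
            merged_off.append(float(o))
            merged_w.append(float(w))
    total = sum(merged_w)
    return [(o, w / total) for o, w in zip(merged_off, merged_w)]
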