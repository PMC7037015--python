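# Methods

## Signal model

The simulator works in the weak-coupling (first-order) regime throughout.
A spin system is a set of proton sites — chemical shift, T1, T2, number of
magnetically equivalent protons — plus scalar couplings J between sites.
Each site's conventional multiplet is the convolution of binomial
sub-patterns, one per coupling partner (an n-proton partner gives n+1
lines spaced J with weights C(n,k)); equivalent protons within a site do
not split each other. Second-order effects (roofing, AB patterns) are out
of scope; a weak-coupling check (|Δν| ≥ 5J at the working field) warns
when a system leaves the regime of validity.

**Conventional acquisition.** The sample is a 1D column of length L
(default 1.5 cm) along z, discretized into n_z equally weighted
isochromats on an inclusive grid over [−L/2, L/2]. Field inhomogeneity is
a linear frequency ramp, slope × z (an arbitrary tabulated profile can be
supplied); the full-sample frequency spread is exactly slope × L. The FID
is the sum over sites, multiplet lines, and isochromats of complex
exponentials damped by each site's T2, weighted by a per-site relaxation
factor:

- IR: 1 − (1 + w)·exp(−τ1/T1), with inversion efficiency w (1 = ideal π
  pulse, recovering the textbook 1 − 2e^(−τ1/T1));
- CPMG: exp(−Δ/T2). The echo train is taken as ideal: static offsets are
  refocused and J modulation suppressed in the short-interpulse limit
  τ2 ≪ 1/J (τ2 = 200 μs here, J ≤ 7 Hz, so Jτ2 ≈ 1.4 × 10⁻³). Finite-τ2
  residual J modulation is not modelled.

**Real-time pure-shift acquisition.** The FID is acquired in n chunks of
duration d (total acquisition time n·d; the first and last chunks are
half-length so that the refocusing midpoints fall at t = 0 and t = n·d).
The decoupling element between chunks — hard π, slice-selective π,
coherence gradients — is treated as instantaneous and ideal: the observed
spin's chemical-shift phase runs continuously while every coupling
partner is inverted once per element, so J evolution is refocused at each
chunk midpoint. The per-site signal is

    fraction · n_eq · weight · exp(2πi ν t − t/T2) · Π_partners cos(πJ(t − t_mid))^n_partner · loss^k

where t_mid is the midpoint of the chunk containing t, k the number of
elements already applied, and `loss` an optional per-element amplitude
penalty (default 1). The cos factor is the in-phase product-operator
result; antiphase terms are not tracked into detection. This closed form
is verified in the test suite against an independent brute-force
density-matrix propagation of the chunked sequence for an AX pair
(weak-coupling Hamiltonian, ideal pulses, ≤ 10 μs steps); agreement is at
machine precision, asserted at < 10⁻⁶ per point.

Samples on a chunk boundary ((k − ½)d) are assigned to the later chunk;
the J factor is even in (t − t_mid), so the choice only affects the
element-loss exponent.

**Slice selection.** Under the weak gradient G4 the resonance offset maps
to position as z = ν/(γG4) (γ = 4257.7 Hz/G). The shaped selective pulse
is idealized as a top-hat inversion band of width K/duration with K = 0.84
(Gaussian-FWHM heuristic, configurable — bandwidth conventions for shaped
pulses are not standardized, and the effective slice fraction depends
directly on this choice). Slice width is then (K/duration)/(γG4), the
slice fraction is width/L capped at 1, and the site's inhomogeneity
contribution collapses to the offset at the slice center. A slice falling
entirely outside the sample contributes zero signal (with a warning). The
coherence-selection gradients are modelled as an ideal pathway filter,
not simulated. With the default convention the 16.2 ms pulse at
G4 = 0.56 G/cm selects ≈ 1.5% of a 1.5 cm sample; reported experimental
pure-shift intensities for this scheme are more like 5–10% of
conventional, so K should be treated as an instrument calibration rather
than a constant.

**Transmitter placement.** Offsets are measured from a configurable
carrier (carrier_ppm); each demo bundle places it mid-spectrum so all
sites fall inside ±sw/2. The ppm axis is carrier_ppm + Hz/spectrometer_MHz.

## Reconstruction and tracking

FIDs are apodized (optional exponential line broadening lb, default 0 for
noiseless synthetic data), first point halved (trapezoid DC correction;
disable for Parseval-exact transforms), zero filled to the next power of
two times a factor, Fourier transformed, and presented on descending
Hz/ppm axes. With the synthesis convention e^(+2πiνt) zero-order phase 0
already gives pure absorption. Peaks are local maxima above a fractional
height threshold, refined by 3-point parabolic interpolation; FWHM is
measured by walking to the interpolated half-height crossings. Reference
peaks are picked once on the series member with the largest total
magnitude (the fully recovered IR spectrum / the shortest-Δ CPMG
spectrum) and their positions held fixed across the array; heights are
the *signed* real part interpolated at those positions, preserving the
negative IR lobe through the null. Tracking is linear in the per-site
relaxation weight, which is what makes noiseless round trips close
essentially exactly.

## Fitting

Nonlinear least squares (lmfit/Levenberg–Marquardt). IR defaults to the
3-parameter model with w floated (bounds [0, 2]); a fixed-efficiency
2-parameter variant is available and identical on ideal data. Initial
values: T1 from the interpolated zero crossing (τ_null/ln 2, an exact
zero datum taken directly; fallback max(τ)/3 when no sign change), I0
from the last point, w = 1. CPMG initializes T2 by log-linear regression
over points above 5% of the maximum. Reported uncertainties are
asymptotic standard errors (Jacobian covariance scaled by residual
variance); a residual-resampling bootstrap is provided as a cross-check
and agrees within a small factor at moderate noise. Solver failure or
degenerate data returns converged=False rather than raising. Fits with
fewer points than parameters raise.

T1/T2 tables join IR and CPMG per-peak fits by position within 0.02 ppm;
unmatched peaks are kept as one-sided rows and flagged, never silently
dropped.

## Fixtures and noise

The three demo systems carry per-value provenance tags in their metadata:
`"reported"` for experimentally measured shifts/relaxation times used as
simulation ground truth, `"invented"` for plausible placeholders. The
bromobutane chain (4 sites, 7 Hz vicinal couplings — invented but typical
for alkyl chains) exercises the pure-shift machinery; quinine (18 singlet
entries covering 16 protons, several sites resolved into two lines) and
azithromycin (25 singlet sites) default to zero J because their
relaxation tables are measured on decoupled singlets — a coupled variant
can be built by passing explicit couplings. The quinine and azithromycin
fixtures default to real-time well-shimmed values; a "conventional"
variant substitutes the separately measured conventional values where
they exist (quinine protons 6 and 7; azithromycin 7′, 8′, 7″, 8″).

Acquisition bundles: bromobutane — 10 IR delays 0.0625–32 s, 10 CPMG
delays 0.025–12.8 s, 40 × 20 ms chunks, sw 2000 Hz, G4 0.56 G/cm,
16.2 ms selective pulse, 177.35 Hz deshimmed spread; quinine — 7 IR
delays 0.04–5.0 s, 8 CPMG delays 0.01–1.40 s, 30 × 20 ms chunks, sw
4000 Hz, G4 0.47 G/cm, 16.6 ms pulse, 182.23 Hz spread; azithromycin —
6 IR delays 0.0625–2.5 s, 8 CPMG delays 0.01–0.7 s, 30 × 20 ms chunks,
sw 2000 Hz, G4 0.56 G/cm, 17.1 ms pulse, 29.3 Hz spread. All CPMG delays
are integer multiples of τ2 = 200 μs (validated at construction).

Noise is additive complex Gaussian, per-point SD = sigma × max|fid| over
the series, independently on the real and imaginary channels,
deterministic under a seed. This emulates receiver noise only — no t1
noise, no phase/frequency drift, no baseline distortion beyond what the
chunking itself produces — so passing noisy-recovery tests demonstrates
estimator correctness and precision scaling, not robustness to every
instrumental artifact of real data.

## Numerical choices and problem sizes

- Isochromat counts: n_z = 101 default; lineshape round-trip measurements
  use 601 (the measured top-hat FWHM is then grid-converged to ≈ 0.2%).
- The deshimmed-lineshape check applies lb = 2 Hz to damp truncation
  ripple; a symmetric kernel does not shift the half-height crossings of
  a top-hat edge, so the measured FWHM stays within 2% of slope × L.
- Simulations in the tests and the acceptance script use the fixture
  acquisition grids as-is (≤ 10 delays × ≤ 1600 complex points), chosen
  to match the conditions the fixtures emulate; the whole suite runs in
  a few seconds.
- The brute-force oracle uses 4–6 chunks at sw 2000 Hz with 10 μs
  propagation steps — small enough to run per-test, large enough to cover
  several refocusing elements.
- Ties/degeneracies: chunk-boundary samples belong to the later chunk;
  an exact-zero IR datum is used as the null directly; merged multiplet
  lines coincide within 10⁻⁶ Hz.

## Known limitations

- First-order multiplets only; no strong coupling, chemical exchange, or
  heteronuclear couplings.
- Decoupling elements are instantaneous; their imperfections are lumped
  into a single per-element amplitude loss, so element-duration phase
  effects and intra-element relaxation are not resolved.
- No finite-τ2 J modulation in the CPMG train, no B1 inhomogeneity,
  radiation damping, diffusion, or NOE.
- Peak heights of lines closer than ~25 Hz pick up tail overlap from
  neighbours with different decay constants, biasing fitted times at the
  few-tenths-of-a-percent level in the crowded quinine fixture; isolated
  sites close round trips to < 0.1%.
- The absolute pure-shift intensity scale depends on the selective-pulse
  bandwidth convention (K); only relative/monotonic statements about the
  sensitivity cost are asserted.
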