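# Methods

## Signal model and estimator

The package models a homodyne frequency-domain FLIM acquisition: sinusoidal
excitation and camera-gain modulation at f = 250 kHz, with the relative phase
stepped over K = 16 equally spaced angles θ_k = 2πk/K. For a
single-exponential emitter of lifetime τ the expected per-pixel intensity is

    I_k = DC · (1 + m_sys · m(τ) · cos(θ_k − φ(τ))),

with φ = arctan(ωτ), m = 1/√(1+(ωτ)²), ω = 2πf. Equal spacing is assumed
throughout; it is what makes the first-harmonic discrete Fourier sum

    F = (2/K) Σ_k I_k e^(−iθ_k) = DC · m_sys · m · e^(−iφ)

exact for any K ≥ 3 (the DC and second-harmonic terms sum to zero on the
uniform grid). The estimator therefore recovers (φ, m) to machine precision
on noise-free input, which the tests verify for K ∈ {3, 4, 8, 16} and
τ ∈ [50, 1000] ns.

Two lifetimes follow: the phase lifetime τ_φ = tan(φ)/ω and the modulation
lifetime τ_m = √(1/m²−1)/ω. The oximetry pipeline consumes τ_φ: it is
insensitive to errors in the instrument modulation depth m_sys, which enters
m multiplicatively but leaves φ untouched. τ_m is retained as a QC
cross-check (the two agree on the universal semicircle for single-exponential
decays). Pixels with φ ≤ 0, φ ≥ π/2, m ∉ (0, 1), or zero DC are flagged
invalid and excluded from all region statistics rather than zeroed.

At 250 kHz the dye's 350–550 ns lifetimes put ωτ in the 0.55–0.87 range,
near the sensitivity optimum of the phase estimator; this is why a kHz-range
modulation suits a ruthenium dye with hundreds-of-ns lifetimes.

## Stern–Volmer oximetry and reference normalization

Oxygen tension is expressed as percent of the gas phase (ambient = 20.9 %)
and the quenching constant K_q carries per-percent units — this matches every
level the assay works with (19.2 %, 13.8 %, …). Calibration uses the two
reference lifetimes τ_N = 533 ns (nitrogen, 0 %) and τ_A = 381 ns (air):
K_q = (τ_N − τ_A)/(τ_A · O₂_A) ≈ 0.019089 per %. The global unquenched
lifetime is τ₀ = τ_N (forced by the relation at zero oxygen).

During a device run the unquenched lifetime drifts (photoquenching of the
~9.4 nL dye volume under repeated exposure), so τ₀ is re-derived at every
timepoint from the empty reference chambers of the same device:
τ₀(t) = τ_E(t)·(1 + K_q·20.9), where τ_E(t) is the pixel-weighted mean of
τ_φ over all empty-chamber interiors (pixel weighting rather than
chamber-mean weighting; with equally sized chambers the two coincide).
Because a common multiplicative drift scales τ_E and every chamber lifetime
identically, the normalization cancels it exactly; the tests check this at
drift magnitudes of 0, 6.4 and 20 ns.

Computed oxygen is deliberately not clipped at zero: τ > τ₀ yields a
negative value that is reported with a QC count (`n_negative`), so reference
problems surface instead of being masked.

Chamber "interior" means pixels within 90 % of the chamber radius, excluding
wall artifacts; the same region defines both the analysis averages and the
simulator's ground-truth chamber means, so recovery comparisons are
like-for-like.

## Forward simulator

The simulator generates the study conditions of the assay:

- **Geometry** — cylindrical chambers of 200 μm diameter × 300 μm height
  (volume ≈ 9.4 nL) on a pixel grid; the field of view and pixel scale are
  free parameters (the demo device uses 4 μm/px).
- **Kinetics** — occupied chambers follow
  O₂(t) = plateau + (initial − plateau)·e^(−rate·max(0, t − delay)).
  Mono-exponential decay toward a plateau is the minimal shape consistent
  with a rapid initial decline that stabilizes; the untreated default
  (initial 19.2 %, plateau 13.8 %, rate ln(54)/25 ≈ 0.16 min⁻¹) passes
  through 13.9 % at 25 min. The 5-FU preset starts at 19.9 % with an
  intermediate plateau of 15.75 %; the oligomycin preset uses a 20 min onset
  delay plus a reduced rate (0.064 min⁻¹, plateau 13.5 %) so oxygen is near
  19.9 % through the first 20 min and ≈14 % at 60 min — a two-parameter
  emulation of suppressed respiration, not a mechanism.
- **Empty-chamber drift** — the empty-chamber lifetime starts at 371.3 ns
  and loses 6.4 ns linearly over the hour (applied as a common scaling of
  the unquenched lifetime, spatially uniform), exercising the per-timepoint
  normalization.
- **Intra-spheroid gradient** — inside the spheroid footprint, oxygen ramps
  linearly from the chamber level at the rim to a configurable core fraction
  (default 0.5) at the center. This is a qualitative emulation of the
  gradients visible in lifetime images, not a diffusion–reaction solution.
  The six-chamber reference preset sets the core fraction to 1.0: its
  configured kinetics are chamber-mean anchor values of the dye-filled
  medium, which is what the per-chamber average reports.
- **Noise** — `photon_budget` is the expected photon count per pixel *per
  phase step* at the DC level. Poisson shot noise per step, then Gaussian
  read noise (default SD 2 photons, a typical sCMOS figure), clipped at
  zero. At the default 10⁴ budget a uniform 400 ns field shows ≈3.7 ns
  spatial lifetime deviation — inside the instrument's stated < 5 ns bound —
  and the per-pixel estimate is unbiased within Monte-Carlo error.
  `photon_budget=inf` with zero read noise renders exact expectations.
- **Brightfield** — chamber walls as dark rings, spheroids as dark disks of
  the configured diameter, empty interiors at the background level.
- **Viability pairs** — cells are uniform-intensity disks (radius 2 px)
  placed disjointly inside spheroid footprints by rejection sampling with
  bounded retries; `floor(dead_fraction·n + 0.5)` spots emit in red only.

All randomness flows from one seeded `numpy` generator recorded in the
output metadata; ground truth (chamber means, medium levels, τ_E series,
counts, diameters) is always emitted with the images. What the simulator
does **not** emulate: optical blur (no PSF), multi-exponential dye decay,
PDMS oxygen diffusion, autofluorescence, stage drift, or spatially
structured illumination. Passing tests therefore demonstrate correctness of
the estimators and the normalization logic under the stated noise model, not
robustness to real-instrument artifacts.

## Chamber detection and occupancy

Chamber diameter is known from the device design, so ROIs are found by
normalized cross-correlation against a disk template with non-maximum
suppression at one diameter spacing (threshold 0.3 on the correlation);
matched filtering is more robust at low contrast than a generic circle
transform when the radius is fixed. Detections truncated by the image border
are refused. Detection runs on the FLIM DC image, where dye-filled chambers
are bright disks; a polarity switch handles dark-disk images.

Occupancy is primarily configuration-driven — in the physical assay whole
channels are left empty by design, so the labels are known, and the pipeline
matches detected chambers to configured centers by nearest neighbour.
Image-based classification from brightfield (Otsu threshold inside the ROI,
guarded by a contrast floor so featureless chambers are not split on noise;
occupied when the largest dark component exceeds 10 % of the chamber area)
is the fallback and is validated down to spheroids of 40 % of the chamber
diameter.

## Morphometry and viability

Spheroid size: contrast-limited adaptive histogram equalization, Otsu
threshold of the inverted ROI, removal of border-touching components (which
discards the chamber-wall ring in a tight chamber crop), a 50 px² minimum
area, hole-filling of the largest remaining component, and the equivalent
diameter 2·√(area/π). A contrast floor flags empty chambers as zero-size
instead of segmenting noise. Rendered disks at 1 μm/px are recovered within
2 px.

Viability: per-channel Otsu threshold, components above 4 px² counted as
cells, viability = live/(live + dead), flagged undefined when both counts
are zero. Component counting is the default (the assay counts cells); a
pixel-area mode is provided for stains too dense to resolve single cells,
since the right denominator for merged spheroid staining is genuinely
ambiguous.

## Consumption metrics and statistics

Defaults: rate window 5 points (0–20 min) for the initial-slope fit, plateau
window 7 points (30–60 min), plateau tolerance 0.5 % O₂ for time-to-plateau
(flagged censored when never reached). Both windows are configurable; the
boundary mirrors the assay's observed transition at ~25 min. The optional
molar rate uses a documented default oxygen solubility of 200 μM for
air-equilibrated aqueous buffer at 37 °C and the 9.4 nL chamber volume; it
has no published anchor in this assay and is provided for cross-study
comparison only.

Group comparison is an equal-variance two-sample Student's t-test per
timepoint (Welch behind a flag), flagged at p < 0.05, with no
multiple-testing correction by default to match the per-timepoint
significance convention of this assay type; Bonferroni is available and off
by default. Two groups with identical values give t = 0, p = 1; zero pooled
variance propagates scipy's NaN rather than being masked.

## Problem sizes and numerical choices

The bundled demo and reproduction runs use a six-chamber device at 4 μm/px
(150 × 220 px, 13 timepoints, 16 steps) — small enough to simulate in
seconds while leaving ~1600 interior pixels per chamber, so chamber means
have negligible shot-noise error. Phase angles are wrapped to (−π, π];
demodulation is linear, so intensity scaling never changes (φ, m); all
tolerances asserted in tests (10⁻⁶ relative for noise-free recovery, 0.05 %
O₂ for noise-free chamber means, 2 px for morphometry) derive from the
rounding/rasterization granularity of the quantity, not from fitted slack.

## Known limitations

- Single-exponential dye decay only; no phasor unmixing of mixtures.
- No tracking of chamber positions across timepoints (stationary stage
  assumed).
- The intra-spheroid gradient is phenomenological; do not interpret core
  values mechanistically.
- The molar consumption rate depends linearly on the assumed solubility and
  is unvalidated against an external standard.
- Image-based occupancy classification fails below ~40 % spheroid/chamber
  diameter ratio; use configuration labels where the design provides them.
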