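# Methods

## Physical model

The package treats a thick amorphous specimen as a homogeneous slab through
which each beam electron passes independently. Three stochastic ingredients
define an electron's state after transit:

1. **Source tilt.** The illumination has a Gaussian angular distribution of
   FWHM 0.01 mrad (per transverse component, standard deviation
   σ = FWHM / (2√(2 ln 2))). The 1/e semi-angle entering the Gaussian
   source envelope is α = √2·σ = FWHM / (2√(ln 2)); this is the unique
   convention under which the analytic envelope
   E_s(q) = exp[−(πα/λ)²(λΔzq + C_sλ³q³)²] equals the brute-force average
   of fringe phase factors over the sampled tilt ensemble (verified in the
   test suite to 1%).
2. **Inelastic event count.** n ~ Poisson(t/λᵢ), capped at n = 6. The
   Poisson mass above the cap is assigned to n = 6 by default ("assign"
   mode; < 10⁻⁴ of electrons for t/λᵢ ≈ 0.8); a "renormalize" mode redraws
   instead. An optional "spectrum" mode first draws the electron's total
   loss from the compound (thickness-scaled) spectrum and then n
   conditional on that loss; because the characteristic angle is linear in
   loss and per-event envelope widths add, the two modes produce the same
   coherence envelopes for a given total loss.
3. **Per-event loss and deflection.** Each event's energy loss is an
   inverse-transform draw from the single-scattering spectrum. Its
   characteristic angle is θ_E = ΔE/(p·v) (small-loss relativistic form;
   exact momentum-loss evaluation differs by < 0.1% at 23 eV, 300 keV), and
   the planar deflection is drawn from the radial law θ/(θ² + θ_E²)
   truncated at the plasmon cutoff 2θ_E, with uniform azimuth. Tilt
   vectors add in the small-angle approximation. Elastic scattering never
   deflects electrons in the simulator; it enters only through Poisson
   signal-fraction bookkeeping.

Energy filtering is an ideal top-hat slit (inclusive edges, default width
6 eV); filtered ensembles record the discarded fraction so curves can be
normalized per incident electron. Chromatic-aberration correction is
modelled *logically*, not numerically: with Cc correction inelastic
electrons are imaged at the same defocus as elastic ones, without it the
zero-loss slit defines the usable signal. No numeric Cc or focal-spread
envelope is modelled.

## Coherence envelopes and fading curves

Underfocus is negative throughout. Angles and spatial frequencies are
related by θ = λq; the envelope integral is evaluated in frequency units
(γ = θ_E/λ, q_c = 2θ_E/λ) with the displacement D = Δzθ + C_sθ³ in Å at
the angle θ of the resolution of interest, the only dimensionally
consistent reading, validated against a Monte Carlo tilt-average oracle.

Because q_c/γ = 2 is fixed, the renormalized envelope depends only on
x = γD. It is tabulated once on x ∈ [0, 60] (step 2×10⁻³, 800-node
Gauss–Legendre quadrature, agreeing with adaptive quadrature to < 10⁻³)
and interpolated; beyond the table the envelope is taken as zero. The
general-(γ, q_c, D) entry point uses adaptive quadrature subdivided at the
Bessel oscillation scale with relative tolerance 10⁻⁸.

* **Envelope method.** Per electron, per-event envelopes multiply
  (independent tilts convolve, so characteristic functions multiply), each
  with γ from its own sampled loss; the Gaussian source envelope
  multiplies in analytically. Its 0.01 mrad width is nearly inert over the
  default defocus grid, fading the signal by < 15% at the extreme grid
  edge for the highest resolution considered.
* **CTF method.** An electron with total tilt τ contributes the phase
  W(θ_g + τ∥) − W(τ∥) at a reflection with θ_g = λ/d, where τ∥ is the tilt
  component along the reflection; this reproduces the displacement form
  dW/dθ·τ to first order. The *signed* CTFs are averaged — tilt dephasing
  then attenuates |⟨sin φ⟩| — and the |sin W| carrier (defocus period
  λ/θ_g², ≈ 280 Å for 2.35 Å at 300 kV) is removed by taking block maxima
  over one period. Averaging |sin φ| per electron instead would converge
  to 2/π rather than 0 and rectification would halve the apparent fading
  scale; the signed average is what makes the CTF and envelope methods
  measure the same decoherence.
* **Image-plane method.** A weak-phase lattice (sinusoidal phase inside a
  disc) is imaged through the aberration phase for an ensemble of beam
  tilts with truncated-Lorentzian weights (Gauss–Legendre radial ×
  uniform azimuthal quadrature; a Monte Carlo mode cross-checks it).
  Tilts are applied by evaluating the aberration at the tilt-shifted
  frequency — exact even for tilts smaller than a Fourier pixel, which a
  real-space phase ramp is not. Reflection power of the averaged image is
  integrated in an annulus (±2 Fourier pixels, median background from
  neighbouring annuli subtracted). The sin²W carrier is removed by
  sampling defocus at carrier maxima; for quantitative envelope
  comparisons the lattice spacing is snapped to a Fourier-commensurate
  value and the disc opened to the full field so the reflection occupies a
  single Fourier pixel. Default grid 512×512 at 0.5 Å/pixel; the fading
  tests use a 0.5 Å/pixel grid with 20–50 defocus samples and
  (32 radial × 8 azimuthal) tilt nodes, which reproduces the (64 × 16)
  default to well under a percent.

Fading curves default to the grid +10 000 → −50 000 Å in 100 Å steps;
the thick-specimen curve family uses symmetric grids scaled with
resolution (span 10⁴·d) so every half maximum is bracketed. FWHM is
extracted either by linear interpolation of the half crossings (baseline
zero — fading curves decay to zero) or by least-squares Lorentzian fit
with a free constant baseline; the two agree within 15% on simulated
curves and within 1% on exact Lorentzians. Normalizations: "unit-peak"
for width measurements (scale-free), "per-electron-fraction" for additive
curve families, "absolute" for raw means.

### Power versus amplitude

The CTF and envelope methods produce amplitude-like signals (mean CTF,
mean envelope); the image-plane method measures reflection *power*, which
fades as the envelope squared. Comparisons are made like-with-like: the
image-plane FWHM is compared against the FWHM of the squared envelope
curve. Both conventions are exposed to the user.

## Materials, spectra and calibration

The materials registry ships amorphous carbon (density 1.7 g/cm³,
λᵢ = 2400 Å at 300 kV), amorphous ice (0.93 g/cm³, λᵢ = 3140 Å) and
protein. Mixtures combine by inverse-MFP additivity over volume
fractions. The protein inelastic MFP (1600 Å) is a *calibration*: it is
chosen so the 30:70 protein:water continuum (mixture density
1.06 g/mL) has λ_mix = 2436 Å and zero-loss fraction
e^(−2000/2436) = 0.44 at 2000 Å, the anchor used for energy-filtered
signal levels. Elastic MFPs are uncalibrated defaults from the ≈ 26/Z
elastic-to-inelastic cross-section ratio rule and should be replaced with
measured values for quantitative elastic bookkeeping; all headline
quantities computed here are independent of them.

The synthetic single-scattering spectrum is a truncated Lorentzian peaked
at 23 eV (HWHM 8 eV), zero below a 3 eV onset, normalized on a 0–140 eV
support with 0.2 eV grid. All three shape parameters are exposed because
real thin-specimen spectra vary with material and instrument. Thickness
scaling is the compound-Poisson mixture of n-fold self-convolutions
(n ≤ 6 by default, warning when the Poisson mass coverage drops below
99.9%); a Monte Carlo path cross-checks the convolution path to < 0.01 in
CDF sup-distance. The idealized zero-loss peak is a delta at 0 eV; no
instrumental ZLP width, background subtraction or deconvolution is
modelled. Note the 3 eV onset places about 2% of single-scattering losses
below a 6 eV counting threshold, so "fraction losing 6–140 eV" computes
marginally below the raw Poisson scattered fraction.

Spectrum I/O supports a plain CSV dialect and a minimal EMSA/MAS (.msa)
two-column dialect (required keywords #FORMAT, #NPOINTS, #XUNITS,
#DATATYPE; an optional ##ZLFRACTION user keyword preserves the zero-loss
mass exactly on round trip, otherwise it is estimated from a |ΔE| < 3 eV
window).

## Mass-limit model

M_min(t) = (M₀·damage_scale + M_blur) / [E·e^(−t·a/λₑ) +
(1 − E)·e^(−t·a(1/λᵢ + 1/λₑ))], with E = 0 recovering the energy-filtered
(no-Cc) case. Defaults M₀ = 42 kDa, M_blur = 0, a = 1.05 (protein-size
correction). `damage_scale` multiplies M₀ only — radiation damage bounds
the fluence that sets M₀ — so a 1.5-fold damage-rate reduction scales the
whole curve by 1/1.5 when M_blur = 0. The defocus-integrated variant
replaces E by the mean per-electron envelope over the defocus interval
[center − t/2, center + t/2] spanned by the specimen (each depth sits at
its own defocus), computed from a 2×10⁴-electron transit ensemble of the
protein:water mixture and 41 defocus samples. M₀ and a are treated as
given constants; no re-derivation from cross sections is attempted.

## What the simulations do and do not show

The synthetic generator emulates: Poisson plural scattering, a
plasmon-dominated loss spectrum, Lorentzian angular spreading with a sharp
2θ_E cutoff, ideal energy slits, an idealized weak-phase lattice object.
It does **not** emulate: elastic angular deflection, specimen charging,
beam-induced motion, plasmon dispersion and damping (the cutoff is a hard
bound, not a physical dispersion surface), detector response, dose or
noise, depth-dependence of scattering within the slab, or atomistic
multislice scattering. Passing tests therefore demonstrate internal
consistency of the transport-plus-envelope treatment — the three fading
methods agree within ~15–25% and conserve electron fractions — not
agreement with any particular microscope's measured fading, which these
unmodelled decoherence sources (and the hard-cutoff choice, to which the
fading scale is directly proportional through θ_E) can shift
substantially: with the parameters above the model places the 23 eV
fading FWHM at 2.35 Å, 300 kV, C_s = 2.7 mm near 2.3 μm, and measured
widths under nominally similar conditions have been reported an order of
magnitude narrower. Users comparing against experiments should treat θ_E
(equivalently the effective cutoff) as the parameter to calibrate.

## Numerical sizes used by the test suite

Monte Carlo ensembles of 10⁵ electrons (statistical errors on FWHMs
≈ 1–2%), 10⁶ draws for distributional property tests, envelope tables as
above, image grids of 256²–512² pixels at 0.5 Å/pixel. All random paths
take explicit integer seeds and are bit-for-bit reproducible; an unseeded
simulator call is an error.
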