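# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package, and what the synthetic-data experiments do and
do not demonstrate.

## Spectral model and conventions

A resonance is a complex Voigt line with amplitude *a*, center *v* (ppm),
FWHM *w* (ppm), mixing *m* ∈ [0, 1] and phase *p*. Two conventions are
provided behind one interface, and every fit records which one it used:

* **pseudo-Voigt** (default): *m*·Lorentzian + (1−*m*)·Gaussian, unit-height
  components sharing the FWHM *w*. This is the reading in which the mixing
  parameter has its usual meaning.
* **Faddeeva (true Voigt)**: the convolution evaluated through *w(z)*, with
  the Lorentzian/Gaussian widths apportioned as *wL = m·w*, *wG = (1−m)·w*
  and the profile normalised to unit height.

Both carry the dispersion (imaginary) part produced by the one-sided Fourier
transform of the corresponding decay envelope, so time-domain synthesis and
frequency-domain evaluation are exact Fourier pairs. The Faddeeva function
is computed with Weideman's rational approximation; the default order (32)
gives ≈1e−13 relative error, and order 24 stays below 1e−6 (verified against
an independent quadrature of the convolution integral and against
`scipy.special.wofz`, which the implementation itself never calls).

ppm axes are referenced to CFCl₃; ppm = f[Hz] / reference frequency [MHz],
with the carrier offset stored separately. Defaults emulate a 9.4 T ¹⁹F
system: reference frequency 376.8 MHz, 200 kHz spectral bandwidth (5 µs
dwell), two receive channels. Spectra are scaled by the dwell time so they
approximate the continuous one-sided transform: a unit-amplitude synthetic
peak returns with unit real height (to within one left-rule discretisation
term, ≈0.3% at the default settings).

## Digital-filter delay, truncation, zero-padding

The filter delay is an integer left-shift recorded in metadata; fractional
group delay is out of scope. Truncation before the DFT acts as a crude
matched filter for short-T2* signals (verified to raise peak SNR at the
serum room-temperature T2* of ≈0.95 ms); it also convolves the line with a
sinc, biasing fitted widths upward when the cut is shorter than a few T2*.
Experiments that compare fitted areas against generator truth therefore use
untruncated series, so the estimator is tested without the truncation
confound; with a 256-of-512 cut the area bias is ≈7%.

## Coil-artifact model and MAP subtraction

The two contaminant lines are modelled with coupled amplitudes *r·a* and
*(1−r)·a* so that a prior on *r* constrains relative contributions
independently of overall intensity. Characterisation fits each control
spectrum separately (complex residuals, trust-region least squares) and
takes the sample mean and sd of (r, v₁, w₁, m₁, v₂, w₂, m₂) per channel.

The constrained fit minimises
Σ|residual/σ_noise|² + Σ((θ−μ)/σ′)², a standardised Gaussian (MAP) penalty
over those seven parameters, with σ′ = √(σ² + σ_drift²) for the two center
frequencies and σ_drift = 250 Hz expressed in ppm via the stored reference
frequency. σ_noise comes from a signal-free background region (configurable;
default: the upfield quarter of the axis). The free peak is bounded to the
drug search window (−70 to −50 ppm by default) and initialised at the
expected drug shift. Amplitude, global phases and the first-order phase are
unconstrained. The penalty weight is exposed (`prior_weight`, default 1 =
proper standardised MAP).

**What subtraction can and cannot preserve.** Only the fitted contaminant
component is subtracted, so unmodelled features pass through *as features*.
Quantitatively, an unmodelled resonance is partially projected onto the
span of the contaminant model's Jacobian (mostly via the mixing/width tail
freedom): in simulations ≈20% of a small peak's pointwise amplitude is
absorbed, largely as a broad, smooth tail component. Because that component
is smooth, the peak's amplitude *as quantified in practice* — a local
Voigt-plus-baseline fit — changes by under 2% (paired against an
identical-noise artifact-free control). Pointwise spectrum differences are
the wrong preservation metric for any penalised fit with this model
freedom.

## Relaxometry

Signal equations: S(TR) ∝ 1 − e^(−TR/T1); S(t) ∝ β e^(−t/T2a) +
(1−β) e^(−t/T2b) with the mono-exponential as the constrained special case.
Estimates use trust-region least squares; the covariance is the linearised
V_p = σ_r²(JᵀJ)⁻¹ (exactly the OLS covariance for linear models, verified).
Canonical ordering T2a ≤ T2b resolves label switching (covariance rows/
columns permuted accordingly).

**Fitting family vs. physical family.** The likelihood-ratio statistic
Λ = n ln(RSS_mono/RSS_bi) with a χ²₂ reference requires the alternative to
be a smooth nesting of the null. With β hard-bounded to [0, 1] the null
sits on the boundary and Λ acquires a point mass at zero; the default bi
fit therefore leaves β free (the general two-exponential family). Measured
under the null (1000 runs, SNR 30): rejection 0.065 at α = 0.05, p-value
KS distance 0.038 from uniform. `physical=True` restores the [0, 1] bound
for parameter-recovery use. The simulator always enforces β ∈ [0, 1].

Bi-exponential fits are initialised by variable projection — a log-grid
search over (T2a, T2b) pairs with the two amplitudes solved linearly —
because gradient descent started at the mono solution stalls on the
degenerate T2a = T2b ridge. The mono-embedded start is always included, so
RSS(bi) ≤ RSS(mono) up to optimizer tolerance.

Per-point noise sds may be supplied (`sigma=`); residuals are then scaled
by them and the covariance follows from the weighted Jacobian, which keeps
Wald intervals near nominal under heteroscedastic noise. Unweighted least
squares remains the default.

**Apparent relaxation time**: the unique root of the normalised decay at
1/e, by Brent's method on [min(T2)/10, 10·max(T2)]. Monte-Carlo propagation
draws 5·10⁴ parameter vectors from N(estimate, V_p); draws violating
β ∈ [0, 1] or positivity are rejected and redrawn (rejection count
reported; more than 50% invalid aborts), and roots are found by vectorised
bisection (80 iterations).

## Sequence optimisation

Closed forms: Ernst angle arccos(e^(−TR/T1)); bSSFP angle
arccos((T1/T2−1)/(T1/T2+1)); both are cross-validated as the numerical
argmax of the corresponding steady-state signal equation. The RARE PSF uses
centric ordering along one phase dimension of 32 lines: the first echo of
each shot fills the most central lines, line *k* carries the echo-train
amplitude S(t_echo), and the FWHM of the zero-padded magnitude PSF is
measured by linear interpolation (the no-decay limit is the Dirichlet
kernel, ≈1.21 voxels). With the serum relaxation parameters and 1.5 ms
echo spacing the ETL selector (FWHM < 1.5 voxels) returns 4 at room and 8
at physiological temperature — one step below the 8/16 operating points
reported for the emulated protocols, consistent with the construction
behind those numbers (segmentation across two phase dimensions, exact FWHM
definition) being underdetermined; the selector is therefore documented as
accurate to ±1 ETL step.

## Radial UTE reconstruction

Ideal golden-spiral (3D) or uniform-angle (2D) center-out trajectories
replace measured ones. Sample *j* of every spoke is acquired at
TE + (j−1)·t_d; T2* decay and off-resonance act per sample, which is what
makes the off-resonance phase correction exp(2πi·(TE+(j−1)t_d)·Δf) exact
for a single resonance (it restored the point-source PSF to the on-resonance
width to machine precision in the validation run; the uncorrected image
loses >25% peak amplitude to ring-shaped blurring at Δf = 2 kHz with a
0.43 ms readout). Sign convention: Δf is the amount the receiver carrier
was shifted away from the resonance; the simulator's per-object offset is
the negative of it.

The adjoint NUFFT uses shell-volume radial density compensation
(((r+Δr/2)^d − (r−Δr/2)^d), DC sample = the central sphere), a width-4
Kaiser–Bessel kernel on a 2× oversampled grid with the Beatty shape
parameter, and closed-form deapodisation. Accuracy against brute-force DFT
summation: NRMSD ≈ 3·10⁻⁴ on a 16³ grid with 200 spokes (the acceptance
bound is 1%). Reconstruction amplitudes are defined by the weighted adjoint
sum; absolute intensity is meaningful only relative to a reference scanned
with the same protocol.

Noise: prewhitening whitens with the inverse Cholesky factor of the sample
channel covariance; RSS noise of N_c channels is σ·χ(2N_c), and SNR maps
divide by σ̂ = mean(RSS noise)/chi-mean(2N_c) (the Rayleigh factor 1.2533
for one channel). Cluster thresholding uses full 26/8-neighbour
connectivity and a 2-voxel minimum cluster by default (the cited protocol's
exact parameters are not restated in the source; both are configurable).

## Synthetic-data generators: what they emulate, and what not

The generators reproduce the *statistical* structure of the study's
acquisitions: line positions and shapes (drug near −59 ppm, contaminants
near −83/−147 ppm with the characterised between-scan parameter spread),
mono/bi-exponential envelopes at the characterised relaxation values,
analytic-ellipsoid k-space with per-sample decay/off-resonance, circularly
symmetric correlated channel noise, and separate noise scans. They do not
model B₀/B₁ field maps, gradient-timing imperfections, motion, chemical
exchange or vendor filter responses — so passing tests validate the
estimators and the processing chain, not robustness to those hardware
effects. Channel sensitivities default to uniform; an optional per-channel
gain or a callable evaluated at object centers gives a piecewise-constant
surface-coil approximation (qualitative only). The inter-channel noise
correlation of the two-channel probe is a free parameter (default 0; not
stated in the source material).

Noise-model conventions in the validation experiments (fixed before the
expected values were frozen):

* *Relaxometry recovery* (bias < 2%, nominal coverage): 1% signal-
  proportional noise, fitted with the matching weights. With additive
  1%-of-S(0) noise the minor serum components are too weakly identified
  for any unbiased estimator to reach 2% (the measured uncertainties on
  those parameters are themselves 7–25%).
* *LRT calibration*: additive noise at SNR 30, unweighted fits (the
  default estimator, matching the test's homoscedastic assumptions).
* *Concentration quantification*: sample and reference share geometry and
  protocol, as with a reference acquired "with otherwise identical
  settings", so the voxelwise SI ratio cancels PSF partial-volume effects
  and tests the calibration chain. With differing geometry or T2*, ratio
  biases of ~10% from resolution effects are expected and real — they are
  properties of the measurement, not the code.

## Problem sizes

The validation suite uses 32-echo CPMG grids (3.2 ms spacing), 512-point
FIDs zero-padded to 4096, 200 control-fit seeds, 1000 null simulations for
test calibration, 16³–32³ image grids with 200–1500 spokes and 10⁵-sample
noise ensembles; these sizes put every Monte-Carlo margin well clear of its
threshold while keeping the full suite a few minutes long.

## Known limitations

* Fractional group delay, eddy-current lineshape distortion and automatic
  phasing beyond coarse grid search are not implemented.
* The artifact model is fixed at two contaminant lines; more would need a
  model extension (the structure generalises but is not built).
* No iterative or compressed-sensing reconstruction; the adjoint NUFFT with
  density compensation is the only image operator.
* Concentration maps are not B₁-corrected; with transceive surface coils
  they are semi-quantitative away from the reference geometry.
* The LRT's χ²₂ reference is asymptotic; at n = 32 it over-rejects slightly
  (0.065 at nominal 0.05), which the calibration experiment documents
  rather than corrects.
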