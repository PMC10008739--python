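# fluormr

Analysis chain for **fluorine-19 MR** detection and quantification of
fluorinated drugs — spectroscopy, relaxometry, pulse-sequence optimisation
and radial ultrashort-echo-time (UTE) imaging — built for the hot-spot
imaging regime where a CF₃-bearing compound (e.g. the multiple-sclerosis
drug siponimod, resonating near −59 ppm vs. CFCl₃) must be detected at
micromolar tissue concentrations with strongly shortened transverse
relaxation times.

The package is aimed at preclinical MR physicists and analysts who need a
tested, scriptable replacement for ad-hoc spectral and image processing:
every stage can be exercised end-to-end on synthetic data from the built-in
generators, with no scanner data required.

## What it implements

**Spectroscopy** (`fluormr.spectra`, `fluormr.lineshape`): digital-filter
delay removal, truncation (matched filtering for short T2*), zero-padding and
Fourier transformation onto a CFCl₃-referenced ppm axis; complex pseudo-Voigt
and Faddeeva-based Voigt line shapes (Weideman's rational approximation of
*w(z)* = e^(−z²) erfc(−iz)); trust-region Voigt fits; peak-SNR (pSNR) and
area-to-noise (ANR) metrics.

**Coil-artifact subtraction** (`fluormr.artifact`): cryogenic RF probes leak
intrinsic ¹⁹F lines (≈ −83 and −147 ppm). These are characterised from
empty-coil control spectra by the coupled two-peak model

    L(f) = a e^{-iφf} ( r e^{-ip} V(f; v₁, w₁, m₁) + (1−r) e^{-iq} V(f; v₂, w₂, m₂) ),

and removed from sample spectra by a three-peak MAP fit: Gaussian priors
(the control-scan means and sds, frequency sds inflated by a 250 Hz drift
allowance) constrain the contaminant pair while a free peak captures the
drug; only the fitted contaminant component is subtracted.

**Relaxometry** (`fluormr.relaxometry`): saturation-recovery T1, mono/
bi-exponential T2 and T2* fits with covariance V_p = σ_r²(JᵀJ)⁻¹, the
Gaussian-errors likelihood-ratio test Λ = n ln(RSS₀/RSS₁) against χ²₂, and
apparent relaxation times (the 1/e time of the fitted bi-exponential),
deterministic or by Monte-Carlo propagation of V_p (5·10⁴ draws).

**Sequence optimisation** (`fluormr.protocol`): Ernst angle, optimal bSSFP
angle, RARE echo-train-length selection from the point-spread-function FWHM,
steady-state signal equations, SNR efficiency (SNR/√TA), detection-limit
√time scaling, ¹⁹F atoms per voxel, cross-species voxel scaling and
dose-proportional concentration projections.

**Imaging** (`fluormr.imaging`): ideal center-out radial trajectories,
off-resonance correction by the delay-dependent phase factor
exp(2πi·(TE+(j−1)t_d)·Δf), adjoint Kaiser–Bessel-gridding NUFFT with radial
density compensation, Cholesky noise prewhitening, root-sum-of-squares
channel combination, SNR maps via the chi-distribution mean correction for
2·N_c degrees of freedom, cluster-based background thresholding (SNR 3.5 in
vivo / 4.0 ex vivo) and reference-phantom concentration mapping.

**Synthetic data** (`fluormr.simulate`): exact time-domain synthesis of
multi-channel FIDs (drug + contaminant lines, optional bi-exponential T2*
envelopes), relaxation series, analytic-ellipsoid radial k-space with
per-sample T2* decay and off-resonance, correlated complex channel noise
and zero-excitation noise scans. All generators are pure functions of their
inputs and a seed.

## Worked example

Fit a CPMG decay measured in serum at physiological temperature, select the
decay model, and summarise it:

```python
import numpy as np
from fluormr.relaxometry import apparent_t2, fit_decay, likelihood_ratio_test
from fluormr.protocol import ernst_angle, snr_efficiency
from fluormr.simulate import simulate_relaxation_series

t = np.arange(1, 33) * 3.2                      # 32 echoes, 3.2 ms spacing
t_ms, s = simulate_relaxation_series(
    "echo_decay", {"beta": 0.405, "t2a": 8.0, "t2b": 21.7}, t,
    noise_sd=0.01, seed=0)

mono = fit_decay(t_ms, s, "mono")
bi = fit_decay(t_ms, s, "bi", physical=True)
lrt = likelihood_ratio_test(mono, bi)
print(f"mono T2              : {mono.estimates.t2:.1f} ms")
print(f"bi (beta, T2a, T2b)  : ({bi.estimates.beta:.3f}, "
      f"{bi.estimates.t2a:.1f} ms, {bi.estimates.t2b:.1f} ms)")
print(f"LRT                  : Lambda = {lrt.statistic:.1f}, "
      f"p = {lrt.p_value:.2e} -> {lrt.preferred_model}")
print(f"apparent T2          : {apparent_t2(bi.estimates):.1f} ms")
print(f"Ernst angle (TR 10 ms, T1 282.1 ms): {ernst_angle(10, 282.1):.1f} deg")
print(f"UTE SNR efficiency (SNR 13.0 in 4 h): {snr_efficiency(13.0, 4*3600):.2f} h^-1/2")
```

Output:

```
mono T2              : 16.7 ms
bi (beta, T2a, T2b)  : (0.441, 9.4 ms, 21.6 ms)
LRT                  : Lambda = 25.1, p = 3.49e-06 -> bi_exp
apparent T2          : 15.1 ms
Ernst angle (TR 10 ms, T1 282.1 ms): 15.2 deg
UTE SNR efficiency (SNR 13.0 in 4 h): 6.50 h^-1/2
```

The likelihood-ratio test rejects the single-exponential decay (p ≪ 0.001),
and the bi-exponential is summarised by its apparent T2 — the time at which
the fitted signal has dropped to 1/e (15.1 ms here; ≈14.7 ms at the
noiseless parameter values). The Ernst angle and SNR efficiency are the
closed-form protocol numbers for the same serum conditions.

A command-line interface mirrors the library (`fluormr --help`):
`simulate`, `fit-spectrum`, `artifact`, `relaxometry`, `optimize`, `recon`,
`snrmap`, `quantify` and `pipeline` subcommands operate on HDF5/CSV/JSON
files and write NIfTI volumes.

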