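# Methods

`nlmscope` is a digital twin of phase-contrast microscopy with a nonlocal
metasurface (NLM): a guided-mode-resonance grating that acts as an *angular*
filter, attenuating and phase-shifting only the near-axis rays. Inserted
between a transparent specimen and an ordinary bright-field objective, it
converts invisible phase structure into intensity contrast, and — after a
one-time contrast calibration — into quantitative phase maps. This note
documents the models, the choices made where the design was genuinely open,
and what the synthetic tests do and do not demonstrate.

## The device and its two models

The device is a 1D surface-relief grating (period p = 390 nm, depth 90 nm,
duty cycle 0.5) etched into a 240-nm silicon nitride slab on fused silica,
operated in TM polarization (magnetic field along the grooves) around
λ₀ = 630 nm. Incident light interferes through two pathways: a broad direct
(Fabry–Pérot, Q ≈ 2) transmission through the film, and a narrow resonant
pathway via the leaky TM₀ guided mode that the grating phase-matches. Their
interference produces a Fano dip in transmission whose angular selectivity
is the imaging filter.

### Coupled-mode (CMT) model — `nlmscope.gmr`

The analytic model writes the transmission as a background `t_bg(λ, θ)`
(identity, or a thin-film transfer-matrix of the unpatterned stack) times a
product of two branch Fano factors

    t/t_bg = ∏_j (x_j − t_min·b_j) / (x_j + i·b_j),   x_j = (λ − λ₀) ∓ h,

with branch half-splitting `h = sqrt((p sinθ)² + (gap/2)²)` and half-widths

    b_bright = b = γ/2 = λ₀/(2Q),      b_dark = b·h²/(b² + h²).

At normal incidence only the bright standing-wave combination of the two
counter-propagating guided modes couples to the incident beam; the dark
branch's radiative width vanishes and its factor reduces to exactly 1, so
the spectral dip has the published linewidth γ = λ₀/Q. Away from normal
incidence the dark width switches on over the scale h ~ b and the two
branches become independent dips. With the default parameters this yields an
on-resonance angular FWHM of ≈ 1.8°, close to the published 2°.

**Residual floor and its phase.** The measured device blocks ~97% of the
paraxial light; the model's `t_min` (default amplitude 0.17, intensity 3%)
reproduces that floor. The transmission zero is placed on the *real* axis,
offset by `t_min·b`, so the residual transmitted field on a branch center is
`+i·t_min·t_bg` — in phase *quadrature* with the off-resonance background.
That quadrature is the mechanism of the contrast (the π/2 shift of the
paraxial rays) and matches the full-wave solver's behavior near its
transmission zero. The price of a quadrature floor is a mild breach of
strict passivity: the asymmetric Fano wing peaks at |t| ≈ 1.014 for
t_min = 0.17 a few linewidths off resonance (exactly passive at t_min = 0);
transfer functions built from the CMT model carry a verified envelope bound
`1 + 1.2·t_min`, while RCWA-derived filters obey |t| ≤ 1 strictly.

The `gap` parameter (branch splitting at θ = 0) defaults to 0; the full-wave
solution of this geometry shows an avoided crossing (below), and the
parameter is exposed for users who want to match it.

### Rigorous coupled-wave analysis — `nlmscope.rcwa`

The exact solver expands each layer's fields in spatial harmonics
(truncation half-width `n_orders`, default 20, converged to ~1e−5 at 14),
using the inverse-rule Fourier factorization for the TM permittivity
products — the eigenproblem is `Ω = A⁻¹(Kx E⁻¹ Kx − I)` with `E` the
Toeplitz matrix of ε harmonics and `A` that of 1/ε — and assembles layers
with Redheffer-star scattering matrices, so only decaying exponentials
appear. Conventions: exp(−iωt), forward phase exp(+ikz z); the zero-order
amplitude is power-normalized (|t|² = transmittance) and phase-referenced
entry face → exit face, which makes the zero-groove-depth limit agree with
the independent thin-film transfer-matrix implementation to machine
precision (this equivalence is a test, not a calibration).

**Material indices.** The published design gives the geometry but not the PECVD
nitride index. Defaults are n(SiO₂) = 1.45 and n(Si₃N₄) = 2.02,
non-dispersive; `calibrate_stack` then adjusts the nitride index once (a
single scalar, secant iteration) so the normal-incidence dip sits at 630 nm,
giving n = 2.0042. All device metrics are computed from that calibrated
stack; nothing else is fitted.

**What the calibrated stack reproduces.** Dip at 630.00 nm with T_min ~
1e−12 (≥ 97% blocking), spectral FWHM 8.5 nm (reported: 11 nm), angular FWHM
2.27° (reported: 2°), T(75°) = 76% (reported: 75%), first diffraction order
opening at 9.5° carrying < 4% (reported: < 5%). The width deviations are the
expected price of a reconstructed duty cycle and index. The branch
dispersion is an avoided crossing: dip loci fit
λ = λ_c ± sqrt((0.81·p·sinθ)² + (g/2)²) with λ_c ≈ 625 nm and g ≈ 10 nm —
the slope compression comes from TM₀ modal dispersion, and the gap is a real
feature of the lamellar geometry that the printed parameters do not pin
down. The bright band edge at θ = 0 is the 630-nm dip.

**Ripple artifact caveat.** Images of sharp phase edges through the filter
show a ripple train whose spacing is one over the spatial frequency of the
sharpest structure in H(fx). In this reconstruction that structure is the
narrow dark-branch dip, whose position is set by the ~10-nm gap; the
simulated spacing (≈ 31 µm under the 6-nm source, by the frozen measurement
procedure: 1.5-µm smoothing, 1% peak prominence, 4–90 µm window beyond the
bar edge) therefore differs from the published 16 µm, which corresponds to
H-structure near 2.3° that the printed geometry alone does not reproduce.
At exact resonance with strictly monochromatic light the model predicts *no*
ripple train at all: the background H(0) ≈ 0 and the notch walls are
pole-like (smooth), so the kernel tail decays without oscillating.

## Image formation — `nlmscope.imaging`

Image formation is done directly in the Fourier domain (the 4f relay is
abstracted; no focal length enters). For each spectral sample λ_k of the
source (Gaussian profile, FWHM 6 nm as published, 7 samples across ±1.5
FWHM; 0 nm = monochromatic): FFT the complex specimen transmission,
multiply by H(fx) interpolated at fx = sinθ/λ_k along the *filtered axis
only* (the 1D NLM is anisotropic), multiply by the circular pupil indicator
fx² + fy² ≤ (NA/λ_k)², inverse FFT, take |·|². Samples add incoherently.
Illumination is a single collimated plane wave (the source's 0.02° angular
spread is 100× smaller than the 2° filter width and is neglected).

Numerical choices: objects are embedded in a background of 1, zero-padded
(factor 2) with a cosine taper applied to the deviation across the pad
margin, so FFT wrap-around — an artifact of the implementation, not the
optics — is suppressed; evanescent frequencies are zeroed; the object pitch
must satisfy pitch ≤ λ/(4·NA), enforced. The camera is ideal; a seeded
Poisson hook exists for robustness experiments. A Zernike phase-contrast
reference path (isotropic annular filter with attenuation and π/2 shift) is
provided for qualitative comparison and reproduces halo/shade-off when the
annulus is wide.

## Quantitative retrieval — `nlmscope.retrieval`

A weak phase object e^{iφ} ≈ 1 + iφ scatters a field in quadrature with the
background; through the filter the camera intensity becomes a monotone
function of φ. The pipeline measures that relation once on features of known
phase and inverts it:

- **Signal estimator** (default): background-normalized region-mean
  intensity, with regions eroded by 2 px so edge ripples do not bias the
  statistics; Michelson contrast is available as an alternative. Region
  means are retrieved by inverting the region-mean signal — the same
  estimator order used to build the calibration — so ripple-induced
  nonlinearity cancels in closed loop.
- **Calibration curve**: monotone PCHIP through ≥ 3 steps (default 10 steps,
  0.02π–0.5π); non-monotone data are refused with the offending interval
  named; extrapolation is forbidden, and out-of-range pixels are masked.
- **Source bandwidth matters.** With strictly monochromatic on-resonance
  illumination the coherent ripples make the 20-µm-patch signal roll over
  near 0.3π and no valid calibration exists; with the published 6-nm source
  the incoherent spectral average smooths the ripples and the signal is
  strictly monotone over the full range. The calibration/retrieval pipeline
  therefore always uses the 6-nm source.
- **Feature-size dependence.** A notch filter removes part of a feature's
  *own* low-frequency content, so the interior signal of a uniform feature
  depends on its size (shade-off): between 12-µm and 22-µm disks the signal
  differs by ~40% at 0.3π. A single curve calibrated on one geometry is
  accurate only for features of matching spectral content — the pillar
  pipeline calibrates on uniform steps of the same 20-µm patch layout. For
  size-heterogeneous specimens, `CalibrationFamily` builds curves on
  uniform-step disks of several diameters and inverts each region with the
  curve interpolated at its label-equivalent diameter.

Closed-loop accuracy with these choices: every region of the 10-patch
pillar phantom (0.04π–0.4π) is recovered to ≤ 0.013π, and over many seeded
cell phantoms the maximum region error stays below 0.02π — the device's
headline accuracy.

## Phantoms — `nlmscope.phantoms`

All phantoms are pure functions of their parameters (and seed): USAF-style
three-bar targets at the printed line widths (3.71 µm and 780 nm; the
standard width formula is provided separately since printed widths deviate
from it), 10-patch pillar arrays (0.04π–0.4π, 20-µm patches; patch gap
defaults to 2× the patch size so neighbouring ripple trains, first lobe
~36 µm out, do not overlap patch interiors), single phase steps, uniform
disks with erf edges (the calibration feature), and cell-like phantoms:
non-overlapping round plateaus (diameters 12–22 µm, 1.5-µm erf rims, core
phases 0.04π–0.3π, 24-µm clearance — sparsely plated, isolated cells).
Phase heights can be specified directly or via thickness and index
(φ = 2π(n − n_amb)t/λ).

What the phantoms do *not* emulate: refractive-index tomograms, absorption,
intra-cell texture, optically dense/confluent cultures, or defocus. Passing
the closed-loop tests shows that the *method* is self-consistent at the
stated accuracy for weak, laterally structured phase objects imaged in
focus; it does not bound errors for specimens whose spatial-frequency
content differs strongly from the calibration features (the size-dependence
above is exactly such an effect, and it is the dominant systematic).

## Pipelines and provenance — `nlmscope.pipeline` / CLI

A single YAML configuration drives filter synthesis → phantom → imaging →
(optional) calibration → retrieval. Every run writes a resolved copy of its
configuration, a manifest with SHA-256 hashes of all artifacts, and stamps
derived artifacts with a configuration hash; retrieval refuses a calibration
whose hash does not match the image's. Identical configuration + seed
reproduces identical bytes. Problem sizes throughout (0.2-µm pitch, fields
of 100–500 µm, 41×345-point RCWA maps) were chosen as the smallest grids on
which the reported quantities are grid-converged at the stated tolerances.

## Known limitations

- Planar (in-plane) incidence and TM polarization only; no conical
  incidence, TE, or 2D (crossed) gratings; non-dispersive materials with an
  imaginary-part hook only.
- Coherent plane-wave illumination; no condenser/partial spatial coherence,
  no defocus or aberrations, no vectorial high-NA diffraction.
- The CMT model is phenomenological off-normal: branch widths and the
  avoided-crossing gap are parameters, not predictions; the quadrature
  residual floor mildly violates strict passivity (bounded, documented).
- Retrieval assumes the imaging configuration of the calibration; phase is
  reported only inside the calibrated range (no unwrapping, no halo
  correction).
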