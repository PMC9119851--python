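# Methods

## The problem

A 4Pi single-molecule localization microscope collects fluorescence
coherently through two opposed objectives. The two wavefronts interfere,
so the point spread function (PSF) carries an axial intensity modulation
with a fringe period of roughly λ/(2 n_sample) ≈ 253 nm for Alexa Fluor
647 in aqueous buffer. That modulation encodes the emitter's z coordinate
with sub-3-nm precision — but only modulo the fringe period, and only if
the model used for fitting has the correct interference phase. Thermal
drift of the interferometric cavity shifts that phase on the scale of
minutes, and a stale model produces "ghost" localizations displaced by
integer multiples of the fringe spacing.

This package implements the dynamic-spline analysis of that problem:

1. an experimentally measured bead z-scan is encoded as a multichannel
   tricubic spline,
2. the spline is decomposed into envelope and modulation, and the
   modulation phase is shifted numerically via a Hilbert transform,
3. raw movies are fit with the (phase-matched) model by multi-start
   maximum likelihood, with Cramér–Rao bounds for the expected precision,
4. registration, sample-drift, phase-drift, refractive-index/wavelength,
   and two-color corrections complete the pipeline.

Everything is testable against a built-in scalar physics simulator.

## Imaging model

The four detection channels (p1, s1, p2, s2) see the same PSF at relative
interference phases 0°, 90°, 180°, 270°. The expected image of an emitter
at (x0, y0, z0) with amplitude A and per-pixel background b is

    mu(x, y, c) = b + A · f_S(x − x0, y − y0, z0, c),

where f_S is the piecewise tricubic polynomial: within each voxel cell the
model is a 64-term polynomial in the normalized cell coordinates, with
coefficients obtained by tensor-product not-a-knot cubic interpolation of
the (preprocessed) bead scan. Not-a-knot was chosen over natural boundary
conditions because it reproduces cubics near the boundary; the
interpolation and continuity invariants hold either way and are asserted
in the test suite. The model's z axis indexes the axial position of the
emitter, so a camera frame is the model slice at z = z0. Out-of-support
evaluations raise; during fitting, position parameters are reflected back
into the support rather than extrapolating the cubic polynomial (which
diverges).

A single amplitude and a single background are shared by all four
channels, which keeps the five-parameter vector identifiable.

## Fit objective

The fit maximizes the Poisson likelihood by Levenberg–Marquardt-damped
Fisher scoring with analytic spline gradients; the reported Chi-square is
the Poisson deviance, which is nonnegative, vanishes for a perfect fit,
and is asymptotically chi-square distributed (the mean deviance of
matched fits ≈ the 191 degrees of freedom of a 7×7×4 ROI). An unweighted
least-squares objective (`objective="lsq"`) is retained. The choice
matters in two places:

* Efficiency. The exact sandwich covariance of the unweighted LS
  estimator on this PSF at 8,000 photons / 10 background is ≈1.28× the
  CRLB laterally; the MLE attains the CRLB within a few percent, which is
  the behavior the precision claims require.
* The two-color model-mismatch bias (below) is a least-squares
  phenomenon; the 1/mu weighting of the MLE suppresses it roughly
  tenfold. The mismatch-bias measurement therefore uses `objective="lsq"`.

Because the PSF is periodic in z, the deviance landscape has local minima
one fringe apart. Every fit is multi-started from z offsets spaced half a
fringe period (≈126 nm) apart across the full model support, and the
lowest-deviance converged start wins; ties break toward the focal plane.
Convergence is declared when the relative deviance improvement of an
accepted step falls below 1e-6 (50 iterations maximum).

## Phase shifting and phase estimation

The rendered model stack is split per z column into a low-pass envelope
(hard Fourier cutoff at a 500 nm period — the simplest faithful filter,
and the envelope + modulation reconstruction is exact by construction)
and the remaining modulation; the Hilbert transform of the modulation
supplies the quadrature component (cos → sin for positive wavenumbers).
The linear combination h_env + cosΔφ·h_mod + sinΔφ·h_mod90 advances the
interference phase by Δφ, moving fringes toward +z by Δφ/k. The test
suite verifies this transform against the simulator generating the same
PSF with its cavity phase advanced directly.

The experimental phase is estimated by fitting a set of emitter images
with 12 phase-shifted models equally spaced over 2π and locating the
minimum of the mean deviance versus model phase. Implementation details:

* Each image is first fit with the base model (full multi-start); each
  phase model then refits warm-started at z displaced by +Δφ/k (the
  geometric image of the phase shift) plus one fringe either side. This
  reproduces the full multi-start result at a fraction of the cost.
* A sine fit (first circular Fourier coefficient — the exact
  least-squares solution on an equally spaced grid) locates the minimum
  coarsely and flags non-sinusoidal curves. On the scalar simulator the
  curve deviates from a pure sinusoid away from its minimum, because the
  fit compensates model phase by sliding z until the compensation
  saturates at the fringe swap; a plain sine fit is then biased by up to
  ~0.26 rad. A parabola through the three samples around the sampled
  minimum removes that bias (<0.02 rad residual) and its vertex noise,
  propagated from the per-model standard errors, provides the reported
  precision. With 250 images of 8,000 photons the spread across repeats
  is ≈0.015–0.03 rad.
* Only images that converge under every model enter the mean.

Windowed application of the estimator gives the phase trace; windows are
unwrapped by nearest-multiple-of-2π continuation and jumps above π are
flagged. The phase-to-z proportionality is measured directly from the
PSF by fitting single z slices with phase-shifted copies of the model
over a 2-radian span; the slope is ≈ +fringe_period/2π ≈ +40 nm/rad with
our sign conventions (advancing the model phase moves the fitted z up;
an instrument phase drift moves apparent z down by the same factor, so
the correction adds slope·(φ(t) − φ_ref) back). The whole dataset is fit
with the model shifted to the mean unwrapped phase; per-window models are
the documented escape hatch when the trace spans more than 60°, the
margin below which fringe misassignment is unaffected (asserted in the
suite).

## Corrections

* Channel registration: second-order 2D polynomial maps fitted by least
  squares to matched bead positions (≥6, non-collinear), applied to
  images by cubic-spline resampling. Synthetic-warp recovery reaches the
  2 nm RMSD quality bar at 1 nm bead noise.
* Sample drift: localizations are split into time windows, rendered as
  3D histograms (10 nm voxels), and offsets measured between all window
  pairs from the cross-correlation peak (Gaussian fit over a 7³-voxel
  window in log space, centroid fallback); the redundant pairwise system
  is solved by weighted least squares (weights from peak heights),
  anchored at the first window.
* z rescaling: fitted z is multiplied by (λ_dye/λ_bead) — the fringe
  period scales with the detected wavelength (712 nm calibration beads
  versus 680/699 nm dyes) — and by (n_sample/n_immersion) = 1.346/1.406,
  because the calibration bead is scanned by the stage through immersion
  oil rather than an emitter moving in the sample medium. The combined
  AF647 factor is ≈0.914. The direction of both factors is validated on
  the simulator rather than assumed.
* Correction order is part of the contract: phase drift → sample drift →
  rescaling.
* Multistep scans: each stage step is analyzed independently with its own
  phase estimate and phase-matched model, then offset by the stage
  position; the low-NA index-mismatch prediction
  Δφ = (n_imm/n_s − n_s/n_imm)·4π n_s/λ0·Δz is logged as a consistency
  check only, never used as the correction.

## Two-color analysis

With the polarization-selective spectral filters, the s-polarized
channels are attenuated by ≈0.6 for Alexa Fluor 647 and ≈0.9 for Cy5.5.
Classification fits every event with both dye-specific (s-rescaled)
models and keeps the lower Chi-square; on simulated 8,000-photon data
this agrees with the plain s/p ratio threshold (midpoint 0.75) for >99%
of events. The simulator has no spectral or photophysical crosstalk, so
the ~93% accuracy observed on real two-dye data is an experimental
figure this package does not claim to reproduce. The fitted background
is apportioned equally across the four channels when computing ratios
(single-b model). A chromatic z offset (default 10 nm) is subtracted
from the Cy5.5 coordinates; which dye carries the offset is arbitrary
and documented. Fitting 0.6-ratio data with the 0.9-ratio model under
least squares biases z by up to ≈8 nm, periodically with half-fringe
(~126 nm) period — the reason the final color assignment must use the
correctly scaled model.

## The simulator

The scalar PSF is an axially modulated, defocus-widened Gaussian:

    I_c ∝ E(x, y, z) · [1 + m(z) cos(k z + δ_c − φ)] · w_c

with k = 2π/(λ0/2n_sample), channel phases δ_c in quadrature, instrument
phase φ, and s-channel weight w_c. Parameters were set once from the
optics they emulate:

* lateral σ0 = 140 nm and pixel size 138.2 nm (high-NA far-red PSF on the
  2×2-binned EMCCD);
* defocus widening σ_xy(z) = σ0·sqrt(1 + (0.25·z/σ0)²) — smooth
  (quadratic) at focus, as physical defocus is; a |z| kink would inject
  broadband power into the modulation band and break the
  envelope/modulation separation;
* an odd width term 0.1·z models index-mismatch spherical aberration.
  Without some parity breaking, the scalar PSF is exactly mirror
  symmetric in z and mirror ghosts become exactly degenerate — a
  pathology no real PSF has;
* axial envelope σ = 300 nm (≈700 nm FWHM focal envelope) and fringe
  visibility decay m(z) = 0.9·exp(−z²/2·700²) from cavity dispersion.
  Together with the width asymmetry this gives each z a unique shape
  signature, reproducing the artifact-free central 1.5 µm measured on
  the real instrument;
* photon budgets: 8,000 photons/event and 10 background photons/pixel
  (typical single-fluorophore statistics), 9,200 photons/frame for
  stepped-bead measurements with illumination equalized per frame.

Poisson shot noise is the only noise source (photon units throughout; no
EMCCD gain or excess-noise factor). What the simulator does *not* model:
vectorial/aberrated PSF structure (side lobes, rings), spectral
crosstalk, dipole orientation effects, detector artifacts. Passing tests
therefore demonstrate the correctness of the algorithms under the stated
statistical structure, not instrument-level fidelity far from focus; in
particular the off-focus artifact rise (~5% at ±1 µm on the instrument)
is not reproduced quantitatively, and the far-focus precision claims are
matched only near focus.

## Problem sizes

The suite and the acceptance script run the method at desk scale chosen
to keep the statistics meaningful: spline models of 17×17×(101–300)
voxels, 50 sets of 250 images for phase precision, 76 z steps × 20
frames for the artifact census, 250–300 images per precision
measurement, and drift fields of ~10⁴ localizations. Numbers quoted
above (CRLB ratios, bias magnitudes, precision) are the values these
runs compute.

## Known limitations

* The ⟨χ²⟩-versus-phase curve of the scalar simulator is not sinusoidal
  far from its minimum; the parabolic refinement handles this, but on
  real 4Pi data the plain sine fit may be adequate (the published curves
  are visibly sinusoidal).
* Per-window phase estimates retain a small (≲0.03 rad) bias that
  depends on where the true phase falls within the 12-model grid; it is
  common mode for slow drift and cancels in drift differences.
* The drift estimator assumes a structured (clustered) sample;
  featureless samples give weak correlation peaks (down-weighted, but
  with fewer constraints).
* Dense/overlapping emitters are not multi-fit; candidates closer than
  2 px merge into the brighter one.
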