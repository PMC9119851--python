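# fourpi-smlm

Dynamic-spline PSF modeling and localization analysis for 4Pi
interferometric single-molecule microscopy (4Pi-STORM / iPALM-class
instruments).

A 4Pi microscope detects each fluorophore through two opposed objectives
whose fields interfere, producing a four-channel PSF (relative
interference phases 0/90/180/270°) with an axial fringe of period
≈ λ/(2n) ≈ 253 nm. The fringe phase encodes the emitter's z coordinate
with nanometer precision — but modulo the fringe period, and only while
the model used for fitting matches the instrument's slowly drifting
cavity phase. A stale model produces *ghost* localizations displaced by
multiples of the fringe spacing.

This package implements the full analysis chain:

* **PSF calibration** — a four-channel bead z-scan is cropped,
  z-downsampled, smoothed, and converted to a multichannel tricubic
  spline `f_S(x, y, z, c)` with analytic gradients (the imaging model is
  `mu = b + A·f_S(x−x0, y−y0, z0, c)`).
* **Dynamic phase shifting** — the model is split into envelope and
  modulation by a Fourier low-pass along z; a Hilbert transform yields
  the quadrature modulation, and
  `h_env + cosΔφ·h_mod + sinΔφ·h_mod90` is the same PSF with its
  interference phase advanced by Δφ.
* **Phase tracking** — sets of ~250 emitter images are fit against 12
  phase-shifted models; the minimum of the mean Chi-square versus model
  phase pins the instrument phase to ≈0.02 rad, giving a time-resolved
  phase trace that is converted to a z correction.
* **Localization** — detection on the modulation-free channel-summed
  movie, grouping across frames, multi-start Poisson maximum-likelihood
  fitting (starts spaced below the fringe period so every local minimum
  is sampled), Cramér–Rao bounds, and fringe-misassignment statistics.
* **Corrections** — quadratic channel co-registration, redundant
  cross-correlation sample-drift estimation, wavelength and
  refractive-index z rescaling, multistep z-stage scans, and
  ratiometric two-dye classification with dye-specific rescaled PSF
  models.
* **Simulator** — a scalar 4Pi PSF generator (envelope × quadrature
  fringe, Poisson noise, phase and sample drift) that makes every stage
  testable without instrument data.

## Worked example

Simulate emitters at known positions, build a spline model, and fit:

```python
import numpy as np
from fourpi_smlm import (
    OpticalConfig, GroundTruthEmitter,
    make_symmetric_4pi_psf, compute_spline_coefficients,
    simulate_emitter_image, fit_images, compute_crlb, PSFModelParams,
)

cfg = OpticalConfig()                      # 680 nm, n=1.346/1.406, 138.2 nm px
stack = make_symmetric_4pi_psf(cfg, n_xy=17, n_z=121, dz=10.0)
psf = compute_spline_coefficients(stack)   # 4 x 64 x 16 x 16 x 120 coefficients

rng = np.random.default_rng(1)
ims = np.stack([
    simulate_emitter_image(
        psf, GroundTruthEmitter(x=10.0, y=5.0, z=0.0,
                                photons=8000, background=10),
        cfg=cfg, rng=rng)
    for _ in range(300)
])
params, chi2, ok = fit_images(ims, psf, cfg.pixel_size_lateral)
print("std x/y/z [nm]:", params[ok, 0].std(), params[ok, 1].std(),
      params[ok, 2].std())

pix = (np.arange(7) - 3) * cfg.pixel_size_lateral
rep = compute_crlb(psf, PSFModelParams(10, 5, 0, 8000, 10), pix, pix)
print("CRLB x/z [nm]:", rep.crlb_x, rep.crlb_z)
```

Output from this run:

```
std x/y/z [nm]: 1.75 1.86 0.74
CRLB x/z [nm]: 1.76 0.75
```

The empirical scatter of 300 fits (1.75 nm lateral, 0.75 nm axial at
8,000 photons with 10 background photons/pixel) matches the Poisson
Cramér–Rao bound — the fringe makes the axial coordinate the *best*
determined one, the defining property of 4Pi detection.

The same API drives phase tracking
(`estimate_phase`, `phase_trace`, `correct_phase_drift`), drift
correction (`estimate_sample_drift`), z rescaling (`rescale_z`), and
two-color assignment (`assign_color`). A thin CLI wraps the pipeline:

```sh
fourpi simulate --mode bead-scan --seed 1 --out scan.tif
fourpi calibrate-psf --scan scan.tif --out psf.h5
fourpi localize --movie movie.tif --psf psf.h5 --out locs.csv
fourpi phase-trace --movie movie.tif --psf psf.h5 --out phase.csv
fourpi drift-correct --locs locs.csv --out corrected.csv
fourpi rescale-z --locs corrected.csv --dye AF647 --out final.csv
```

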