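"""Physics-based synthetic data for the 4Pi analysis pipeline.

The scalar PSF model is an axially modulated, defocus-widened Gaussian:

    I_c(x, y, z) = E(x, y, z) * [1 + m * cos(k_z z + delta_c - phi)] * w_c

with ``k_z = 2 pi / fringe_period`` (fringe period ≈ λ0 / (2 n_sample)),
``delta_c`` the channel interference phases (0, 90, 180, 270 degrees),
``phi`` the instrument (cavity) phase, ``m`` the modulation depth and
``w_c`` the s/p amplitude ratio for s-polarized channels.  The envelope E
is Gaussian along z and Gaussian in (x, y) with a lateral sigma that widens
linearly with defocus.  Increasing ``phi`` moves the fringes toward +z, so
it matches the ``delta_phi`` convention of the Hilbert phase-shift
transform.

This is not a vectorial diffraction computation — it reproduces the one
structural property the analysis relies on, a periodic axial component
under a slowly varying envelope, with photon (Poisson) statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import OpticalConfig, S_CHANNEL_INDICES
from .psf_spline import BeadStack, SplinePSF

__all__ = [
    "GroundTruthEmitter",
    "DriftTraces",
    "scalar_psf_channels",
    "make_symmetric_4pi_psf",
    "simulate_emitter_image",
    "simulate_bead_scan",
    "simulate_experiment",
    "default_roi_coords",
]


@dataclass
class GroundTruthEmitter:
    """True state of one simulated fluorophore.

    ``photons`` is the expected number of detected photons summed over all
    four channels for an in-focus emitter; ``background`` is in
    photons/pixel/frame (per channel).
    """

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    photons: float = 8000.0
    background: float = 10.0
    frame_on: list = field(default_factory=lambda: [0])
    color: str = "AF647"

    def __post_init__(self) -> None:
        if self.photons <= 0:
            raise ValueError("photons must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")


@dataclass
class DriftTraces:
    """Per-frame instrument phase (rad) and 3D sample drift (nm)."""

    phase_vs_time: np.ndarray
    xyz_drift_vs_time: np.ndarray

    def __post_init__(self) -> None:
        self.phase_vs_time = np.asarray(self.phase_vs_time, float)
        self.xyz_drift_vs_time = np.atleast_2d(
            np.asarray(self.xyz_drift_vs_time, float)
        )
        if self.xyz_drift_vs_time.shape != (len(self.phase_vs_time), 3):
            raise ValueError("drift trace must be (n_frames, 3) matching phase trace")

    @classmethod
    def zero(cls, n_frames: int) -> "DriftTraces":
        return cls(np.zeros(n_frames), np.zeros((n_frames, 3)))


def scalar_psf_channels(
    cfg: OpticalConfig,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    phase: float = 0.0,
    sp_ratio: float | None = None,
) -> np.ndarray:
    """Unnormalized four-channel scalar PSF at broadcastable (x, y, z) nm.

    Returns an array with a leading channel axis (p1, s1, p2, s2).
    """
    x, y, z = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    )
    # smooth defocus widening: quadratic near focus, asymptotically linear
    # with slope defocus_spread_rate (a |z| kink at focus would leak
    # broadband content into the modulation band and break the
    # envelope/modulation separation)
    # plus an odd component from index-mismatch spherical aberration that
    # breaks the z -> -z mirror symmetry, as in any real PSF
    s0 = cfg.envelope_lateral_sigma0
    sigma_xy = (
        s0 * np.sqrt(1.0 + (cfg.defocus_spread_rate * z / s0) ** 2)
        + cfg.defocus_asymmetry * z
    )
    env = (
        np.exp(-0.5 * (x * x + y * y) / sigma_xy**2)
        / (2.0 * np.pi * sigma_xy**2)
        * np.exp(-0.5 * (z / cfg.envelope_axial_sigma) ** 2)
    )
    w_s = cfg.sp_amplitude_ratio if sp_ratio is None else sp_ratio
    # fringe visibility decays away from focus (cavity dispersion)
    m_eff = cfg.modulation_depth * np.exp(
        -0.5 * (z / cfg.modulation_axial_sigma) ** 2
    )
    out = np.empty((4,) + x.shape)
    for c, delta in enumerate(cfg.channel_phase_offsets):
        w = w_s if c in S_CHANNEL_INDICES else 1.0
        out[c] = w * env * (
            1.0 + m_eff * np.cos(cfg.k_axial * z + delta - phase)
        )
    return out


def _grid_coords(n: int, d: float) -> np.ndarray:
    return (np.arange(n) - 0.5 * (n - 1)) * d


def make_symmetric_4pi_psf(
    cfg: OpticalConfig,
    n_xy: int = 17,
    n_z: int = 121,
    dz: float = 10.0,
    phase: float = 0.0,
    sp_ratio: float | None = None,
) -> BeadStack:
    """Noiseless four-channel scalar 4Pi PSF on a voxel grid.

    The stack is normalized so the four-channel lateral sum at the focal
    (z = 0) plane integrates to 1: the fit amplitude A is then on the scale
    of detected photons.  The grid must cover at least one fringe period
    axially and 17 pixels laterally.
    """
    if n_xy < 17:
        raise ValueError("lateral extent must be at least 17 pixels")
    if (n_z - 1) * dz < cfg.fringe_period:
        raise ValueError("axial grid too small to contain one fringe period")
    dxy = cfg.pixel_size_lateral
    xs = _grid_coords(n_xy, dxy)
    zs = _grid_coords(n_z, dz)
    Z, Y, X = np.meshgrid(zs, xs, xs, indexing="ij")
    data = scalar_psf_channels(cfg, X, Y, Z, phase=phase, sp_ratio=sp_ratio)
    # normalize: four-channel z=0 lateral sum integrates to 1
    k0 = int(np.argmin(np.abs(zs)))
    norm = data[:, k0].sum()
    data /= norm
    return BeadStack(
        data=data,
        voxel_size=(dxy, dxy, dz),
        z_origin=float(zs[0]),
    )


def default_roi_coords(cfg: OpticalConfig, roi_size: int = 7) -> np.ndarray:
    """Pixel-center coordinates (nm) of a centered square ROI."""
    return _grid_coords(roi_size, cfg.pixel_size_lateral)


def _expected_roi_image(
    psf,
    cfg: OpticalConfig,
    emitter: GroundTruthEmitter,
    roi_size: int,
    phase: float,
) -> np.ndarray:
    """Noise-free expected ROI image (4, roi, roi) excluding background."""
    px = default_roi_coords(cfg, roi_size)
    X, Y = np.meshgrid(px - emitter.x, px - emitter.y)
    Z = np.full_like(X, emitter.z)
    if isinstance(psf, SplinePSF):
        f = psf.evaluate(X, Y, Z)
    elif isinstance(psf, BeadStack):
        # interpret a BeadStack as a pixel-matched model via its own spline
        from .psf_spline import compute_spline_coefficients

        f = compute_spline_coefficients(psf).evaluate(X, Y, Z)
    else:  # OpticalConfig → analytic scalar model, photon-normalized
        model = scalar_psf_channels(cfg, X, Y, Z, phase=phase)
        x_full = _grid_coords(17, cfg.pixel_size_lateral)
        Xf, Yf = np.meshgrid(x_full, x_full)
        norm = scalar_psf_channels(cfg, Xf, Yf, np.zeros_like(Xf), phase=phase).sum()
        f = model / norm
    return emitter.photons * f


def simulate_emitter_image(
    psf,
    emitter: GroundTruthEmitter,
    cfg: OpticalConfig | None = None,
    roi_size: int = 7,
    rng=None,
    phase: float = 0.0,
    noiseless: bool = False,
) -> np.ndarray:
    """Poisson-noisy four-channel ROI image of a single emitter.

    ``psf`` may be a SplinePSF, a BeadStack, or None (then the analytic
    scalar model of ``cfg`` at instrument phase ``phase`` is used).  The
    expected pixel values are ``photons * f + background``; the emitter must
    lie within the model's support.
    """
    if cfg is None:
        if not isinstance(psf, (SplinePSF, BeadStack)):
            raise ValueError("cfg required when no PSF model is given")
        cfg = OpticalConfig()
    if isinstance(psf, (SplinePSF, BeadStack)):
        support = (
            psf.support[2]
            if isinstance(psf, SplinePSF)
            else (psf.z_coords[0], psf.z_coords[-1])
        )
        if not support[0] <= emitter.z <= support[1]:
            raise ValueError(
                f"emitter z={emitter.z:.0f} nm outside model support {support}"
            )
    mu = _expected_roi_image(psf, cfg, emitter, roi_size, phase) + emitter.background
    if noiseless:
        return mu
    rng = np.random.default_rng(rng)
    return rng.poisson(np.clip(mu, 0.0, None)).astype(float)


def simulate_bead_scan(
    source,
    z_range: float = 3000.0,
    n_steps: int = 3000,
    photons_per_frame: float = 9200.0,
    background: float = 0.0,
    rng=None,
    noiseless: bool = False,
    equalize_frames: bool = True,
    n_xy: int = 17,
) -> BeadStack:
    """Simulate a bead z-scan: one frame per z step over ``z_range`` nm.

    ``source`` is an OpticalConfig (analytic scalar PSF) or a SplinePSF.
    With ``equalize_frames`` (illumination adjusted per frame, as when a
    bead is used as a single-fluorophore stand-in) every frame has expected
    total ``photons_per_frame``; otherwise the axial envelope decay is kept
    and the focal frame carries ``photons_per_frame``.  ``noiseless``
    disables the Poisson draw for oracle tests.
    """
    if n_steps < 2:
        raise ValueError("need at least 2 z steps")
    dz = z_range / n_steps
    zs = _grid_coords(n_steps, dz)
    if isinstance(source, SplinePSF):
        dxy = source.knot_spacings[0]
        xs = _grid_coords(n_xy, dxy)
        (zlo, zhi) = source.support[2]
        if zs[0] < zlo or zs[-1] > zhi:
            raise ValueError("requested z range exceeds the spline support")
        Z, Y, X = np.meshgrid(zs, xs, xs, indexing="ij")
        data = source.evaluate(X, Y, Z)
    else:
        cfg = source
        dxy = cfg.pixel_size_lateral
        xs = _grid_coords(n_xy, dxy)
        Z, Y, X = np.meshgrid(zs, xs, xs, indexing="ij")
        data = scalar_psf_channels(cfg, X, Y, Z)
    data = np.clip(data, 0.0, None)
    if equalize_frames:
        totals = data.sum(axis=(0, 2, 3))
        data = data / totals[None, :, None, None] * photons_per_frame
    else:
        k0 = int(np.argmin(np.abs(zs)))
        data = data / data[:, k0].sum() * photons_per_frame
    data = data + background
    if not noiseless:
        rng = np.random.default_rng(rng)
        data = rng.poisson(data).astype(float)
    return BeadStack(data=data, voxel_size=(dxy, dxy, dz), z_origin=float(zs[0]))


def simulate_stepped_bead(
    psf,
    z_positions: np.ndarray,
    photons_per_frame: float = 9200.0,
    background: float = 10.0,
    n_frames_per_step: int = 20,
    roi_size: int = 7,
    pixel_size: float | None = None,
    rng=None,
    noiseless: bool = False,
):
    """Emitter images of a bead stepped through z at constant brightness.

    Emulates the stepped-bead precision measurement: the illumination is
    adjusted so every frame carries ``photons_per_frame`` expected detected
    photons regardless of the axial envelope decay.  ``psf`` is a SplinePSF;
    returns (images (N, 4, roi, roi), z_true (N,)).
    """
    rng = np.random.default_rng(rng)
    if pixel_size is None:
        pixel_size = psf.knot_spacings[0]
    px = _grid_coords(roi_size, pixel_size)
    X, Y = np.meshgrid(px, px)
    ims = []
    z_true = []
    for z in np.asarray(z_positions, float):
        f = psf.evaluate(X, Y, np.full_like(X, z))
        tot = f.sum()
        if tot <= 0:
            raise ValueError(f"PSF integrates to zero at z={z:.0f} nm")
        mu = photons_per_frame * f / tot + background
        for _ in range(n_frames_per_step):
            img = mu if noiseless else rng.poisson(np.clip(mu, 0, None)).astype(float)
            ims.append(img)
            z_true.append(z)
    return np.stack(ims), np.array(z_true)


def simulate_experiment(
    cfg: OpticalConfig,
    emitters: list,
    drift: DriftTraces | None = None,
    n_frames: int | None = None,
    rng=None,
    roi_size: int = 7,
    frame_time_s: float = 0.01,
):
    """Compose emitter images over frames with phase and sample drift.

    Returns ``(images, truth)`` where ``images`` is a dict mapping frame
    index to a list of (emitter_index, roi_image) entries and ``truth`` is a
    DataFrame with the true coordinates (drift applied), photons, frame,
    time and instrument phase at emission time.  Emitters are simulated as
    isolated ROIs — the full-field rendering lives in the movie writer.
    """
    rng = np.random.default_rng(rng)
    if n_frames is None:
        n_frames = 1 + max(max(e.frame_on) for e in emitters)
    if drift is None:
        drift = DriftTraces.zero(n_frames)
    if len(drift.phase_vs_time) < n_frames:
        raise ValueError("drift traces shorter than the movie")
    images: dict = {f: [] for f in range(n_frames)}
    rows = []
    for idx, em in enumerate(emitters):
        for f in em.frame_on:
            if f >= n_frames:
                continue
            dx, dy, dz_ = drift.xyz_drift_vs_time[f]
            phi = drift.phase_vs_time[f]
            shifted = GroundTruthEmitter(
                x=em.x + dx,
                y=em.y + dy,
                z=em.z + dz_,
                photons=em.photons,
                background=em.background,
                frame_on=[f],
                color=em.color,
            )
            img = simulate_emitter_image(
                None, shifted, cfg=cfg, roi_size=roi_size, rng=rng, phase=phi
            )
            images[f].append((idx, img))
            rows.append(
                dict(
                    emitter=idx,
                    frame=f,
                    time_s=f * frame_time_s,
                    x_nm=shifted.x,
                    y_nm=shifted.y,
                    z_nm=shifted.z,
                    photons=em.photons,
                    background=em.background,
                    phase_rad=phi,
                    color=em.color,
                )
            )
    truth = pd.DataFrame(rows)
    return images, truth
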