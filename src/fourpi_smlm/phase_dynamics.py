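"""Envelope/modulation decomposition, numerical phase shifting, phase
estimation and phase-drift correction.

The 4Pi PSF is split along z into a slowly varying envelope (Fourier
low-pass, hard cutoff at a 500 nm period by default) and an oscillating
interference modulation.  A Hilbert transform of the modulation yields its
90-degree-shifted quadrature partner, and the linear combination

    h(dphi) = h_env + cos(dphi) * h_mod + sin(dphi) * h_mod90

is the same PSF with its interference phase advanced by dphi (fringes move
toward +z by dphi / k_z).  Because the emitter z coordinate is encoded in
the interference phase, an instrument phase drift of dphi shifts apparent
z by -dphi / k_z when fitting with a fixed model; the calibration below
measures that proportionality directly from the PSF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from . import _kernels
from .localization import _geom, fit_images
from .psf_spline import BeadStack, SplinePSF, compute_spline_coefficients

__all__ = [
    "PSFDecomposition",
    "PhaseTrace",
    "PhaseZCalibration",
    "decompose_psf",
    "phase_shift_psf",
    "build_phase_models",
    "estimate_phase",
    "phase_trace",
    "calibrate_phase_to_z",
    "correct_phase_drift",
]


@dataclass
class PSFDecomposition:
    """Envelope + modulation (+ quadrature) split of a four-channel PSF."""

    h_env: np.ndarray
    h_mod: np.ndarray
    h_mod_90: np.ndarray
    voxel_size: tuple
    z_origin: float
    channel_order: tuple

    def reconstruct(self) -> np.ndarray:
        """h_env + h_mod — equals the source stack exactly by construction."""
        return self.h_env + self.h_mod


@dataclass
class PhaseTrace:
    """Time-resolved PSF interference phase (unwrapped)."""

    window_times: np.ndarray
    window_phases: np.ndarray
    phase_precision: np.ndarray
    n_locs_per_window: np.ndarray
    jump_flags: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.window_times = np.asarray(self.window_times, float)
        self.window_phases = np.asarray(self.window_phases, float)
        if self.jump_flags is None:
            self.jump_flags = np.zeros(len(self.window_phases), bool)

    @property
    def mean_phase(self) -> float:
        return float(np.mean(self.window_phases))

    def phase_at(self, t) -> np.ndarray:
        """Linear interpolation between windows; nearest-window beyond."""
        return np.interp(t, self.window_times, self.window_phases)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            dict(
                time_s=self.window_times,
                phase_rad=self.window_phases,
                precision_rad=self.phase_precision,
                n_locs=self.n_locs_per_window,
            )
        ).to_csv(path, index=False)


@dataclass
class PhaseZCalibration:
    """Apparent-z shift per radian of model phase shift.

    ``slope`` is d(fitted z)/d(model phase) in nm/rad; with the fringe
    convention used here it is positive, ≈ +fringe_period / 2π.  The
    apparent z of a localization fitted with a *fixed* model moves with the
    opposite sign when the instrument phase drifts, so the correction adds
    ``slope * (phase(t) - reference_phase)`` back onto z.
    """

    slope: float
    residual_rms: float = 0.0
    r_squared: float = 1.0
    flagged: bool = False


def decompose_psf(stack, cutoff_period: float = 500.0) -> PSFDecomposition:
    """Split a PSF stack into envelope and modulation along z.

    The envelope keeps Fourier components with a period longer than
    ``cutoff_period`` nm (hard cutoff, no taper); the modulation is the
    remainder, and its quadrature partner is the Hilbert transform along z
    (cos -> sin for positive wavenumbers).
    """
    if isinstance(stack, SplinePSF):
        stack = stack.render(sampling=1)
    data = stack.data
    nz = data.shape[1]
    dz = stack.voxel_size[2]
    if nz * dz <= cutoff_period:
        raise ValueError("z extent must exceed the cutoff period")
    freqs = np.fft.rfftfreq(nz, d=dz)
    keep = freqs < 1.0 / cutoff_period
    spec = np.fft.rfft(data, axis=1)
    spec[:, ~keep] = 0.0
    h_env = np.fft.irfft(spec, n=nz, axis=1)
    h_mod = data - h_env
    h_mod_90 = np.imag(hilbert(h_mod, axis=1))
    return PSFDecomposition(
        h_env=h_env,
        h_mod=h_mod,
        h_mod_90=h_mod_90,
        voxel_size=stack.voxel_size,
        z_origin=stack.z_origin,
        channel_order=stack.channel_order,
    )


def phase_shift_psf(
    dec: PSFDecomposition, delta_phi: float, rebuild_spline: bool = True
):
    """PSF with its interference phase advanced by ``delta_phi`` radians.

    Returns (BeadStack, SplinePSF) — the spline records the applied
    ``phase_offset`` — or just the stack if ``rebuild_spline`` is False.
    """
    data = (
        dec.h_env
        + np.cos(delta_phi) * dec.h_mod
        + np.sin(delta_phi) * dec.h_mod_90
    )
    stack = BeadStack(
        data=data,
        voxel_size=dec.voxel_size,
        z_origin=dec.z_origin,
        channel_order=dec.channel_order,
    )
    if not rebuild_spline:
        return stack
    psf = compute_spline_coefficients(stack)
    psf.phase_offset = float(delta_phi)
    return stack, psf


def build_phase_models(base_psf: SplinePSF, n_models: int = 12) -> list:
    """``n_models`` phase-shifted copies of a PSF, equally spaced in
    [0, 2π).  Returns a list of (delta_phi, SplinePSF)."""
    dec = decompose_psf(base_psf)
    out = []
    for dphi in np.arange(n_models) * 2 * np.pi / n_models:
        _, psf = phase_shift_psf(dec, float(dphi))
        out.append((float(dphi), psf))
    return out


def _sine_fit_minimum(phases: np.ndarray, chi2: np.ndarray) -> tuple:
    """Fit a + c*cos(dphi - phi*) to equally spaced samples; the first
    circular Fourier coefficient is the exact least-squares solution.
    Returns (phase_of_minimum, amplitude, offset, residual_rms)."""
    n = len(phases)
    a = chi2.mean()
    c_cos = 2.0 / n * np.sum(chi2 * np.cos(phases))
    c_sin = 2.0 / n * np.sum(chi2 * np.sin(phases))
    amp = float(np.hypot(c_cos, c_sin))
    phi_max = float(np.arctan2(c_sin, c_cos))
    fit = a + c_cos * np.cos(phases) + c_sin * np.sin(phases)
    resid = float(np.sqrt(np.mean((chi2 - fit) ** 2)))
    phi_min = (phi_max + np.pi) % (2 * np.pi)
    return phi_min, amp, float(a), resid


def estimate_phase(
    images: np.ndarray,
    base_psf: SplinePSF,
    pixel_size: float,
    n_phase_models: int = 12,
    models: list | None = None,
    fringe_period: float | None = None,
    return_curve: bool = False,
):
    """Estimate the experimental PSF phase from a set of emitter images.

    Every image is fit against ``n_phase_models`` phase-shifted models; the
    mean Chi-square versus model phase has a single minimum at the phase of
    the data.  A sine fit locates the minimum coarsely (and flags
    non-sinusoidal curves); a parabola through the three samples around the
    sampled minimum refines it.  Returns (phase in [0, 2π), precision in
    rad, info dict).

    ``images`` is an (N, 4, roi, roi) array; pass a prebuilt ``models``
    list (from :func:`build_phase_models`) to amortize model construction.
    """
    images = np.ascontiguousarray(images, dtype=np.float64)
    if images.ndim != 4:
        raise ValueError("images must be (N, channels, roi, roi)")
    if models is None:
        models = build_phase_models(base_psf, n_phase_models)
    if fringe_period is None:
        from .localization import _modulation_wavenumber_estimate

        fringe_period = 2 * np.pi / _modulation_wavenumber_estimate(base_psf)
    n = images.shape[0]
    roi = images.shape[-1]
    pix = (np.arange(roi) - 0.5 * (roi - 1)) * pixel_size

    params0, _, conv0 = fit_images(images, base_psf, pixel_size)
    ok = conv0.copy()
    phases = np.array([m[0] for m in models])
    mean_chi2 = np.full(len(models), np.nan)
    conv_all = ok.copy()
    chi2_per_model = np.full((len(models), n), np.nan)
    k_mod = 2 * np.pi / fringe_period
    for im, (dphi, psf) in enumerate(models):
        # a model with its phase advanced by dphi fits the same image at a z
        # displaced by +dphi/k; warm-start there and one fringe either side
        z_shift = dphi / k_mod
        z_offsets = z_shift + np.array([-fringe_period, 0.0, fringe_period])
        _, chi2s, conv = _kernels.refit_batch(
            *_geom(psf), pix, pix, images,
            np.ascontiguousarray(params0), z_offsets, 50, 1e-6,
            _kernels.MODE_MLE,
        )
        chi2_per_model[im] = chi2s
        conv_all &= conv
    if not conv_all.any():
        raise ValueError("no image converged under every phase model")
    used = chi2_per_model[:, conv_all]
    mean_chi2 = used.mean(axis=1)
    n_used = int(conv_all.sum())
    sem = used.std(axis=1, ddof=1) / np.sqrt(max(n_used, 2))
    phi_sine, amp, offset, resid = _sine_fit_minimum(phases, mean_chi2)
    # the scalar-model <chi2> curve departs from a pure sinusoid away from
    # its minimum (the z compensation saturates at the fringe swap), which
    # would bias the sine-fit minimum; refine with a parabola through the
    # three samples around the sampled minimum
    nmod = len(models)
    h = phases[1] - phases[0]
    i0 = int(np.argmin(mean_chi2))
    y0, y1, y2 = (
        mean_chi2[(i0 - 1) % nmod],
        mean_chi2[i0],
        mean_chi2[(i0 + 1) % nmod],
    )
    den = y0 - 2 * y1 + y2
    if den > 0:
        shift = 0.5 * (y0 - y2) / den
        phi_min = float((phases[i0] + shift * h) % (2 * np.pi))
        # propagate the per-point standard errors through the vertex
        sig = float(np.mean(sem[[(i0 - 1) % nmod, i0, (i0 + 1) % nmod]]))
        num = y0 - y2
        precision = float(
            0.5 * h * sig * np.sqrt(2 * den**2 + 6 * num**2) / den**2
        )
    else:  # degenerate curvature: fall back to the sine-fit minimum
        phi_min = phi_sine
        precision = np.inf
    low_confidence = amp <= 0 or resid > 0.75 * amp or not np.isfinite(precision)
    info = dict(
        phases=phases,
        mean_chi2=mean_chi2,
        amplitude=amp,
        offset=offset,
        residual_rms=resid,
        n_used=n_used,
        low_confidence=bool(low_confidence),
    )
    if return_curve:
        return phi_min, precision, info
    return phi_min, precision, info


def phase_trace(
    images: np.ndarray,
    times: np.ndarray,
    base_psf: SplinePSF,
    pixel_size: float,
    window_size: int = 250,
    min_window: int = 50,
    n_phase_models: int = 12,
) -> PhaseTrace:
    """Windowed phase estimation over a time-ordered localization stream.

    ``images`` (N, 4, roi, roi) and ``times`` (N,) must be time-ordered.
    Windows of ``window_size`` images are estimated independently and
    unwrapped by nearest-multiple-of-2π continuation; a trailing window
    smaller than ``min_window`` is merged into its predecessor.
    """
    times = np.asarray(times, float)
    if np.any(np.diff(times) < 0):
        raise ValueError("stream must be time-ordered")
    n = images.shape[0]
    edges = list(range(0, n, window_size))
    if len(edges) > 1 and n - edges[-1] < min_window:
        edges.pop()
    bounds = [(s, min(s + window_size, n)) for s in edges]
    if bounds and len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < min_window:
        s_prev, _ = bounds[-2]
        bounds = bounds[:-2] + [(s_prev, n)]
    models = build_phase_models(base_psf, n_phase_models)
    t_list, phi_list, prec_list, n_list = [], [], [], []
    for s, e in bounds:
        phi, prec, _ = estimate_phase(
            images[s:e], base_psf, pixel_size, models=models
        )
        t_list.append(times[s:e].mean())
        phi_list.append(phi)
        prec_list.append(prec)
        n_list.append(e - s)
    phi_arr = np.unwrap(np.array(phi_list))
    jumps = np.zeros(len(phi_arr), bool)
    if len(phi_arr) > 1:
        jumps[1:] = np.abs(np.diff(phi_arr)) > np.pi
    return PhaseTrace(
        window_times=np.array(t_list),
        window_phases=phi_arr,
        phase_precision=np.array(prec_list),
        n_locs_per_window=np.array(n_list),
        jump_flags=jumps,
    )


def calibrate_phase_to_z(
    psf: SplinePSF,
    phase_span: float = 2.0,
    n_shifts: int = 9,
    n_planes: int = 5,
    r2_threshold: float = 0.99,
) -> PhaseZCalibration:
    """Measure the apparent-z shift per radian of model phase shift.

    Central z slices of the PSF are fit with phase-shifted copies of the
    full model, with shifts spanning ``phase_span`` radians; the fitted z
    versus applied phase is linear and its slope is the phase-to-z
    proportionality.
    """
    if phase_span <= 0:
        raise ValueError("phase_span must be positive (degenerate fit)")
    stack = psf.render(sampling=1)
    dec = decompose_psf(stack)
    dz = stack.voxel_size[2]
    nz = stack.data.shape[1]
    zc = stack.z_coords
    k0 = int(np.argmin(np.abs(zc)))
    span_planes = max(1, int(0.15 * nz))
    plane_idx = np.unique(
        np.linspace(k0 - span_planes, k0 + span_planes, n_planes).astype(int)
    )
    pix_x = stack.x_coords
    pix_y = stack.y_coords
    shifts = np.linspace(-0.5 * phase_span, 0.5 * phase_span, n_shifts)
    slopes = []
    all_shift, all_z = [], []
    for dphi in shifts:
        _, model = phase_shift_psf(dec, float(dphi))
        for kp in plane_idx:
            data = np.ascontiguousarray(stack.data[:, kp])
            p0 = np.array([0.0, 0.0, zc[kp], 1.0, 0.0])
            A0, b0 = _kernels._init_amplitude(
                *_geom(model), pix_x, pix_y, data, 0.0, 0.0, zc[kp]
            )
            p0[3], p0[4] = A0, b0
            p, chi2, conv, _ = _kernels.lm_fit(
                *_geom(model), pix_x, pix_y, data, p0, 50, 1e-8,
                _kernels.MODE_LSQ,
            )
            if conv:
                all_shift.append(dphi)
                all_z.append(p[2] - zc[kp])
    all_shift = np.array(all_shift)
    all_z = np.array(all_z)
    if len(all_shift) < 3:
        raise ValueError("too few converged plane fits for calibration")
    A = np.vstack([all_shift, np.ones_like(all_shift)]).T
    coef, res, *_ = np.linalg.lstsq(A, all_z, rcond=None)
    fit = A @ coef
    ss_res = float(np.sum((all_z - fit) ** 2))
    ss_tot = float(np.sum((all_z - all_z.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PhaseZCalibration(
        slope=float(coef[0]),
        residual_rms=float(np.sqrt(ss_res / len(all_z))),
        r_squared=float(r2),
        flagged=bool(r2 < r2_threshold),
    )


def correct_phase_drift(
    locs: pd.DataFrame,
    trace: PhaseTrace,
    cal: PhaseZCalibration,
    reference_phase: float | None = None,
    time_column: str = "time_s",
    z_column: str = "z_nm",
) -> pd.DataFrame:
    """Subtract the apparent-z drift caused by PSF phase drift.

    ``reference_phase`` defaults to the mean of the unwrapped trace — the
    phase the fitting model was shifted to.  With our positive slope
    convention the apparent z is low by ``slope * (phase(t) - ref)``, so
    that amount is added back.
    """
    if reference_phase is None:
        reference_phase = trace.mean_phase
    out = locs.copy()
    phase_t = trace.phase_at(out[time_column].to_numpy())
    out[z_column] = out[z_column] + cal.slope * (phase_t - reference_phase)
    out["phase_rad"] = phase_t
    return out
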