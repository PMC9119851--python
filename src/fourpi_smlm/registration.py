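"""Channel registration, sample-drift correction, z rescaling and
multistep-scan analysis.

The four EMCCD quadrants are co-registered with second-order (quadratic)
polynomial warps measured from bead positions.  Sample drift is estimated
by redundant cross-correlation: super-resolved histograms are rendered per
time window, offsets are measured between *all* window pairs, and one
trajectory is solved by weighted least squares.  Axial coordinates are
rescaled for the bead/dye wavelength difference and for the
sample/immersion refractive-index mismatch of the piezo bead scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .config import IndexWavelengthConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelTransform",
    "DriftTrajectory",
    "fit_channel_transform",
    "warp_channel",
    "estimate_sample_drift",
    "apply_drift_correction",
    "rescale_z",
    "predict_step_phase_shift",
    "analyze_multistep",
]


def _quad_design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(x), x, y, x * x, x * y, y * y]
    )


@dataclass
class ChannelTransform:
    """Quadratic polynomial maps between a channel and the reference (p1).

    ``to_ref`` maps channel coordinates to the reference frame (applied to
    localization coordinates); ``from_ref`` is the inverse-direction map
    used to resample channel images onto the reference grid.  Coefficient
    arrays have shape (2, 6) for [1, x, y, x^2, xy, y^2].
    """

    to_ref: np.ndarray
    from_ref: np.ndarray
    residual_rmsd: float = 0.0

    @classmethod
    def identity(cls) -> "ChannelTransform":
        c = np.zeros((2, 6))
        c[0, 1] = 1.0
        c[1, 2] = 1.0
        return cls(to_ref=c.copy(), from_ref=c.copy())

    def apply(self, xy: np.ndarray, inverse: bool = False) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, float))
        c = self.from_ref if inverse else self.to_ref
        D = _quad_design(xy[:, 0], xy[:, 1])
        return D @ c.T


def fit_channel_transform(
    ref_xy: np.ndarray, ch_xy: np.ndarray, holdout_fraction: float = 0.0
) -> ChannelTransform:
    """Least-squares quadratic map between bead positions in one channel
    and the reference channel.

    Requires at least 6 non-degenerate bead positions.  ``residual_rmsd``
    is evaluated on a held-out subset when ``holdout_fraction`` > 0,
    otherwise in-sample.
    """
    ref_xy = np.asarray(ref_xy, float)
    ch_xy = np.asarray(ch_xy, float)
    n = len(ref_xy)
    if n < 6 or len(ch_xy) != n:
        raise ValueError("need >= 6 matched bead positions")
    n_fit = n
    if holdout_fraction > 0:
        n_fit = max(6, int(round(n * (1 - holdout_fraction))))
    fit_idx = np.arange(n_fit)
    test_idx = np.arange(n_fit, n) if n_fit < n else fit_idx

    D_ch = _quad_design(ch_xy[fit_idx, 0], ch_xy[fit_idx, 1])
    if np.linalg.matrix_rank(D_ch) < 6:
        raise ValueError("degenerate bead geometry (collinear positions)")
    to_ref, *_ = np.linalg.lstsq(D_ch, ref_xy[fit_idx], rcond=None)
    D_ref = _quad_design(ref_xy[fit_idx, 0], ref_xy[fit_idx, 1])
    from_ref, *_ = np.linalg.lstsq(D_ref, ch_xy[fit_idx], rcond=None)

    pred = _quad_design(ch_xy[test_idx, 0], ch_xy[test_idx, 1]) @ to_ref
    rmsd = float(np.sqrt(np.mean(np.sum((pred - ref_xy[test_idx]) ** 2, axis=1))))
    return ChannelTransform(
        to_ref=to_ref.T, from_ref=from_ref.T, residual_rmsd=rmsd
    )


def warp_channel(
    image: np.ndarray, transform: ChannelTransform, fill_value: float = 0.0
) -> np.ndarray:
    """Resample a channel image onto the reference grid.

    Cubic-spline interpolation (order 3) with constant fill outside the
    source; coordinates are in pixels, (x, y) = (column, row).
    """
    ny, nx = image.shape
    Y, X = np.mgrid[0:ny, 0:nx].astype(float)
    src = transform.apply(np.column_stack([X.ravel(), Y.ravel()]), inverse=True)
    coords = np.vstack([src[:, 1], src[:, 0]])  # row, col order
    out = map_coordinates(
        image.astype(float), coords, order=3, mode="constant", cval=fill_value
    )
    return out.reshape(ny, nx)


@dataclass
class DriftTrajectory:
    """Per-window 3D drift offsets (nm), anchored at zero for the first
    window."""

    window_times: np.ndarray
    offsets: np.ndarray  # (n_windows, 3)

    def __post_init__(self) -> None:
        self.window_times = np.asarray(self.window_times, float)
        self.offsets = np.asarray(self.offsets, float)
        self.offsets = self.offsets - self.offsets[0]

    def at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return np.column_stack(
            [np.interp(t, self.window_times, self.offsets[:, d]) for d in range(3)]
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            dict(
                time_s=self.window_times,
                dx_nm=self.offsets[:, 0],
                dy_nm=self.offsets[:, 1],
                dz_nm=self.offsets[:, 2],
            )
        ).to_csv(path, index=False)


def _render_hist(coords: np.ndarray, edges: list) -> np.ndarray:
    h, _ = np.histogramdd(coords, bins=edges)
    return h


def _corr_peak_offset(a: np.ndarray, b: np.ndarray, fit_window: int = 7):
    """Offset of histogram b relative to a (in voxels) from the 3D
    cross-correlation, with sub-voxel refinement by a Gaussian (quadratic
    in log space) fit over a ``fit_window``-cubed region around the peak.
    Returns (offset_xyzvoxels, peak_height)."""
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    corr = np.real(np.fft.ifftn(fa * np.conj(fb)))
    corr = np.fft.fftshift(corr)
    center = np.array(corr.shape) // 2
    peak = np.array(np.unravel_index(np.argmax(corr), corr.shape))
    half = fit_window // 2
    slices = []
    for d in range(3):
        lo = int(np.clip(peak[d] - half, 0, corr.shape[d] - fit_window))
        slices.append(slice(lo, lo + fit_window))
    win = corr[tuple(slices)]
    wmin = win.min()
    logw = np.log(win - wmin + 1e-3 * (win.max() - wmin) + 1e-12)
    g = np.mgrid[0:fit_window, 0:fit_window, 0:fit_window].reshape(3, -1).T.astype(float)
    D = np.column_stack(
        [
            np.ones(len(g)),
            g[:, 0], g[:, 1], g[:, 2],
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            g[:, 0] * g[:, 1], g[:, 0] * g[:, 2], g[:, 1] * g[:, 2],
        ]
    )
    coef, *_ = np.linalg.lstsq(D, logw.ravel(), rcond=None)
    H = np.array(
        [
            [2 * coef[4], coef[7], coef[8]],
            [coef[7], 2 * coef[5], coef[9]],
            [coef[8], coef[9], 2 * coef[6]],
        ]
    )
    rhs = -coef[1:4]
    try:
        sub = np.linalg.solve(H, rhs)
    except np.linalg.LinAlgError:
        sub = np.full(3, np.nan)
    eigs = np.linalg.eigvalsh(H)
    if not np.all(eigs < 0) or np.any(np.abs(sub - half) > fit_window):
        # not a well-formed peak: fall back to intensity centroid
        w = win - wmin
        tot = w.sum()
        sub = (w.reshape(-1) @ g) / tot if tot > 0 else np.full(3, float(half))
    origin = np.array([s.start for s in slices])
    offset = origin + sub - center
    return offset, float(corr.max())


def estimate_sample_drift(
    locs: pd.DataFrame,
    n_windows: int | None = None,
    window_size: int | None = None,
    voxel: float = 10.0,
    smooth_voxels: float = 1.0,
    fit_window: int = 7,
    columns: tuple = ("x_nm", "y_nm", "z_nm"),
    time_column: str = "time_s",
) -> DriftTrajectory:
    """Redundant cross-correlation drift estimation.

    Localizations are split into time windows, each rendered as a 3D
    histogram at ``voxel`` nm; offsets between all window pairs are
    measured from correlation peaks and combined into one trajectory by
    weighted least squares (weights = peak heights).
    """
    locs = locs.sort_values(time_column)
    n = len(locs)
    if window_size is None:
        if n_windows is None:
            raise ValueError("give n_windows or window_size")
        window_size = max(1, n // n_windows)
    starts = list(range(0, n, window_size))
    if len(starts) > 1 and n - starts[-1] < window_size // 2:
        starts.pop()
    bounds = [(s, min(s + window_size, n)) for s in starts]
    bounds[-1] = (bounds[-1][0], n)
    W = len(bounds)
    if W < 2:
        raise ValueError("need at least 2 time windows")
    coords = locs[list(columns)].to_numpy()
    times = locs[time_column].to_numpy()
    mins = coords.min(axis=0) - 2 * voxel
    maxs = coords.max(axis=0) + 2 * voxel
    edges = [np.arange(mins[d], maxs[d] + voxel, voxel) for d in range(3)]
    hists = []
    t_mid = []
    for s, e in bounds:
        h = _render_hist(coords[s:e], edges)
        if smooth_voxels > 0:
            h = gaussian_filter(h, smooth_voxels)
        hists.append(h)
        t_mid.append(times[s:e].mean())
    pairs = []
    for i in range(W):
        for j in range(i + 1, W):
            off, height = _corr_peak_offset(hists[i], hists[j], fit_window)
            if np.all(np.isfinite(off)):
                pairs.append((i, j, off * voxel, height))
    if not pairs:
        raise ValueError("no significant correlation peaks found")
    heights = np.array([p[3] for p in pairs])
    ref = np.median(heights)
    # solve d_j - d_i = -offset_ij for window offsets (d_0 = 0): a peak of
    # the correlation of window j against i at +s means j is displaced by -s
    rows = []
    rhs = []
    weights = []
    for i, j, off, height in pairs:
        row = np.zeros(W - 1)
        if j > 0:
            row[j - 1] = 1.0
        if i > 0:
            row[i - 1] -= 1.0
        rows.append(row)
        rhs.append(-off)
        weights.append(max(height, 1e-6) / max(ref, 1e-6))
    A = np.array(rows)
    B = np.array(rhs)
    w = np.sqrt(np.array(weights))
    sol = np.zeros((W, 3))
    for d in range(3):
        x, *_ = np.linalg.lstsq(A * w[:, None], B[:, d] * w, rcond=None)
        sol[1:, d] = x
    return DriftTrajectory(window_times=np.array(t_mid), offsets=sol)


def apply_drift_correction(
    locs: pd.DataFrame,
    traj: DriftTrajectory,
    columns: tuple = ("x_nm", "y_nm", "z_nm"),
    time_column: str = "time_s",
) -> pd.DataFrame:
    """Subtract the drift trajectory from localization coordinates."""
    out = locs.copy()
    d = traj.at(out[time_column].to_numpy())
    for k, col in enumerate(columns):
        out[col] = out[col] - d[:, k]
    return out


def rescale_z(
    locs: pd.DataFrame,
    cfg: IndexWavelengthConfig,
    dye: str,
    z_column: str = "z_nm",
) -> pd.DataFrame:
    """Linear rescaling of z for dye wavelength and index mismatch.

    z is multiplied by (lambda_dye / lambda_bead) — the fringe period
    scales with the detected wavelength — and by (n_sample / n_immersion)
    — the bead was scanned with the piezo stage through the immersion
    medium rather than an emitter moving in the sample medium.
    """
    if dye not in cfg.lambda_dye:
        raise ValueError(f"unknown dye {dye!r}; known: {sorted(cfg.lambda_dye)}")
    factor = (cfg.lambda_dye[dye] / cfg.lambda_bead) * (
        cfg.n_sample / cfg.n_immersion
    )
    logger.info("z rescaling for %s: factor %.6f", dye, factor)
    out = locs.copy()
    out[z_column] = out[z_column] * factor
    return out


def predict_step_phase_shift(delta_z: float, cfg: IndexWavelengthConfig) -> float:
    """Approximate PSF phase shift for a sample-stage step of ``delta_z`` nm.

    Low-NA approximation combining the focal-plane shift and the
    interferometric path-length change:
    (n_imm/n_sample - n_sample/n_imm) * 4 pi n_sample / lambda0 * delta_z,
    with lambda0 the dye vacuum wavelength (bead wavelength if no dye
    context is given).
    """
    lam0 = cfg.lambda_bead
    return (
        (cfg.n_immersion / cfg.n_sample - cfg.n_sample / cfg.n_immersion)
        * 4.0
        * np.pi
        * cfg.n_sample
        / lam0
        * delta_z
    )


def analyze_multistep(
    steps: list,
    base_psf,
    pixel_size: float,
    iw_cfg: IndexWavelengthConfig | None = None,
    min_locs_for_phase: int = 50,
) -> pd.DataFrame:
    """Analyze a multistep z-stage scan, one phase estimate per step.

    ``steps`` is a list of dicts with keys ``images`` (N, 4, roi, roi),
    ``times`` (N,) and ``stage_z`` (nm, stage displacement of the step).
    Each step's PSF phase is estimated from its own localizations, the
    step is fit with a model shifted to that phase, and the stage offset is
    added to z.  The low-NA phase prediction for each stage step is logged
    as a consistency check only.  Steps with too few localizations inherit
    the previous step's phase (with a warning).
    """
    from .localization import fit_images
    from .phase_dynamics import decompose_psf, estimate_phase, phase_shift_psf

    dec = decompose_psf(base_psf)
    tables = []
    prev_phase = 0.0
    phases = []
    for s_idx, step in enumerate(steps):
        images = np.asarray(step["images"], float)
        times = np.asarray(step["times"], float)
        if images.shape[0] >= min_locs_for_phase:
            phase, prec, _ = estimate_phase(images, base_psf, pixel_size)
        else:
            logger.warning(
                "step %d has %d localizations (< %d); inheriting phase %.3f",
                s_idx, images.shape[0], min_locs_for_phase, prev_phase,
            )
            phase = prev_phase
        phases.append(phase)
        prev_phase = phase
        if iw_cfg is not None and s_idx > 0:
            dz_step = step["stage_z"] - steps[s_idx - 1]["stage_z"]
            logger.info(
                "step %d: estimated phase %.3f rad; low-NA prediction for "
                "stage step %.0f nm: %.3f rad",
                s_idx, phase, dz_step, predict_step_phase_shift(dz_step, iw_cfg),
            )
        _, model = phase_shift_psf(dec, phase)
        params, chi2s, conv = fit_images(images, model, pixel_size)
        tab = pd.DataFrame(
            dict(
                x_nm=params[:, 0],
                y_nm=params[:, 1],
                z_nm=params[:, 2] + step["stage_z"],
                photons=params[:, 3],
                background=np.maximum(params[:, 4], 0.0),
                chi2=chi2s,
                time_s=times,
                converged=conv,
                step=s_idx,
                step_phase=phase,
            )
        )
        tables.append(tab[tab["converged"]])
    return pd.concat(tables, ignore_index=True)
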