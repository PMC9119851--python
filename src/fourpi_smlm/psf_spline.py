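"""Multichannel 3D cubic-spline PSF model.

A measured 4Pi PSF — a four-channel bead z-scan — is converted into a
piecewise tricubic polynomial ``f_S(x, y, z, c)``.  Within each voxel cell
``(i, j, k)`` the model is

    f_S = sum_{m,n,o=0..3} S[i,j,k,m,n,o,c] * sx^m * sy^n * sz^o,

where ``sx = (x - t_i) / dx`` etc. are cell-normalized coordinates.  The
expected image of an emitter is ``b + A * f_S(x - x0, y - y0, z0, c)``: the
z axis of the model indexes the axial position of the emitter, so a single
camera frame of an emitter at z0 is the model slice at z = z0.

Splines are built as tensor products of 1D not-a-knot cubic interpolants
(value and first derivatives continuous, data reproduced exactly at the
knots) applied sequentially along x, y and z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .config import CHANNEL_ORDER

__all__ = [
    "BeadStack",
    "SplinePSF",
    "PSFModelParams",
    "preprocess_bead_scan",
    "compute_spline_coefficients",
]


@dataclass
class BeadStack:
    """A four-channel 3D pixelated PSF measurement.

    ``data`` has shape (n_channels, nz, ny, nx); ``voxel_size`` is
    (dx, dy, dz) in nm; ``z_origin`` is the z coordinate (nm, relative to
    focus) of the first plane.  Lateral coordinates are centered: the voxel
    at lateral index i sits at ``(i - (n - 1) / 2) * d``.
    """

    data: np.ndarray
    voxel_size: tuple
    z_origin: float | None = None
    channel_order: tuple = CHANNEL_ORDER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must have shape (channels, nz, ny, nx)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.z_origin is None:
            nz = self.data.shape[1]
            self.z_origin = -0.5 * (nz - 1) * self.voxel_size[2]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def x_coords(self) -> np.ndarray:
        n = self.data.shape[3]
        return (np.arange(n) - 0.5 * (n - 1)) * self.voxel_size[0]

    @property
    def y_coords(self) -> np.ndarray:
        n = self.data.shape[2]
        return (np.arange(n) - 0.5 * (n - 1)) * self.voxel_size[1]

    @property
    def z_coords(self) -> np.ndarray:
        n = self.data.shape[1]
        return self.z_origin + np.arange(n) * self.voxel_size[2]


@dataclass
class PSFModelParams:
    """Parameters of the imaging model: PSF center, amplitude, background."""

    x0: float = 0.0
    y0: float = 0.0
    z0: float = 0.0
    A: float = 1.0
    b: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.z0, self.A, self.b], float)


def preprocess_bead_scan(
    raw: BeadStack,
    crop_size: int = 17,
    z_downsample: int = 10,
    boxcar_width_nm: float = 50.0,
) -> BeadStack:
    """Crop, z-downsample and z-smooth a raw bead scan.

    The channel-summed stack locates the bead; a ``crop_size`` lateral
    region centered on it is cropped, the z axis is block-averaged by
    ``z_downsample`` and then smoothed with a boxcar filter whose width is
    ``boxcar_width_nm`` converted to (odd) planes at the new z sampling.
    A 3000-plane scan becomes a 17x17x300 stack this way.
    """
    c, nz, ny, nx = raw.data.shape
    if nx < crop_size or ny < crop_size:
        raise ValueError(f"stack must be at least {crop_size} pixels laterally")
    summed = raw.data.sum(axis=0).max(axis=0)  # (ny, nx) peak projection
    py, px = np.unravel_index(np.argmax(summed), summed.shape)
    half = crop_size // 2
    if (
        px - half < 0
        or py - half < 0
        or px + half >= nx
        or py + half >= ny
        or min(px, py, nx - 1 - px, ny - 1 - py) < 2
    ):
        raise ValueError(
            f"bead peak at (x={px}, y={py}) too close to the border to crop "
            f"a centered {crop_size}x{crop_size} region"
        )
    cropped = raw.data[:, :, py - half : py + half + 1, px - half : px + half + 1]

    n_keep = (nz // z_downsample) * z_downsample
    ds = cropped[:, :n_keep].reshape(
        c, n_keep // z_downsample, z_downsample, crop_size, crop_size
    ).mean(axis=2)

    dz_new = raw.voxel_size[2] * z_downsample
    width = max(1, round(boxcar_width_nm / dz_new))
    if width % 2 == 0:
        width += 1
    if width > 1:
        ds = uniform_filter1d(ds, size=width, axis=1, mode="nearest")

    z0_new = raw.z_origin + 0.5 * (z_downsample - 1) * raw.voxel_size[2]
    return BeadStack(
        data=ds,
        voxel_size=(raw.voxel_size[0], raw.voxel_size[1], dz_new),
        z_origin=z0_new,
        channel_order=raw.channel_order,
    )


def _axis_spline_coeffs(values: np.ndarray, knots: np.ndarray, axis: int) -> np.ndarray:
    """1D not-a-knot cubic spline along ``axis``; returns cell-normalized
    ascending-power coefficients with shape (4, n_cells) + rest.
    """
    cs = CubicSpline(knots, values, axis=axis, bc_type="not-a-knot")
    c = cs.c  # (4, n-1, *rest): c[r] multiplies (x - x_i)^(3-r)
    delta = float(knots[1] - knots[0])
    powers = delta ** np.arange(4)
    extra = (1,) * (c.ndim - 1)
    return c[::-1] * powers.reshape((4,) + extra)


def compute_spline_coefficients(stack: BeadStack) -> "SplinePSF":
    """Build the multichannel tricubic spline model of a bead stack.

    For each channel the 64 per-cell polynomial coefficients are obtained by
    sequentially fitting 1D cubic interpolants along x, then y, then z —
    legitimate because spline fitting is linear in the data, so the nested
    construction yields the tensor-product interpolant.
    """
    c, nz, ny, nx = stack.data.shape
    if min(nx, ny, nz) < 4:
        raise ValueError("need at least 4 voxels per axis for a cubic spline")
    xk = stack.x_coords
    yk = stack.y_coords
    zk = stack.z_coords

    # (C, nx, ny, nz) for construction in logical (x, y, z) order
    vals = stack.data.transpose(0, 3, 2, 1)
    ax = _axis_spline_coeffs(vals, xk, axis=1)  # (4, nx-1, C, ny, nz)
    ay = _axis_spline_coeffs(ax, yk, axis=3)  # (4, ny-1, 4, nx-1, C, nz)
    az = _axis_spline_coeffs(ay, zk, axis=5)  # (4, nz-1, 4, ny-1, 4, nx-1, C)
    # -> (C, i, j, k, m, n, o) with i,m along x; j,n along y; k,o along z
    S = az.transpose(6, 5, 3, 1, 4, 2, 0)
    S = np.ascontiguousarray(S.reshape(c, nx - 1, ny - 1, nz - 1, 64))
    return SplinePSF(
        coefficients=S,
        x_knots=xk,
        y_knots=yk,
        z_knots=zk,
        channel_order=stack.channel_order,
    )


def _poly_basis(s: np.ndarray) -> np.ndarray:
    """Powers [1, s, s^2, s^3] stacked on a new last axis."""
    s = np.asarray(s, float)
    return np.stack([np.ones_like(s), s, s * s, s * s * s], axis=-1)


def _poly_basis_d(s: np.ndarray) -> np.ndarray:
    """Derivatives [0, 1, 2s, 3s^2] of the power basis."""
    s = np.asarray(s, float)
    return np.stack(
        [np.zeros_like(s), np.ones_like(s), 2.0 * s, 3.0 * s * s], axis=-1
    )


@dataclass
class SplinePSF:
    """The analytic multichannel cubic-spline PSF model.

    ``coefficients`` has shape (n_channels, n_cells_x, n_cells_y, n_cells_z,
    64); the flat polynomial index is ``(m * 4 + n) * 4 + o`` for powers
    (m, n, o) of the normalized (x, y, z) cell coordinates.  ``phase_offset``
    records the interference-phase shift applied relative to the source bead
    scan (0 for the static model).
    """

    coefficients: np.ndarray
    x_knots: np.ndarray
    y_knots: np.ndarray
    z_knots: np.ndarray
    phase_offset: float = 0.0
    channel_order: tuple = CHANNEL_ORDER
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.ascontiguousarray(self.coefficients, dtype=np.float64)
        self.x_knots = np.asarray(self.x_knots, float)
        self.y_knots = np.asarray(self.y_knots, float)
        self.z_knots = np.asarray(self.z_knots, float)
        nc, ni, nj, nk, n64 = self.coefficients.shape
        if n64 != 64:
            raise ValueError("expected 64 polynomial coefficients per cell")
        if (ni, nj, nk) != (
            len(self.x_knots) - 1,
            len(self.y_knots) - 1,
            len(self.z_knots) - 1,
        ):
            raise ValueError("coefficient grid does not match knot grid")

    # -- geometry -----------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.coefficients.size

    @property
    def knot_spacings(self) -> tuple:
        return (
            float(self.x_knots[1] - self.x_knots[0]),
            float(self.y_knots[1] - self.y_knots[0]),
            float(self.z_knots[1] - self.z_knots[0]),
        )

    @property
    def support(self) -> tuple:
        """((xmin, xmax), (ymin, ymax), (zmin, zmax)) of the model, nm."""
        return (
            (float(self.x_knots[0]), float(self.x_knots[-1])),
            (float(self.y_knots[0]), float(self.y_knots[-1])),
            (float(self.z_knots[0]), float(self.z_knots[-1])),
        )

    def _locate(self, coords: np.ndarray, knots: np.ndarray) -> tuple:
        d = knots[1] - knots[0]
        t = (coords - knots[0]) / d
        n_cells = len(knots) - 1
        if np.any(t < -1e-9) or np.any(t > n_cells + 1e-9):
            raise ValueError(
                "evaluation point outside spline support "
                f"[{knots[0]:.1f}, {knots[-1]:.1f}] nm"
            )
        idx = np.clip(np.floor(t).astype(np.intp), 0, n_cells - 1)
        return idx, t - idx

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, x, y, z, channel=None, derivatives: bool = False):
        """Evaluate f_S (and optionally its spatial gradient) at points.

        x, y, z broadcast together; ``channel`` selects one channel or, if
        None, all channels are returned with a leading channel axis.
        Points outside the knot support raise ``ValueError`` — the cubic
        polynomial is never extrapolated.
        """
        x, y, z = np.broadcast_arrays(
            np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
        )
        i, sx = self._locate(x, self.x_knots)
        j, sy = self._locate(y, self.y_knots)
        k, sz = self._locate(z, self.z_knots)
        channels = range(self.n_channels) if channel is None else [channel]
        bx, by, bz = _poly_basis(sx), _poly_basis(sy), _poly_basis(sz)
        # basis64[..., (m*4+n)*4+o]
        basis = (
            bx[..., :, None, None] * by[..., None, :, None] * bz[..., None, None, :]
        ).reshape(x.shape + (64,))
        out_val = []
        out_grad = []
        if derivatives:
            dx, dy, dz = self.knot_spacings
            dbx, dby, dbz = _poly_basis_d(sx), _poly_basis_d(sy), _poly_basis_d(sz)
            basis_dx = (
                dbx[..., :, None, None]
                * by[..., None, :, None]
                * bz[..., None, None, :]
            ).reshape(x.shape + (64,)) / dx
            basis_dy = (
                bx[..., :, None, None]
                * dby[..., None, :, None]
                * bz[..., None, None, :]
            ).reshape(x.shape + (64,)) / dy
            basis_dz = (
                bx[..., :, None, None]
                * by[..., None, :, None]
                * dbz[..., None, None, :]
            ).reshape(x.shape + (64,)) / dz
        for c in channels:
            cell = self.coefficients[c][i, j, k]  # (..., 64)
            out_val.append(np.einsum("...p,...p->...", cell, basis))
            if derivatives:
                out_grad.append(
                    np.stack(
                        [
                            np.einsum("...p,...p->...", cell, basis_dx),
                            np.einsum("...p,...p->...", cell, basis_dy),
                            np.einsum("...p,...p->...", cell, basis_dz),
                        ]
                    )
                )
        val = out_val[0] if channel is not None else np.stack(out_val)
        if not derivatives:
            return val
        grad = out_grad[0] if channel is not None else np.stack(out_grad)
        return val, grad

    def model_image(
        self, params: PSFModelParams, pixel_x: np.ndarray, pixel_y: np.ndarray
    ) -> np.ndarray:
        """Expected image b + A f_S(x - x0, y - y0, z0, c).

        ``pixel_x`` / ``pixel_y`` are the ROI pixel-center coordinates in nm;
        output shape is (n_channels, len(pixel_y), len(pixel_x)).
        """
        X, Y = np.meshgrid(
            np.asarray(pixel_x, float) - params.x0,
            np.asarray(pixel_y, float) - params.y0,
        )
        f = self.evaluate(X, Y, np.full_like(X, params.z0))
        return params.b + params.A * f

    def model_gradient(
        self, params: PSFModelParams, pixel_x: np.ndarray, pixel_y: np.ndarray
    ) -> tuple:
        """Expected image and its gradient w.r.t. (x0, y0, z0, A, b).

        Returns (mu, jac) with jac shape (5, n_channels, ny, nx).  The
        spatial derivatives carry the chain-rule sign: d mu / d x0 =
        -A df/dx, while d mu / d z0 = +A df/dz since z0 enters directly.
        """
        X, Y = np.meshgrid(
            np.asarray(pixel_x, float) - params.x0,
            np.asarray(pixel_y, float) - params.y0,
        )
        f, g = self.evaluate(X, Y, np.full_like(X, params.z0), derivatives=True)
        mu = params.b + params.A * f
        jac = np.stack(
            [
                -params.A * g[:, 0],
                -params.A * g[:, 1],
                params.A * g[:, 2],
                f,
                np.ones_like(f),
            ]
        )
        return mu, jac

    def render(self, sampling: int = 1) -> BeadStack:
        """Render the spline as a BeadStack at ``sampling``-fold density.

        With sampling=1 the knot-grid values (i.e. the source stack) are
        reproduced; higher factors divide the voxel size accordingly.
        """
        if sampling < 1:
            raise ValueError("sampling factor must be >= 1")
        dx, dy, dz = self.knot_spacings

        def dense(knots, d):
            n = (len(knots) - 1) * sampling + 1
            return knots[0] + np.arange(n) * (d / sampling)

        xs, ys, zs = (
            dense(self.x_knots, dx),
            dense(self.y_knots, dy),
            dense(self.z_knots, dz),
        )
        # evaluate plane by plane: the polynomial basis arrays are 64x the
        # point count, so a full 3D meshgrid would be needlessly large
        X, Y = np.meshgrid(xs, ys)
        data = np.empty((self.n_channels, len(zs), len(ys), len(xs)))
        for k, z in enumerate(zs):
            data[:, k] = self.evaluate(X, Y, np.full_like(X, z))
        return BeadStack(
            data=data,
            voxel_size=(dx / sampling, dy / sampling, dz / sampling),
            z_origin=float(zs[0]),
            channel_order=self.channel_order,
        )

    def with_coefficients(self, coeffs: np.ndarray, **meta) -> "SplinePSF":
        """Copy of this model with replaced coefficients (same geometry)."""
        kwargs = dict(
            coefficients=coeffs,
            x_knots=self.x_knots,
            y_knots=self.y_knots,
            z_knots=self.z_knots,
            phase_offset=self.phase_offset,
            channel_order=self.channel_order,
            metadata=dict(self.metadata),
        )
        kwargs.update(meta)
        return SplinePSF(**kwargs)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("coefficients", data=self.coefficients)
            f.create_dataset("x_knots", data=self.x_knots)
            f.create_dataset("y_knots", data=self.y_knots)
            f.create_dataset("z_knots", data=self.z_knots)
            f.attrs["phase_offset"] = self.phase_offset
            f.attrs["channel_order"] = ",".join(self.channel_order)
            for key, val in self.metadata.items():
                f.attrs[f"meta_{key}"] = val

    @classmethod
    def load(cls, path) -> "SplinePSF":
        with h5py.File(path, "r") as f:
            meta = {
                k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")
            }
            return cls(
                coefficients=f["coefficients"][()],
                x_knots=f["x_knots"][()],
                y_knots=f["y_knots"][()],
                z_knots=f["z_knots"][()],
                phase_offset=float(f.attrs["phase_offset"]),
                channel_order=tuple(str(f.attrs["channel_order"]).split(",")),
                metadata=meta,
            )
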