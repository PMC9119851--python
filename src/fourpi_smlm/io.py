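"""File formats: multi-page TIFF stacks, localization tables, rendering.

Two TIFF dialects are supported and declared in the page metadata:

* ``per_channel_page`` — one page per (plane, channel), channel-fastest;
* ``quadrant`` — one page per plane, the four channels tiled as quadrants
  [[p1, s1], [p2, s2]] of a double-size page (as on the EMCCD).

Localization tables round-trip through CSV and HDF5 with a versioned
schema; canonical units (nm, photons, seconds) are part of the column
names.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .config import CHANNEL_ORDER
from .psf_spline import BeadStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_movie",
    "read_movie",
    "write_locs",
    "read_locs",
    "render_image",
    "LOC_SCHEMA_VERSION",
    "MANDATORY_COLUMNS",
]

LOC_SCHEMA_VERSION = 1
MANDATORY_COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "photons", "chi2", "time_s"]


def _to_pages(frames: np.ndarray, dialect: str) -> np.ndarray:
    n, c, ny, nx = frames.shape
    if c != 4:
        raise ValueError("expected four channels")
    if dialect == "per_channel_page":
        return frames.reshape(n * c, ny, nx)
    if dialect == "quadrant":
        pages = np.empty((n, 2 * ny, 2 * nx), frames.dtype)
        pages[:, :ny, :nx] = frames[:, 0]
        pages[:, :ny, nx:] = frames[:, 1]
        pages[:, ny:, :nx] = frames[:, 2]
        pages[:, ny:, nx:] = frames[:, 3]
        return pages
    raise ValueError(f"unknown dialect {dialect!r}")


def _from_pages(pages: np.ndarray, dialect: str) -> np.ndarray:
    if dialect == "per_channel_page":
        if pages.shape[0] % 4:
            raise ValueError("page count not a multiple of 4 channels")
        n = pages.shape[0] // 4
        return pages.reshape(n, 4, pages.shape[1], pages.shape[2])
    if dialect == "quadrant":
        if pages.shape[1] % 2 or pages.shape[2] % 2:
            raise ValueError("quadrant pages must have even dimensions")
        ny, nx = pages.shape[1] // 2, pages.shape[2] // 2
        out = np.empty((pages.shape[0], 4, ny, nx), pages.dtype)
        out[:, 0] = pages[:, :ny, :nx]
        out[:, 1] = pages[:, :ny, nx:]
        out[:, 2] = pages[:, ny:, :nx]
        out[:, 3] = pages[:, ny:, nx:]
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def write_movie(
    path,
    frames: np.ndarray,
    dialect: str = "quadrant",
    pixel_size: float | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a four-channel movie (n_frames, 4, ny, nx) as multi-page TIFF."""
    frames = np.asarray(frames)
    meta = dict(metadata or {})
    meta.update(
        dialect=dialect,
        n_frames=int(frames.shape[0]),
        channel_order=list(CHANNEL_ORDER),
    )
    if pixel_size is not None:
        meta["pixel_size_nm"] = float(pixel_size)
    tifffile.imwrite(
        path,
        _to_pages(frames, dialect),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_movie(path) -> tuple:
    """Read a movie written by :func:`write_movie`; returns (frames, meta)."""
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    dialect = meta.get("dialect", "quadrant")
    if pages.ndim == 2:
        pages = pages[None]
    frames = _from_pages(pages, dialect)
    if "n_frames" in meta and frames.shape[0] != meta["n_frames"]:
        raise ValueError("inconsistent page count vs metadata")
    return frames, meta


def write_stack(path, stack: BeadStack, dialect: str = "per_channel_page") -> None:
    """Write a BeadStack as multi-page TIFF (planes as frames)."""
    frames = stack.data.transpose(1, 0, 2, 3)  # (nz, 4, ny, nx)
    meta = dict(
        voxel_size_nm=list(stack.voxel_size),
        z_origin_nm=float(stack.z_origin),
    )
    write_movie(path, frames, dialect=dialect, metadata=meta)


def read_stack(path) -> BeadStack:
    frames, meta = read_movie(path)
    return BeadStack(
        data=frames.transpose(1, 0, 2, 3),
        voxel_size=tuple(meta["voxel_size_nm"]),
        z_origin=meta.get("z_origin_nm"),
        channel_order=tuple(meta.get("channel_order", CHANNEL_ORDER)),
    )


def write_locs(path, locs: pd.DataFrame) -> None:
    """Write a localization table to CSV or HDF5 (by file extension)."""
    missing = [c for c in MANDATORY_COLUMNS if c not in locs.columns]
    if missing:
        raise ValueError(f"localization table missing columns: {missing}")
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = LOC_SCHEMA_VERSION
            f.attrs["units"] = "nm, photons, seconds"
            g = f.create_group("locs")
            for col in locs.columns:
                vals = locs[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)
    else:
        with open(path, "w") as fh:
            fh.write(
                f"# fourpi_smlm localization table v{LOC_SCHEMA_VERSION}; "
                "units: nm, photons, seconds\n"
            )
            locs.to_csv(fh, index=False)


def read_locs(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            g = f["locs"]
            data = {}
            for col in g:
                vals = g[col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                data[col] = vals
            locs = pd.DataFrame(data)
    else:
        locs = pd.read_csv(path, comment="#")
    missing = [c for c in MANDATORY_COLUMNS if c not in locs.columns]
    if missing:
        raise ValueError(f"localization table missing columns: {missing}")
    return locs


def render_image(
    locs: pd.DataFrame,
    voxel: float = 10.0,
    blur_voxels: float = 1.0,
    dims: int = 2,
    color_by: str | None = None,
    columns: tuple = ("x_nm", "y_nm", "z_nm"),
):
    """Gaussian-blurred histogram rendering of a localization table.

    Total weight equals the number of localizations.  With
    ``color_by='z_nm'`` a 2D rendering also returns the intensity-weighted
    mean of that column per pixel (for z color-coding).  Returns
    (image, edges) or (image, edges, colormap_values).
    """
    import warnings

    if len(locs) == 0:
        warnings.warn("empty localization table; returning empty image")
        shape = (0,) * dims
        return np.zeros(shape), None
    use = columns[:dims]
    coords = locs[list(use)].to_numpy()
    mins = coords.min(axis=0) - 2 * voxel
    maxs = coords.max(axis=0) + 2 * voxel
    edges = [np.arange(mins[d], maxs[d] + voxel, voxel) for d in range(dims)]
    hist, _ = np.histogramdd(coords, bins=edges)
    if blur_voxels > 0:
        img = gaussian_filter(hist, blur_voxels)
    else:
        img = hist
    if color_by is not None and dims == 2:
        w = locs[color_by].to_numpy()
        hw, _ = np.histogramdd(coords, bins=edges, weights=w)
        if blur_voxels > 0:
            hw = gaussian_filter(hw, blur_voxels)
        with np.errstate(invalid="ignore", divide="ignore"):
            cvals = np.where(img > 1e-12, hw / np.maximum(img, 1e-12), np.nan)
        return img, edges, cvals
    return img, edges
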