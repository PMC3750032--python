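"""Apply a color LUT to FA volumes and render slice mosaics.

FA maps are scalar NIfTI volumes in [0, 1]; colorization maps each finite
in-mask voxel through the LUT's piecewise-linear ramps and renders NaN /
out-of-mask voxels as exact black, so non-brain background stays visually
distinct. Display uses nearest-voxel slicing only — no resampling or
smoothing, which would blur FA by partial-volume mixing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from PIL import Image

from .lut_builder import ColorLUT, sample_lut

__all__ = ["FAVolume", "RGBVolume", "load_fa", "colorize", "render_mosaic", "save_rgb_nifti"]

logger = logging.getLogger(__name__)

PLANES = {"sagittal": 0, "coronal": 1, "axial": 2}

BACKGROUND: tuple[int, int, int] = (0, 0, 0)


@dataclass
class FAVolume:
    """Scalar FA volume: finite values in [0, 1], NaN marks background."""

    voxels: np.ndarray
    affine: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError(f"FA volume must be 3D, got shape {self.voxels.shape}")


@dataclass
class RGBVolume:
    """Per-voxel RGB counterpart of an FA volume (shape + (3,), uint8)."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.voxels.ndim != 4 or self.voxels.shape[-1] != 3:
            raise ValueError(f"RGB volume must have shape (x, y, z, 3), got {self.voxels.shape}")


def load_fa(path: str | Path) -> FAVolume:
    """Load an FA map from NIfTI-1, clamping stray values into [0, 1].

    Values below 0 are set to 0, above 1 to 1 (numerical excursions from
    tensor fitting), and non-finite voxels become NaN background. The number
    of clamped voxels is logged.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D FA volume, got shape {img.shape}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    finite = np.isfinite(data)
    n_clamped = int(np.sum(finite & ((data < 0) | (data > 1))))
    if n_clamped:
        logger.info("load_fa(%s): clamped %d voxel(s) into [0, 1]", path, n_clamped)
    data = np.where(finite, np.clip(data, 0.0, 1.0), np.nan)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return FAVolume(voxels=data, affine=np.asarray(img.affine), voxel_size=zooms)


def volume_from_array(voxels: np.ndarray, voxel_size_mm: float = 2.2) -> FAVolume:
    """Wrap a raw in-memory FA array (e.g. a phantom) as an FAVolume."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return FAVolume(voxels=np.asarray(voxels, dtype=np.float64), affine=aff,
                    voxel_size=(voxel_size_mm,) * 3)


def colorize(volume: FAVolume, lut: ColorLUT, mask: np.ndarray | None = None) -> RGBVolume:
    """Map an FA volume through the LUT; NaN / out-of-mask voxels go black.

    Each finite in-mask voxel is interpolated on the anchor polyline exactly
    as :func:`falut.lut_builder.interpolate_color` does, so voxels sitting
    precisely on an anchor FA value carry that anchor's color exactly.
    """
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != volume.voxels.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume shape {volume.voxels.shape}"
            )
    data = volume.voxels
    finite = np.isfinite(data)
    keep = finite if mask is None else (finite & (mask > 0))
    # Exact anchor reproduction: interpolate per voxel via np.interp on the
    # anchor polyline rather than a precomputed grid.
    xs = np.array([p.fa for p in lut.points])
    vals = np.clip(data[keep], 0.0, 1.0)
    rgb = np.zeros(data.shape + (3,), dtype=np.uint8)
    for c in range(3):
        ys = np.array([p.rgb[c] for p in lut.points], dtype=float)
        rgb[keep, c] = np.floor(np.interp(vals, xs, ys) + 0.5).astype(np.uint8)
    return RGBVolume(voxels=rgb, affine=volume.affine.copy())


def _slice_to_image(rgb: np.ndarray, axis: int, index: int, radiological: bool) -> np.ndarray:
    sl = np.take(rgb, index, axis=axis)
    # display with the first remaining axis horizontal, second vertical-flipped
    img = np.flipud(sl.transpose(1, 0, 2))
    if radiological and axis in (1, 2):
        img = np.fliplr(img)
    return np.ascontiguousarray(img)


def render_mosaic(
    rgb: RGBVolume,
    plane: str,
    slices: Sequence[int],
    path: str | Path,
    lut: ColorLUT | None = None,
    n_cols: int | None = None,
    colorbar_height: int = 16,
    radiological: bool = True,
) -> None:
    """Write a PNG grid of selected slices, with a LUT color bar appended.

    ``plane`` is one of axial / coronal / sagittal; ``slices`` are voxel
    indices along that axis. When ``lut`` is given, a horizontal strip of
    ``colorbar_height`` pixels sampling the LUT left-to-right over [0, 1] is
    appended below the grid. Output is deterministic for fixed inputs.
    """
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {sorted(PLANES)}, got {plane!r}")
    axis = PLANES[plane]
    n_slices_avail = rgb.voxels.shape[axis]
    for idx in slices:
        if not (0 <= idx < n_slices_avail):
            raise IndexError(f"slice {idx} out of range [0, {n_slices_avail}) along {plane} axis")
    if not slices:
        raise ValueError("slices must be non-empty")
    tiles = [_slice_to_image(rgb.voxels, axis, i, radiological) for i in slices]
    th, tw = tiles[0].shape[:2]
    n = len(tiles)
    ncols = n_cols or int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    grid = np.zeros((nrows * th, ncols * tw, 3), dtype=np.uint8)
    for k, tile in enumerate(tiles):
        r, c = divmod(k, ncols)
        grid[r * th:(r + 1) * th, c * tw:(c + 1) * tw] = tile
    if lut is not None and colorbar_height > 0:
        bar = sample_lut(lut, grid.shape[1])[None, :, :]
        bar = np.repeat(bar, colorbar_height, axis=0)
        grid = np.concatenate([grid, bar], axis=0)
    Image.fromarray(grid, mode="RGB").save(str(path), format="PNG")


def save_rgb_nifti(rgb: RGBVolume, path: str | Path) -> None:
    """Persist an RGB volume as a NIfTI with a trailing channel dimension."""
    img = nib.Nifti1Image(rgb.voxels, rgb.affine)
    nib.save(img, str(path))
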