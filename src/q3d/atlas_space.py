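"""Mapping detections into a labeled reference atlas and building heatmaps.

Every sample is acquired in its own "native" voxel grid; a per-sample affine
transform (estimated upstream by image registration, consumed here) maps
downsampled native coordinates into the common atlas grid (25 µm isotropic by
default, emulating a reference brain template).  Quantities accumulated per
atlas voxel -- object counts, mean object size, or segmented-structure volume
-- are then smoothed with a spherical region-of-interest (ROI) kernel to form
density heatmaps, and aggregated over anatomically labeled regions.

Coordinate conventions (stated here because nothing downstream works without
them): voxel indices are 0-based; the physical position of voxel ``i`` is
``i * spacing_um`` (voxel-corner origin); binning to the atlas grid is
half-open, ``floor(position_um / atlas_spacing_um)``; the affine acts on those
integer bin coordinates and the result is rounded to the nearest atlas voxel,
so counts stay integer and are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import BinaryMask, ObjectSet


@dataclass
class AffineTransform:
    """Affine map from downsampled native bins to atlas voxel coordinates."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset)

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "offset": self.offset.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.array(d["matrix"]), np.array(d["offset"]))


@dataclass
class LabelAtlas:
    """Integer label grid at atlas spacing; label 0 means outside the brain."""

    labels: np.ndarray
    spacing_um: float = 25.0
    regions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["id", "name"]))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        table = set(int(i) for i in self.regions["id"])
        missing = present - table
        if missing:
            raise ValueError(f"labels missing from the region table: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def interior(self) -> np.ndarray:
        return self.labels > 0

    def region_name(self, region_id: int) -> str:
        row = self.regions.loc[self.regions["id"] == region_id, "name"]
        return str(row.iloc[0]) if len(row) else str(region_id)


@dataclass
class AtlasGrid:
    """A 3D quantity grid aligned to the atlas.

    ``quantity`` is one of ``plaque_count``, ``plaque_mean_size_um3`` or
    ``microglia_volume_um3`` (free text accepted for derived quantities).
    When ``smoothed``, ``roi_diameter_vox`` records the spherical-ROI kernel
    used, and ``roi_diameter_um`` reports its physical size.
    """

    values: np.ndarray
    quantity: str
    spacing_um: float = 25.0
    smoothed: bool = False
    roi_diameter_vox: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("atlas grid must be 3D")
        if np.any(self.values < 0):
            raise ValueError("atlas grid values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def roi_diameter_um(self) -> float | None:
        if self.roi_diameter_vox is None:
            return None
        return self.roi_diameter_vox * self.spacing_um


def map_native_points(
    points_vox: np.ndarray,
    native_spacing_um: tuple[float, float, float],
    atlas: LabelAtlas,
    transform: AffineTransform,
) -> tuple[np.ndarray, np.ndarray]:
    """Map native voxel coordinates into atlas voxel indices.

    Returns ``(indices, in_bounds)``: integer atlas indices of shape (N, 3)
    (only valid where ``in_bounds``) and the boolean in-bounds mask.
    """
    pts = np.atleast_2d(np.asarray(points_vox, dtype=float))
    position_um = pts * np.asarray(native_spacing_um, dtype=float)
    bins = np.floor(position_um / atlas.spacing_um)
    mapped = transform.apply(bins)
    idx = np.rint(mapped).astype(np.int64)
    shape = np.asarray(atlas.shape)
    in_bounds = np.all((idx >= 0) & (idx < shape), axis=1)
    return idx, in_bounds


def fit_native_to_atlas(
    native_shape: tuple[int, int, int],
    native_spacing_um: tuple[float, float, float],
    atlas: LabelAtlas,
) -> AffineTransform:
    """Scaling transform that maps a native volume's bin box onto the atlas box.

    Convenience for phantoms: real pipelines consume registration transforms.
    """
    extent_um = np.asarray(native_shape) * np.asarray(native_spacing_um, dtype=float)
    max_bin = np.ceil(extent_um / atlas.spacing_um) - 1
    max_bin = np.maximum(max_bin, 1)
    scale = (np.asarray(atlas.shape) - 1) / max_bin
    return AffineTransform(np.diag(scale), np.zeros(3))


def bin_centers(
    objects: ObjectSet,
    atlas: LabelAtlas,
    transform: AffineTransform,
) -> tuple[AtlasGrid, AtlasGrid, int]:
    """Accumulate object centers into per-voxel count and mean-size grids.

    Each centroid is converted to µm, floored into an atlas-resolution bin,
    affine-transformed and rounded.  The count grid receives 1 per object;
    the mean-size grid holds the mean object volume (µm³) per bin, 0 where the
    count is 0.  Objects mapping outside the atlas are dropped and reported:
    count-grid total + dropped == number of objects, exactly.
    """
    counts = np.zeros(atlas.shape, dtype=float)
    size_sum = np.zeros(atlas.shape, dtype=float)
    n_dropped = 0
    if len(objects):
        idx, ok = map_native_points(objects.centroids(), objects.spacing_um, atlas, transform)
        n_dropped = int((~ok).sum())
        kept = idx[ok]
        vols = objects.volumes_um3()[ok]
        np.add.at(counts, (kept[:, 0], kept[:, 1], kept[:, 2]), 1.0)
        np.add.at(size_sum, (kept[:, 0], kept[:, 1], kept[:, 2]), vols)
    with np.errstate(invalid="ignore"):
        mean_size = np.where(counts > 0, size_sum / np.maximum(counts, 1), 0.0)
    return (
        AtlasGrid(counts, "plaque_count", atlas.spacing_um),
        AtlasGrid(mean_size, "plaque_mean_size_um3", atlas.spacing_um),
        n_dropped,
    )


def microglia_volume_grid(
    source: ObjectSet | BinaryMask,
    atlas: LabelAtlas,
    transform: AffineTransform,
) -> tuple[AtlasGrid, int]:
    """Total segmented volume (µm³) per atlas voxel.

    Every accepted foreground native voxel is mapped to an atlas bin; the grid
    value is the mapped-voxel count times the native voxel volume, so the grid
    total equals foreground voxels x voxel volume minus what fell outside.
    """
    if isinstance(source, ObjectSet):
        if source.labels is None:
            raise ValueError("ObjectSet lacks a label grid; rerun filter_components")
        fg = source.labels > 0
        spacing = source.spacing_um
    else:
        fg = source.values
        spacing = source.spacing_um
    voxel_volume = float(np.prod(spacing))
    grid = np.zeros(atlas.shape, dtype=float)
    coords = np.argwhere(fg)
    n_dropped = 0
    if len(coords):
        idx, ok = map_native_points(coords, spacing, atlas, transform)
        n_dropped = int((~ok).sum())
        kept = idx[ok]
        np.add.at(grid, (kept[:, 0], kept[:, 1], kept[:, 2]), voxel_volume)
    return AtlasGrid(grid, "microglia_volume_um3", atlas.spacing_um), n_dropped


def spherical_kernel(diameter_vox: int, weights: str = "uniform") -> np.ndarray:
    """Spherical ROI footprint: center-to-center distance <= diameter/2, inclusive."""
    if diameter_vox < 1 or diameter_vox % 2 == 0:
        raise ValueError(f"ROI diameter must be odd and >= 1, got {diameter_vox}")
    radius = diameter_vox / 2.0
    half = diameter_vox // 2
    ax = np.arange(-half, half + 1, dtype=float)
    dist = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    inside = dist <= radius
    if weights == "uniform":
        return inside.astype(float)
    if weights == "radial":
        # linearly decaying weight, 1 at the center, 0 at the ROI surface
        return np.where(inside, 1.0 - dist / (radius + 1e-12), 0.0)
    raise ValueError(f"unknown ROI weighting {weights!r}")


def smooth_spherical(
    grid: AtlasGrid,
    diameter_vox: int = 15,
    mode: str = "sum",
    counts: AtlasGrid | None = None,
    weights: str = "uniform",
) -> AtlasGrid:
    """Spherical-ROI smoothing of an atlas grid.

    ``sum`` mode: each output voxel is the (weighted) sum of input values over
    the sphere of the given diameter centred there, zero-padded at the edges.
    ``mean_size`` mode: the count-weighted mean of the per-voxel mean sizes
    within the ROI (requires the companion ``counts`` grid), 0 where the ROI
    holds no objects.
    """
    kernel = spherical_kernel(diameter_vox, weights)
    if mode == "sum":
        out = ndimage.convolve(grid.values, kernel, mode="constant", cval=0.0)
        out = np.maximum(out, 0.0)
    elif mode == "mean_size":
        if counts is None:
            raise ValueError("mean_size smoothing needs the companion count grid")
        if counts.shape != grid.shape:
            raise ValueError("count grid shape mismatch")
        num = ndimage.convolve(grid.values * counts.values, kernel, mode="constant", cval=0.0)
        den = ndimage.convolve(counts.values, kernel, mode="constant", cval=0.0)
        out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        out = np.maximum(out, 0.0)
    else:
        raise ValueError(f"unknown smoothing mode {mode!r}")
    return AtlasGrid(
        out, grid.quantity, grid.spacing_um, smoothed=True, roi_diameter_vox=diameter_vox
    )


def regional_table(grid: AtlasGrid, atlas: LabelAtlas, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Aggregate a quantity grid over atlas regions.

    ``mask`` (optional) restricts the aggregation to voxels with a nonzero
    mask value -- typically the significance map, so regional statistics only
    include voxels with a corrected group difference.
    Columns: region_id, name, n_voxels, sum, mean.
    """
    if grid.shape != atlas.shape:
        raise ValueError(f"grid shape {grid.shape} does not match atlas {atlas.shape}")
    include = atlas.labels > 0
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != atlas.shape:
            raise ValueError("mask shape mismatch")
        include &= mask != 0
    labels = atlas.labels[include].ravel()
    values = grid.values[include].ravel()
    region_ids = [int(i) for i in atlas.regions["id"]]
    nmax = (max(region_ids) if region_ids else 0) + 1
    n_vox = np.bincount(labels, minlength=nmax)
    sums = np.bincount(labels, weights=values, minlength=nmax)
    rows = []
    for rid in region_ids:
        n = int(n_vox[rid])
        s = float(sums[rid])
        rows.append(
            {
                "region_id": rid,
                "name": atlas.region_name(rid),
                "n_voxels": n,
                "sum": s,
                "mean": s / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def group_regional_stats(tables: list[pd.DataFrame], groups: list[str]) -> pd.DataFrame:
    """Per-region mean and SD of the regional sums, by sample group."""
    if len(tables) != len(groups):
        raise ValueError("one group label per table required")
    frames = []
    for table, group in zip(tables, groups):
        t = table[["region_id", "name", "sum", "mean"]].copy()
        t["group"] = group
        frames.append(t)
    stacked = pd.concat(frames, ignore_index=True)
    agg = (
        stacked.groupby(["region_id", "name", "group"], sort=True)
        .agg(
            group_mean=("sum", "mean"),
            group_sd=("sum", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            n_samples=("sum", "size"),
        )
        .reset_index()
    )
    return agg


__all__ = [
    "AffineTransform",
    "LabelAtlas",
    "AtlasGrid",
    "map_native_points",
    "fit_native_to_atlas",
    "bin_centers",
    "microglia_volume_grid",
    "spherical_kernel",
    "smooth_spherical",
    "regional_table",
    "group_regional_stats",
]
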