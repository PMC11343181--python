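"""Voxel classification and 3D blob detection on restored volumes.

A voxel is foreground when its restored (normalized) intensity reaches a
minimum threshold; connected foreground voxels form one object (a microglia
cell or an amyloid plaque, depending on the channel and parameter block), and
components are then filtered by a minimum voxel volume and a minimum peak
intensity to eliminate small or dim artifacts.

The threshold-based classifier sits behind ``binarize``; an external voxel
classifier can be swapped in by supplying its own boolean mask to
``connected_components``/``filter_components``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .restoration import RestorationParams, Volume3D, restore

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class DetectionParams:
    """Thresholds of the voxel classifier and component filters.

    ``tau`` is the inclusive foreground threshold on normalized intensity
    (1.8 by default, identical for all samples).  ``min_volume_vox`` and
    ``min_peak`` remove components smaller than a 3x3x3 cube or whose maximum
    restored intensity stays below 2.2.
    """

    tau: float = 1.8
    connectivity: int = 26
    min_volume_vox: int = 27
    min_peak: float = 2.2

    def validate(self) -> None:
        if not self.tau > 1:
            raise ValueError(f"tau must exceed 1 (normalized background), got {self.tau}")
        if self.connectivity not in _STRUCTURES:
            raise ValueError(f"connectivity must be one of 6/18/26, got {self.connectivity}")
        if self.min_volume_vox < 1:
            raise ValueError("min_volume_vox must be >= 1")
        if self.min_peak < self.tau:
            raise ValueError("min_peak must be >= tau")


@dataclass
class BinaryMask:
    values: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")


@dataclass
class DetectedObject:
    id: int
    centroid_vox: tuple[float, float, float]
    voxel_count: int
    volume_um3: float
    peak_intensity: float


@dataclass
class ObjectSet:
    """Detected objects plus provenance.

    ``labels`` (optional) is the relabeled integer grid keeping only the
    surviving objects, with the same ids as ``objects``; it carries the
    per-voxel membership needed for volume-per-atlas-voxel maps.
    """

    objects: list[DetectedObject]
    spacing_um: tuple[float, float, float]
    labels: np.ndarray | None = None
    params: DetectionParams | None = None
    restoration: RestorationParams | None = None

    def __len__(self) -> int:
        return len(self.objects)

    def centroids(self) -> np.ndarray:
        if not self.objects:
            return np.empty((0, 3), dtype=float)
        return np.array([o.centroid_vox for o in self.objects], dtype=float)

    def volumes_um3(self) -> np.ndarray:
        return np.array([o.volume_um3 for o in self.objects], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [o.id for o in self.objects],
                "x_vox": [o.centroid_vox[0] for o in self.objects],
                "y_vox": [o.centroid_vox[1] for o in self.objects],
                "z_vox": [o.centroid_vox[2] for o in self.objects],
                "voxel_count": [o.voxel_count for o in self.objects],
                "volume_um3": [o.volume_um3 for o in self.objects],
                "peak_intensity": [o.peak_intensity for o in self.objects],
            }
        )


def binarize(restored: Volume3D, params: DetectionParams | None = None) -> BinaryMask:
    """Classify voxels as foreground where restored intensity >= tau (inclusive)."""
    params = params or DetectionParams()
    params.validate()
    if not np.all(np.isfinite(restored.values)):
        raise ValueError("restored volume contains non-finite voxels")
    return BinaryMask(restored.values >= params.tau, restored.spacing_um)


def connected_components(mask: BinaryMask, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Label connected foreground voxels under 6/18/26 adjacency.

    Returns the labeled grid (0 = background, components 1..n) and n.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    labels, n = ndimage.label(mask.values, structure=_STRUCTURES[connectivity])
    return labels.astype(np.int32), int(n)


def filter_components(
    labels: np.ndarray,
    n_components: int,
    restored: Volume3D,
    params: DetectionParams | None = None,
) -> ObjectSet:
    """Keep components with voxel_count >= min_volume_vox and peak >= min_peak.

    Survivors are relabeled 1..k in lexicographic order of their (unweighted)
    centroids, so the output is independent of scan order.
    """
    params = params or DetectionParams()
    params.validate()
    if labels.shape != restored.values.shape:
        raise ValueError("label grid does not match the restored volume")
    voxel_volume = restored.voxel_volume_um3
    if n_components == 0:
        return ObjectSet([], restored.spacing_um, np.zeros_like(labels, dtype=np.int32), params)

    counts = np.bincount(labels.ravel(), minlength=n_components + 1)[1:]
    index = np.arange(1, n_components + 1)
    peaks = ndimage.labeled_comprehension(
        restored.values, labels, index, np.max, float, -np.inf
    )
    keep = (counts >= params.min_volume_vox) & (peaks >= params.min_peak)
    kept_ids = index[keep]

    centroids = np.array(ndimage.center_of_mass(np.ones_like(labels), labels, kept_ids)).reshape(
        -1, 3
    )
    order = np.lexsort((centroids[:, 2], centroids[:, 1], centroids[:, 0]))

    remap = np.zeros(n_components + 1, dtype=np.int32)
    objects: list[DetectedObject] = []
    for new_id, i in enumerate(order, start=1):
        old = kept_ids[i]
        remap[old] = new_id
        objects.append(
            DetectedObject(
                id=new_id,
                centroid_vox=tuple(centroids[i]),
                voxel_count=int(counts[old - 1]),
                volume_um3=float(counts[old - 1] * voxel_volume),
                peak_intensity=float(peaks[old - 1]),
            )
        )
    return ObjectSet(objects, restored.spacing_um, remap[labels], params)


def detect_objects(
    raw: Volume3D,
    rest_params: RestorationParams | None = None,
    det_params: DetectionParams | None = None,
) -> ObjectSet:
    """Full detection: restore -> binarize -> connected components -> filter."""
    rest_params = rest_params or RestorationParams()
    det_params = det_params or DetectionParams()
    restored = restore(raw, rest_params)
    mask = binarize(restored, det_params)
    labels, n = connected_components(mask, det_params.connectivity)
    objects = filter_components(labels, n, restored, det_params)
    objects.restoration = rest_params
    return objects


__all__ = [
    "DetectionParams",
    "BinaryMask",
    "DetectedObject",
    "ObjectSet",
    "binarize",
    "connected_components",
    "filter_components",
    "detect_objects",
]
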