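"""Image restoration for light-sheet volumes.

Cleared-tissue light-sheet acquisitions carry a smooth multiplicative
autofluorescence background (tissue- and depth-dependent illumination) plus
per-voxel camera digitization noise.  Restoration proceeds in three steps:

1. estimate the background as a wide Gaussian blur of the raw data
   (``sigma_bg_vox``, much larger than a cell body but smaller than the
   autofluorescence patches),
2. divide the raw data by that estimate, yielding dimensionless normalized
   intensities that sit near 1.0 in pure background, and
3. suppress the remaining voxel-level noise with a narrow Gaussian
   (``sigma_dn_vox``).

Because both smoothing scales are defined in *voxels* and the division is by
the volume's own blur, the whole chain is invariant to a global intensity
rescaling of the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with per-axis voxel spacing in micrometres."""

    values: np.ndarray
    spacing_um: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("every axis must have at least one voxel")
        spacing = tuple(float(s) for s in self.spacing_um)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_um}")
        self.spacing_um = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        return math.prod(self.spacing_um)


@dataclass
class RestorationParams:
    """Restoration scales, in voxels.

    ``sigma_bg_vox`` is the background-model Gaussian standard deviation
    (default 50 voxels); ``sigma_dn_vox`` the denoising standard deviation
    (default 1 voxel).  ``epsilon`` is the positive floor added to the
    background before division; ``None`` means ``1e-6 *`` the background mean,
    which keeps the normalization exactly invariant under global rescaling.
    """

    sigma_bg_vox: float = 50.0
    sigma_dn_vox: float = 1.0
    epsilon: float | None = None

    def validate(self) -> None:
        if not (self.sigma_bg_vox > self.sigma_dn_vox > 0):
            raise ValueError(
                f"need sigma_bg_vox > sigma_dn_vox > 0, got "
                f"{self.sigma_bg_vox} / {self.sigma_dn_vox}"
            )
        if self.epsilon is not None and not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


def _check_finite(vol: Volume3D) -> None:
    if not np.all(np.isfinite(vol.values)):
        raise ValueError("volume contains non-finite voxels")


def _gaussian(vol: Volume3D, sigma: float) -> Volume3D:
    smoothed = ndimage.gaussian_filter(
        vol.values.astype(np.float64, copy=False), sigma=sigma, mode="reflect"
    )
    return Volume3D(smoothed, vol.spacing_um, vol.channel)


def estimate_background(vol: Volume3D, params: RestorationParams | None = None) -> Volume3D:
    """Model the autofluorescence background as a wide Gaussian blur.

    Boundary handling is reflection, so constant volumes are preserved
    exactly.  Returns a volume with the same shape and spacing.
    """
    params = params or RestorationParams()
    params.validate()
    _check_finite(vol)
    return _gaussian(vol, params.sigma_bg_vox)


def normalize(vol: Volume3D, background: Volume3D, params: RestorationParams | None = None) -> Volume3D:
    """Divide the raw volume by its background estimate.

    The result is dimensionless: ~1.0 in pure background, >1 on bright
    foreground.  A small positive floor avoids division blow-ups in empty
    corners.
    """
    params = params or RestorationParams()
    params.validate()
    if vol.values.shape != background.values.shape:
        raise ValueError(
            f"shape mismatch: volume {vol.values.shape} vs background {background.values.shape}"
        )
    bg = background.values
    if np.any(bg < 0):
        raise ValueError("background must be nonnegative")
    eps = params.epsilon
    if eps is None:
        mean = float(bg.mean())
        eps = 1e-6 * mean if mean > 0 else 1e-6
    out = vol.values.astype(np.float64, copy=False) / (bg + eps)
    return Volume3D(out, vol.spacing_um, vol.channel)


def denoise(vol: Volume3D, params: RestorationParams | None = None) -> Volume3D:
    """Suppress digitization noise with a narrow Gaussian (reflection boundary)."""
    params = params or RestorationParams()
    params.validate()
    _check_finite(vol)
    return _gaussian(vol, params.sigma_dn_vox)


def restore(vol: Volume3D, params: RestorationParams | None = None) -> Volume3D:
    """Full restoration: denoise(normalize(vol, estimate_background(vol)))."""
    params = params or RestorationParams()
    params.validate()
    background = estimate_background(vol, params)
    return denoise(normalize(vol, background, params), params)


__all__ = [
    "Volume3D",
    "RestorationParams",
    "estimate_background",
    "normalize",
    "denoise",
    "restore",
]
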