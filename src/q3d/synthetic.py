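"""Synthetic phantoms, toy atlases and two-group cohorts with known truth.

The generator emulates the study conditions of a cleared-brain light-sheet
experiment: anisotropic acquisition at 3.26 x 3.26 x 3 µm³ voxels, a smooth
multiplicative autofluorescence field, bright quasi-spherical objects
(plaques or microglia) laid down as a homogeneous Poisson process inside the
brain, per-voxel Gaussian camera noise, and treated-vs-control cohorts where
treatment multiplies the object rate and size in chosen atlas regions.

Generative model for a voxel at physical position x (µm):

    I(x) = L * f(x) * (1 + sum_j (c_j - 1) * g_j(x)) + eta,   eta ~ N(0, s²)

with L the mean background level, f a positive cosine-mixture field of unit
mean (amplitude a < 1, three random orientations -- a closed form the
restoration tests can divide out), g_j an isotropic Gaussian bump of
sigma = radius/2 truncated at 3 sigma, and c_j > 1 the peak-over-background
contrast.  Everything is drawn from one seeded generator per sample, so a
(spec, seed) pair reproduces volumes bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas_space import AffineTransform, LabelAtlas, fit_native_to_atlas, map_native_points
from .restoration import Volume3D


@dataclass
class PhantomSpec:
    """Imaging and object-process parameters of one phantom volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_um: tuple[float, float, float] = (3.26, 3.26, 3.0)
    background_level: float = 100.0
    background_amplitude: float = 0.3
    background_wavelength_um: float = 1000.0
    noise_sd: float = 2.0
    object_rate: float = 300.0  # expected objects per mm^3 of brain interior
    object_radius_um: tuple[float, float] = (15.0, 3.0)  # mean, sd
    object_contrast: tuple[float, float] = (3.0, 0.5)  # mean, sd of peak multiplier
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing must be positive")
        if not (0 <= self.background_amplitude < 1):
            raise ValueError("background_amplitude must lie in [0, 1)")
        if self.background_level <= 0 or self.background_wavelength_um <= 0:
            raise ValueError("background level and wavelength must be positive")
        if self.noise_sd < 0 or self.object_rate < 0:
            raise ValueError("noise_sd and object_rate must be nonnegative")
        if self.object_radius_um[0] <= 0 or self.object_radius_um[1] < 0:
            raise ValueError("radius mean must be positive, radius SD nonnegative")
        if self.object_contrast[0] <= 1:
            raise ValueError("mean contrast must exceed 1")

    @property
    def volume_mm3(self) -> float:
        return math.prod(self.shape) * math.prod(self.spacing_um) * 1e-9


@dataclass
class TruthObject:
    center_vox: tuple[float, float, float]
    radius_um: float
    contrast: float
    region_id: int


@dataclass
class GroundTruth:
    """Every draw of the generative model, for recovery tests."""

    objects: list[TruthObject]
    background_field: np.ndarray  # the multiplicative field f(x), unit mean

    def __len__(self) -> int:
        return len(self.objects)

    def centers(self) -> np.ndarray:
        if not self.objects:
            return np.empty((0, 3))
        return np.array([o.center_vox for o in self.objects], dtype=float)

    def region_ids(self) -> np.ndarray:
        return np.array([o.region_id for o in self.objects], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_vox": [o.center_vox[0] for o in self.objects],
                "y_vox": [o.center_vox[1] for o in self.objects],
                "z_vox": [o.center_vox[2] for o in self.objects],
                "radius_um": [o.radius_um for o in self.objects],
                "contrast": [o.contrast for o in self.objects],
                "region_id": [o.region_id for o in self.objects],
            }
        )


@dataclass
class CohortSpec:
    """Two-arm cohort: control uses the base phantom process; the treated arm
    thins the object process per region by the rate multiplier and scales
    object radii by the size multiplier."""

    base: PhantomSpec = field(default_factory=PhantomSpec)
    n_per_group: int = 6
    effect_map: dict[int, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        self.base.validate()
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per arm")
        for rid, (rate_mult, size_mult) in self.effect_map.items():
            if rate_mult <= 0 or size_mult <= 0:
                raise ValueError(f"multipliers must be positive (region {rid})")
            if rate_mult > 1.0:
                raise ValueError(
                    f"rate multiplier above 1 (region {rid}) cannot be realised by thinning"
                )


def generate_toy_atlas(shape: tuple[int, int, int], n_regions: int, seed: int = 0) -> LabelAtlas:
    """A stand-in reference atlas: an ellipsoidal brain partitioned into
    contiguous regions by a seeded Voronoi tessellation; label 0 = outside."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    shape = tuple(int(s) for s in shape)
    if any(s < 8 for s in shape):
        raise ValueError("atlas shape must be at least 8 voxels per axis")
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.42
    grid = np.indices(shape).reshape(3, -1).T
    inside = (((grid - center) / semi) ** 2).sum(axis=1) <= 1.0
    interior = grid[inside]
    if n_regions > len(interior):
        raise ValueError(
            f"cannot partition {len(interior)} interior voxels into {n_regions} regions"
        )
    rng = np.random.default_rng(seed)
    seeds = interior[rng.choice(len(interior), size=n_regions, replace=False)]
    d2 = ((interior[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assignment = d2.argmin(axis=1) + 1
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(interior.T)] = assignment
    regions = pd.DataFrame(
        {"id": np.arange(1, n_regions + 1), "name": [f"region_{i:02d}" for i in range(1, n_regions + 1)]}
    )
    return LabelAtlas(labels, 25.0, regions)


def _background_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency cosine mixture, unit mean, range [1-a, 1+a]."""
    a = spec.background_amplitude
    dirs = rng.normal(size=(3, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    coords = [np.arange(s, dtype=np.float64) * sp for s, sp in zip(spec.shape, spec.spacing_um)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    fld = np.ones(spec.shape, dtype=np.float64)
    if a > 0:
        k = 2 * np.pi / spec.background_wavelength_um
        for i in range(3):
            phase = k * (dirs[i, 0] * X + dirs[i, 1] * Y + dirs[i, 2] * Z) + phases[i]
            fld += (a / 3.0) * np.cos(phase)
    else:
        # keep the generator stream identical whether or not the field is flat
        pass
    return fld


def _validate_transform_domain(spec: PhantomSpec, atlas: LabelAtlas, transform: AffineTransform) -> None:
    extent_um = np.asarray(spec.shape) * np.asarray(spec.spacing_um)
    max_bin = np.maximum(np.ceil(extent_um / atlas.spacing_um) - 1, 0)
    corners = np.array(
        [[bx, by, bz] for bx in (0, max_bin[0]) for by in (0, max_bin[1]) for bz in (0, max_bin[2])],
        dtype=float,
    )
    idx = np.rint(transform.apply(corners))
    shape = np.asarray(atlas.shape)
    if np.any(idx < -1) or np.any(idx > shape):
        raise ValueError(
            "transform maps the native volume outside the atlas bounds; "
            "check shape/spacing against the transform domain"
        )


def _sample_objects(
    spec: PhantomSpec,
    atlas: LabelAtlas,
    transform: AffineTransform,
    rng: np.random.Generator,
) -> list[TruthObject]:
    """Homogeneous Poisson process on the brain interior, by rejection."""
    lam = spec.object_rate * spec.volume_mm3
    n_total = int(rng.poisson(lam)) if lam > 0 else 0
    objects: list[TruthObject] = []
    if n_total == 0:
        return objects
    centers = rng.uniform(0, 1, size=(n_total, 3)) * np.asarray(spec.shape)
    radii = _truncated_normal(rng, *spec.object_radius_um, n_total, lower=1e-3)
    contrasts = _truncated_normal(rng, *spec.object_contrast, n_total, lower=1.0 + 1e-6)
    idx, ok = map_native_points(centers, spec.spacing_um, atlas, transform)
    for i in range(n_total):
        if not ok[i]:
            continue
        rid = int(atlas.labels[tuple(idx[i])])
        if rid == 0:
            continue
        objects.append(TruthObject(tuple(centers[i]), float(radii[i]), float(contrasts[i]), rid))
    return objects


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lower: float
) -> np.ndarray:
    draws = rng.normal(mean, sd, size=n)
    bad = draws <= lower
    for _ in range(100):
        if not bad.any():
            break
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = draws <= lower
    return np.maximum(draws, lower)


def render_objects(values: np.ndarray, spec: PhantomSpec, objects: list[TruthObject]) -> None:
    """Add (contrast-1) Gaussian bumps (sigma = radius/2, truncated at 3 sigma,
    physically isotropic) to the dimensionless object field, in place."""
    spacing = np.asarray(spec.spacing_um)
    shape = np.asarray(spec.shape)
    for obj in objects:
        sigma = obj.radius_um / 2.0
        cutoff = 3.0 * sigma
        center = np.asarray(obj.center_vox)
        lo = np.maximum(np.floor(center - cutoff / spacing).astype(int), 0)
        hi = np.minimum(np.ceil(center + cutoff / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [
            (np.arange(lo[d], hi[d]) - center[d]) * spacing[d]
            for d in range(3)
        ]
        r2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        bump = np.where(r2 <= cutoff**2, np.exp(-r2 / (2 * sigma**2)), 0.0)
        values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (obj.contrast - 1.0) * bump


def render_phantom(
    spec: PhantomSpec,
    objects: list[TruthObject],
    background_field: np.ndarray,
    rng: np.random.Generator | None = None,
) -> Volume3D:
    """Evaluate the generative model for a given object list and field."""
    object_field = np.zeros(spec.shape, dtype=np.float64)
    render_objects(object_field, spec, objects)
    values = spec.background_level * background_field * (1.0 + object_field)
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return Volume3D(values, spec.spacing_um, channel="phantom")


def generate_phantom(
    spec: PhantomSpec,
    atlas: LabelAtlas,
    transform: AffineTransform | None = None,
    render: bool = True,
) -> tuple[Volume3D | None, GroundTruth]:
    """Draw one phantom volume and its ground truth.

    ``render=False`` skips rasterization and returns ``(None, truth)``; the
    object process and the background field are drawn identically either way,
    which makes large object-process studies cheap.
    """
    spec.validate()
    if transform is None:
        transform = fit_native_to_atlas(spec.shape, spec.spacing_um, atlas)
    _validate_transform_domain(spec, atlas, transform)
    rng = np.random.default_rng(spec.seed)
    fld = _background_field(spec, rng)
    objects = _sample_objects(spec, atlas, transform, rng)
    truth = GroundTruth(objects, fld)
    if not render:
        return None, truth
    volume = render_phantom(spec, objects, fld, rng)
    return volume, truth


def _thin_objects(
    objects: list[TruthObject],
    effect_map: dict[int, tuple[float, float]],
    rng: np.random.Generator,
) -> list[TruthObject]:
    """Independent Bernoulli thinning + radius scaling per region (exact
    thinning of the Poisson process)."""
    out: list[TruthObject] = []
    for obj in objects:
        rate_mult, size_mult = effect_map.get(obj.region_id, (1.0, 1.0))
        if rate_mult < 1.0 and rng.uniform() >= rate_mult:
            continue
        radius = obj.radius_um * size_mult
        out.append(replace(obj, radius_um=radius))
    return out


def sample_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-sample seed derived from the cohort seed."""
    return int(np.random.SeedSequence((cohort_seed, index)).generate_state(1)[0] % (2**31))


def generate_cohort(
    cohort: CohortSpec,
    atlas: LabelAtlas,
    transform: AffineTransform | None = None,
    render: bool = True,
) -> list[tuple[Volume3D | None, GroundTruth, str]]:
    """Draw a two-arm cohort: controls first, then treated samples.

    The treated arm applies the region-specific rate thinning and radius
    scaling of ``cohort.effect_map``.  Per-sample seeds are derived
    deterministically from the cohort seed.
    """
    cohort.validate()
    known = set(int(i) for i in atlas.regions["id"])
    unknown = set(cohort.effect_map) - known
    if unknown:
        raise ValueError(f"effect_map refers to unknown regions: {sorted(unknown)}")
    if transform is None:
        transform = fit_native_to_atlas(cohort.base.shape, cohort.base.spacing_um, atlas)

    samples: list[tuple[Volume3D | None, GroundTruth, str]] = []
    for arm_index, group in enumerate(("control", "treated")):
        for i in range(cohort.n_per_group):
            seed = sample_seed(cohort.seed, arm_index * cohort.n_per_group + i)
            spec = replace(cohort.base, seed=seed)
            spec.validate()
            _validate_transform_domain(spec, atlas, transform)
            rng = np.random.default_rng(seed)
            fld = _background_field(spec, rng)
            objects = _sample_objects(spec, atlas, transform, rng)
            if group == "treated" and cohort.effect_map:
                objects = _thin_objects(objects, cohort.effect_map, rng)
            truth = GroundTruth(objects, fld)
            volume = render_phantom(spec, objects, fld, rng) if render else None
            samples.append((volume, truth, group))
    return samples


__all__ = [
    "PhantomSpec",
    "TruthObject",
    "GroundTruth",
    "CohortSpec",
    "generate_toy_atlas",
    "generate_phantom",
    "generate_cohort",
    "render_phantom",
    "render_objects",
    "sample_seed",
]
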