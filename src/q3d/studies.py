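"""Self-contained phantom studies exercising the pipeline end to end.

These functions generate their own synthetic inputs, run the relevant stages
and return the measured quantities.  They back both the validation suite and
the reproduction script, so the problem sizes here (16³ null maps, a 64³
atlas for the effect-recovery study) are the package's standard desk-scale
study conditions.
"""

from __future__ import annotations

import numpy as np

from .atlas_space import (
    AtlasGrid,
    bin_centers,
    fit_native_to_atlas,
    smooth_spherical,
)
from .restoration import RestorationParams
from .segmentation import DetectedObject, DetectionParams, ObjectSet, detect_objects
from .synthetic import (
    CohortSpec,
    GroundTruth,
    PhantomSpec,
    TruthObject,
    generate_cohort,
    generate_toy_atlas,
    render_phantom,
)
from .voxel_stats import TfceParams, binarize_significance, permutation_correct, tfce


def roi_geometry(diameter_vox: int = 15, atlas_spacing_um: float = 25.0) -> float:
    """Physical diameter (µm) reported by the smoothing metadata."""
    grid = AtlasGrid(np.zeros((8, 8, 8)), "plaque_count", spacing_um=atlas_spacing_um)
    return float(smooth_spherical(grid, diameter_vox, "sum").roi_diameter_um)


def tfce_single_voxel_ratio(h0: float = 4.0, dh: float = 0.005) -> float:
    """TFCE of an isolated voxel divided by h0^3; -> 1/3 as dh -> 0."""
    stat = np.zeros((9, 9, 9))
    stat[4, 4, 4] = h0
    out = tfce(stat, TfceParams(dh=dh))
    return float(out[4, 4, 4] / h0**3)


def truth_object_set(truth: GroundTruth, spacing_um) -> ObjectSet:
    """Wrap ground-truth object centers as a detection result (unit volumes),
    for studies that bypass image-space detection."""
    objs = [
        DetectedObject(i + 1, o.center_vox, 1, 1.0, o.contrast)
        for i, o in enumerate(truth.objects)
    ]
    return ObjectSet(objs, tuple(spacing_um))


def null_familywise_error(
    seed: int,
    n_cohorts: int = 200,
    n_per_group: int = 5,
    shape: tuple[int, int, int] = (16, 16, 16),
    roi_diameter: int = 5,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> float:
    """Family-wise error rate of the TFCE permutation test on null cohorts.

    Each cohort holds 2 x n exchangeable smoothed noise heatmaps; the FWER is
    the fraction of cohorts with any voxel p_corr < alpha.  Exhaustive
    enumeration is used whenever C(2n, n) <= n_perm.
    """
    rng = np.random.default_rng(seed)
    false_positives = 0
    for _ in range(n_cohorts):
        maps = [
            smooth_spherical(
                AtlasGrid(np.abs(rng.normal(2.0, 1.0, size=shape)), "plaque_count"),
                roi_diameter,
                "sum",
            ).values
            for _ in range(2 * n_per_group)
        ]
        params = TfceParams(n_perm=n_perm, seed=int(rng.integers(2**31)))
        stats = permutation_correct(maps[:n_per_group], maps[n_per_group:], params)
        false_positives += bool((stats.p_corr_map < alpha).any())
    return false_positives / n_cohorts


def effect_recovery(
    seed: int,
    n_per_group: int = 6,
    atlas_shape: tuple[int, int, int] = (64, 64, 64),
    n_regions: int = 6,
    object_rate: float = 4800.0,
    rate_multiplier: float = 0.5,
    roi_diameter: int = 15,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Region-specific rate-reduction recovery on a synthetic cohort.

    The treated arm halves the plaque rate in one region (the median-sized
    one); ground-truth centers run through atlas binning, spherical smoothing
    and the TFCE permutation test.  Returns the fraction of the affected
    region flagged as decrease, the decrease fraction elsewhere in the brain,
    and the realized treated/control count ratio in the affected region.
    """
    atlas = generate_toy_atlas(atlas_shape, n_regions, seed=seed)
    sizes = {int(r): int((atlas.labels == r).sum()) for r in atlas.regions["id"]}
    ordered = sorted(sizes, key=lambda r: sizes[r])
    target = ordered[len(ordered) // 2]  # median-sized region

    spec = PhantomSpec(
        shape=atlas_shape,
        spacing_um=(atlas.spacing_um,) * 3,
        object_rate=object_rate,
        seed=seed,
    )
    cohort = CohortSpec(
        base=spec,
        n_per_group=n_per_group,
        effect_map={target: (rate_multiplier, 1.0)},
        seed=seed,
    )
    transform = fit_native_to_atlas(spec.shape, spec.spacing_um, atlas)
    samples = generate_cohort(cohort, atlas, transform, render=False)

    grids = {"control": [], "treated": []}
    region_counts = {"control": 0, "treated": 0}
    for _, truth, group in samples:
        objects = truth_object_set(truth, spec.spacing_um)
        counts, _, _ = bin_centers(objects, atlas, transform)
        grids[group].append(smooth_spherical(counts, roi_diameter, "sum"))
        region_counts[group] += int((truth.region_ids() == target).sum())

    params = TfceParams(n_perm=n_perm, seed=seed)
    stats = permutation_correct(grids["treated"], grids["control"], params)
    sig = binarize_significance(stats, alpha)

    in_region = atlas.labels == target
    elsewhere = (atlas.labels > 0) & ~in_region
    return {
        "region_id": target,
        "frac_region_decrease": float((sig.values[in_region] == -1).mean()),
        "frac_elsewhere_decrease": float((sig.values[elsewhere] == -1).mean()),
        "frac_elsewhere_flagged": float((sig.values[elsewhere] != 0).mean()),
        "count_ratio_region": region_counts["treated"] / max(region_counts["control"], 1),
        "n_voxels_region": int(in_region.sum()),
        "n_voxels_elsewhere": int(elsewhere.sum()),
    }


def detection_recovery(seed: int, n_objects: int = 20) -> dict:
    """Detection recall on a grid of planted bright objects at native scale."""
    spec = PhantomSpec(
        shape=(66, 66, 72),
        spacing_um=(3.26, 3.26, 3.0),
        background_amplitude=0.0,
        noise_sd=0.5,
        object_rate=0.0,
        seed=seed,
    )
    centers = []
    for i in range(n_objects):
        gx, gy, gz = i % 3, (i // 3) % 3, i // 9
        centers.append((11.0 + 22 * gx, 11.0 + 22 * gy, 12.0 + 24 * gz))
    objs = [TruthObject(c, 12.0, 3.5, 1) for c in centers]
    rng = np.random.default_rng(seed)
    volume = render_phantom(spec, objs, np.ones(spec.shape), rng)
    detected = detect_objects(volume, RestorationParams(), DetectionParams())
    got = detected.centroids()
    matched = 0
    for c in centers:
        if len(got) and np.abs(got - np.asarray(c)).max(axis=1).min() <= 2.0:
            matched += 1
    return {
        "n_planted": n_objects,
        "n_detected": len(detected),
        "recall": matched / n_objects,
    }


__all__ = [
    "roi_geometry",
    "tfce_single_voxel_ratio",
    "truth_object_set",
    "null_familywise_error",
    "effect_recovery",
    "detection_recovery",
]
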