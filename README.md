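# q3d — quantitative 3D histochemistry

Voxel-level statistical mapping of labeled objects in cleared-brain
light-sheet volumes.  `q3d` is aimed at preclinical drug-efficacy studies
that ask not "did total amyloid go down?" but "*where* in the brain did
plaque count, plaque size, or microglia volume change?" — comparing treated
and control cohorts voxel by voxel in a common atlas space.

The pipeline:

1. **Restoration** — background autofluorescence is modelled as a wide
   Gaussian blur (σ_bg = 50 voxels) and divided out; digitization noise is
   suppressed with a narrow Gaussian (σ_dn = 1 voxel).  The normalized
   intensities are dimensionless (≈ 1 in background) and invariant to
   global exposure rescaling.
2. **Segmentation** — voxels with normalized intensity ≥ 1.8 are
   foreground; 26-connected components become objects, filtered by minimum
   volume (27 voxels) and minimum peak intensity (2.2).
3. **Atlas mapping** — object centers (or segmented voxels) are binned to
   the 25 µm atlas grid, pushed through the per-sample registration affine,
   and accumulated into per-voxel count / mean-size / volume grids.
4. **Heatmaps** — spherical-ROI smoothing with a 15-voxel (375 µm)
   diameter ball produces density heatmaps.
5. **Voxel statistics** — per-voxel pooled-variance Student t between the
   two groups, threshold-free cluster enhancement
   (TFCE(v) = Σ_h e_h(v)^E h^H dh, E = 0.5, H = 2), and max-statistic
   permutation correction give family-wise-corrected p-values, binarized at
   p < 0.05 into ternary decrease/none/increase maps.
6. **Reporting** — regional tables (group mean ± SD, significant-voxel
   fractions per atlas region) and 2×2 colocalization matrices between two
   significance maps (e.g. plaques vs microglia).

A synthetic-data module generates phantoms with known ground truth —
anisotropic 3.26 × 3.26 × 3 µm acquisition, multiplicative background,
Poisson-process objects, two-arm cohorts with region-specific rate/size
effects — so the entire chain is testable without any imaging data.

## Worked example

```python
import numpy as np
from q3d import (CohortSpec, PhantomSpec, PipelineConfig, SampleSpec,
                 fit_native_to_atlas, generate_cohort, generate_toy_atlas,
                 run_pipeline)
from q3d.config import StatsParams
from q3d.voxel_stats import TfceParams

atlas = generate_toy_atlas((12, 12, 12), n_regions=2, seed=1)
spec = PhantomSpec(shape=(64, 64, 64), spacing_um=(5.0, 5.0, 5.0),
                   object_rate=8000.0, object_radius_um=(14.0, 2.0),
                   object_contrast=(3.5, 0.4), seed=1)
transform = fit_native_to_atlas(spec.shape, spec.spacing_um, atlas)
cohort = CohortSpec(base=spec, n_per_group=5,
                    effect_map={1: (0.4, 1.0), 2: (0.4, 1.0)},  # 60% fewer objects
                    seed=1)
samples = [SampleSpec(volume=vol, group=group, transform=transform)
           for vol, _, group in generate_cohort(cohort, atlas, transform)]

config = PipelineConfig()
config.atlas.roi_diameter_vox = 9
config.stats = StatsParams(alpha=0.05, tfce=TfceParams(n_perm=260, seed=1))
result = run_pipeline(config, samples, atlas)

print("objects per sample:", result.n_objects)
print("decrease voxels:", int(np.count_nonzero(result.sig_count.values == -1)))
```

prints

```
objects per sample: [27, 27, 32, 27, 36, 16, 17, 16, 15, 19]
decrease voxels: 32
```

i.e. the detector finds ~30 objects in each control sample and ~17 in each
treated sample (the planted 0.4× rate effect), and after ROI smoothing,
TFCE enhancement and exhaustive permutation correction (C(10,5) = 252
assignments), 32 atlas voxels are flagged as a significant decrease in
object count.

The same stages are available from the shell:

```sh
q3d simulate --outdir demo/
q3d restore --sigma-bg 50 --sigma-dn 1 demo/sample_00_control.nii restored.nii
q3d segment --tau 1.8 --min-volume 27 --min-peak 2.2 demo/sample_00_control.nii objects.csv
q3d run --atlas demo/atlas.nii --regions demo/regions.csv --manifest demo/manifest.json --outdir out/
```

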