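# Methods

## Scope and model

`q3d` implements the quantitative analysis chain for whole-brain /
whole-hemisphere light-sheet histochemistry: raw anisotropic intensity
volumes of labeled objects (amyloid plaques, Iba1+ microglia) are restored,
segmented into 3D objects, mapped into a common labeled atlas grid,
smoothed into density heatmaps, compared voxel-by-voxel between two cohorts
with family-wise-corrected permutation statistics, and summarized as
regional tables and significance-map colocalization matrices.  Registration
itself is out of scope: per-sample affine transforms are consumed, never
estimated.

## Restoration

Background autofluorescence is modelled as a wide Gaussian blur of the raw
volume and removed by division; remaining digitization noise is suppressed
by a narrow Gaussian.  Both scales are Gaussian *standard deviations in
voxels* — `sigma_bg_vox = 50`, `sigma_dn_vox = 1` by default.  The vernacular
"variance" of filtering pipelines names the sigma parameter; reading it as
sigma² would give a ~7-voxel background scale, smaller than typical
autofluorescent patches and inconsistent with the stated intent that the
background scale exceed the foreground radius.

Numerical choices: reflection boundaries (constants are exact fixed points);
the division floor is `1e-6 ×` the background mean, which makes the whole
chain *exactly* invariant under global intensity rescaling — a useful
invariant because light-sheet exposure varies between samples.  Smoothing is
applied to the full grid without tissue masking.

A consequence worth stating because it constrains every downstream
parameter: a Gaussian object of physical sigma `s` (radius = 2s in the
generator's convention) is attenuated by the sigma=1 denoising step by
`prod_axis s_vox / sqrt(s_vox² + 1)`.  At 3.26 × 3.26 × 3 µm voxels an
object must have a radius of roughly ≥ 10–12 µm for a contrast-3 peak to
survive above the detection threshold of 1.8 — smaller/dimmer structures are
invisible to this parameter set by design, matching the "large and bright"
detection intent.  The recovery and idempotence tests plant objects in this
physically detectable regime (radius 12–40 µm).

## Segmentation

Foreground is `restored intensity >= tau` (inclusive; tau = 1.8 for all
samples).  Connected components under 26-adjacency (6/18 exposed) become
candidate objects; survivors need `voxel_count >= 27` (a 3³ cube) and peak
restored intensity `>= 2.2`.  The volume/peak filter values are mandatory
config entries: the original thresholds were validated visually and are not
published, so runs must be self-documenting.  Centroids are unweighted voxel
means; object ids are 1..n in lexicographic centroid order, making the
output independent of scan order.  The same detector with a plaque-tuned
parameter block stands in for an externally trained voxel classifier; the
classifier sits behind the `binarize` boundary so one can substitute any
boolean mask.

## Atlas mapping and heatmaps

Voxel indices are 0-based; physical position = index × spacing
(corner origin); binning to the 25 µm atlas grid is
`floor(position/25)`; the per-sample affine acts on integer bin coordinates
and is rounded to the nearest atlas voxel.  Nearest-neighbour assignment
(no count splitting) keeps counts integral, so conservation is exact:
objects in = grid total + dropped, and segmented-volume totals equal
foreground voxels × voxel volume.

Spherical-ROI smoothing uses the inclusive Euclidean ball of 15-voxel
diameter (radius 7.5, i.e. 375 µm at 25 µm spacing), zero-padded at edges.
The microglia "weighted sum" is implemented with uniform weights (the
original weighting is unspecified); a linearly decaying radial weight is
available behind a flag.  Mean plaque size per voxel is the mean object
volume in µm³; ROI smoothing of mean sizes is count-weighted
(Σ size·count / Σ count within the ROI).

## Voxel statistics

Per-voxel pooled-variance Student t (df = nA+nB−2); Welch is deliberately
not the default since pooled t is the convention of this pipeline lineage.
Zero-variance voxels get t = 0, p = 1, and never enter the null maxima.

TFCE: `TFCE(v) = Σ_h e_h(v)^E · h^H · dh` with E = 0.5, H = 2, thresholds
from `dh·max` to `max` in steps of `dh·max` (dh = 0.01), cluster extent
under 26-adjacency, supra-threshold rule `stat >= h`.  The implementation
sweeps thresholds downward with an incremental union-find, which is
algebraically identical to rebuilding clusters per threshold (the test
oracle does exactly that rebuild and agrees to 1e-9).  Two caveats that the
tests encode explicitly:

- because `dh` is a *fraction of the map maximum*, two maps with different
  maxima integrate on different Riemann grids; pointwise monotonicity of
  TFCE is exact only at a fixed threshold grid and approximate otherwise;
- an isolated voxel of height h0 enhances to ≈ h0³/3 (E=0.5, H=2), with a
  positive O(dh) discretization bias (+0.75% at dh=0.005).

Family-wise correction uses the max-statistic permutation null on the
*two-sided* enhanced statistic (TFCE of +t and −t, combined voxelwise).
Assignments are enumerated exhaustively when `C(n, nA) <= n_perm`, otherwise
the identity plus `n_perm − 1` uniform draws are used;
`p_corr(v) = #{permutation maxima >= TFCE_obs(v)} / n_used`.  Because the
two-sided statistic is invariant under swapping the groups, enumerated
assignments come in complement pairs with identical maxima: the attainable
p-value floor at nA = nB = 3 is 2/20 = 0.1, which means **no voxel can reach
p < 0.05 with 3 samples per arm** under exhaustive two-sided permutation.
At 4v4 the floor is 2/70 ≈ 0.029.  Significance maps are ternary:
−1/+1 where `p_corr < alpha` (strict) with the sign of the group-A−group-B
effect, 0 elsewhere.

## Synthetic phantoms

The generator draws, per sample and from one seeded generator (order:
background field, Poisson count, centers, radii, contrasts, thinning,
noise):

    I(x) = L · f(x) · (1 + Σ_j (c_j − 1) g_j(x)) + N(0, s²)

- `f`: cosine mixture over three random unit directions, unit mean,
  amplitude 0.3, wavelength 1000 µm — a closed form the restoration tests
  divide out exactly.  Smoothed-noise fields would be more realistic but
  have no closed form.
- objects: homogeneous Poisson inside the brain interior (rejection
  sampling against the atlas; objects falling on label 0 are discarded so
  every truth object has a region).  Default rate 300/mm³ (plaque-like);
  studies override per design.  Radii ~ N(15, 3²) µm truncated positive,
  contrasts ~ N(3, 0.5²) truncated > 1; kernel is an isotropic Gaussian
  with sigma = radius/2 truncated at the 3-sigma sphere, so "radius" is a
  full-width-like scale and peaks equal `L·c` exactly at grid-aligned
  centers.
- noise: additive Gaussian, default 2% of the background level (camera
  read-noise proxy; Poisson shot noise omitted for closed-form testability).

Cohorts: control arm = base process; treated arm applies per-region
independent Bernoulli thinning (exact thinning of a Poisson process) and
radius scaling.  Per-sample seeds derive from `SeedSequence((cohort_seed,
index))`.  Rate multipliers above 1 are rejected (thinning cannot amplify).

What the phantoms do **not** emulate: PSF anisotropy, stripe/shadow
artifacts, stitching seams, vasculature, object clustering around pathology,
two-channel maturity staining.  Passing tests therefore demonstrate the
correctness of the *computational chain* under a known generative model,
not segmentation accuracy on real tissue.

## Study conditions and problem sizes

The validation studies run at desk scale, chosen so the full suite and the
reproduction script each finish comfortably on one CPU:

- **Null calibration**: 200 cohorts of 2×5 exchangeable smoothed-noise 16³
  heatmaps, exhaustive 252 assignments each; family-wise error must sit in
  the 95% binomial band around alpha = 0.05 (the theoretical rate under
  exhaustive two-sided enumeration is 6/126 ≈ 0.048).
- **Effect recovery**: 6v6 cohort on a 64³ toy atlas (6 Voronoi regions in
  an ellipsoidal brain), plaque rate halved in the median-sized region,
  object rate 4800/mm³.  The rate was fixed a priori by a power argument:
  with ROI sums λ ≈ 130 counts, halving the rate gives a whole-region
  t ≈ sqrt(λ) ≈ 11 at n = 6, leaving the 375 µm smoothing spillover beyond
  the region boundary (~1–2 voxels of significant shell) well under the 5%
  false-territory budget while keeping near-surface region voxels powered.
  Densities of a few thousand objects per mm³ are in the range reported for
  heavily plaque-laden aged amyloidosis models.
- **Detection recall**: 20 well-separated radius-12 µm, contrast-3.5
  objects at native 3.26 × 3.26 × 3 µm spacing; expected recall 1.0.
- **End-to-end demo**: a rendered 5v5 cohort (64³ native at 5 µm, 12³
  atlas, 9-voxel ROI) through the full
  restore→detect→map→smooth→test→colocalize chain.  Five per group because
  3 per group cannot reach significance (see the p-floor above), and a
  9-voxel ROI because very sparse ROI sums (a handful of counts) leave
  near-binary voxels whose permuted t statistics have almost-zero pooled
  variance; such voxels inflate the permutation null maxima and make the
  unregularized max-statistic test severely conservative.  Dense ROI sums
  (tens of counts and up, as in the effect-recovery study at λ ≈ 130) are
  the test's intended operating regime.

## Known limitations

- Desk-scale arrays only; no tiling/out-of-core path for full-brain grids.
- Affine transforms only; nonrigid displacement fields are not consumed.
- No watershed splitting: touching objects merge, so counts saturate at
  high volume fractions (the generator's defaults stay well below that).
- The toy atlas is a convex-region Voronoi partition, not an anatomical
  ontology; regional aggregation does not traverse a region hierarchy.
- Colocalization is reported as counts and proportions; no null model for
  the overlap itself is fitted.
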