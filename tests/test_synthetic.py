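"""Phantom generator: toy atlas, generative model, cohort effect structure."""

import numpy as np
import pytest
from scipy import stats as sps

from q3d import (
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    generate_toy_atlas,
    map_native_points,
)
from q3d.atlas_space import fit_native_to_atlas
from q3d.synthetic import render_phantom, TruthObject


class TestToyAtlas:
    def test_partitions_interior(self):
        atlas = generate_toy_atlas((32, 32, 32), 4, seed=1)
        labels = np.unique(atlas.labels)
        assert set(labels) == {0, 1, 2, 3, 4}
        assert (atlas.labels > 0).sum() == atlas.interior.sum()

    def test_deterministic(self):
        a = generate_toy_atlas((16, 16, 16), 3, seed=5)
        b = generate_toy_atlas((16, 16, 16), 3, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_region_counts_sum_to_interior_by_exhaustive_scan(self):
        atlas = generate_toy_atlas((16, 16, 16), 5, seed=2)
        per_region = 0
        interior = 0
        for idx in np.ndindex(atlas.shape):
            lab = atlas.labels[idx]
            if lab > 0:
                per_region += 1
            if atlas.interior[idx]:
                interior += 1
        assert per_region == interior
        counts = [int((atlas.labels == i).sum()) for i in range(1, 6)]
        assert sum(counts) == interior
        assert all(c > 0 for c in counts)

    def test_oversized_region_request_rejected(self):
        with pytest.raises(ValueError, match="interior"):
            generate_toy_atlas((8, 8, 8), 10_000, seed=0)


class TestGeneratePhantom:
    def test_zero_rate_gives_pure_background(self, toy_atlas):
        spec = PhantomSpec(shape=(16, 16, 16), spacing_um=(25.0, 25.0, 25.0),
                           object_rate=0.0, seed=4)
        volume, truth = generate_phantom(spec, toy_atlas)
        assert len(truth) == 0
        assert volume.values.shape == (16, 16, 16)

    def test_bit_identical_for_same_seed(self, toy_atlas):
        spec = PhantomSpec(shape=(16, 16, 16), spacing_um=(25.0, 25.0, 25.0),
                           object_rate=3000.0, seed=21)
        v1, t1 = generate_phantom(spec, toy_atlas)
        v2, t2 = generate_phantom(spec, toy_atlas)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(t1.centers(), t2.centers())

    def test_poisson_mean_of_object_count(self, toy_atlas):
        """Interior-restricted homogeneous Poisson: mean count over 200 seeds
        within 3 SE of rate x interior volume."""
        spec = PhantomSpec(shape=(24, 24, 24), spacing_um=(16.0, 16.0, 16.0),
                           object_rate=1500.0)
        transform = fit_native_to_atlas(spec.shape, spec.spacing_um, toy_atlas)
        # interior volume via brute-force mapping of every native voxel center
        grid = np.indices(spec.shape).reshape(3, -1).T + 0.5
        idx, ok = map_native_points(grid, spec.spacing_um, toy_atlas, transform)
        inside = np.zeros(len(grid), dtype=bool)
        inside[ok] = toy_atlas.labels[tuple(idx[ok].T)] > 0
        v_interior_mm3 = inside.sum() * np.prod(spec.spacing_um) * 1e-9
        lam = spec.object_rate * v_interior_mm3

        counts = []
        for seed in range(200):
            s = PhantomSpec(**{**spec.__dict__, "seed": seed})
            _, truth = generate_phantom(s, toy_atlas, transform, render=False)
            counts.append(len(truth))
        se = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) <= 3 * se

    def test_zero_noise_volume_matches_generative_formula(self, toy_atlas):
        spec = PhantomSpec(shape=(16, 16, 16), spacing_um=(25.0, 25.0, 25.0),
                           noise_sd=0.0, object_rate=4000.0, seed=8)
        volume, truth = generate_phantom(spec, toy_atlas)
        assert len(truth) > 0
        # independent re-evaluation of the closed form at every voxel
        expected = np.zeros(spec.shape)
        coords_um = np.indices(spec.shape).astype(float) * 25.0
        for obj in truth.objects:
            sigma = obj.radius_um / 2
            c = np.asarray(obj.center_vox) * 25.0
            r2 = sum((coords_um[d] - c[d]) ** 2 for d in range(3))
            expected += (obj.contrast - 1) * np.where(
                r2 <= (3 * sigma) ** 2, np.exp(-r2 / (2 * sigma**2)), 0.0
            )
        expected = spec.background_level * truth.background_field * (1 + expected)
        np.testing.assert_allclose(volume.values, expected, rtol=1e-6)

    def test_planted_object_peak_equals_level_times_contrast(self):
        spec = PhantomSpec(shape=(32, 32, 32), spacing_um=(4.0, 4.0, 4.0),
                           background_amplitude=0.0, noise_sd=0.0, object_rate=0.0)
        obj = TruthObject((16.0, 16.0, 16.0), radius_um=12.0, contrast=2.8, region_id=1)
        volume = render_phantom(spec, [obj], np.ones(spec.shape))
        assert volume.values.max() == pytest.approx(
            spec.background_level * obj.contrast, rel=1e-9
        )

    def test_truth_labels_consistent_with_atlas(self, toy_atlas):
        spec = PhantomSpec(shape=(20, 20, 20), spacing_um=(20.0, 20.0, 20.0),
                           object_rate=3000.0, seed=13)
        transform = fit_native_to_atlas(spec.shape, spec.spacing_um, toy_atlas)
        _, truth = generate_phantom(spec, toy_atlas, transform, render=False)
        assert len(truth) > 0
        idx, ok = map_native_points(truth.centers(), spec.spacing_um, toy_atlas, transform)
        assert ok.all()
        np.testing.assert_array_equal(
            toy_atlas.labels[tuple(idx.T)], truth.region_ids()
        )

    def test_mismatched_transform_domain_rejected(self, toy_atlas):
        from q3d import AffineTransform

        spec = PhantomSpec(shape=(16, 16, 16), spacing_um=(25.0, 25.0, 25.0))
        bad = AffineTransform(np.eye(3) * 40.0, np.zeros(3))
        with pytest.raises(ValueError, match="bounds"):
            generate_phantom(spec, toy_atlas, bad)


class TestGenerateCohort:
    BASE = dict(shape=(20, 20, 20), spacing_um=(20.0, 20.0, 20.0), object_rate=2500.0)

    def test_sample_bookkeeping(self, toy_atlas):
        cohort = CohortSpec(base=PhantomSpec(**self.BASE), n_per_group=3, seed=1)
        samples = generate_cohort(cohort, toy_atlas, render=False)
        assert len(samples) == 6
        groups = [g for _, _, g in samples]
        assert groups.count("control") == 3 and groups.count("treated") == 3

    def test_unknown_effect_region_rejected(self, toy_atlas):
        cohort = CohortSpec(base=PhantomSpec(**self.BASE),
                            effect_map={99: (0.5, 1.0)}, seed=0)
        with pytest.raises(ValueError, match="unknown region"):
            generate_cohort(cohort, toy_atlas, render=False)

    def test_rate_thinning_is_region_specific(self, toy_atlas):
        """Treated/control count ratio ~0.5 in the thinned region, ~1 elsewhere."""
        treated = {r: 0 for r in (1, 2, 3, 4)}
        control = {r: 0 for r in (1, 2, 3, 4)}
        for draw in range(100):
            cohort = CohortSpec(
                base=PhantomSpec(**self.BASE), n_per_group=2,
                effect_map={1: (0.5, 1.0)}, seed=draw,
            )
            for _, truth, group in generate_cohort(cohort, toy_atlas, render=False):
                bucket = treated if group == "treated" else control
                for rid in truth.region_ids():
                    bucket[rid] += 1
        ratio_a = treated[1] / control[1]
        se_a = ratio_a * np.sqrt(1 / treated[1] + 1 / control[1])
        assert abs(ratio_a - 0.5) <= 3 * se_a
        other_t = sum(treated[r] for r in (2, 3, 4))
        other_c = sum(control[r] for r in (2, 3, 4))
        ratio_o = other_t / other_c
        se_o = ratio_o * np.sqrt(1 / other_t + 1 / other_c)
        assert abs(ratio_o - 1.0) <= 3 * se_o

    def test_null_cohort_arms_are_exchangeable(self, toy_atlas):
        """With an empty effect map the arms are exchangeable: the t-test on
        total counts rejects at ~the nominal 5% rate (3-sigma binomial band)."""
        n_draws = 200
        rejections = 0
        for draw in range(n_draws):
            cohort = CohortSpec(base=PhantomSpec(**self.BASE), n_per_group=3,
                                effect_map={}, seed=1000 + draw)
            totals = {"control": [], "treated": []}
            for _, truth, group in generate_cohort(cohort, toy_atlas, render=False):
                totals[group].append(len(truth))
            _, p = sps.ttest_ind(totals["treated"], totals["control"])
            rejections += p < 0.05
        bound = 0.05 * n_draws + 3 * np.sqrt(n_draws * 0.05 * 0.95)
        assert rejections <= bound

    def test_size_multiplier_scales_radii(self, toy_atlas):
        cohort = CohortSpec(
            base=PhantomSpec(**self.BASE), n_per_group=2,
            effect_map={2: (1.0, 0.7)}, seed=3,
        )
        radii = {"control": [], "treated": []}
        for _, truth, group in generate_cohort(cohort, toy_atlas, render=False):
            for obj in truth.objects:
                if obj.region_id == 2:
                    radii[group].append(obj.radius_um)
        assert np.mean(radii["treated"]) < 0.85 * np.mean(radii["control"])
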