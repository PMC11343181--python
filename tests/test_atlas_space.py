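"""Atlas binning, spherical-ROI smoothing and regional aggregation."""

import numpy as np
import pandas as pd
import pytest

from oracle_utils import bin_and_transform_oracle, roi_sum_bruteforce, sphere_offsets
from q3d import (
    AffineTransform,
    AtlasGrid,
    LabelAtlas,
    bin_centers,
    generate_toy_atlas,
    microglia_volume_grid,
    regional_table,
    smooth_spherical,
)
from q3d.segmentation import BinaryMask, DetectedObject, ObjectSet

SPACING = (3.26, 3.26, 3.0)


def make_objects(centers, spacing=SPACING, volumes=None):
    objs = []
    for i, c in enumerate(centers):
        vol = volumes[i] if volumes is not None else 100.0
        objs.append(DetectedObject(i + 1, tuple(c), 10, float(vol), 3.0))
    return ObjectSet(objs, spacing)


def random_invertible_affine(rng, scale=1.0):
    while True:
        m = np.eye(3) * scale + rng.normal(0, 0.1, size=(3, 3))
        if abs(np.linalg.det(m)) > 0.1:
            return AffineTransform(m, rng.normal(0, 2, size=3))


@pytest.fixture(scope="module")
def atlas16():
    return generate_toy_atlas((16, 16, 16), 3, seed=0)


class TestBinCenters:
    def test_single_object_at_origin(self, atlas16):
        objects = make_objects([(0.0, 0.0, 0.0)])
        counts, sizes, dropped = bin_centers(objects, atlas16, AffineTransform.identity())
        assert dropped == 0
        assert counts.values.sum() == 1
        assert counts.values[0, 0, 0] == 1
        assert sizes.values[0, 0, 0] == pytest.approx(100.0)

    def test_count_conservation_under_random_affines(self, atlas16, rng):
        for _ in range(10):
            centers = rng.uniform(0, 200, size=(200, 3))
            objects = make_objects(centers)
            transform = random_invertible_affine(rng)
            counts, _, dropped = bin_centers(objects, atlas16, transform)
            assert counts.values.sum() + dropped == 200

    def test_matches_per_object_oracle(self, atlas16, rng):
        centers = rng.uniform(0, 130, size=(1000, 3))
        objects = make_objects(centers)
        transform = random_invertible_affine(rng)
        counts, _, dropped = bin_centers(objects, atlas16, transform)
        exp_counts, exp_dropped, _ = bin_and_transform_oracle(
            centers, SPACING, atlas16.spacing_um,
            transform.matrix.tolist(), transform.offset.tolist(), atlas16.shape,
        )
        np.testing.assert_array_equal(counts.values, exp_counts)
        assert dropped == exp_dropped

    def test_mean_size_is_mean_of_bin_members(self, atlas16):
        # two objects in the same 25 µm bin, one elsewhere
        centers = [(0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (40.0, 40.0, 40.0)]
        objects = make_objects(centers, spacing=(10.0, 10.0, 10.0),
                               volumes=[100.0, 300.0, 50.0])
        counts, sizes, _ = bin_centers(objects, atlas16, AffineTransform.identity())
        assert counts.values[0, 0, 0] == 2
        assert sizes.values[0, 0, 0] == pytest.approx(200.0)
        assert sizes.values[counts.values == 0].max() == 0.0

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.zeros((3, 3)), np.zeros(3))


class TestMicrogliaVolumeGrid:
    def test_conservation_of_foreground_volume(self, atlas16):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels[2:5, 2:5, 2:5] = 1  # 27 voxels
        objects = ObjectSet([], SPACING, labels=labels)
        grid, dropped = microglia_volume_grid(objects, atlas16, AffineTransform.identity())
        voxel_volume = 3.26 * 3.26 * 3.0
        assert dropped == 0
        assert grid.values.sum() == pytest.approx(27 * voxel_volume, rel=1e-9)

    def test_empty_set_gives_zero_grid(self, atlas16):
        objects = ObjectSet([], SPACING, labels=np.zeros((8, 8, 8), dtype=np.int32))
        grid, dropped = microglia_volume_grid(objects, atlas16, AffineTransform.identity())
        assert not grid.values.any() and dropped == 0

    def test_matches_per_voxel_oracle(self, atlas16, rng):
        mask = rng.uniform(size=(24, 24, 24)) < 0.1
        transform = random_invertible_affine(rng)
        grid, dropped = microglia_volume_grid(
            BinaryMask(mask, SPACING), atlas16, transform
        )
        coords = np.argwhere(mask).astype(float)
        exp_counts, exp_dropped, _ = bin_and_transform_oracle(
            coords, SPACING, atlas16.spacing_um,
            transform.matrix.tolist(), transform.offset.tolist(), atlas16.shape,
        )
        voxel_volume = 3.26 * 3.26 * 3.0
        np.testing.assert_allclose(grid.values, exp_counts * voxel_volume, rtol=1e-12)
        assert dropped == exp_dropped


class TestSmoothSpherical:
    def test_zero_grid_stays_zero(self):
        grid = AtlasGrid(np.zeros((16, 16, 16)), "plaque_count")
        out = smooth_spherical(grid, 15, "sum")
        assert not out.values.any()

    def test_reports_physical_roi_diameter(self):
        grid = AtlasGrid(np.zeros((8, 8, 8)), "plaque_count", spacing_um=25.0)
        out = smooth_spherical(grid, 15, "sum")
        assert out.smoothed and out.roi_diameter_vox == 15
        assert out.roi_diameter_um == pytest.approx(375.0)

    def test_single_count_spreads_over_exact_sphere(self):
        values = np.zeros((31, 31, 31))
        values[15, 15, 15] = 1.0
        out = smooth_spherical(AtlasGrid(values, "plaque_count"), 15, "sum")
        offsets = sphere_offsets(15)
        expected = np.zeros_like(values)
        for dx, dy, dz in offsets:
            expected[15 + dx, 15 + dy, 15 + dz] = 1.0
        np.testing.assert_array_equal(out.values, expected)
        assert out.values.sum() == len(offsets)

    def test_matches_bruteforce_roi_sum(self, rng):
        values = rng.integers(0, 5, size=(32, 32, 32)).astype(float)
        out = smooth_spherical(AtlasGrid(values, "plaque_count"), 15, "sum")
        expected = roi_sum_bruteforce(values, 15)
        np.testing.assert_array_equal(out.values, expected)

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_spherical(AtlasGrid(np.zeros((8, 8, 8)), "q"), 14, "sum")

    def test_sum_mode_is_linear(self, rng):
        g1 = rng.uniform(size=(16, 16, 16))
        g2 = rng.uniform(size=(16, 16, 16))
        a, b = 2.0, 3.0
        lhs = smooth_spherical(AtlasGrid(a * g1 + b * g2, "q"), 7, "sum").values
        rhs = a * smooth_spherical(AtlasGrid(g1, "q"), 7, "sum").values + \
            b * smooth_spherical(AtlasGrid(g2, "q"), 7, "sum").values
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-12)

    def test_mean_size_mode_weights_by_counts(self, rng):
        counts = rng.integers(0, 3, size=(20, 20, 20)).astype(float)
        sizes = np.where(counts > 0, rng.uniform(50, 150, size=(20, 20, 20)), 0.0)
        out = smooth_spherical(
            AtlasGrid(sizes, "plaque_mean_size_um3"), 7, "mean_size",
            counts=AtlasGrid(counts, "plaque_count"),
        )
        num = roi_sum_bruteforce(sizes * counts, 7)
        den = roi_sum_bruteforce(counts, 7)
        expected = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        np.testing.assert_allclose(out.values, expected, rtol=1e-10, atol=1e-12)


class TestRegionalTable:
    def _two_region_atlas(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[:4, :, :] = 1
        labels[4:, :, :] = 2
        regions = pd.DataFrame({"id": [1, 2], "name": ["front", "back"]})
        return LabelAtlas(labels, 25.0, regions)

    def test_hand_computed_sums(self):
        atlas = self._two_region_atlas()
        values = np.zeros((8, 8, 8))
        values[0, 0, 0] = 5.0
        values[7, 7, 7] = 2.0
        values[1, 1, 1] = 1.0
        table = regional_table(AtlasGrid(values, "q"), atlas)
        assert table.loc[table.region_id == 1, "sum"].iloc[0] == 6.0
        assert table.loc[table.region_id == 2, "sum"].iloc[0] == 2.0
        assert (table["n_voxels"] == 256).all()

    def test_partition_conservation(self, atlas16, rng):
        values = rng.uniform(size=atlas16.shape)
        table = regional_table(AtlasGrid(values, "q"), atlas16)
        assert table["sum"].sum() == pytest.approx(values[atlas16.labels > 0].sum())

    def test_mask_restricts_to_intersection(self):
        atlas = self._two_region_atlas()
        rng = np.random.default_rng(5)
        values = rng.uniform(size=(8, 8, 8))
        mask = np.zeros((8, 8, 8), dtype=np.int8)
        mask[:2, :, :] = -1  # half of region 1 flagged
        table = regional_table(AtlasGrid(values, "q"), atlas, mask=mask)
        expected = values[(atlas.labels == 1) & (mask != 0)].sum()
        assert table.loc[table.region_id == 1, "sum"].iloc[0] == pytest.approx(expected)
        assert table.loc[table.region_id == 2, "sum"].iloc[0] == 0.0

    def test_shape_mismatch_rejected(self, atlas16):
        with pytest.raises(ValueError, match="shape"):
            regional_table(AtlasGrid(np.zeros((4, 4, 4)), "q"), atlas16)


class TestTransformRoundTrip:
    def test_inverse_recovers_interior_bins(self, rng):
        transform = random_invertible_affine(rng)
        bins = rng.integers(0, 10, size=(50, 3)).astype(float)
        back = transform.inverse().apply(transform.apply(bins))
        np.testing.assert_allclose(back, bins, atol=1e-9)
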