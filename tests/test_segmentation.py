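import numpy as np
import pytest

from glioscan.imaging_io import GrayImage
from glioscan.segmentation import (
    RegionGrowParams,
    SeedSet,
    StructuringElement,
    auto_seed,
    clean_mask,
    cross_se,
    dilate,
    erode,
    grow_region,
    region_area,
    square_se,
)
from oracles import bf_dilate, bf_erode, bf_flood_fill


def gray(arr):
    return GrayImage(np.asarray(arr, dtype=np.uint8))


class TestGrowRegion:
    def test_constant_image_fills_everything(self):
        img = gray(np.full((6, 6), 77))
        mask = grow_region(img, [(3, 3)], RegionGrowParams(delta=0))
        assert mask.all()

    def test_stops_at_contrast_edge(self):
        img = gray([[10, 10, 50], [10, 10, 50], [10, 10, 50]])
        mask = grow_region(img, [(0, 0)], RegionGrowParams(delta=5, connectivity=4))
        expected = np.zeros((3, 3), dtype=bool)
        expected[:, :2] = True
        np.testing.assert_array_equal(mask, expected)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_fixed_mean_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(20):
            arr = (rng.integers(0, 8, size=(32, 32)) * 36).astype(np.uint8)
            img = gray(arr)
            seed = np.unravel_index(np.argmax(arr), arr.shape)
            params = RegionGrowParams(
                delta=36.0, connectivity=connectivity, mean_mode="fixed"
            )
            mask = grow_region(img, [tuple(int(x) for x in seed)], params)
            oracle = bf_flood_fill(arr, tuple(int(x) for x in seed), 36.0, connectivity)
            np.testing.assert_array_equal(mask, oracle)

    def test_seed_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            grow_region(gray(np.zeros((4, 4))), [(4, 0)])

    def test_output_contains_seeds_and_is_connected(self, random_image):
        from scipy import ndimage

        seeds = [(5, 5), (5, 6)]
        mask = grow_region(random_image, seeds, RegionGrowParams(delta=300))
        assert all(mask[s] for s in seeds)
        _, n = ndimage.label(mask)
        assert n == 1  # delta=inf-like: the full connected image

    def test_running_mean_is_deterministic(self, random_image):
        params = RegionGrowParams(delta=40, mean_mode="running")
        a = grow_region(random_image, [(16, 16)], params)
        b = grow_region(random_image, [(16, 16)], params)
        np.testing.assert_array_equal(a, b)


class TestMorphology:
    def test_single_pixel_dilates_to_block(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        out = dilate(mask, square_se(3))
        assert out.sum() == 9 and out[1:4, 1:4].all()

    def test_all_false_stays_false(self):
        mask = np.zeros((4, 4), dtype=bool)
        assert not dilate(mask, square_se(3)).any()
        assert not erode(mask, square_se(3)).any()

    def test_block_erodes_to_center(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        out = erode(mask, square_se(3))
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = True
        np.testing.assert_array_equal(out, expected)

    def test_all_true_erodes_to_interior(self):
        mask = np.ones((5, 5), dtype=bool)
        out = erode(mask, square_se(3))
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:4, 1:4] = True  # border false: outside the image is false
        np.testing.assert_array_equal(out, expected)

    @pytest.mark.parametrize("se_factory", [square_se, cross_se])
    def test_matches_brute_force_oracles(self, rng, se_factory):
        se = se_factory(3)
        for _ in range(10):
            mask = rng.random((16, 16)) < 0.4
            np.testing.assert_array_equal(
                dilate(mask, se), bf_dilate(mask, se.footprint, se.origin)
            )
            np.testing.assert_array_equal(
                erode(mask, se), bf_erode(mask, se.footprint, se.origin)
            )

    def test_duality_erode_is_complement_dilate_complement(self, rng):
        # on a padded domain so the outside-false convention cancels out
        se = cross_se(3)
        for _ in range(50):
            mask = rng.random((12, 12)) < 0.5
            padded = np.pad(mask, 2, constant_values=True)
            left = erode(padded, se)
            right = ~dilate(~padded, se)  # cross is symmetric = its reflection
            np.testing.assert_array_equal(left[2:-2, 2:-2], right[2:-2, 2:-2])

    def test_dilate_grows_and_erode_shrinks_area(self, rng):
        se = square_se(3)
        mask = rng.random((20, 20)) < 0.3
        assert region_area(dilate(mask, se)) >= region_area(mask)
        assert region_area(erode(mask, se)) <= region_area(mask)

    def test_asymmetric_footprint_with_offset_origin(self, rng):
        fp = np.array([[1, 1, 0], [0, 1, 0]], dtype=bool)
        se = StructuringElement(fp, (0, 1))
        mask = rng.random((10, 10)) < 0.5
        np.testing.assert_array_equal(dilate(mask, se), bf_dilate(mask, fp, (0, 1)))
        np.testing.assert_array_equal(erode(mask, se), bf_erode(mask, fp, (0, 1)))

    def test_origin_must_be_true_cell(self):
        with pytest.raises(ValueError):
            StructuringElement(np.array([[True, False]]), (0, 1))


class TestCleanMask:
    def test_opening_removes_speckle_keeps_block(self):
        mask = np.zeros((15, 15), dtype=bool)
        mask[2:12, 2:12] = True
        mask[13, 13] = True  # isolated pixel
        out = clean_mask(mask, square_se(3), min_component_px=5)
        assert out[2:12, 2:12].all() and not out[13, 13]

    def test_all_false_passes_through(self):
        assert not clean_mask(np.zeros((8, 8), dtype=bool)).any()

    def test_small_component_filtered_largest_kept(self):
        # blobs of 40 px and 12 px survive opening with min 20 -> 40 only
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:9, 1:6] = True  # 40 px
        mask[12:16, 12:15] = True  # 12 px
        out = clean_mask(mask, square_se(1), min_component_px=20)
        assert out[1:9, 1:6].all() and not out[12:16, 12:15].any()
        assert region_area(out) == 40

    def test_opening_is_idempotent(self, rng):
        se = square_se(3)
        for _ in range(10):
            mask = rng.random((24, 24)) < 0.55
            once = clean_mask(mask, se, 10)
            twice = clean_mask(once, se, 10)
            np.testing.assert_array_equal(once, twice)


class TestRegionAreaAndSeeding:
    def test_area_counts_true_cells(self, rng):
        assert region_area(np.zeros((256, 256), dtype=bool)) == 0
        rect = np.zeros((8, 8), dtype=bool)
        rect[1:4, 2:6] = True
        assert region_area(rect) == 12
        mask = rng.random((13, 7)) < 0.5
        assert region_area(mask) == sum(
            bool(mask[r, c]) for r in range(13) for c in range(7)
        )

    def test_auto_seed_lands_on_bright_region(self):
        arr = np.full((32, 32), 20, dtype=np.uint8)
        arr[10:15, 20:25] = 240
        seed = auto_seed(gray(arr)).points[0]
        assert arr[seed] == 240

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            SeedSet([])
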