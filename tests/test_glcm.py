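import math

import numpy as np
import pytest

from glioscan.glcm import (
    FEATURE_ORDER,
    contrast,
    cooc_matrix,
    correlation,
    energy,
    entropy,
    feature_vector,
    glcm_features,
    homogeneity,
    quantize,
)
from oracles import bf_features, bf_glcm_counts

# the 4x4 worked example used throughout: its symmetric horizontal GLCM
# has 24 counts with known cell values
WORKED = np.array(
    [
        [0, 0, 1, 1],
        [0, 0, 1, 1],
        [0, 2, 2, 2],
        [2, 2, 3, 3],
    ]
)


@pytest.fixture
def worked_matrix():
    return cooc_matrix(WORKED, S=1, angle=0, symmetric=True)


class TestQuantize:
    def test_constant_maps_to_zero(self):
        assert not quantize(np.full((4, 4), 3.7), 8).any()

    def test_8bit_range_matches_bin_edges(self):
        v = np.arange(256).reshape(16, 16)
        q = quantize(v, 8)
        np.testing.assert_array_equal(q, np.minimum(v // 32, 7))

    def test_equally_spaced_values_relabel_identically(self):
        arr = np.array([[0.0, 2.5, 5.0, 7.5]] * 2)
        np.testing.assert_array_equal(quantize(arr, 4), [[0, 1, 2, 3]] * 2)

    def test_g_below_two_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((2, 2)), 1)


class TestCoocMatrix:
    def test_worked_example_counts(self, worked_matrix):
        counts = worked_matrix.counts
        assert counts.sum() == 24
        expected = {
            (0, 0): 4, (0, 1): 2, (1, 0): 2, (1, 1): 4, (0, 2): 1,
            (2, 0): 1, (2, 2): 6, (2, 3): 1, (3, 2): 1, (3, 3): 2,
        }
        for (p, q), n in expected.items():
            assert counts[p, q] == n
        assert counts.sum() == sum(expected.values())

    def test_constant_image_single_cell(self):
        for angle in (0, 45, 90, 135):
            M = cooc_matrix(np.zeros((3, 3), dtype=int), S=1, angle=angle)
            assert M.probs[0, 0] == 1.0

    def test_normalization_and_symmetry(self, rng):
        q = rng.integers(0, 8, size=(16, 16))
        for angle in (0, 45, 90, 135):
            M = cooc_matrix(q, S=1, angle=angle, symmetric=True)
            assert M.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert (M.probs >= 0).all()
            np.testing.assert_array_equal(M.counts, M.counts.T)

    def test_asymmetric_counts_one_direction_only(self):
        M = cooc_matrix(WORKED, S=1, angle=0, symmetric=False)
        assert M.counts.sum() == 12  # 4 rows x 3 horizontal pairs

    def test_image_too_small_for_offset(self):
        with pytest.raises(ValueError):
            cooc_matrix(np.zeros((2, 2), dtype=int), S=5, angle=0)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_counts_match_pair_enumeration_oracle(self, rng, angle, symmetric):
        q = rng.integers(0, 8, size=(16, 16))
        M = cooc_matrix(q, S=1, angle=angle, symmetric=symmetric)
        np.testing.assert_array_equal(M.counts, bf_glcm_counts(q, 1, angle, symmetric))

    def test_matches_skimage_reference(self, rng):
        # independent library cross-check of the counting convention
        from skimage.feature import graycomatrix

        q = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        # skimage offsets are (+sin, +cos): its pi/4 is the down-right
        # diagonal, i.e. the reverse of our up-left 135 degree offset —
        # identical under symmetric counting (and vice versa for 3*pi/4)
        for angle_deg, angle_rad in [(0, 0), (135, np.pi / 4), (90, np.pi / 2), (45, 3 * np.pi / 4)]:
            ours = cooc_matrix(q, S=1, angle=angle_deg, symmetric=True).counts
            ref = graycomatrix(q, [1], [angle_rad], levels=8, symmetric=True)[:, :, 0, 0]
            np.testing.assert_array_equal(ours, ref)


class TestFeatures:
    def test_worked_example_values(self, worked_matrix):
        assert contrast(worked_matrix) == pytest.approx(14 / 24)
        assert homogeneity(worked_matrix) == pytest.approx(19.4 / 24)
        assert energy(worked_matrix) == pytest.approx(math.sqrt(84 / 576))
        assert entropy(worked_matrix) == pytest.approx(3.022, abs=5e-4)
        ref = bf_features(worked_matrix.probs)
        assert correlation(worked_matrix) == pytest.approx(ref["COR"], abs=1e-12)

    def test_constant_image_feature_identities(self):
        M = cooc_matrix(np.zeros((3, 3), dtype=int), S=1, angle=0)
        assert contrast(M) == 0.0
        assert energy(M) == 1.0
        assert homogeneity(M) == 1.0
        assert entropy(M) == 0.0
        assert math.isnan(correlation(M))

    def test_checkerboard_extremes(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        M = cooc_matrix(board, S=1, angle=0, symmetric=True)
        assert contrast(M) == pytest.approx(1.0)  # all mass at |p-q| = 1
        assert homogeneity(M) == pytest.approx(0.5)

    def test_uniform_matrix_closed_forms(self):
        k = 16
        probs = np.full((4, 4), 1 / k)
        assert energy(probs) == pytest.approx(math.sqrt(1 / k))
        assert entropy(probs) == pytest.approx(math.log2(k))

    def test_perfect_diagonal_correlation_is_one(self):
        G = 5
        probs = np.eye(G) / G
        assert correlation(probs) == pytest.approx(1.0)

    def test_all_features_match_oracle_on_random_images(self, rng):
        for _ in range(50):
            q = rng.integers(0, 8, size=(16, 16))
            for angle in (0, 45, 90, 135):
                M = cooc_matrix(q, S=1, angle=angle, symmetric=True)
                ref = bf_features(M.probs)
                got = glcm_features(M)
                for name in FEATURE_ORDER:
                    if math.isnan(ref[name]):
                        assert math.isnan(got[name])
                    else:
                        assert got[name] == pytest.approx(ref[name], abs=1e-10)


class TestFeatureVector:
    def test_constant_subband_composition(self):
        out = feature_vector([(1, "LL", np.full((8, 8), 5.0))], G=8)
        assert out[(1, "LL", "CON")] == 0.0
        assert out[(1, "LL", "COR")] == 0.0  # NaN sentinel mapped to 0
        assert out[(1, "LL", "ENE")] == 1.0
        assert out[(1, "LL", "HOM")] == 1.0
        assert out[(1, "LL", "ENT")] == 0.0

    def test_two_subbands_ordering(self, rng):
        subs = [(2, "HL", rng.random((8, 8))), (1, "LL", rng.random((8, 8)))]
        out = feature_vector(subs, G=4)
        assert len(out) == 10
        keys = list(out)
        assert keys[:5] == [(1, "LL", f) for f in FEATURE_ORDER]
        assert keys[5:] == [(2, "HL", f) for f in FEATURE_ORDER]

    def test_mean_aggregation_over_angles(self, rng):
        arr = rng.random((32, 32))
        mean_out = feature_vector([(1, "LL", arr)], G=8, aggregate="mean")
        q = quantize(arr, 8)
        for name in FEATURE_ORDER:
            per_angle = []
            for angle in (0, 45, 90, 135):
                ref = bf_features(cooc_matrix(q, S=1, angle=angle).probs)[name]
                per_angle.append(0.0 if math.isnan(ref) else ref)
            assert mean_out[(1, "LL", name)] == pytest.approx(
                np.mean(per_angle), abs=1e-10
            )

    def test_shift_invariance_with_shifted_bins(self, rng):
        # adding a constant before quantization leaves all features
        # unchanged (bin edges shift equally because they are min/max based)
        arr = rng.random((16, 16)) * 100
        a = feature_vector([(1, "LL", arr)], G=8)
        b = feature_vector([(1, "LL", arr + 37.5)], G=8)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-10)

    def test_empty_subband_list_rejected(self):
        with pytest.raises(ValueError):
            feature_vector([], G=8)
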