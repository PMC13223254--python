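"""Mesh ternary descriptor: unit behaviour, worked values, and oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshtex.descriptor import (MeshScale, ThresholdParams, adaptive_threshold,
                                center_bounds, compute_pattern_images,
                                extract_features, feature_names,
                                lmtp_visualization, local_std_map,
                                mesh_neighbor_index, pattern_histogram,
                                sample_neighbors, ternary_encode)
from oracle_descriptor import oracle_features, oracle_pattern_images


class TestLocalStd:
    def test_constant_image_gives_zero(self):
        img = np.full((10, 10), 42, dtype=np.uint8)
        assert (local_std_map(img, 3) == 0).all()

    def test_single_bright_centre_worked_value(self):
        # 8 zeros + one 90: mean 10, var (8*100 + 6400)/9 = 800, sd = 28.284
        img = np.zeros((3, 3), dtype=np.uint8)
        img[1, 1] = 90
        sd = local_std_map(img, 3)
        assert sd.shape == (1, 1)
        assert sd[0, 0] == pytest.approx(math.sqrt(800), abs=1e-12)

    def test_shift_invariance_is_exact(self, random_image):
        img = np.clip(random_image, 0, 215)
        assert (local_std_map(img, 3) == local_std_map(img + 40, 3)).all()

    def test_even_window_rejected(self, random_image):
        with pytest.raises(ValueError, match="odd"):
            local_std_map(random_image, 4)


class TestAdaptiveThreshold:
    def test_worked_example(self):
        assert adaptive_threshold(20.0, ThresholdParams(0.2, 5)) == 9.0

    def test_flat_region_floors_at_beta(self):
        assert adaptive_threshold(0.0, ThresholdParams(0.2, 5)) == 5.0

    def test_direct_arithmetic(self):
        assert adaptive_threshold(10.0, ThresholdParams(0.1, 1)) == pytest.approx(2.0)

    def test_vectorized_over_sigma_map(self):
        out = adaptive_threshold(np.array([0.0, 20.0]), ThresholdParams(0.2, 5))
        assert np.allclose(out, [5.0, 9.0])

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            ThresholdParams(-0.1, 5)


class TestCenterBounds:
    @pytest.mark.parametrize("center,T,expected", [
        (72, 9, (81, 63)),       # the canonical worked example
        (100, 0, (100, 100)),
        (250, 9, (255, 241)),    # clamped at the top
        (4, 9, (13, 0)),         # clamped at the bottom
    ])
    def test_bounds(self, center, T, expected):
        assert center_bounds(center, T) == expected


class TestMeshIndex:
    @pytest.mark.parametrize("i,a,expected", [(1, 1, 2), (8, 1, 1), (1, 3, 4)])
    def test_worked_values(self, i, a, expected):
        assert mesh_neighbor_index(i, 8, a) == expected

    @given(st.integers(1, 8), st.integers(1, 7))
    @settings(derandomize=True)
    def test_partner_in_range_and_distinct(self, i, a):
        b = mesh_neighbor_index(i, 8, a)
        assert 1 <= b <= 8 and b != i

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            mesh_neighbor_index(0, 8, 1)
        with pytest.raises(ValueError):
            mesh_neighbor_index(9, 8, 1)


class TestSampleNeighbors:
    def test_r1_axis_positions_are_exact_reads(self, random_image):
        s = sample_neighbors(random_image, 5, 5, MeshScale(3))
        img = random_image.astype(float)
        # i=1,3,5,7 sit on the axes: east, north, west, south
        assert s[0] == img[5, 6] and s[2] == img[4, 5]
        assert s[4] == img[5, 4] and s[6] == img[6, 5]

    def test_constant_image_all_samples_equal(self):
        img = np.full((9, 9), 31, dtype=np.uint8)
        assert (sample_neighbors(img, 4, 4, MeshScale(7)) == 31).all()

    def test_r3_diagonal_on_linear_ramp(self):
        # on I(x, y) = x, the diagonal sample at x + 3*cos(45 deg) = x + 2.121
        img = np.tile(np.arange(16, dtype=np.uint8), (16, 1))
        s = sample_neighbors(img, 8, 8, MeshScale(7))
        assert s[1] == pytest.approx(8 + 3 * math.cos(math.pi / 4), abs=1e-9)

    def test_insufficient_support_rejected(self, random_image):
        with pytest.raises(ValueError, match="support"):
            sample_neighbors(random_image, 1, 1, MeshScale(7))


class TestTernaryEncode:
    @pytest.mark.parametrize("diff,T,code", [
        (15, 9, 1), (0, 9, 0), (-9, 9, -1),   # inclusive lower boundary
        (9, 9, 1), (8.999, 9, 0), (-8.999, 9, 0),
    ])
    def test_rule(self, diff, T, code):
        assert ternary_encode(diff, T) == code

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ternary_encode(1, -1)


class TestPatternImages:
    def test_constant_image_gives_all_zero_codes(self):
        img = np.full((12, 12), 99, dtype=np.uint8)
        for p in compute_pattern_images(img, MeshScale(3)):
            assert (p.codes == 0).all()

    def test_six_images_ordered_by_order_and_polarity(self, random_image):
        pats = compute_pattern_images(random_image, MeshScale(3))
        assert [(p.order, p.polarity) for p in pats] == [
            (1, "upper"), (1, "lower"), (2, "upper"),
            (2, "lower"), (3, "upper"), (3, "lower")]

    @pytest.mark.parametrize("window", [3, 7])
    def test_matches_per_pixel_oracle(self, rng, window):
        for _ in range(10):
            h, w = rng.integers(12, 21, 2)
            img = rng.integers(0, 256, (h, w), dtype=np.uint8)
            ref = oracle_pattern_images(img, window, 0.2, 5.0)
            for p in compute_pattern_images(img, MeshScale(window)):
                assert (p.codes == ref[(p.order, p.polarity)]).all()

    def test_upper_lower_bits_mutually_exclusive(self, rng):
        img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        for window in (3, 7):
            pats = compute_pattern_images(img, MeshScale(window))
            by = {(p.order, p.polarity): p.codes.astype(int) for p in pats}
            for a in (1, 2, 3):
                assert (by[(a, "upper")] & by[(a, "lower")]).max() == 0

    def test_raising_threshold_never_adds_codes(self, rng):
        img = rng.integers(0, 256, (20, 20), dtype=np.uint8)

        def nonzero_bits(params):
            total = 0
            for p in compute_pattern_images(img, MeshScale(3), params):
                total += np.unpackbits(p.codes).sum()
            return total

        base = nonzero_bits(ThresholdParams(0.2, 5))
        assert nonzero_bits(ThresholdParams(0.4, 5)) <= base
        assert nonzero_bits(ThresholdParams(0.2, 10)) <= base

    def test_undersized_image_rejected(self):
        with pytest.raises(ValueError):
            compute_pattern_images(np.zeros((4, 4), np.uint8), MeshScale(7))


class TestVisualization:
    def test_identical_inputs_pass_through(self, random_image):
        pats = compute_pattern_images(random_image, MeshScale(3))
        six = [pats[0]] * 6
        assert (lmtp_visualization(six) == pats[0].codes).all()

    def test_mean_then_round(self):
        pats = compute_pattern_images(np.full((12, 12), 7, np.uint8), MeshScale(3))
        # all-zero codes average to zero
        assert (lmtp_visualization(pats) == 0).all()


class TestHistogram:
    def test_all_zero_pattern_concentrates_at_bin_zero(self):
        pats = compute_pattern_images(np.full((12, 12), 50, np.uint8), MeshScale(3))
        h = pattern_histogram(pats[0])
        assert h[0] == 1.0 and h[1:].sum() == 0.0

    def test_counting_example(self):
        from meshtex.descriptor import PatternImage
        p = PatternImage(np.array([[3, 3], [7, 255]], dtype=np.uint8),
                         1, "upper", MeshScale(3))
        h = pattern_histogram(p)
        assert h[3] == 0.5 and h[7] == 0.25 and h[255] == 0.25
        raw = pattern_histogram(p, normalize=False)
        assert raw[3] == 2 and raw.sum() == 4

    def test_sums_to_one(self, random_image):
        for p in compute_pattern_images(random_image, MeshScale(3)):
            assert pattern_histogram(p).sum() == pytest.approx(1.0, abs=1e-9)


class TestExtractFeatures:
    def test_geometry_3072_and_unit_blocks(self, random_image):
        f = extract_features(random_image)
        assert f.shape == (3072,)
        for b in range(12):
            assert f[b * 256:(b + 1) * 256].sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_image_all_mass_at_bin_zero(self):
        f = extract_features(np.full((16, 16), 200, np.uint8))
        blocks = f.reshape(12, 256)
        assert (blocks[:, 0] == 1.0).all() and blocks[:, 1:].sum() == 0.0

    def test_additive_shift_invariance_exact(self, rng):
        img = rng.integers(0, 216, (18, 18), dtype=np.uint8)
        assert (extract_features(img) == extract_features(img + 40)).all()

    def test_matches_full_oracle(self, rng):
        img = rng.integers(0, 256, (14, 14), dtype=np.uint8)
        assert (extract_features(img) == oracle_features(img)).all()

    def test_deterministic_across_runs(self, random_image):
        assert (extract_features(random_image) ==
                extract_features(random_image.copy())).all()

    def test_feature_names_match_layout(self):
        names = feature_names()
        assert len(names) == 3072
        assert names[0] == "a1_up_s3_b000"
        assert names[256] == "a1_up_s7_b000"
        assert names[512] == "a1_low_s3_b000"
        assert names[-1] == "a3_low_s7_b255"

    def test_undersized_image_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((6, 6), np.uint8))
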