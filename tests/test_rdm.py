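"""RDM constructions against brute-force oracles and known geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strsa
from strsa import (
    RDM,
    ConvLayerSpec,
    ROIPatterns,
    binary_category_rdm,
    conv_output_shape,
    correlation_distance_rdm,
    devectorize_rdm,
    euclidean_rdm,
    extract_conv_features,
    motion_energy_vector,
    rating_difference_rdm,
    similarity_inversion_rdm,
    vectorize_rdm,
)

from conftest import random_rdm


# ---------------------------------------------------------------------------
# Convolutional geometry
# ---------------------------------------------------------------------------

class TestConvGeometry:
    def test_alexnet_conv1_output_shape(self):
        """A 640x360 frame through the 11x11/stride-4/pad-2 64-kernel layer."""
        spec = ConvLayerSpec(kernel=11, stride=4, padding=2, n_kernels=64)
        assert conv_output_shape(360, 640, spec) == (89, 159, 64)

    def test_kernel_equals_input(self):
        spec = ConvLayerSpec(kernel=11, stride=1, padding=0, n_kernels=5)
        assert conv_output_shape(11, 11, spec) == (1, 1, 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_placement_count(self, seed):
        """Output dims equal a brute-force count of valid kernel placements."""
        r = np.random.default_rng(seed)
        k, s, p = int(r.integers(1, 6)), int(r.integers(1, 4)), int(r.integers(0, 3))
        h, w = int(r.integers(k + 1, 20)), int(r.integers(k + 1, 20))
        spec = ConvLayerSpec(kernel=k, stride=s, padding=p)

        def count(n):
            placements = 0
            pos = 0
            while pos + k <= n + 2 * p:
                placements += 1
                pos += s
            return placements

        oh, ow, _ = conv_output_shape(h, w, spec)
        assert (oh, ow) == (count(h), count(w))

    def test_input_too_small(self):
        with pytest.raises(ValueError):
            conv_output_shape(3, 3, ConvLayerSpec(kernel=11))


class TestConvFeatures:
    def brute_force_conv(self, img, w, spec):
        c, h, wd = img.shape
        padded = np.pad(img, ((0, 0), (spec.padding,) * 2, (spec.padding,) * 2))
        oh, ow, _ = conv_output_shape(h, wd, spec)
        out = np.zeros((spec.n_kernels, oh, ow))
        for n in range(spec.n_kernels):
            for i in range(oh):
                for j in range(ow):
                    patch = padded[
                        :,
                        i * spec.stride : i * spec.stride + spec.kernel,
                        j * spec.stride : j * spec.stride + spec.kernel,
                    ]
                    out[n, i, j] = (patch * w[n]).sum()
        return out.ravel()

    def test_zero_image_zero_bias_gives_zero_features(self, rng):
        spec = ConvLayerSpec(kernel=3, stride=2, padding=1, n_kernels=4)
        w = rng.standard_normal((4, 1, 3, 3))
        feats = extract_conv_features(np.zeros((10, 12)), spec, w)
        assert np.all(feats == 0.0)

    def test_identity_kernel_reproduces_subsampled_image(self, rng):
        """A single kernel with one central 1 returns the strided image."""
        img = rng.random((9, 9))
        spec = ConvLayerSpec(kernel=1, stride=2, padding=0, n_kernels=1)
        w = np.ones((1, 1, 1, 1))
        feats = extract_conv_features(img, spec, w, relu=False)
        assert np.allclose(feats, img[::2, ::2].ravel())

    def test_matches_brute_force_convolution(self, rng):
        spec = ConvLayerSpec(kernel=3, stride=2, padding=1, n_kernels=3)
        img = rng.standard_normal((2, 8, 11))
        w = rng.standard_normal((3, 2, 3, 3))
        got = extract_conv_features(img, spec, w, relu=False)
        expected = self.brute_force_conv(img, w, spec)
        assert np.allclose(got, expected, atol=1e-5)

    def test_shape_mismatch_raises(self, rng):
        spec = ConvLayerSpec(kernel=3, n_kernels=2)
        with pytest.raises(ValueError):
            extract_conv_features(np.zeros((5, 5)), spec, np.zeros((2, 4, 4)))


class TestMotionEnergy:
    def test_uniform_unit_flow(self):
        flow = np.zeros((1, 10, 10, 2))
        flow[..., 0] = 1.0
        assert motion_energy_vector(flow) == pytest.approx([100.0])

    def test_zero_flow(self):
        assert np.all(motion_energy_vector(np.zeros((3, 4, 4, 2))) == 0.0)

    def test_13_frame_video_gives_length_13(self, rng):
        flow = rng.standard_normal((13, 6, 8, 2))
        assert motion_energy_vector(flow).shape == (13,)

    def test_magnitudes_do_not_cancel(self):
        """Opposing flow vectors still contribute energy."""
        flow = np.zeros((1, 2, 1, 2))
        flow[0, 0, 0, 0] = 1.0
        flow[0, 1, 0, 0] = -1.0
        assert motion_energy_vector(flow) == pytest.approx([2.0])


# ---------------------------------------------------------------------------
# Distance constructions
# ---------------------------------------------------------------------------

class TestEuclideanRDM:
    def test_3_4_5_triangle(self):
        r = euclidean_rdm(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert r.matrix[0, 1] == pytest.approx(5.0)

    def test_identical_vectors(self):
        r = euclidean_rdm(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert r.matrix[0, 1] == 0.0

    def test_matches_double_loop(self, rng):
        x = rng.standard_normal((20, 8))
        r = euclidean_rdm(x)
        for i in range(20):
            for j in range(20):
                assert r.matrix[i, j] == pytest.approx(
                    np.linalg.norm(x[i] - x[j]), abs=1e-10
                )

    def test_triangle_inequality(self, rng):
        x = rng.standard_normal((10, 4))
        m = euclidean_rdm(x).matrix
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-10


class TestCategoryAndRatingRDMs:
    def test_binary_category_example(self):
        r = binary_category_rdm(["social", "social", "nonsocial"])
        assert r.matrix[0, 1] == 0.0
        assert r.matrix[0, 2] == 1.0 and r.matrix[1, 2] == 1.0

    def test_single_category_all_zero(self):
        assert np.all(binary_category_rdm(["x"] * 5).matrix == 0.0)

    def test_39_social_36_nonsocial_pair_count(self):
        """39 x 36 cross-category pairs are at distance 1."""
        labels = ["social"] * 39 + ["nonsocial"] * 36
        v = vectorize_rdm(binary_category_rdm(labels))
        assert int(v.sum()) == 39 * 36 == 1404

    def test_rating_difference_examples(self):
        r = rating_difference_rdm([2.0, 5.0])
        assert r.matrix[0, 1] == 3.0
        assert rating_difference_rdm([4.0, 4.0]).matrix[0, 1] == 0.0

    def test_rating_triangle_inequality(self, rng):
        m = rating_difference_rdm(rng.standard_normal(12)).matrix
        n = m.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-12

    def test_binary_equals_rating_on_01_codes(self):
        """Cross-construction consistency on a two-level feature."""
        labels = ["a", "b", "a", "b", "b"]
        codes = [0.0 if lab == "a" else 1.0 for lab in labels]
        assert np.array_equal(
            binary_category_rdm(labels).matrix,
            rating_difference_rdm(codes).matrix,
        )

    def test_nonfinite_rating_raises(self):
        with pytest.raises(ValueError):
            rating_difference_rdm([1.0, np.nan])


class TestSimilarityInversion:
    def make_judgments(self, pairs_scores):
        import pandas as pd

        rows = []
        for (i, j), scores in pairs_scores.items():
            for r, s in enumerate(scores):
                rows.append({"cond_i": i, "cond_j": j, "rater": r, "score": s})
        return pd.DataFrame(rows)

    def test_identical_judged_7_gives_zero(self):
        df = self.make_judgments({(0, 1): [7, 7, 7]})
        r = similarity_inversion_rdm(df, condition_ids=[0, 1])
        assert r.matrix[0, 1] == 0.0

    def test_most_distinct_gives_6(self):
        df = self.make_judgments({(0, 1): [1, 1]})
        assert similarity_inversion_rdm(df).matrix[0, 1] == 6.0

    def test_two_raters_mean(self):
        df = self.make_judgments({(0, 1): [3, 5]})
        assert similarity_inversion_rdm(df).matrix[0, 1] == pytest.approx(3.0)

    def test_out_of_range_raises(self):
        df = self.make_judgments({(0, 1): [8]})
        with pytest.raises(ValueError):
            similarity_inversion_rdm(df)


class TestCorrelationDistance:
    def test_duplicated_conditions_distance_zero(self, rng):
        col = rng.standard_normal(10)
        pats = ROIPatterns("evc", np.column_stack([col, col, rng.standard_normal(10)]))
        assert correlation_distance_rdm(pats).matrix[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self, rng):
        col = rng.standard_normal(10)
        pats = ROIPatterns("evc", np.column_stack([col, -col, rng.standard_normal(10)]))
        assert correlation_distance_rdm(pats).matrix[0, 1] == pytest.approx(2.0)

    def test_matches_direct_pearson(self, rng):
        x = rng.standard_normal((50, 10))
        m = correlation_distance_rdm(ROIPatterns("roi", x)).matrix
        for i in range(10):
            for j in range(i + 1, 10):
                r = np.corrcoef(x[:, i], x[:, j])[0, 1]
                assert m[i, j] == pytest.approx(1.0 - r, abs=1e-10)

    def test_constant_pattern_raises(self):
        pats = ROIPatterns("roi", np.column_stack(
            [np.ones(5), np.arange(5.0), np.arange(5.0) ** 2]
        ))
        with pytest.raises(ValueError, match="correlation undefined"):
            correlation_distance_rdm(pats)


# ---------------------------------------------------------------------------
# Vectorization
# ---------------------------------------------------------------------------

class TestVectorize:
    def test_smallest_case_ordering(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        assert np.array_equal(vectorize_rdm(RDM(m)), [1.0, 2.0, 3.0])

    def test_75_conditions_gives_2775_pairs(self, rng):
        r = random_rdm(rng, 75)
        assert vectorize_rdm(r).shape == (2775,)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(n=st.integers(2, 12), seed=st.integers(0, 1000))
    def test_round_trip_identity(self, n, seed):
        r = random_rdm(np.random.default_rng(seed), n)
        back = devectorize_rdm(vectorize_rdm(r))
        assert np.allclose(back.matrix, r.matrix)

    def test_asymmetric_raises(self):
        with pytest.raises(ValueError):
            vectorize_rdm(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestRDMInvariants:
    @pytest.mark.parametrize("builder", [
        lambda rng: euclidean_rdm(rng.standard_normal((8, 3))),
        lambda rng: binary_category_rdm(list("aabbabab")),
        lambda rng: rating_difference_rdm(rng.standard_normal(8)),
        lambda rng: correlation_distance_rdm(
            ROIPatterns("r", rng.standard_normal((12, 8)))
        ),
    ])
    def test_symmetric_zero_diagonal_nonnegative(self, builder, rng):
        m = builder(rng).matrix
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0.0)
        assert np.all(m >= 0.0)
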