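"""Fusion neck: node equations, normalized fusion, resizing, stacking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lgfusion.autodiff import Tensor
from lgfusion.backbone import DimensionError, FeaturePyramid
from lgfusion.neck import (
    FuseLayer,
    Neck,
    NeckConfig,
    fast_normalized_fuse,
    resize_to,
)

from oracles import np_fast_fuse, np_fuse_layer

TINY = NeckConfig(num_layers=1, inner_channels=4, reduction_r=2, fusion_epsilon=1e-4)


def make_pyramid(rng, channels=4, base=8, batch=2):
    return FeaturePyramid(
        [Tensor(rng.standard_normal((batch, channels, s, s)))
         for s in (base, base // 2, base // 4, base // 8)]
    )


class TestFastNormalizedFusion:
    def test_equal_weights_of_identical_inputs_reproduce_input(self, rng):
        x = rng.standard_normal((1, 3, 2, 2))
        out = fast_normalized_fuse([Tensor(x), Tensor(x)], np.array([1.0, 1.0]), 0.0)
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_zero_weight_drops_an_input(self, rng):
        a, b = rng.standard_normal((1, 2, 2, 2)), rng.standard_normal((1, 2, 2, 2))
        out = fast_normalized_fuse([Tensor(a), Tensor(b)], np.array([2.0, 0.0]), 0.0)
        np.testing.assert_allclose(out.data, a, atol=1e-12)

    def test_three_inputs_match_direct_formula(self, rng):
        inputs = [rng.standard_normal((1, 1, 2, 2)) for _ in range(3)]
        w = np.array([0.2, 0.5, 0.3])
        out = fast_normalized_fuse([Tensor(x) for x in inputs], w, 1e-4)
        np.testing.assert_allclose(out.data, np_fast_fuse(inputs, w, 1e-4), atol=1e-12)

    def test_negative_weights_are_rectified(self, rng):
        a, b = rng.standard_normal((1, 1, 2, 2)), rng.standard_normal((1, 1, 2, 2))
        out = fast_normalized_fuse([Tensor(a), Tensor(b)], np.array([-3.0, 1.0]), 0.0)
        np.testing.assert_allclose(out.data, b, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        w=st.lists(st.floats(-2, 2), min_size=2, max_size=4),
        seed=st.integers(0, 2**16),
    )
    def test_coefficients_nonnegative_and_sum_below_one(self, w, seed):
        """Effective coefficients are relu(w)/ (sum relu(w) + eps) < 1 in total."""
        rng = np.random.default_rng(seed)
        eps = 1e-4
        w = np.asarray(w)
        ones = [Tensor(np.ones((1, 1, 2, 2))) for _ in w]
        out = fast_normalized_fuse(ones, w, eps)
        total = np.maximum(w, 0).sum()
        expected = total / (total + eps)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)
        assert out.data.max() < 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), i=st.integers(0, 2), j=st.integers(0, 2))
    def test_permutation_consistency(self, seed, i, j):
        """Swapping two inputs with their weights leaves the output unchanged."""
        rng = np.random.default_rng(seed)
        inputs = [rng.standard_normal((1, 2, 2, 2)) for _ in range(3)]
        w = rng.uniform(-1, 2, 3)
        base = fast_normalized_fuse([Tensor(x) for x in inputs], w, 1e-4)
        inputs[i], inputs[j] = inputs[j], inputs[i]
        w2 = w.copy()
        w2[i], w2[j] = w[j], w[i]
        swapped = fast_normalized_fuse([Tensor(x) for x in inputs], w2, 1e-4)
        np.testing.assert_allclose(base.data, swapped.data, atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(DimensionError):
            fast_normalized_fuse(
                [Tensor(np.zeros((1, 1, 2, 2))), Tensor(np.zeros((1, 1, 4, 4)))],
                np.array([1.0, 1.0]),
                1e-4,
            )


class TestResize:
    def test_upsample_replicates_constant(self):
        x = Tensor(np.full((1, 2, 2, 2), 3.25))
        out = resize_to(x, (4, 4))
        np.testing.assert_array_equal(out.data, np.full((1, 2, 4, 4), 3.25))

    def test_downsample_takes_block_max(self):
        x = Tensor(np.arange(16.0).reshape(1, 1, 4, 4))
        out = resize_to(x, (2, 2))
        np.testing.assert_array_equal(out.data, [[[[5, 7], [13, 15]]]])

    def test_round_trip_on_constant_is_identity(self):
        x = Tensor(np.full((1, 3, 2, 2), -1.5))
        back = resize_to(resize_to(x, (4, 4)), (2, 2))
        np.testing.assert_array_equal(back.data, x.data)

    def test_non_power_of_two_ratio_rejected(self):
        with pytest.raises(DimensionError):
            resize_to(Tensor(np.zeros((1, 1, 4, 4))), (12, 12))


class TestFuseLayer:
    def test_output_shapes_equal_input_shapes(self, rng):
        layer = FuseLayer(TINY, rng)
        pyr = make_pyramid(rng)
        out = layer(pyr)
        assert out.spatial_sizes == pyr.spatial_sizes
        assert out.channels == pyr.channels

    def test_matches_straight_line_transcription(self, rng):
        """All six node outputs agree with an independent transcription."""
        layer = FuseLayer(TINY, rng)
        # randomize everything the transcription reads
        for _, p in layer.named_parameters():
            p.data = rng.standard_normal(p.data.shape) * 0.5
        pyr = make_pyramid(rng)
        expected = np_fuse_layer([lvl.data for lvl in pyr], layer)
        out = layer(pyr)
        for got, exp in zip(out, expected):
            np.testing.assert_allclose(got.data, exp, atol=1e-5, rtol=1e-5)

    def test_identity_aggregators_average_inputs(self, rng):
        """With alpha=1 and equal weights, P4_2 = (P4_0 + down(P3_2)) / 2 up to eps."""
        layer = FuseLayer(TINY, rng)
        for node in layer.nodes:
            for agg in node.aggregators:
                agg.alpha.data = np.asarray(1.0)
        pyr = make_pyramid(rng)
        out = layer(pyr)
        # reconstruct P3_2 from the transcription with identity aggregators
        expected = np_fuse_layer([lvl.data for lvl in pyr], layer)
        p3_2 = expected[2]
        down = p3_2.reshape(2, 4, 1, 2, 1, 2).max(axis=(3, 5))
        n_w = 2.0
        target = (pyr[3].data + down) / (n_w + TINY.fusion_epsilon)
        np.testing.assert_allclose(out[3].data, target, atol=1e-6)

    def test_intermediate_node_feeds_both_descendants(self, rng):
        """P2_1 is reused: perturbing it moves both P1_2 and P2_2."""
        layer = FuseLayer(TINY, rng)
        pyr = make_pyramid(rng)
        base = layer(pyr)
        node21 = layer.node("2_1")
        original_forward = node21.forward
        node21.forward = lambda inputs: original_forward(inputs) + 0.5
        try:
            shifted = layer(pyr)
        finally:
            node21.forward = original_forward
        assert not np.allclose(base[0].data, shifted[0].data)  # P1_2 moved
        assert not np.allclose(base[1].data, shifted[1].data)  # P2_2 moved
        assert np.allclose(base[3].data, shifted[3].data) is False  # cascades


class TestNeck:
    def test_lateral_projection_maps_all_levels_to_inner_width(self, rng):
        neck = Neck((3, 5, 7, 9), TINY, rng)
        pyr = FeaturePyramid(
            [Tensor(rng.standard_normal((1, c, s, s)))
             for c, s in zip((3, 5, 7, 9), (8, 4, 2, 1))]
        )
        projected = neck.project_laterals(pyr)
        assert projected.channels == (4, 4, 4, 4)
        assert projected.spatial_sizes == pyr.spatial_sizes

    def test_identity_projection_preserves_values(self, rng):
        neck = Neck((4, 4, 4, 4), TINY, rng)
        for w, b in zip(neck.lateral_weights, neck.lateral_biases):
            w.data = np.eye(4).reshape(4, 4, 1, 1)
            b.data[...] = 0.0
        pyr = make_pyramid(rng)
        projected = neck.project_laterals(pyr)
        for got, orig in zip(projected, pyr):
            np.testing.assert_allclose(got.data, orig.data, atol=1e-12)

    def test_single_layer_neck_equals_projection_plus_fuse(self, rng):
        neck = Neck((4, 4, 4, 4), TINY, rng)
        pyr = make_pyramid(rng)
        manual = neck.layers[0](neck.project_laterals(pyr))
        auto = neck(pyr)
        for a, b in zip(auto, manual):
            np.testing.assert_array_equal(a.data, b.data)

    def test_parameter_count_grows_linearly_in_layers(self, rng):
        counts = [
            Neck((4, 4, 4, 4), NeckConfig(num_layers=k, inner_channels=4,
                                          reduction_r=2), rng).num_parameters()
            for k in (1, 2, 3)
        ]
        assert counts[1] - counts[0] == counts[2] - counts[1] > 0

    def test_three_layer_neck_finite_outputs(self, rng):
        cfg = NeckConfig(num_layers=3, inner_channels=4, reduction_r=2)
        neck = Neck((4, 4, 4, 4), cfg, rng)
        out = neck(make_pyramid(rng))
        for level in out:
            assert np.isfinite(level.data).all()
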