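"""Attribution maps: gradients, integrated gradients, SAM/ISAM, mappings."""

import numpy as np
import pytest

import snnxattr as sx
from snnxattr.attribution import (
    IGPathConfig,
    prefix_sample_times,
    stride_sample_times,
)
from snnxattr.network import ValidationError


@pytest.fixture(scope="module")
def sample(event_dataset):
    return event_dataset[0][0]


class TestGrad3D:
    def test_zero_weight_net_zero_map(self, sample):
        net = sx.make_toy_conv_net((2, 10, 10), 3, seed=0).zero_weights()
        amap = sx.snn_grad3d(net, sample)
        assert not amap.scores.any()
        assert amap.method_tag == "snn-grad3d"

    def test_default_target_is_winner(self, trained_event_net, sample):
        rec = sx.simulate_forward(trained_event_net, sample)
        winner = sx.class_scores(rec).winner
        amap = sx.snn_grad3d(trained_event_net, sample)
        assert amap.target_class == winner
        explicit = sx.snn_grad3d(trained_event_net, sample, target_class=winner)
        np.testing.assert_array_equal(amap.scores, explicit.scores)

    def test_equals_input_gradient(self, trained_event_net, sample):
        amap = sx.snn_grad3d(trained_event_net, sample, target_class=2)
        g = sx.input_gradient(trained_event_net, sample, 2)
        np.testing.assert_array_equal(amap.scores, g)


class TestIGDegeneratePaths:
    def test_ig3d_single_step_equals_grad(self, trained_event_net, sample):
        for heuristic in ("stride", "prefix"):
            ig = sx.snn_ig3d(
                trained_event_net,
                sample,
                IGPathConfig(n_steps=1, sampling_heuristic=heuristic),
            )
            grad = sx.snn_grad3d(trained_event_net, sample)
            np.testing.assert_array_equal(ig.scores, grad.scores)

    def test_ig2d_single_step_equals_grad(self, trained_image_setup):
        net, img, enc = trained_image_setup
        ig = sx.snn_ig2d(net, img, enc, IGPathConfig(n_steps=1))
        grad = sx.snn_grad3d(net, sx.encode(img, enc))
        np.testing.assert_array_equal(ig.scores, grad.scores)

    def test_ig2d_baseline_equals_input(self, trained_image_setup):
        net, img, enc = trained_image_setup
        ig = sx.snn_ig2d(net, img, enc, IGPathConfig(n_steps=4, baseline=img))
        grad = sx.snn_grad3d(net, sx.encode(img, enc))
        np.testing.assert_allclose(ig.scores, grad.scores, rtol=1e-12)

    def test_ig3d_endpoint_is_full_input(self, sample):
        T = sample.n_timesteps
        for heuristic, fn in (("stride", stride_sample_times), ("prefix", prefix_sample_times)):
            keep = fn(T, 4, 4)
            assert sorted(keep.tolist()) == list(range(T))

    def test_stride_sampling_enumeration(self):
        # T=8, n=4: evenly spaced subsets of sizes 2, 4, 6, 8
        expected = [
            [0, 4],
            [0, 2, 4, 6],
            [0, 1, 2, 4, 5, 6],
            [0, 1, 2, 3, 4, 5, 6, 7],
        ]
        got = [stride_sample_times(8, k, 4).tolist() for k in (1, 2, 3, 4)]
        assert got == expected

    def test_n_steps_beyond_T_rejected(self, trained_event_net, sample):
        with pytest.raises(ValidationError):
            sx.snn_ig3d(trained_event_net, sample, IGPathConfig(n_steps=99))

    def test_linear_case_ig_equals_grad(self):
        # With a nearly flat surrogate (alpha -> 0) the backward pass is
        # input-independent up to O(alpha), so averaging gradients along any
        # path changes nothing: the linear-model equivalence of IG and Grad.
        p = sx.NeuronParams(threshold=0.5, leak_factor=1.0, surrogate_sharpness=1e-6)
        spec = sx.NetworkSpec(
            layers=(sx.DenseSpec(2, p),), input_shape=(2, 3, 3), n_classes=2, seed=5
        )
        net = sx.build_network(spec)
        rng = np.random.default_rng(2)
        x = sx.SpikeTensor((rng.random((2, 3, 3, 8)) < 0.3).astype(float))
        ig = sx.snn_ig3d(net, x, IGPathConfig(n_steps=4), target_class=1)
        grad = sx.snn_grad3d(net, x, target_class=1)
        # deviation is O(alpha * potential range), far below 1e-4 relative
        np.testing.assert_allclose(ig.scores, grad.scores, rtol=1e-4, atol=1e-18)


class TestSAM:
    def test_silent_layer_zero_map(self):
        net = sx.make_toy_conv_net((2, 10, 10), 3, seed=0).zero_weights()
        amap = sx.sam(net, sx.SpikeTensor.zeros(2, 10, 10, 8), layer_index=0)
        assert not amap.scores.any()

    def test_single_spike_decay_closed_form(self, trained_event_net, sample):
        # NCS contribution of a spike at t'=0 observed at t is exp(-t/gamma)
        rec = sx.simulate_forward(trained_event_net, sample)
        s = rec.spikes[0]
        amap = sx.sam(trained_event_net, sample, layer_index=0, gamma=1.0)
        # reconstruct one cell by brute force
        c_, y_, x_ = 1, 2, 2
        t = 5
        expected = sum(
            np.exp(-(t - tp))
            for tp in range(t)
            for c in range(s.shape[0])
            if s[c, y_, x_, tp]
        )
        # channel-summed map at (y, x, t)
        got = amap.scores[0, y_, x_, t]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_scores_non_negative(self, trained_event_net, sample):
        amap = sx.sam(trained_event_net, sample, layer_index=0, gamma=2.0)
        assert np.all(amap.scores >= 0)

    def test_non_conv_layer_rejected(self, trained_event_net, sample):
        with pytest.raises(ValidationError):
            sx.sam(trained_event_net, sample, layer_index=1)

    def test_isam_is_exact_negative(self, trained_event_net, sample):
        s = sx.sam(trained_event_net, sample, layer_index=0)
        i = sx.isam(trained_event_net, sample, layer_index=0)
        np.testing.assert_array_equal(i.scores, -s.scores)

    def test_isam_ranking_reverses_sam(self, trained_event_net, sample):
        from snnxattr.evaluation import rank_features

        s = sx.sam(trained_event_net, sample, layer_index=0)
        i = sx.isam(trained_event_net, sample, layer_index=0)
        # break ties so order comparison is exact
        rng = np.random.default_rng(0)
        jitter = rng.random(s.scores.shape) * 1e-9
        s.scores = s.scores + jitter
        i.scores = -s.scores
        rs = rank_features(s, mode="signed").coords
        ri = rank_features(i, mode="signed").coords
        np.testing.assert_array_equal(ri, rs[::-1])


class TestUpscale:
    def test_identity_when_same_size(self):
        m = sx.AttributionMap2D(np.arange(9.0).reshape(3, 3))
        up = sx.upscale_layer_map(m, (3, 3))
        np.testing.assert_allclose(up.scores, m.scores, atol=1e-12)

    def test_constant_map_stays_constant(self):
        m = sx.AttributionMap2D(np.full((2, 3), 4.2))
        up = sx.upscale_layer_map(m, (8, 9))
        np.testing.assert_allclose(up.scores, 4.2)

    def test_corner_preservation_2x2_to_4x4(self):
        m = sx.AttributionMap2D(np.array([[1.0, 2.0], [3.0, 5.0]]))
        up = sx.upscale_layer_map(m, (4, 4)).scores
        assert up[0, 0] == pytest.approx(1.0)
        assert up[0, 3] == pytest.approx(2.0)
        assert up[3, 0] == pytest.approx(3.0)
        assert up[3, 3] == pytest.approx(5.0)
        # interior follows the bilinear formula
        assert up[0, 1] == pytest.approx(1 + 1 / 3)


class TestCollapse:
    def test_sum_conserves_total_mass(self, trained_event_net, sample):
        amap = sx.snn_grad3d(trained_event_net, sample)
        flat = sx.collapse_time(amap, "sum")
        assert flat.scores.sum() == pytest.approx(amap.scores.sum(), rel=1e-12)
        assert flat.scores.shape == sample.shape[1:3]

    def test_single_timestep_single_channel_is_slice(self):
        arr = np.random.default_rng(0).normal(size=(1, 4, 4, 1))
        amap = sx.AttributionMap3D(arr, target_class=0, method_tag="x")
        flat = sx.collapse_time(amap, "sum")
        np.testing.assert_allclose(flat.scores, arr[0, :, :, 0])

    def test_max_picks_per_pixel_maximum(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(2, 3, 3, 5))
        amap = sx.AttributionMap3D(arr, target_class=0, method_tag="x")
        flat = sx.collapse_time(amap, "max")
        np.testing.assert_allclose(flat.scores, arr.max(axis=(0, 3)))

    def test_sum_collapse_is_linear(self):
        rng = np.random.default_rng(4)
        xa = rng.normal(size=(2, 3, 3, 4))
        xb = rng.normal(size=(2, 3, 3, 4))
        mk = lambda a: sx.AttributionMap3D(a, target_class=0, method_tag="x")
        lhs = sx.collapse_time(mk(2 * xa + 3 * xb), "sum").scores
        rhs = 2 * sx.collapse_time(mk(xa), "sum").scores + 3 * sx.collapse_time(
            mk(xb), "sum"
        ).scores
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_input_delta_scaling_applied_after_collapse(self, trained_image_setup):
        net, img, enc = trained_image_setup
        plain = sx.snn_ig2d(net, img, enc, IGPathConfig(n_steps=2))
        scaled = sx.snn_ig2d(
            net, img, enc, IGPathConfig(n_steps=2, scale_by_input_delta=True)
        )
        np.testing.assert_array_equal(plain.scores, scaled.scores)
        f_plain = sx.collapse_time(plain)
        f_scaled = sx.collapse_time(scaled)
        np.testing.assert_allclose(
            f_scaled.scores, f_plain.scores * (np.asarray(img) / 255.0), rtol=1e-12
        )


class TestNormalize:
    def test_printed_formula_on_crafted_map(self):
        out = sx.normalize_map(np.array([[2.0, 4.0], [3.0, 2.0]]))
        np.testing.assert_allclose(out, [[0.0, 1.0], [0.5, 0.0]])

    def test_output_in_unit_interval(self, trained_event_net, sample):
        amap = sx.snn_grad3d(trained_event_net, sample)
        out = sx.normalize_map(amap)
        assert out.scores.min() >= 0 and out.scores.max() <= 1

    def test_constant_map_maps_to_zeros(self):
        out = sx.normalize_map(np.full((3, 3), 7.0))
        assert not out.any()

    def test_signed_vs_abs_ranking_differ_only_with_negatives(self):
        from snnxattr.evaluation import rank_features

        pos = sx.AttributionMap2D(np.array([[3.0, 1.0], [2.0, 0.5]]))
        assert np.array_equal(
            rank_features(pos, "signed").coords, rank_features(pos, "abs").coords
        )
        mixed = sx.AttributionMap2D(np.array([[3.0, -5.0]]))
        assert rank_features(mixed, "abs").coords[0].tolist() == [0, 1]
        assert rank_features(mixed, "signed").coords[0].tolist() == [0, 0]
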