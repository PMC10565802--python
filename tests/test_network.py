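"""LIF dynamics, class scores, surrogate functions, and input gradients."""

import numpy as np
import pytest

import snnxattr as sx
from snnxattr.network import ValidationError, ConfigurationError

from conftest import finite_difference_gradient


def single_neuron_net(threshold=1.0, leak=1.0, reset="subtract", weight=None):
    p = sx.NeuronParams(threshold=threshold, leak_factor=leak, reset_mode=reset)
    spec = sx.NetworkSpec(
        layers=(sx.DenseSpec(1, p),), input_shape=(1, 1, 1), n_classes=1, seed=0
    )
    net = sx.build_network(spec)
    if weight is not None:
        net.set_weights({"layer_0": np.array([[weight]])})
    return net


class TestSimulateForward:
    def test_single_neuron_hand_stepped_recurrence(self):
        # w = theta, lambda = 1: one input spike at t=0 drives U to exactly
        # theta, so the neuron fires at t=0; subtract-reset leaves U at 0
        # and there are no further spikes.
        net = single_neuron_net(threshold=1.0, leak=1.0, weight=1.0)
        x = np.zeros((1, 1, 1, 4))
        x[0, 0, 0, 0] = 1
        rec = sx.simulate_forward(net, sx.SpikeTensor(x))
        assert rec.output_spikes[0].tolist() == [1, 0, 0, 0]
        assert rec.potentials[0][0, 0] == pytest.approx(1.0)

    def test_subthreshold_accumulation_then_fire(self):
        # w = 0.5 theta: two input spikes needed before firing; hand-stepped
        # oracle: U = 0.5, 1.0 -> fire at t=1, subtract reset -> U=0.5 at t=2.
        net = single_neuron_net(threshold=1.0, leak=1.0, weight=0.5)
        x = np.ones((1, 1, 1, 3))
        rec = sx.simulate_forward(net, sx.SpikeTensor(x))
        assert rec.output_spikes[0].tolist() == [0, 1, 0]
        assert rec.potentials[0][0].tolist() == [0.5, 1.0, 0.5]

    def test_zero_reset_clears_potential(self):
        net = single_neuron_net(threshold=1.0, leak=1.0, reset="zero", weight=0.6)
        x = np.ones((1, 1, 1, 4))
        rec = sx.simulate_forward(net, sx.SpikeTensor(x))
        # U: 0.6, 1.2(fire), 0.6, 1.2(fire)
        assert rec.output_spikes[0].tolist() == [0, 1, 0, 1]

    def test_zero_weight_net_silent(self, tiny_dense_net):
        tiny_dense_net.zero_weights()
        x = np.zeros((1, 4, 4, 5))
        x[0, 1, 2, 0] = 1
        rec = sx.simulate_forward(tiny_dense_net, sx.SpikeTensor(x))
        for s, u in zip(rec.spikes, rec.potentials):
            assert not s.any()
            assert np.all(u <= 0)

    def test_empty_input_no_spikes(self, trained_event_net):
        rec = sx.simulate_forward(trained_event_net, sx.SpikeTensor.zeros(2, 10, 10, 16))
        assert all(not s.any() for s in rec.spikes)

    def test_shape_mismatch_rejected(self, tiny_dense_net):
        with pytest.raises(ConfigurationError):
            tiny_dense_net.simulate(np.zeros((1, 5, 5, 3)))

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValidationError):
            sx.SpikeTensor(np.full((1, 2, 2, 3), 0.5))

    def test_causality_by_truncation(self, trained_event_net, event_dataset):
        # output at t depends only on inputs at t' <= t: simulating a prefix
        # must reproduce the prefix of the full run.
        x = event_dataset[0][0].values
        full = trained_event_net.simulate(x)
        cut = 7
        part = trained_event_net.simulate(x[..., :cut])
        for s_full, s_part in zip(full.spikes, part.spikes):
            np.testing.assert_array_equal(s_part, s_full[..., :cut])

    def test_perfect_integrator_limit(self):
        # lambda = 1 and threshold far above reach: final potential equals
        # the cumulative weighted input sum.
        p = sx.NeuronParams(threshold=1e6, leak_factor=1.0)
        spec = sx.NetworkSpec(
            layers=(sx.DenseSpec(2, p),), input_shape=(1, 2, 2), n_classes=2, seed=3
        )
        net = sx.build_network(spec)
        rng = np.random.default_rng(0)
        x = (rng.random((1, 2, 2, 9)) < 0.5).astype(float)
        rec = net.simulate(x)
        w = net.get_weights()["layer_0"]
        expected = w @ x.reshape(4, 9).sum(axis=1)
        np.testing.assert_allclose(rec.potentials[0][:, -1], expected, rtol=1e-12)


class TestClassScores:
    def test_counts_output_spikes(self):
        rec = sx.ForwardRecord(
            potentials=[np.zeros((2, 4))],
            spikes=[np.array([[1, 0, 1, 1], [0, 1, 0, 0]], dtype=float)],
        )
        cs = sx.class_scores(rec)
        assert cs.scores.tolist() == [3, 1]
        assert cs.winner == 0

    def test_silent_output_ties_to_class_zero(self):
        rec = sx.ForwardRecord(potentials=[np.zeros((3, 5))], spikes=[np.zeros((3, 5))])
        cs = sx.class_scores(rec)
        assert cs.scores.tolist() == [0, 0, 0]
        assert cs.winner == 0

    def test_tie_broken_toward_lower_index(self):
        spikes = np.array([[0, 0, 1], [1, 0, 0], [1, 1, 0]], dtype=float)
        rec = sx.ForwardRecord(potentials=[np.zeros((3, 3))], spikes=[spikes])
        # class 2 leads with 2 spikes; ties among 0 and 1 are irrelevant here
        assert sx.class_scores(rec).winner == 2
        equal = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=float)
        rec2 = sx.ForwardRecord(potentials=[np.zeros((3, 3))], spikes=[equal])
        assert sx.class_scores(rec2).winner == 0

    def test_permutation_equivariance(self, trained_event_net, event_dataset):
        rec = sx.simulate_forward(trained_event_net, event_dataset[0][0])
        cs = sx.class_scores(rec)
        perm = np.array([2, 0, 1])
        rec_p = sx.ForwardRecord(
            potentials=[rec.potentials[-1][perm]], spikes=[rec.spikes[-1][perm]]
        )
        cs_p = sx.class_scores(rec_p)
        np.testing.assert_array_equal(cs_p.scores, cs.scores[perm])


class TestSurrogate:
    @pytest.mark.parametrize("family", ["exponential", "fast_sigmoid"])
    def test_peak_at_threshold_and_symmetry(self, family):
        p = sx.NeuronParams(threshold=1.3, surrogate_sharpness=3.0, surrogate=family)
        peak = sx.surrogate_spike_derivative(1.3, p)
        assert peak == pytest.approx(1.5)  # alpha / 2
        for d in (0.1, 0.5, 2.0):
            lo = sx.surrogate_spike_derivative(1.3 - d, p)
            hi = sx.surrogate_spike_derivative(1.3 + d, p)
            assert lo == pytest.approx(hi)
            assert 0 < lo < peak

    def test_exponential_closed_form(self):
        p = sx.NeuronParams(threshold=1.0, surrogate_sharpness=1.0)
        assert sx.surrogate_spike_derivative(2.0, p) == pytest.approx(
            np.exp(-1) / 2, rel=1e-12
        )

    @pytest.mark.parametrize("family", ["exponential", "fast_sigmoid"])
    def test_smooth_spike_integrates_surrogate(self, family):
        # sigma' = rho, checked by finite differences away from the kink
        p = sx.NeuronParams(threshold=0.7, surrogate_sharpness=2.5, surrogate=family)
        for u in (-0.5, 0.3, 0.9, 1.4):
            num = (sx.smooth_spike(u + 1e-6, p) - sx.smooth_spike(u - 1e-6, p)) / 2e-6
            assert num == pytest.approx(sx.surrogate_spike_derivative(u, p), rel=1e-4)


class TestInputGradient:
    def test_zero_weight_net_zero_gradient(self, tiny_dense_net):
        tiny_dense_net.zero_weights()
        x = np.zeros((1, 4, 4, 5))
        x[0, 0, 0, 0] = 1
        g = sx.input_gradient(tiny_dense_net, sx.SpikeTensor(x), 0)
        assert not g.any()

    def test_gradient_shape_matches_input(self, trained_event_net, event_dataset):
        sp = event_dataset[0][0]
        g = sx.input_gradient(trained_event_net, sp, 1)
        assert g.shape == sp.shape

    def test_invalid_class_rejected(self, tiny_dense_net):
        with pytest.raises(ValidationError):
            sx.input_gradient(tiny_dense_net, sx.SpikeTensor.zeros(1, 4, 4, 3), 7)

    @pytest.mark.parametrize(
        "reset,surrogate", [("subtract", "exponential"), ("zero", "fast_sigmoid")]
    )
    def test_matches_finite_differences_dense(self, reset, surrogate):
        p = sx.NeuronParams(
            threshold=0.8, leak_factor=0.9, reset_mode=reset, surrogate=surrogate
        )
        spec = sx.NetworkSpec(
            layers=(sx.DenseSpec(5, p), sx.DenseSpec(3, p)),
            input_shape=(1, 4, 4),
            n_classes=3,
            seed=1,
        )
        net = sx.build_network(spec)
        x = np.random.default_rng(0).random((1, 4, 4, 6))
        g = sx.input_gradient(net, x, 1, mode="relaxed")
        gfd = finite_difference_gradient(net, x, 1)
        err = np.max(np.abs(g - gfd)) / np.max(np.abs(gfd))
        assert err < 1e-3

    def test_matches_finite_differences_conv_pool(self):
        p = sx.NeuronParams(threshold=0.6, leak_factor=1.0)
        spec = sx.NetworkSpec(
            layers=(
                sx.ConvSpec(3, 3, stride=1, pad=1, neuron=p),
                sx.PoolSpec(2, sx.NeuronParams(threshold=0.4, leak_factor=0.8)),
                sx.DenseSpec(2, p),
            ),
            input_shape=(1, 4, 4),
            n_classes=2,
            seed=3,
        )
        net = sx.build_network(spec)
        assert net.n_neurons() <= 100
        x = np.random.default_rng(1).random((1, 4, 4, 5))
        g = sx.input_gradient(net, x, 0, mode="relaxed")
        gfd = finite_difference_gradient(net, x, 0)
        err = np.max(np.abs(g - gfd)) / np.max(np.abs(gfd))
        assert err < 1e-3


class TestSerialization:
    def test_spec_yaml_round_trip(self, tmp_path, trained_event_net):
        from snnxattr.serialize import save_network, load_network

        save_network(trained_event_net, tmp_path / "net.yaml", tmp_path / "w.npz")
        net2 = load_network(tmp_path / "net.yaml", tmp_path / "w.npz")
        for (k1, w1), (k2, w2) in zip(
            trained_event_net.get_weights().items(), net2.get_weights().items()
        ):
            assert k1 == k2
            np.testing.assert_array_equal(w1, w2)

    def test_same_seed_same_weights(self):
        net1 = sx.make_toy_conv_net((2, 8, 8), 3, seed=42)
        net2 = sx.make_toy_conv_net((2, 8, 8), 3, seed=42)
        for w1, w2 in zip(net1.get_weights().values(), net2.get_weights().values()):
            np.testing.assert_array_equal(w1, w2)
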