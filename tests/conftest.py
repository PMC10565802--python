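import numpy as np
import pytest

import snnxattr as sx


@pytest.fixture(scope="session")
def event_dataset():
    """Moving-dot event streams converted to spike tensors (3 classes)."""
    cfg = sx.ToyDatasetConfig(
        n_classes=3,
        n_samples_per_class=8,
        image_size=10,
        noise_level=0.3,
        seed=5,
        n_timesteps=16,
    )
    streams = sx.make_toy_event_streams(cfg)
    return [(sx.events_to_tensor(s), y) for s, y in streams]


@pytest.fixture(scope="session")
def trained_event_net(event_dataset):
    """A toy conv net trained on the event fixture (shared across tests)."""
    net = sx.make_toy_conv_net((2, 10, 10), 3, seed=7)
    sx.train(net, event_dataset, sx.TrainConfig(epochs=10, seed=11))
    return net


@pytest.fixture(scope="session")
def trained_image_setup():
    """Bar-image classifier: (net, one training image, encoder config).

    Poisson coding at T=16 keeps the time axis short; a flatter surrogate
    (alpha=2) is used for stable training on dense rate-coded input.
    """
    cfg = sx.ToyDatasetConfig(
        n_classes=3, n_samples_per_class=8, image_size=12, noise_level=0.1, seed=0
    )
    images = sx.make_toy_images(cfg)
    enc = sx.EncoderConfig(coding="poisson", n_timesteps=16, seed=50)
    data = [(sx.encode(im, enc), y) for im, y in images]
    net = sx.make_toy_conv_net((1, 12, 12), 3, seed=1, surrogate_sharpness=2.0)
    sx.train(net, data, sx.TrainConfig(epochs=20, seed=2))
    return net, images[0][0], enc


@pytest.fixture()
def tiny_dense_net():
    """Two small dense layers; 8 neurons, good for gradient oracles."""
    p = sx.NeuronParams(threshold=0.8, leak_factor=0.9, surrogate_sharpness=2.0)
    spec = sx.NetworkSpec(
        layers=(sx.DenseSpec(5, p), sx.DenseSpec(3, p)),
        input_shape=(1, 4, 4),
        n_classes=3,
        seed=1,
    )
    return sx.build_network(spec)


def finite_difference_gradient(net, x, target_class, eps=1e-5):
    """Central differences of the relaxed (surrogate-smoothed) class score."""

    def score(xv):
        rec = net.simulate(xv, mode="relaxed")
        return rec.output_spikes[target_class].sum()

    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (score(xp) - score(xm)) / (2 * eps)
    return g
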