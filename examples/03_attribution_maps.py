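"""Compute spike-level and pixel-level attribution maps.

Trains the toy event model, explains one decision with SNN-Grad3D and
SNN-IG3D, collapses the 3D maps to pixel maps by summation across time,
and normalizes them to [0, 1] for display.  Also shows the forward-only
SAM baseline and its inversion.
"""

import numpy as np

import snnxattr as sx
from snnxattr.attribution import IGPathConfig

cfg = sx.ToyDatasetConfig(n_classes=3, n_samples_per_class=8, image_size=10,
                          noise_level=0.3, seed=5, n_timesteps=16)
samples = [(sx.events_to_tensor(s), y) for s, y in sx.make_toy_event_streams(cfg)]
net = sx.make_toy_conv_net((2, 10, 10), 3, seed=7)
sx.train(net, samples, sx.TrainConfig(epochs=10, seed=11))

spikes, label = samples[0]

grad = sx.snn_grad3d(net, spikes)  # gradient of S_C per (c, y, x, t) cell
ig = sx.snn_ig3d(net, spikes, IGPathConfig(n_steps=4))  # averaged along a time-sampled path
print(f"explaining class {grad.target_class} (true label {label})")
print(f"SNN-Grad3D: shape {grad.scores.shape}, "
      f"score range [{grad.scores.min():+.3f}, {grad.scores.max():+.3f}]")
print(f"SNN-IG3D  : shape {ig.scores.shape}, "
      f"score range [{ig.scores.min():+.3f}, {ig.scores.max():+.3f}]")

flat = sx.collapse_time(grad, "sum")  # summation across channel and time
norm = sx.normalize_map(flat)
print(f"pixel map : shape {flat.scores.shape}, mass {flat.scores.sum():+.3f} "
      f"(equals the 3D total {grad.scores.sum():+.3f})")
print(f"normalized: range [{norm.scores.min():.2f}, {norm.scores.max():.2f}]")

s = sx.sam(net, spikes, layer_index=0, gamma=1.0)
i = sx.isam(net, spikes, layer_index=0, gamma=1.0)
assert np.array_equal(i.scores, -s.scores)
print(f"SAM at conv layer 0: layer-resolution map {s.scores.shape}, "
      f"total activation {s.scores.sum():.2f}; ISAM is its exact negative")
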