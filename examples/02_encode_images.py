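"""Encode a grayscale image under the four neural codings.

Each coding distributes the same pixel information differently over the
time axis; the printed spike counts show the spectrum from the sparsest
(TTFS: one spike per pixel) to the densest (Poisson at high intensity).
"""

import numpy as np

import snnxattr as sx

cfg = sx.ToyDatasetConfig(n_classes=3, n_samples_per_class=1, image_size=12,
                          noise_level=0.1, seed=3)
img, label = sx.make_toy_images(cfg)[0]
print(f"image: {img.shape}, intensities {img.min()}..{img.max()}, class {label}")

ttfs = sx.ttfs_encode(img)
print(f"TTFS    : T={ttfs.n_timesteps:4d}, {ttfs.spike_count():5d} spikes "
      f"(exactly one per pixel; latency = intensity)")
assert np.array_equal(sx.ttfs_decode(ttfs), img)  # exactly invertible

poisson = sx.poisson_encode(img, T=64, seed=1)
print(f"Poisson : T={poisson.n_timesteps:4d}, {poisson.spike_count():5d} spikes "
      f"(rate per cell = intensity/255)")

phase = sx.phase_encode(img, T=64, period=8)
print(f"Phase   : T={phase.n_timesteps:4d}, {phase.spike_count():5d} spikes "
      f"(binary expansion, MSB first, repeating every period)")

burst = sx.burst_encode(img, T=64, max_spikes=5)
print(f"Burst   : T={burst.n_timesteps:4d}, {burst.spike_count():5d} spikes "
      f"(count and inter-spike interval code intensity)")
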