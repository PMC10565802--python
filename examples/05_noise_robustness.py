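"""Sweep jitter and deletion noise at the input and inside the network.

Relative accuracy = accuracy under noise / clean accuracy, measured on
samples the clean network classifies correctly.  Jitter displaces spike
times; deletion drops spikes entirely, which starves membrane potentials
and degrades the network much faster.
"""

import snnxattr as sx

cfg = sx.ToyDatasetConfig(n_classes=3, n_samples_per_class=8, image_size=10,
                          noise_level=0.3, seed=5, n_timesteps=16)
samples = [(sx.events_to_tensor(s), y) for s, y in sx.make_toy_event_streams(cfg)]
net = sx.make_toy_conv_net((2, 10, 10), 3, seed=7)
sx.train(net, samples, sx.TrainConfig(epochs=10, seed=11))

configs = [sx.NoiseConfig(kind="jitter", level=j, site="input", seed=1)
           for j in range(5)]
configs += [sx.NoiseConfig(kind="deletion", level=p, site="input", seed=1)
            for p in (0.0, 0.3, 0.6, 0.9)]
configs += [sx.NoiseConfig(kind="deletion", level=p, site="network", seed=1)
            for p in (0.0, 0.2)]

table = sx.run_noise_sweep(net, samples, configs, n_repeats=5)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# level 0 rows are exactly 1.0 by construction; deletion noise inside the
# network typically bites harder than at the input
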