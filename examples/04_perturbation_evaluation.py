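"""Judge attribution quality with deletion/insertion perturbation curves.

Good attribution maps identify the spikes that matter: deleting the
top-ranked spike cells should collapse accuracy faster than deleting
random cells, and re-inserting them into an empty stream should restore
accuracy faster.  The area under each curve (AUC) summarises this.
"""

import snnxattr as sx
from snnxattr import attribution as attr
from snnxattr import evaluation as ev

cfg = sx.ToyDatasetConfig(n_classes=3, n_samples_per_class=8, image_size=10,
                          noise_level=0.3, seed=5, n_timesteps=16)
samples = [(sx.events_to_tensor(s), y) for s, y in sx.make_toy_event_streams(cfg)]
net = sx.make_toy_conv_net((2, 10, 10), 3, seed=7)
sx.train(net, samples, sx.TrainConfig(epochs=10, seed=11))

subset = sx.filter_correct(net, samples)  # evaluate only on correct decisions
fractions = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)
grad_fn = lambda n, sp: attr.snn_grad3d(n, sp)  # noqa: E731

for direction in ("delete", "insert"):
    g = ev.run_perturbation_experiment(net, subset, grad_fn, "spike", direction, fractions)
    r = ev.run_perturbation_experiment(net, subset, "random", "spike", direction,
                                       fractions, seed=3)
    print(f"{direction:6s}: SNN-Grad3D(ABS) AUC={ev.curve_auc(g):.3f}  "
          f"random AUC={ev.curve_auc(r):.3f}")
# expected ordering: grad deletion AUC below random (faster degradation),
# grad insertion AUC above random (faster restoration)
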