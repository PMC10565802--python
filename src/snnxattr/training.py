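"""Surrogate-gradient training of spike-count targets.

Training drives each sample's per-class output spike counts toward a
target vector: a high count for the true class and a predefined reduced
count for every other class (keeping the losing neurons mildly active is
what makes spike-count classification trainable).  The loss is the squared
error between counts and targets, minimised with Adam on gradients
obtained by backprop-through-time with the surrogate spike derivative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .network import Network, SpikeTensor, ValidationError, class_scores

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate_accuracy"]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``target_high`` / ``target_low`` are desired output spike counts for
    the true class and the other classes; if None they default to 0.5*T
    and 0.05*T, with T taken from the first sample.
    """

    epochs: int = 20
    learning_rate: float = 0.02
    target_high: Optional[float] = None
    target_low: Optional[float] = None
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


@dataclass
class TrainResult:
    net: Network
    loss_history: list
    accuracy_history: list


def _sample_loss_grad(net: Network, x: np.ndarray, targets: np.ndarray):
    record = net.simulate(x, mode="spike")
    counts = record.output_spikes.sum(axis=-1)
    err = counts - targets
    loss = float(np.sum(err**2))
    T = x.shape[-1]
    # dL/ds_out(c, t) = 2 (S_c - target_c), constant across t
    g_output = np.repeat((2.0 * err)[:, None], T, axis=1)
    _, gw = net.backward(x, record, g_output, want_weight_grads=True)
    pred = int(np.argmax(counts))
    return loss, gw, pred


def train(net: Network, dataset: Sequence, config: TrainConfig) -> TrainResult:
    """Fit ``net`` on ``dataset`` (sequence of (SpikeTensor, label) pairs).

    Deterministic given the config seed: sample order shuffling and all
    optimiser state derive from it.  The network is updated in place and
    also returned inside the result.
    """
    if not dataset:
        raise ValidationError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    first_x = dataset[0][0]
    T = first_x.n_timesteps if isinstance(first_x, SpikeTensor) else first_x.shape[-1]
    hi = config.target_high if config.target_high is not None else 0.5 * T
    lo = config.target_low if config.target_low is not None else 0.05 * T
    n_classes = net.n_classes

    m = {k: np.zeros_like(w) for k, w in net.get_weights().items()}
    v = {k: np.zeros_like(w) for k, w in net.get_weights().items()}
    step = 0
    loss_history, acc_history = [], []

    for _epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        total_loss = 0.0
        correct = 0
        for idx in order:
            sample, label = dataset[idx]
            x = sample.values if isinstance(sample, SpikeTensor) else np.asarray(sample)
            targets = np.full(n_classes, lo)
            targets[label] = hi
            loss, gw, pred = _sample_loss_grad(net, x, targets)
            total_loss += loss
            correct += pred == label
            step += 1
            weights = net.get_weights()
            for key, g in gw.items():
                m[key] = config.adam_beta1 * m[key] + (1 - config.adam_beta1) * g
                v[key] = config.adam_beta2 * v[key] + (1 - config.adam_beta2) * g**2
                mhat = m[key] / (1 - config.adam_beta1**step)
                vhat = v[key] / (1 - config.adam_beta2**step)
                weights[key] = weights[key] - config.learning_rate * mhat / (
                    np.sqrt(vhat) + config.adam_eps
                )
            net.set_weights(weights)
        loss_history.append(total_loss / len(dataset))
        acc_history.append(correct / len(dataset))
    return TrainResult(net=net, loss_history=loss_history, accuracy_history=acc_history)


def evaluate_accuracy(net: Network, dataset: Sequence) -> float:
    """Fraction of samples whose most-spiking output neuron is the label."""
    if not dataset:
        raise ValidationError("dataset is empty")
    correct = 0
    for sample, label in dataset:
        x = sample.values if isinstance(sample, SpikeTensor) else np.asarray(sample)
        record = net.simulate(x, mode="spike")
        correct += class_scores(record).winner == label
    return correct / len(dataset)
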