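"""Discrete-time leaky integrate-and-fire networks with surrogate-gradient backprop.

The simulator is the differentiable substrate the attribution methods are
built on.  Neurons integrate weighted input spikes into a leaking membrane
potential ``U`` and emit a binary spike when ``U`` crosses the threshold
``theta``; the non-differentiable threshold is paired with a smooth
surrogate derivative so that gradients of the class score with respect to
any input spike cell can be computed by backpropagation through time.

Two simulation modes are provided:

``spike``
    The ordinary binary forward pass.  Backward passes through it use the
    surrogate derivative at every spike function (the standard
    surrogate-gradient approximation).
``relaxed``
    The spike function is replaced by its smooth integral, so activations
    are real-valued and the backward pass is the *exact* gradient of the
    forward computation.  This mode exists so the backprop machinery can be
    verified against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "NeuronParams",
    "ConvSpec",
    "PoolSpec",
    "DenseSpec",
    "NetworkSpec",
    "SpikeTensor",
    "ForwardRecord",
    "ClassScores",
    "Network",
    "build_network",
    "simulate_forward",
    "class_scores",
    "surrogate_spike_derivative",
    "smooth_spike",
    "input_gradient",
    "ConfigurationError",
    "ValidationError",
]


class ConfigurationError(ValueError):
    """Raised when a network/layer configuration is inconsistent."""


class ValidationError(ValueError):
    """Raised when runtime data violates an operation's preconditions."""


# ---------------------------------------------------------------------------
# Parameter and spec types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron parameters.

    threshold
        Firing threshold ``theta`` in potential units, > 0.
    leak_factor
        Multiplicative membrane leak ``lam`` per timestep, in (0, 1].
        ``lam = 1`` is a perfect (non-leaky) integrator.
    surrogate_sharpness
        Sharpness ``alpha`` of the surrogate derivative, > 0.
    reset_mode
        ``"subtract"`` (soft reset, ``U <- U - theta`` on spike) or
        ``"zero"`` (hard reset to 0).
    surrogate
        Surrogate family: ``"exponential"`` or ``"fast_sigmoid"``.
    """

    threshold: float = 1.0
    leak_factor: float = 0.9
    surrogate_sharpness: float = 2.0
    reset_mode: str = "subtract"
    surrogate: str = "exponential"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ConfigurationError("threshold must be > 0")
        if not 0 < self.leak_factor <= 1:
            raise ConfigurationError("leak_factor must be in (0, 1]")
        if not self.surrogate_sharpness > 0:
            raise ConfigurationError("surrogate_sharpness must be > 0")
        if self.reset_mode not in ("subtract", "zero"):
            raise ConfigurationError(f"unknown reset_mode {self.reset_mode!r}")
        if self.surrogate not in ("exponential", "fast_sigmoid"):
            raise ConfigurationError(f"unknown surrogate {self.surrogate!r}")


@dataclass(frozen=True)
class ConvSpec:
    out_channels: int
    kernel: int
    stride: int = 1
    pad: int = 0
    neuron: NeuronParams = field(default_factory=NeuronParams)


@dataclass(frozen=True)
class PoolSpec:
    """Non-overlapping average pooling feeding a spiking neuron per cell."""

    window: int
    neuron: NeuronParams = field(default_factory=lambda: NeuronParams(threshold=0.5))


@dataclass(frozen=True)
class DenseSpec:
    out_units: int
    neuron: NeuronParams = field(default_factory=NeuronParams)


LayerSpec = ConvSpec | PoolSpec | DenseSpec


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: ordered layers over a fixed input shape."""

    layers: tuple
    input_shape: tuple  # (channels, height, width)
    n_classes: int
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "input_shape", tuple(self.input_shape))
        if len(self.input_shape) != 3:
            raise ConfigurationError("input_shape must be (channels, height, width)")
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")
        if not self.layers or not isinstance(self.layers[-1], DenseSpec):
            raise ConfigurationError("last layer must be dense")
        if self.layers[-1].out_units != self.n_classes:
            raise ConfigurationError("last dense layer must have out_units == n_classes")


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


class SpikeTensor:
    """Binary spike volume indexed ``(channel, y, x, t)``.

    The universal currency of the toolkit: encoders produce it, the
    simulator consumes it, attribution maps share its shape.
    """

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray):
        values = np.asarray(values)
        if values.ndim != 4:
            raise ValidationError("SpikeTensor must be 4-D (channel, y, x, t)")
        if values.shape[-1] < 1:
            raise ValidationError("SpikeTensor needs at least one timestep")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError("SpikeTensor entries must be binary")
        self.values = values.astype(np.float64)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[-1]

    def copy(self) -> "SpikeTensor":
        return SpikeTensor(self.values.copy())

    def spike_count(self) -> int:
        return int(self.values.sum())

    @classmethod
    def zeros(cls, channels: int, height: int, width: int, T: int) -> "SpikeTensor":
        return cls(np.zeros((channels, height, width, T)))

    def __eq__(self, other) -> bool:
        return isinstance(other, SpikeTensor) and np.array_equal(self.values, other.values)

    def __repr__(self) -> str:
        return f"SpikeTensor(shape={self.values.shape}, spikes={self.spike_count()})"


@dataclass
class ForwardRecord:
    """Per-layer membrane potentials and spike trains from one simulation."""

    potentials: list  # list of arrays, layer_shape + (T,)
    spikes: list      # list of arrays, layer_shape + (T,)
    mode: str = "spike"

    @property
    def output_spikes(self) -> np.ndarray:
        """Output-layer spike train, shape (n_classes, T)."""
        return self.spikes[-1]

    @property
    def n_timesteps(self) -> int:
        return self.spikes[-1].shape[-1]


@dataclass(frozen=True)
class ClassScores:
    """Per-class spike counts and the winning class.

    The class score of neuron ``c`` is the number of spikes it emitted over
    the simulation window; the decision is the most-spiking neuron, ties
    broken toward the lowest class index.
    """

    scores: np.ndarray
    winner: int


# ---------------------------------------------------------------------------
# Surrogate spike functions
# ---------------------------------------------------------------------------


def surrogate_spike_derivative(u, params: NeuronParams):
    """Surrogate derivative rho(u) of the spike function.

    Positive everywhere, maximal at ``u = threshold`` and decaying with
    ``|u - threshold|``.  Default family: ``rho(u) = alpha/2 * exp(-alpha |u - theta|)``.
    """
    a = params.surrogate_sharpness
    d = np.abs(np.asarray(u, dtype=np.float64) - params.threshold)
    if params.surrogate == "exponential":
        return 0.5 * a * np.exp(-a * d)
    # fast sigmoid
    return 0.5 * a / (1.0 + a * d) ** 2


def smooth_spike(u, params: NeuronParams):
    """Smooth spike function sigma(u) whose derivative is the surrogate.

    Monotone from 0 to 1 with sigma(theta) = 1/2; used by the relaxed
    simulation mode so gradient checks have an exactly differentiable
    forward pass.
    """
    a = params.surrogate_sharpness
    z = a * (np.asarray(u, dtype=np.float64) - params.threshold)
    if params.surrogate == "exponential":
        return np.where(z < 0, 0.5 * np.exp(z), 1.0 - 0.5 * np.exp(-z))
    return 0.5 * (1.0 + z / (1.0 + np.abs(z)))


# ---------------------------------------------------------------------------
# im2col convolution helpers
# ---------------------------------------------------------------------------


def _conv_out_hw(h: int, w: int, k: int, stride: int, pad: int) -> tuple:
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    if oh < 1 or ow < 1:
        raise ConfigurationError("conv kernel larger than (padded) input")
    return oh, ow


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    oh, ow = _conv_out_hw(h, w, k, stride, pad)
    cols = np.empty((c, k, k, oh, ow), dtype=np.float64)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = x[:, i : i + oh * stride : stride, j : j + ow * stride : stride]
    return cols.reshape(c * k * k, oh * ow)


def _col2im(cols: np.ndarray, in_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    c, h, w = in_shape
    oh, ow = _conv_out_hw(h, w, k, stride, pad)
    xp = np.zeros((c, h + 2 * pad, w + 2 * pad), dtype=np.float64)
    cols = cols.reshape(c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, i : i + oh * stride : stride, j : j + ow * stride : stride] += cols[:, i, j]
    if pad:
        xp = xp[:, pad:-pad, pad:-pad]
    return xp


# ---------------------------------------------------------------------------
# Runtime layers
# ---------------------------------------------------------------------------


class _Layer:
    spec: LayerSpec
    in_shape: tuple
    out_shape: tuple
    weights: Optional[np.ndarray]

    @property
    def neuron(self) -> NeuronParams:
        return self.spec.neuron

    def forward(self, s_in: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward_input(self, g_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def weight_grad(self, g_out: np.ndarray, s_in: np.ndarray) -> Optional[np.ndarray]:
        return None


class _ConvLayer(_Layer):
    def __init__(self, spec: ConvSpec, in_shape: tuple, rng: np.random.Generator):
        self.spec = spec
        self.in_shape = in_shape
        c, h, w = in_shape
        oh, ow = _conv_out_hw(h, w, spec.kernel, spec.stride, spec.pad)
        self.out_shape = (spec.out_channels, oh, ow)
        fan_in = c * spec.kernel * spec.kernel
        bound = np.sqrt(1.0 / fan_in)
        self.weights = rng.uniform(-bound, bound, (spec.out_channels, c, spec.kernel, spec.kernel))

    def forward(self, s_in: np.ndarray) -> np.ndarray:
        cols = _im2col(s_in, self.spec.kernel, self.spec.stride, self.spec.pad)
        out = self.weights.reshape(self.spec.out_channels, -1) @ cols
        return out.reshape(self.out_shape)

    def backward_input(self, g_out: np.ndarray) -> np.ndarray:
        w2 = self.weights.reshape(self.spec.out_channels, -1)
        gcols = w2.T @ g_out.reshape(self.spec.out_channels, -1)
        return _col2im(gcols, self.in_shape, self.spec.kernel, self.spec.stride, self.spec.pad)

    def weight_grad(self, g_out: np.ndarray, s_in: np.ndarray) -> np.ndarray:
        cols = _im2col(s_in, self.spec.kernel, self.spec.stride, self.spec.pad)
        gw = g_out.reshape(self.spec.out_channels, -1) @ cols.T
        return gw.reshape(self.weights.shape)


class _PoolLayer(_Layer):
    def __init__(self, spec: PoolSpec, in_shape: tuple, rng: np.random.Generator):
        self.spec = spec
        self.in_shape = in_shape
        c, h, w = in_shape
        if h % spec.window or w % spec.window:
            raise ConfigurationError(
                f"pool window {spec.window} does not divide input {h}x{w}"
            )
        self.out_shape = (c, h // spec.window, w // spec.window)
        self.weights = None

    def forward(self, s_in: np.ndarray) -> np.ndarray:
        c, h, w = self.in_shape
        k = self.spec.window
        return s_in.reshape(c, h // k, k, w // k, k).mean(axis=(2, 4))

    def backward_input(self, g_out: np.ndarray) -> np.ndarray:
        k = self.spec.window
        g = np.repeat(np.repeat(g_out, k, axis=1), k, axis=2)
        return g / (k * k)


class _DenseLayer(_Layer):
    def __init__(self, spec: DenseSpec, in_shape: tuple, rng: np.random.Generator):
        self.spec = spec
        self.in_shape = in_shape
        self.out_shape = (spec.out_units,)
        fan_in = int(np.prod(in_shape))
        bound = np.sqrt(1.0 / fan_in)
        self.weights = rng.uniform(-bound, bound, (spec.out_units, fan_in))

    def forward(self, s_in: np.ndarray) -> np.ndarray:
        return self.weights @ s_in.ravel()

    def backward_input(self, g_out: np.ndarray) -> np.ndarray:
        return (self.weights.T @ g_out).reshape(self.in_shape)

    def weight_grad(self, g_out: np.ndarray, s_in: np.ndarray) -> np.ndarray:
        return np.outer(g_out, s_in.ravel())


def _make_layer(spec: LayerSpec, in_shape: tuple, rng: np.random.Generator) -> _Layer:
    if isinstance(spec, ConvSpec):
        return _ConvLayer(spec, in_shape, rng)
    if isinstance(spec, PoolSpec):
        return _PoolLayer(spec, in_shape, rng)
    if isinstance(spec, DenseSpec):
        return _DenseLayer(spec, in_shape, rng)
    raise ConfigurationError(f"unknown layer spec {type(spec).__name__}")


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class Network:
    """A runtime network: a NetworkSpec plus instantiated weights.

    Weights are initialised from a scaled-uniform distribution seeded from
    ``spec.seed``, so building the same spec twice yields identical nets.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.layers: list[_Layer] = []
        shape = spec.input_shape
        for ls in spec.layers:
            layer = _make_layer(ls, shape, rng)
            self.layers.append(layer)
            shape = layer.out_shape

    # -- introspection ---------------------------------------------------

    @property
    def input_shape(self) -> tuple:
        return self.spec.input_shape

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    def conv_layer_indices(self) -> list:
        return [i for i, l in enumerate(self.layers) if isinstance(l, _ConvLayer)]

    def n_neurons(self) -> int:
        return sum(int(np.prod(l.out_shape)) for l in self.layers)

    def get_weights(self) -> dict:
        return {
            f"layer_{i}": l.weights.copy()
            for i, l in enumerate(self.layers)
            if l.weights is not None
        }

    def set_weights(self, weights: dict) -> None:
        for i, l in enumerate(self.layers):
            key = f"layer_{i}"
            if l.weights is not None:
                if key not in weights:
                    raise ConfigurationError(f"missing weights for {key}")
                w = np.asarray(weights[key], dtype=np.float64)
                if w.shape != l.weights.shape:
                    raise ConfigurationError(f"shape mismatch for {key}")
                l.weights = w.copy()

    def zero_weights(self) -> "Network":
        for l in self.layers:
            if l.weights is not None:
                l.weights = np.zeros_like(l.weights)
        return self

    # -- simulation ------------------------------------------------------

    def simulate(self, x: np.ndarray, mode: str = "spike", noise=None) -> ForwardRecord:
        """Run the LIF recurrence over all timesteps, recording every layer.

        ``x`` is a (channels, y, x, T) array: binary for ``mode="spike"``,
        real-valued allowed for ``mode="relaxed"``.  ``noise`` is an
        optional injector with a ``transform(layer_index, t, spikes)``
        method applied to hidden layers' emitted spike trains.
        """
        if mode not in ("spike", "relaxed"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[:3] != self.input_shape:
            raise ConfigurationError(
                f"input shape {x.shape} does not match network input {self.input_shape}"
            )
        T = x.shape[-1]
        L = len(self.layers)
        potentials = [np.zeros(l.out_shape + (T,)) for l in self.layers]
        spikes = [np.zeros(l.out_shape + (T,)) for l in self.layers]
        U = [np.zeros(l.out_shape) for l in self.layers]
        s_prev = [np.zeros(l.out_shape) for l in self.layers]
        if noise is not None:
            noise.reset(self, T)
        for t in range(T):
            below = x[..., t]
            for l in range(L):
                layer = self.layers[l]
                p = layer.neuron
                current = layer.forward(below)
                if p.reset_mode == "subtract":
                    u = p.leak_factor * (U[l] - p.threshold * s_prev[l]) + current
                else:
                    u = p.leak_factor * U[l] * (1.0 - s_prev[l]) + current
                if mode == "spike":
                    s = (u >= p.threshold).astype(np.float64)
                else:
                    s = smooth_spike(u, p)
                if noise is not None and l < L - 1:
                    s = noise.transform(l, t, s)
                U[l] = u
                s_prev[l] = s
                potentials[l][..., t] = u
                spikes[l][..., t] = s
                below = s
        return ForwardRecord(potentials=potentials, spikes=spikes, mode=mode)

    # -- backward --------------------------------------------------------

    def backward(
        self,
        x: np.ndarray,
        record: ForwardRecord,
        g_output: np.ndarray,
        want_weight_grads: bool = False,
    ) -> tuple:
        """Backpropagate through time.

        ``g_output`` is dLoss/d(output spike train), shape (n_classes, T).
        Returns ``(g_input, weight_grads)`` where ``g_input`` has the shape
        of ``x`` and ``weight_grads`` maps layer names to gradient arrays
        (empty dict unless requested).

        In spike mode the derivative of each spike function is replaced by
        the surrogate; in relaxed mode the same expression is the exact
        derivative of the smooth forward pass.
        """
        x = np.asarray(x, dtype=np.float64)
        T = x.shape[-1]
        L = len(self.layers)
        g_input = np.zeros_like(x)
        gW = {
            f"layer_{i}": np.zeros_like(l.weights)
            for i, l in enumerate(self.layers)
            if want_weight_grads and l.weights is not None
        }
        gU_next = [np.zeros(l.out_shape) for l in self.layers]
        for t in range(T - 1, -1, -1):
            gs_from_above: Optional[np.ndarray] = None
            for l in range(L - 1, -1, -1):
                layer = self.layers[l]
                p = layer.neuron
                u_t = record.potentials[l][..., t]
                gun = gU_next[l]
                gs = np.zeros(layer.out_shape)
                if l == L - 1:
                    gs += g_output[..., t].reshape(layer.out_shape)
                if gs_from_above is not None:
                    gs += gs_from_above
                # membrane carry from t+1 and the reset path through s(t)
                if p.reset_mode == "subtract":
                    gs += -p.leak_factor * p.threshold * gun
                    carry = p.leak_factor * gun
                else:
                    s_t = record.spikes[l][..., t]
                    gs += -p.leak_factor * u_t * gun
                    carry = p.leak_factor * (1.0 - s_t) * gun
                gu = gs * surrogate_spike_derivative(u_t, p) + carry
                gU_next[l] = gu
                s_below = x[..., t] if l == 0 else record.spikes[l - 1][..., t]
                if want_weight_grads and layer.weights is not None:
                    gW[f"layer_{l}"] += layer.weight_grad(gu, s_below)
                g_below = layer.backward_input(gu)
                if l == 0:
                    g_input[..., t] += g_below
                else:
                    gs_from_above = g_below
        return g_input, gW


def build_network(spec: NetworkSpec) -> Network:
    """Instantiate a Network (weights seeded from ``spec.seed``)."""
    return Network(spec)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def simulate_forward(net: Network, input_spikes: SpikeTensor, noise=None) -> ForwardRecord:
    """Simulate the binary LIF forward pass on a spike tensor."""
    return net.simulate(input_spikes.values, mode="spike", noise=noise)


def class_scores(record: ForwardRecord) -> ClassScores:
    """Sum output spikes per class; winner = argmax, lowest index on ties."""
    scores = record.output_spikes.sum(axis=-1)
    return ClassScores(scores=scores, winner=int(np.argmax(scores)))


def input_gradient(
    net: Network,
    input_spikes,
    target_class: int,
    mode: str = "spike",
    record: Optional[ForwardRecord] = None,
) -> np.ndarray:
    """Gradient of the class score S_C w.r.t. every input cell (c, y, x, t).

    Entry ``(c, y, x, t)`` estimates how much the target class's spike
    count would change if a spike could be added or removed at that point.
    ``input_spikes`` may be a SpikeTensor or, in relaxed mode, a raw real
    array of the same layout.
    """
    if not 0 <= target_class < net.n_classes:
        raise ValidationError(
            f"target_class {target_class} out of range for {net.n_classes} classes"
        )
    x = input_spikes.values if isinstance(input_spikes, SpikeTensor) else np.asarray(input_spikes)
    if record is None or record.mode != mode:
        record = net.simulate(x, mode=mode)
    T = x.shape[-1]
    g_output = np.zeros((net.n_classes, T))
    g_output[target_class] = 1.0
    g_input, _ = net.backward(x, record, g_output)
    return g_input
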