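"""Spike-level (3D) and pixel-level (2D) attribution maps for SNNs.

Gradient methods
----------------
``snn_grad3d`` is the saliency map adapted to spiking networks: the
surrogate gradient of the class score S_C (the winning neuron's spike
count) with respect to every input spike cell (c, y, x, t).

``snn_ig2d`` / ``snn_ig3d`` adapt Integrated Gradients.  For images the
path interpolates pixel intensities from a baseline (default all-black)
to the source image, encoding each step; for native event streams a path
of intermediate streams is built by sampling timesteps at increasing
rates from the empty stream up to the full input.

Activation baselines
--------------------
``sam`` is the forward-only Spike Activation Map: each neuron's score at
time t is the exponentially decayed sum of its previous spikes.  ``isam``
is its sign-inverted variant.

``collapse_time`` reduces 3D maps to pixel maps (summation across time by
default) and ``normalize_map`` rescales maps to [0, 1] for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .encoders import EncoderConfig, encode, validate_gray_image
from .network import (
    Network,
    SpikeTensor,
    ValidationError,
    class_scores,
    input_gradient,
)

__all__ = [
    "AttributionMap3D",
    "AttributionMap2D",
    "IGPathConfig",
    "snn_grad3d",
    "snn_grad2d",
    "snn_ig2d",
    "snn_ig3d",
    "sam",
    "isam",
    "stride_sample_times",
    "prefix_sample_times",
    "upscale_layer_map",
    "collapse_time",
    "normalize_map",
]


@dataclass
class AttributionMap3D:
    """Real-valued importance per spike cell, same shape as the input tensor.

    ``pixel_scale`` is an optional (height, width) factor attached by
    IG2D when ``scale_by_input_delta`` is on; ``collapse_time`` applies it
    after the temporal reduction.
    """

    scores: np.ndarray  # (channel, y, x, t)
    target_class: int
    method_tag: str
    pixel_scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 4:
            raise ValidationError("3D attribution maps are indexed (channel, y, x, t)")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("attribution scores must be finite")


@dataclass
class AttributionMap2D:
    """Real-valued importance per pixel."""

    scores: np.ndarray  # (y, x)
    mapping_used: str = "sum"
    target_class: Optional[int] = None
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValidationError("2D attribution maps are indexed (y, x)")


@dataclass(frozen=True)
class IGPathConfig:
    """Integrated-gradients path settings.

    ``n_steps`` interpolation steps from the baseline to the input;
    ``baseline`` an image for the 2D method (None = all-black);
    ``sampling_heuristic`` chooses how 3D paths sample timesteps;
    ``scale_by_input_delta`` multiplies the collapsed 2D map elementwise
    by (input - baseline)/255, the classical IG completeness weighting.
    """

    n_steps: int = 50
    baseline: Optional[np.ndarray] = None
    sampling_heuristic: str = "stride"
    scale_by_input_delta: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if self.sampling_heuristic not in ("stride", "prefix"):
            raise ValidationError(f"unknown heuristic {self.sampling_heuristic!r}")


def _resolve_target(net: Network, spikes: SpikeTensor, target_class: Optional[int]) -> int:
    if target_class is not None:
        if not 0 <= target_class < net.n_classes:
            raise ValidationError(f"target_class {target_class} out of range")
        return target_class
    record = net.simulate(spikes.values, mode="spike")
    return class_scores(record).winner


# ---------------------------------------------------------------------------
# Gradient methods
# ---------------------------------------------------------------------------


def snn_grad3d(
    net: Network, input_spikes: SpikeTensor, target_class: Optional[int] = None
) -> AttributionMap3D:
    """Surrogate gradient of the class score w.r.t. every input spike cell.

    Defaults to explaining the winning class (the most-spiking output
    neuron) when no target is given.
    """
    target = _resolve_target(net, input_spikes, target_class)
    g = input_gradient(net, input_spikes, target, mode="spike")
    return AttributionMap3D(scores=g, target_class=target, method_tag="snn-grad3d")


def snn_grad2d(
    net: Network,
    input_spikes: SpikeTensor,
    target_class: Optional[int] = None,
    strategy: str = "sum",
) -> AttributionMap2D:
    """SNN-Grad3D followed by the time-collapse mapping."""
    return collapse_time(snn_grad3d(net, input_spikes, target_class), strategy)


def snn_ig2d(
    net: Network,
    img,
    encoder: EncoderConfig,
    path: IGPathConfig = IGPathConfig(),
) -> AttributionMap3D:
    """Integrated gradients for real-valued images through the encoder.

    Builds n_steps images from the baseline (default all-black) to the
    source image, encodes each one, computes the surrogate gradient of the
    original input's winning class at every step, and averages the
    gradients along the path.
    """
    arr = validate_gray_image(img)
    baseline = (
        np.zeros_like(arr)
        if path.baseline is None
        else validate_gray_image(path.baseline)
    )
    if baseline.shape != arr.shape:
        raise ValidationError("baseline shape must match the image")
    full = encode(arr, encoder)
    if full.shape[:3] != net.input_shape:
        raise ValidationError(
            f"encoded shape {full.shape[:3]} does not match network input {net.input_shape}"
        )
    target = class_scores(net.simulate(full.values, mode="spike")).winner
    n = path.n_steps
    delta = arr - baseline
    total = np.zeros(full.shape)
    for k in range(1, n + 1):
        step_img = np.floor(baseline + (k / n) * delta + 0.5).astype(np.int64)  # round half up
        step_spikes = encode(step_img, encoder)
        total += input_gradient(net, step_spikes, target, mode="spike")
    scale = delta / 255.0 if path.scale_by_input_delta else None
    return AttributionMap3D(
        scores=total / n,
        target_class=target,
        method_tag="snn-ig2d",
        pixel_scale=scale,
    )


def prefix_sample_times(T: int, k: int, n: int) -> np.ndarray:
    """Path step k of n keeps the first ceil(T*k/n) timesteps."""
    m = int(np.ceil(T * k / n))
    return np.arange(m)


def stride_sample_times(T: int, k: int, n: int) -> np.ndarray:
    """Path step k of n keeps ceil(T*k/n) evenly spaced timesteps."""
    m = int(np.ceil(T * k / n))
    return np.floor(np.arange(m) * T / m).astype(int)


def snn_ig3d(
    net: Network,
    input_spikes: SpikeTensor,
    path: IGPathConfig = IGPathConfig(),
    target_class: Optional[int] = None,
) -> AttributionMap3D:
    """Integrated gradients for native event streams.

    Spikes are binary, so the path runs along the time axis: intermediate
    streams sample timesteps from the input at increasing rates, from the
    empty stream ("no spike" baseline) up to the complete stream.  The
    gradient of the original input's winning class is averaged over the
    path.
    """
    T = input_spikes.n_timesteps
    n = path.n_steps
    if n > T:
        raise ValidationError(f"n_steps={n} exceeds the {T} available timesteps")
    sampler = stride_sample_times if path.sampling_heuristic == "stride" else prefix_sample_times
    target = _resolve_target(net, input_spikes, target_class)
    total = np.zeros(input_spikes.shape)
    for k in range(1, n + 1):
        keep = sampler(T, k, n)
        step = np.zeros_like(input_spikes.values)
        step[..., keep] = input_spikes.values[..., keep]
        total += input_gradient(net, SpikeTensor(step), target, mode="spike")
    return AttributionMap3D(scores=total / n, target_class=target, method_tag="snn-ig3d")


# ---------------------------------------------------------------------------
# Activation-map baselines
# ---------------------------------------------------------------------------


def sam(
    net: Network,
    input_spikes: SpikeTensor,
    layer_index: int,
    gamma: float = 1.0,
    channel_aggregate: str = "sum",
) -> AttributionMap3D:
    """Spike Activation Map at a convolutional layer (forward-only).

    Each neuron's contribution score at time t is the sum of
    exp(-(t - t')/gamma) over its own previous spike times t' < t; scores
    are aggregated across channels onto the layer's spatial grid, giving a
    (1, layer_h, layer_w, T) map at layer resolution.
    """
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    if layer_index not in net.conv_layer_indices():
        raise ValidationError(
            f"layer {layer_index} is not convolutional; SAM is limited to conv layers"
        )
    record = net.simulate(input_spikes.values, mode="spike")
    s = record.spikes[layer_index]  # (C, h, w, T)
    T = s.shape[-1]
    ncs = np.zeros_like(s)
    for t in range(1, T):
        lags = np.exp(-(t - np.arange(t)) / gamma)
        ncs[..., t] = np.tensordot(s[..., :t], lags, axes=([-1], [0]))
    agg = ncs.sum(axis=0) if channel_aggregate == "sum" else ncs.mean(axis=0)
    winner = class_scores(record).winner
    return AttributionMap3D(scores=agg[None], target_class=winner, method_tag="sam")


def isam(
    net: Network,
    input_spikes: SpikeTensor,
    layer_index: int,
    gamma: float = 1.0,
    channel_aggregate: str = "sum",
) -> AttributionMap3D:
    """Inverted SAM: the elementwise negative of the SAM scores."""
    base = sam(net, input_spikes, layer_index, gamma, channel_aggregate)
    return AttributionMap3D(
        scores=-base.scores, target_class=base.target_class, method_tag="isam"
    )


def upscale_layer_map(layer_map: AttributionMap2D, target: tuple) -> AttributionMap2D:
    """Bilinearly upscale a layer-resolution map to the input image size.

    Corner-aligned, so values at the source grid points are preserved.
    """
    src = layer_map.scores
    th, tw = target
    sh, sw = src.shape
    if th < sh or tw < sw:
        raise ValidationError("target size must be >= layer resolution")
    if sh == 1 and sw == 1:
        out = np.full((th, tw), src[0, 0])
    else:
        # degenerate axes are repeated, proper axes interpolated corner-aligned
        src2 = src
        if sh == 1:
            src2 = np.repeat(src2, 2, axis=0)
            sh = 2
        if sw == 1:
            src2 = np.repeat(src2, 2, axis=1)
            sw = 2
        interp = RegularGridInterpolator(
            (np.linspace(0, 1, sh), np.linspace(0, 1, sw)), src2, method="linear"
        )
        yy, xx = np.meshgrid(np.linspace(0, 1, th), np.linspace(0, 1, tw), indexing="ij")
        out = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(th, tw)
    return AttributionMap2D(
        scores=out,
        mapping_used=layer_map.mapping_used,
        target_class=layer_map.target_class,
        method_tag=layer_map.method_tag,
    )


# ---------------------------------------------------------------------------
# Mapping and normalization
# ---------------------------------------------------------------------------

_REDUCERS = {"sum": np.sum, "max": np.max, "avg": np.mean}


def collapse_time(map3d: AttributionMap3D, strategy: str = "sum") -> AttributionMap2D:
    """Reduce a 3D spike-attribution map over channel and time.

    Summation across time is the default mapping.  If the map carries a
    ``pixel_scale`` (IG input-delta weighting) it is applied after the
    reduction.
    """
    if strategy not in _REDUCERS:
        raise ValidationError(f"unknown mapping {strategy!r}; choose from {sorted(_REDUCERS)}")
    out = _REDUCERS[strategy](map3d.scores, axis=(0, 3))
    if map3d.pixel_scale is not None:
        out = out * map3d.pixel_scale
    return AttributionMap2D(
        scores=out,
        mapping_used=strategy,
        target_class=map3d.target_class,
        method_tag=map3d.method_tag,
    )


def normalize_map(H):
    """Linearly normalize a map to [0, 1]: H' = |(H - Hmin)/(Hmax - Hmin)|.

    Constant maps (Hmax = Hmin) return all-zeros by convention.  Accepts
    an AttributionMap2D/3D (returned as the same type) or a bare array.
    """
    if isinstance(H, AttributionMap3D):
        return AttributionMap3D(
            scores=normalize_map(H.scores),
            target_class=H.target_class,
            method_tag=H.method_tag,
        )
    if isinstance(H, AttributionMap2D):
        return AttributionMap2D(
            scores=normalize_map(H.scores),
            mapping_used=H.mapping_used,
            target_class=H.target_class,
            method_tag=H.method_tag,
        )
    arr = np.asarray(H, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return np.abs((arr - lo) / (hi - lo))
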