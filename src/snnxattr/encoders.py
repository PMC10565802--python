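"""Neural codings: grayscale images <-> spike tensors.

Four codings with different spatio-temporal structure are provided:

- **TTFS** (time to first spike): one spike per pixel at a latency equal
  to its intensity.  The sparsest coding; exactly invertible.
- **Poisson** (rate coding): each timestep spikes independently with
  probability v/255.
- **Phase**: the 8-bit binary expansion of the intensity is played out
  most-significant bit first, one bit per phase, repeating every period.
- **Burst**: intensity codes both the number of spikes and the inter-spike
  interval (brighter pixels burst more, and more densely).

All encoders produce a single-channel ``SpikeTensor`` of shape
``(1, height, width, T)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import SpikeTensor, ValidationError

__all__ = [
    "EncoderConfig",
    "validate_gray_image",
    "ttfs_encode",
    "ttfs_decode",
    "poisson_encode",
    "phase_encode",
    "burst_encode",
    "encode",
]

TTFS_TIMESTEPS = 256  # one timestep per 8-bit gray level


@dataclass(frozen=True)
class EncoderConfig:
    """Which coding to apply and its parameters.

    ``n_timesteps`` defaults to 256 for every coding so cross-coding
    comparisons share a time axis with TTFS.
    """

    coding: str = "ttfs"
    n_timesteps: int = TTFS_TIMESTEPS
    seed: Optional[int] = None
    phase_period: int = 8
    burst_max_spikes: int = 5
    ttfs_inverted: bool = False

    def __post_init__(self) -> None:
        if self.coding not in ("ttfs", "phase", "poisson", "burst"):
            raise ValidationError(f"unknown coding {self.coding!r}")
        if self.n_timesteps < 1:
            raise ValidationError("n_timesteps must be >= 1")
        if self.coding == "poisson" and self.seed is None:
            raise ValidationError("poisson coding requires a seed")


def validate_gray_image(img) -> np.ndarray:
    """Check an 8-bit grayscale image and return it as an int array."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError("image must be 2-D (height, width)")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ValidationError("pixel values must be integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("pixel values must be in [0, 255]")
    return arr.astype(np.int64)


def ttfs_encode(img, inverted: bool = False) -> SpikeTensor:
    """Time-to-first-spike coding over a 0-255 timestep window.

    Pixel value v yields exactly one spike at t = v (black fires
    earliest).  ``inverted=True`` gives the bright-first convention,
    t = 255 - v.
    """
    arr = validate_gray_image(img)
    h, w = arr.shape
    t_idx = (255 - arr) if inverted else arr
    out = np.zeros((1, h, w, TTFS_TIMESTEPS))
    yy, xx = np.indices(arr.shape)
    out[0, yy.ravel(), xx.ravel(), t_idx.ravel()] = 1.0
    return SpikeTensor(out)


def ttfs_decode(spikes: SpikeTensor, inverted: bool = False, missing: Optional[int] = None):
    """Invert TTFS coding: pixel value = spike time.

    Each pixel must carry at most one spike.  Pixels with no spike raise
    unless ``missing`` supplies a sentinel value.
    """
    vals = spikes.values
    if vals.shape[0] != 1:
        raise ValidationError("TTFS tensors are single-channel")
    counts = vals[0].sum(axis=-1)
    if np.any(counts > 1):
        raise ValidationError("a pixel has more than one spike; not a TTFS tensor")
    if np.any(counts == 0) and missing is None:
        raise ValidationError("a pixel has no spike and no sentinel was given")
    t = np.argmax(vals[0], axis=-1)
    img = (255 - t) if inverted else t
    img = img.astype(np.int64)
    if missing is not None:
        img[counts == 0] = missing
    return img


def poisson_encode(img, T: int, seed: int) -> SpikeTensor:
    """Rate coding: each (y, x, t) cell spikes independently with p = v/255."""
    arr = validate_gray_image(img)
    if T < 1:
        raise ValidationError("T must be >= 1")
    rng = np.random.default_rng(seed)
    p = arr / 255.0
    draws = rng.random((arr.shape[0], arr.shape[1], T))
    return SpikeTensor((draws < p[..., None]).astype(np.float64)[None])


def phase_encode(img, T: int, period: int = 8) -> SpikeTensor:
    """Binary-expansion phase coding, most-significant bit first.

    Within each period of ``period`` timesteps, phase p spikes iff bit p
    (counting from the MSB) of the 8-bit pixel value is set; the pattern
    repeats every period.  T must be a multiple of the period.
    """
    arr = validate_gray_image(img)
    if period < 1 or T % period:
        raise ValidationError("T must be a positive multiple of the phase period")
    n_bits = min(period, 8)
    bits = np.zeros(arr.shape + (period,))
    for p in range(n_bits):
        bits[..., p] = (arr >> (7 - p)) & 1
    pattern = np.tile(bits, T // period)
    return SpikeTensor(pattern[None])


def burst_encode(img, T: int, max_spikes: int = 5) -> SpikeTensor:
    """Burst coding: intensity codes spike count and inter-spike interval.

    N(v) = ceil(max_spikes * v/255) spikes starting at t = 0 with interval
    ISI(v) = ceil((T-1) * (1 - v/255)), clamped to >= 1 and capped at
    floor((T-1)/(N-1)) so the burst always fits the window.  The interval
    shrinks as intensity grows, so bright pixels burst densely.
    """
    arr = validate_gray_image(img)
    if max_spikes < 1:
        raise ValidationError("max_spikes must be >= 1")
    if T < 1:
        raise ValidationError("T must be >= 1")
    h, w = arr.shape
    out = np.zeros((1, h, w, T))
    frac = arr / 255.0
    n_spikes = np.ceil(max_spikes * frac).astype(int)
    isi = np.ceil((T - 1) * (1.0 - frac)).astype(int)
    with np.errstate(divide="ignore"):
        cap = np.where(n_spikes > 1, (T - 1) // np.maximum(n_spikes - 1, 1), T)
    isi = np.maximum(np.minimum(isi, cap), 1)
    last = (n_spikes - 1) * isi
    bad = (n_spikes > 1) & (last >= T)
    if np.any(bad):
        raise ValidationError(
            f"burst coding infeasible for value(s) {np.unique(arr[bad])} at T={T}"
        )
    for y, x in zip(*np.nonzero(n_spikes)):
        times = np.arange(n_spikes[y, x]) * isi[y, x]
        out[0, y, x, times] = 1.0
    return SpikeTensor(out)


def encode(img, cfg: EncoderConfig) -> SpikeTensor:
    """Dispatch an image through the coding named in ``cfg``."""
    if cfg.coding == "ttfs":
        return ttfs_encode(img, inverted=cfg.ttfs_inverted)
    if cfg.coding == "poisson":
        return poisson_encode(img, cfg.n_timesteps, cfg.seed)
    if cfg.coding == "phase":
        return phase_encode(img, cfg.n_timesteps, cfg.phase_period)
    return burst_encode(img, cfg.n_timesteps, cfg.burst_max_spikes)
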