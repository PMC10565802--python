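"""Synthetic fixtures and event-stream I/O.

Two toy dataset families stand in for full-scale image and event-camera
benchmarks:

- **Toy images**: oriented bright bars on a dark background, one bar
  angle per class, with optional salt noise.  Class-separable enough that
  a nearest-template classifier is near-perfect at moderate noise.
- **Toy event streams**: a bright dot translating across the sensor, one
  heading per class, emitting ON events at its new position and OFF
  events at the position it left, plus Bernoulli noise events.

Event streams use a plain-text CSV dialect (header ``x,y,t,polarity``
preceded by a ``# height width T`` preamble) so fixtures stay
human-readable; polarity maps to two spike-tensor channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import (
    ConvSpec,
    DenseSpec,
    NetworkSpec,
    NeuronParams,
    Network,
    SpikeTensor,
    ValidationError,
    build_network,
)

__all__ = [
    "EventStream",
    "ToyDatasetConfig",
    "make_toy_images",
    "make_toy_event_streams",
    "nearest_template_classify",
    "events_to_tensor",
    "tensor_to_events",
    "read_events",
    "write_events",
    "make_toy_conv_net",
]


class EventStreamParseError(ValueError):
    """Malformed event CSV; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class EventStream:
    """Sparse (x, y, t, polarity) records over a fixed sensor geometry.

    Records are kept sorted by (t, y, x); polarity is 0 (OFF) or 1 (ON).
    """

    records: np.ndarray  # (N, 4) int array, columns x, y, t, polarity
    sensor_shape: tuple  # (height, width, T)

    def __post_init__(self) -> None:
        rec = np.asarray(self.records, dtype=np.int64).reshape(-1, 4)
        h, w, T = self.sensor_shape
        if rec.size:
            x, y, t, pol = rec.T
            if np.any((x < 0) | (x >= w)):
                raise ValidationError("event x out of sensor bounds")
            if np.any((y < 0) | (y >= h)):
                raise ValidationError("event y out of sensor bounds")
            if np.any((t < 0) | (t >= T)):
                raise ValidationError("event t out of sensor bounds")
            if np.any((pol != 0) & (pol != 1)):
                raise ValidationError("polarity must be 0 or 1")
            order = np.lexsort((pol, x, y, t))
            rec = rec[order]
        self.records = rec
        self.sensor_shape = tuple(self.sensor_shape)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventStream)
            and self.sensor_shape == other.sensor_shape
            and np.array_equal(self.records, other.records)
        )


@dataclass(frozen=True)
class ToyDatasetConfig:
    """Synthetic dataset parameters (shared by both fixture families)."""

    n_classes: int = 3
    n_samples_per_class: int = 10
    image_size: int = 12
    noise_level: float = 0.05
    seed: int = 0
    n_timesteps: int = 16  # event streams only
    dot_size: int = 2  # event streams only: moving pattern is dot_size x dot_size

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.image_size < 8:
            raise ValidationError("image_size must be >= 8")
        if not 0 <= self.noise_level <= 1:
            raise ValidationError("noise_level must be in [0, 1]")


# ---------------------------------------------------------------------------
# Toy images
# ---------------------------------------------------------------------------

_BAR_FG = 200
_BAR_BG = 30


def _bar_template(size: int, angle: float) -> np.ndarray:
    """Oriented bar: pixels within a half-thickness of the centre line."""
    c = (size - 1) / 2.0
    yy, xx = np.indices((size, size)).astype(np.float64)
    dy, dx = yy - c, xx - c
    # perpendicular distance to a line through the centre at `angle`
    perp = np.abs(-dx * np.sin(angle) + dy * np.cos(angle))
    along = np.abs(dx * np.cos(angle) + dy * np.sin(angle))
    thickness = max(size / 8.0, 1.0)
    length = size * 0.45
    img = np.full((size, size), _BAR_BG, dtype=np.int64)
    img[(perp <= thickness) & (along <= length)] = _BAR_FG
    return img


def make_toy_images(cfg: ToyDatasetConfig) -> list:
    """Labelled oriented-bar images: class c has angle 180 deg * c / n_classes.

    Foreground 200 on background 30, plus salt noise (pixels flipped to
    255) at ``cfg.noise_level``.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    for c in range(cfg.n_classes):
        angle = np.pi * c / cfg.n_classes
        template = _bar_template(cfg.image_size, angle)
        for _ in range(cfg.n_samples_per_class):
            img = template.copy()
            if cfg.noise_level > 0:
                salt = rng.random(img.shape) < cfg.noise_level
                img[salt] = 255
            out.append((img, c))
    return out


def nearest_template_classify(img: np.ndarray, cfg: ToyDatasetConfig) -> int:
    """Oracle classifier: nearest noise-free bar template in L2 distance."""
    templates = [
        _bar_template(cfg.image_size, np.pi * c / cfg.n_classes) for c in range(cfg.n_classes)
    ]
    dists = [np.sum((np.asarray(img, dtype=np.float64) - t) ** 2) for t in templates]
    return int(np.argmin(dists))


# ---------------------------------------------------------------------------
# Toy event streams
# ---------------------------------------------------------------------------


def _dot_path(size: int, T: int, angle: float) -> np.ndarray:
    """Positions (y, x) of a dot crossing the sensor at a given heading."""
    c = (size - 1) / 2.0
    r = size * 0.35
    # travel from -r to +r along the heading over T steps
    s = np.linspace(-r, r, T)
    ys = np.clip(np.round(c + s * np.sin(angle)), 0, size - 1).astype(int)
    xs = np.clip(np.round(c + s * np.cos(angle)), 0, size - 1).astype(int)
    return np.stack([ys, xs], axis=1)


def _blob_cells(anchor: np.ndarray, dot_size: int, size: int) -> set:
    """Occupied (y, x) cells of the dot: a dot_size square clipped to the sensor."""
    ys = np.clip(np.arange(anchor[0], anchor[0] + dot_size), 0, size - 1)
    xs = np.clip(np.arange(anchor[1], anchor[1] + dot_size), 0, size - 1)
    return {(int(y), int(x)) for y in ys for x in xs}


def make_toy_event_streams(cfg: ToyDatasetConfig) -> list:
    """Labelled moving-dot event streams: class c heads at 360 deg * c / n_classes.

    A ``dot_size``-square bright pattern crosses the sensor; each move
    emits ON events at newly covered cells and OFF events at vacated
    ones, mimicking the change-detection behaviour of an event camera.
    Per timestep, Binomial(image_size, noise_level) noise events land at
    uniform random cells with uniform polarity.  Deterministic per seed;
    duplicate records are dropped.
    """
    rng = np.random.default_rng(cfg.seed)
    size, T = cfg.image_size, cfg.n_timesteps
    out = []
    for c in range(cfg.n_classes):
        angle = 2 * np.pi * c / cfg.n_classes
        path = _dot_path(size, T, angle)
        for _ in range(cfg.n_samples_per_class):
            records = []
            prev = _blob_cells(path[0], cfg.dot_size, size)
            for y, x in sorted(prev):
                records.append((x, y, 0, 1))
            for t in range(1, T):
                cur = _blob_cells(path[t], cfg.dot_size, size)
                for y, x in sorted(cur - prev):
                    records.append((x, y, t, 1))
                for y, x in sorted(prev - cur):
                    records.append((x, y, t, 0))
                prev = cur
            for t in range(T):
                n_noise = rng.binomial(size, cfg.noise_level)
                for _ in range(n_noise):
                    records.append(
                        (int(rng.integers(size)), int(rng.integers(size)), t, int(rng.integers(2)))
                    )
            records = list(dict.fromkeys(records))
            out.append((EventStream(np.array(records), (size, size, T)), c))
    return out


# ---------------------------------------------------------------------------
# Conversions and I/O
# ---------------------------------------------------------------------------


def events_to_tensor(stream: EventStream) -> SpikeTensor:
    """Dense binary tensor with polarity as channel (2, h, w, T).

    Duplicate records collapse onto the same cell (logical OR).
    """
    h, w, T = stream.sensor_shape
    out = np.zeros((2, h, w, T))
    if len(stream):
        x, y, t, pol = stream.records.T
        out[pol, y, x, t] = 1.0
    return SpikeTensor(out)


def tensor_to_events(spikes: SpikeTensor) -> EventStream:
    """Inverse of ``events_to_tensor`` for 2-channel tensors."""
    if spikes.shape[0] != 2:
        raise ValidationError("expected a 2-channel (polarity) spike tensor")
    pol, y, x, t = np.nonzero(spikes.values)
    records = np.stack([x, y, t, pol], axis=1)
    c, h, w, T = spikes.shape
    return EventStream(records, (h, w, T))


def write_events(path, stream: EventStream) -> None:
    """Write the plain-text event dialect: preamble + x,y,t,polarity rows."""
    h, w, T = stream.sensor_shape
    lines = [f"# {h} {w} {T}", "x,y,t,polarity"]
    for x, y, t, pol in stream.records:
        lines.append(f"{x},{y},{t},{pol}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_events(path) -> EventStream:
    """Read the event CSV dialect; malformed lines raise with their number."""
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("#"):
        raise EventStreamParseError("missing '# height width T' preamble", 1)
    try:
        h, w, T = (int(v) for v in text[0][1:].split())
    except ValueError:
        raise EventStreamParseError("preamble must be '# height width T'", 1) from None
    if len(text) < 2 or text[1].strip() != "x,y,t,polarity":
        raise EventStreamParseError("missing 'x,y,t,polarity' header", 2)
    records = []
    for i, line in enumerate(text[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise EventStreamParseError(f"expected 4 fields, got {len(parts)}", i)
        try:
            rec = [int(v) for v in parts]
        except ValueError:
            raise EventStreamParseError(f"non-integer field in {line!r}", i) from None
        records.append(rec)
    try:
        return EventStream(np.array(records).reshape(-1, 4), (h, w, T))
    except ValidationError as e:
        raise EventStreamParseError(str(e), 3) from None


# ---------------------------------------------------------------------------
# Tiny network factories
# ---------------------------------------------------------------------------


def make_toy_conv_net(
    input_shape: tuple,
    n_classes: int,
    seed: int = 0,
    conv_channels: int = 4,
    leak: float = 0.9,
    threshold: float = 0.5,
    surrogate_sharpness: float = 10.0,
) -> Network:
    """One spiking conv layer + dense readout; enough for the toy fixtures.

    The default surrogate is deliberately sharp (alpha = 10) so gradients
    concentrate near cells whose membrane potential is close to threshold
    rather than spreading over silent regions; this makes the attribution
    maps of the toy model crisp enough to study.
    """
    params = NeuronParams(
        threshold=threshold, leak_factor=leak, surrogate_sharpness=surrogate_sharpness
    )
    spec = NetworkSpec(
        layers=(
            ConvSpec(out_channels=conv_channels, kernel=3, stride=2, pad=1, neuron=params),
            DenseSpec(out_units=n_classes, neuron=params),
        ),
        input_shape=tuple(input_shape),
        n_classes=n_classes,
        seed=seed,
    )
    return build_network(spec)
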