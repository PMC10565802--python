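"""Quantitative assessment of attribution maps.

Deletion / insertion perturbation
---------------------------------
Features (spike cells or pixels) are ranked by an attribution map and the
top k fraction is iteratively removed from the input (deletion) or
restored into a baseline (insertion); mean class-recall accuracy and the
originally-winning class's spike count are recorded per fraction.  A
seeded random ranking serves as the control.  Experiments run on a subset
the network classifies correctly, so a deletion curve starts at accuracy
exactly 1.

Noise robustness
----------------
Spike jitter (uniform temporal displacement) and spike deletion
(independent drop-out) applied either to the input tensor or to every
hidden layer's emitted spikes during simulation; reported as accuracy
relative to the clean run on the same samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .attribution import AttributionMap2D, AttributionMap3D
from .encoders import EncoderConfig, encode
from .network import Network, SpikeTensor, ValidationError, class_scores

__all__ = [
    "FeatureRanking",
    "PerturbationCurve",
    "NoiseConfig",
    "rank_features",
    "random_ranking",
    "perturb_spikes",
    "perturb_pixels",
    "run_perturbation_experiment",
    "curve_auc",
    "apply_jitter",
    "apply_deletion_noise",
    "DeletionInjector",
    "JitterInjector",
    "run_noise_sweep",
]

PIXEL_BASELINES = {"black": 0, "gray": 128, "white": 255}
DEFAULT_FRACTIONS = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class FeatureRanking:
    """Total order over feature coordinates, most important first.

    ``coords`` is an (N, d) integer array of pixel (y, x) or spike-cell
    (c, y, x, t) coordinates covering every potential feature location.
    Ties in score are broken lexicographically by coordinate.
    """

    coords: np.ndarray
    mode: str  # "signed" | "abs" | "random"

    def __len__(self) -> int:
        return len(self.coords)

    def top(self, n: int) -> np.ndarray:
        return self.coords[:n]


@dataclass
class PerturbationCurve:
    """Metric values versus fraction of features perturbed."""

    fractions: np.ndarray
    accuracy: np.ndarray
    winning_class_score: np.ndarray
    method_tag: str = ""
    direction: str = "delete"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method_tag,
                "direction": self.direction,
                "fraction": self.fractions,
                "accuracy": self.accuracy,
                "winning_class_score": self.winning_class_score,
            }
        )


@dataclass(frozen=True)
class NoiseConfig:
    """One cell of a noise-robustness sweep."""

    kind: str  # "jitter" | "deletion"
    level: float  # jitter intensity (timesteps) or deletion probability
    site: str = "input"  # "input" | "network"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("jitter", "deletion"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.site not in ("input", "network"):
            raise ValidationError(f"unknown noise site {self.site!r}")
        if self.kind == "jitter" and (self.level < 0 or self.level != int(self.level)):
            raise ValidationError("jitter intensity must be a non-negative integer")
        if self.kind == "deletion" and not 0 <= self.level <= 1:
            raise ValidationError("deletion probability must be in [0, 1]")


# ---------------------------------------------------------------------------
# Ranking and perturbation
# ---------------------------------------------------------------------------


def rank_features(
    attribution: Union[AttributionMap2D, AttributionMap3D], mode: str = "abs"
) -> FeatureRanking:
    """Order all feature coordinates by descending (absolute) score.

    ``mode="abs"`` sorts by |score| (the ABS variant), ``mode="signed"``
    by the raw score.  Ties fall back to lexicographic coordinate order.
    """
    if mode not in ("signed", "abs"):
        raise ValidationError(f"unknown ranking mode {mode!r}")
    scores = attribution.scores
    key = np.abs(scores) if mode == "abs" else scores
    # stable argsort on the C-ordered flat array = lexicographic tie-break
    order = np.argsort(-key.ravel(), kind="stable")
    coords = np.stack(np.unravel_index(order, scores.shape), axis=1)
    return FeatureRanking(coords=coords, mode=mode)


def random_ranking(shape: tuple, seed: int) -> FeatureRanking:
    """Seeded uniform-random ranking over all coordinates (the control)."""
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    order = rng.permutation(n)
    coords = np.stack(np.unravel_index(order, shape), axis=1)
    return FeatureRanking(coords=coords, mode="random")


def _check_cover(ranking: FeatureRanking, shape: tuple) -> None:
    if len(ranking) != int(np.prod(shape)):
        raise ValidationError(
            f"ranking covers {len(ranking)} coordinates but the input has "
            f"{int(np.prod(shape))} potential feature locations"
        )


def perturb_spikes(
    input_spikes: SpikeTensor,
    ranking: FeatureRanking,
    k_frac: float,
    direction: str = "delete",
) -> SpikeTensor:
    """Delete (insert) the top k fraction of ranked spike cells.

    The ranking must cover every potential spike location, i.e. all
    (c, y, x, t) cells.  Deletion zeroes the top cells in a copy of the
    input; insertion starts from the empty ("no spike") baseline and
    copies the input's value at the top cells.  The input is never
    mutated.
    """
    if not 0 <= k_frac <= 1:
        raise ValidationError("k_frac must be in [0, 1]")
    if direction not in ("delete", "insert"):
        raise ValidationError(f"unknown direction {direction!r}")
    _check_cover(ranking, input_spikes.shape)
    n = int(np.floor(k_frac * len(ranking)))
    top = ranking.top(n)
    if direction == "delete":
        out = input_spikes.values.copy()
        if n:
            out[tuple(top.T)] = 0.0
    else:
        out = np.zeros_like(input_spikes.values)
        if n:
            out[tuple(top.T)] = input_spikes.values[tuple(top.T)]
    return SpikeTensor(out)


def perturb_pixels(
    img: np.ndarray,
    ranking: FeatureRanking,
    k_frac: float,
    direction: str = "delete",
    baseline: str = "black",
) -> np.ndarray:
    """Delete (insert) the top k fraction of ranked pixels against a baseline.

    Baselines: black = 0, gray = 128, white = 255.
    """
    if baseline not in PIXEL_BASELINES:
        raise ValidationError(f"unknown baseline {baseline!r}")
    if not 0 <= k_frac <= 1:
        raise ValidationError("k_frac must be in [0, 1]")
    if direction not in ("delete", "insert"):
        raise ValidationError(f"unknown direction {direction!r}")
    arr = np.asarray(img)
    _check_cover(ranking, arr.shape)
    value = PIXEL_BASELINES[baseline]
    n = int(np.floor(k_frac * len(ranking)))
    top = ranking.top(n)
    if direction == "delete":
        out = arr.copy()
        if n:
            out[tuple(top.T)] = value
    else:
        out = np.full_like(arr, value)
        if n:
            out[tuple(top.T)] = arr[tuple(top.T)]
    return out


# ---------------------------------------------------------------------------
# Perturbation experiment
# ---------------------------------------------------------------------------


def _predict(net: Network, spikes: SpikeTensor):
    record = net.simulate(spikes.values, mode="spike")
    cs = class_scores(record)
    return cs.winner, cs.scores


def filter_correct(net: Network, samples: Sequence) -> list:
    """Keep only samples the network classifies correctly (spike inputs)."""
    kept = []
    for spikes, label in samples:
        winner, _ = _predict(net, spikes)
        if winner == label:
            kept.append((spikes, label))
    return kept


def run_perturbation_experiment(
    net: Network,
    samples: Sequence,
    attr_fn: Union[str, Callable],
    level: str = "spike",
    direction: str = "delete",
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    baseline: str = "black",
    rank_mode: str = "abs",
    encoder: Optional[EncoderConfig] = None,
    seed: int = 0,
) -> PerturbationCurve:
    """Deletion/insertion curve for one attribution method.

    ``samples`` must already be filtered to correctly-classified inputs:
    (SpikeTensor, label) pairs for spike level, (image, label) pairs for
    pixel level (``encoder`` then maps perturbed images back to spikes).
    ``attr_fn`` is a callable mapping (net, input) to an attribution map
    matching the level, or the string ``"random"`` for the seeded control.
    """
    if level not in ("spike", "pixel"):
        raise ValidationError(f"unknown level {level!r}")
    if level == "pixel" and encoder is None:
        raise ValidationError("pixel-level perturbation needs an encoder config")
    if not samples:
        raise ValidationError("no samples: the correctly-classified subset is empty")
    fractions = np.asarray(sorted(fractions), dtype=np.float64)
    if fractions[0] != 0 or np.any(np.diff(fractions) <= 0):
        raise ValidationError("fractions must strictly increase from 0")

    prepared = []  # (input, label, original winner, ranking)
    for i, (inp, label) in enumerate(samples):
        spikes = inp if level == "spike" else encode(inp, encoder)
        winner, _ = _predict(net, spikes)
        if attr_fn == "random":
            shape = spikes.shape if level == "spike" else np.asarray(inp).shape
            ranking = random_ranking(shape, seed + i)
        else:
            amap = attr_fn(net, inp)
            ranking = rank_features(amap, mode=rank_mode)
            expect = spikes.shape if level == "spike" else np.asarray(inp).shape
            _check_cover(ranking, expect)
        prepared.append((inp, label, winner, ranking))

    acc = np.zeros(len(fractions))
    wcs = np.zeros(len(fractions))
    for fi, frac in enumerate(fractions):
        hits, score_sum = 0, 0.0
        for inp, label, winner, ranking in prepared:
            if level == "spike":
                pert = perturb_spikes(inp, ranking, frac, direction)
            else:
                pert_img = perturb_pixels(inp, ranking, frac, direction, baseline)
                pert = encode(pert_img, encoder)
            pred, scores = _predict(net, pert)
            hits += pred == label
            score_sum += scores[winner]
        acc[fi] = hits / len(prepared)
        wcs[fi] = score_sum / len(prepared)
    tag = "random" if attr_fn == "random" else getattr(attr_fn, "__name__", "custom")
    return PerturbationCurve(
        fractions=fractions,
        accuracy=acc,
        winning_class_score=wcs,
        method_tag=tag,
        direction=direction,
    )


def curve_auc(curve: PerturbationCurve, metric: str = "accuracy") -> float:
    """Trapezoidal area under a perturbation curve."""
    if metric not in ("accuracy", "winning_class_score"):
        raise ValidationError(f"unknown metric {metric!r}")
    if len(curve.fractions) < 2:
        raise ValidationError("curve needs at least two fractions")
    y = curve.accuracy if metric == "accuracy" else curve.winning_class_score
    return float(np.trapezoid(y, curve.fractions))


# ---------------------------------------------------------------------------
# Noise models
# ---------------------------------------------------------------------------


def apply_jitter(input_spikes: SpikeTensor, j: int, seed: int = 0) -> SpikeTensor:
    """Shift each spike by an integer drawn uniformly from [-j, +j].

    Shifts landing outside [0, T) are clipped to the boundary; spikes
    colliding on one cell merge by logical OR (counts can only shrink).
    """
    if j < 0:
        raise ValidationError("jitter intensity must be >= 0")
    if j == 0:
        return input_spikes.copy()
    rng = np.random.default_rng(seed)
    T = input_spikes.n_timesteps
    c, y, x, t = np.nonzero(input_spikes.values)
    shifts = rng.integers(-j, j + 1, size=t.size)
    t_new = np.clip(t + shifts, 0, T - 1)
    out = np.zeros_like(input_spikes.values)
    out[c, y, x, t_new] = 1.0
    return SpikeTensor(out)


def apply_deletion_noise(input_spikes: SpikeTensor, p: float, seed: int = 0) -> SpikeTensor:
    """Keep each spike independently with probability 1 - p."""
    if not 0 <= p <= 1:
        raise ValidationError("deletion probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = input_spikes.values.copy()
    c, y, x, t = np.nonzero(out)
    drop = rng.random(t.size) < p
    out[c[drop], y[drop], x[drop], t[drop]] = 0.0
    return SpikeTensor(out)


def attribution_vs_random_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_samples_per_class: int = 8,
    image_size: int = 10,
    n_timesteps: int = 16,
    noise_level: float = 0.3,
    epochs: int = 10,
    ig_steps: int = 4,
    n_eval: int = 12,
    fractions: Sequence[float] = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
) -> pd.DataFrame:
    """Repeated deletion/insertion experiment: gradient methods vs random.

    For each seed, a fresh moving-dot event dataset is generated, a toy
    conv net trained on it, and deletion and insertion curves computed
    for SNN-Grad3D(ABS), SNN-IG3D(ABS) and the random control on the
    correctly-classified subset.  Returns one row per seed with the AUC
    of every (method, direction) pair plus the training accuracy — the
    raw material for a sign test of whether attribution-guided
    perturbation beats random.
    """
    from . import attribution as attr
    from .datagen import ToyDatasetConfig, events_to_tensor, make_toy_event_streams
    from .datagen import make_toy_conv_net
    from .training import TrainConfig, evaluate_accuracy, train

    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = ToyDatasetConfig(
            n_classes=3,
            n_samples_per_class=n_samples_per_class,
            image_size=image_size,
            noise_level=noise_level,
            seed=seed,
            n_timesteps=n_timesteps,
        )
        data = [(events_to_tensor(s), y) for s, y in make_toy_event_streams(cfg)]
        net = make_toy_conv_net((2, image_size, image_size), 3, seed=seed + 100)
        train(net, data, TrainConfig(epochs=epochs, seed=seed + 200))
        acc = evaluate_accuracy(net, data)
        subset = filter_correct(net, data)[:n_eval]
        row = {"seed": seed, "train_accuracy": acc}
        methods = {
            "snn-grad3d": lambda n, sp: attr.snn_grad3d(n, sp),
            "snn-ig3d": lambda n, sp: attr.snn_ig3d(
                n, sp, attr.IGPathConfig(n_steps=ig_steps)
            ),
            "random": "random",
        }
        for name, fn in methods.items():
            for direction in ("delete", "insert"):
                curve = run_perturbation_experiment(
                    net, subset, fn, "spike", direction, fractions, seed=seed + 300
                )
                row[f"{name}_{direction}_auc"] = curve_auc(curve)
        rows.append(row)
    return pd.DataFrame(rows)


class DeletionInjector:
    """Drops each hidden-layer spike independently with probability p."""

    def __init__(self, p: float, seed: int = 0, layers: Optional[set] = None):
        if not 0 <= p <= 1:
            raise ValidationError("deletion probability must be in [0, 1]")
        self.p = p
        self.seed = seed
        self.layers = layers
        self.rng = np.random.default_rng(seed)

    def reset(self, net: Network, T: int) -> None:
        self.rng = np.random.default_rng(self.seed)

    def transform(self, layer_index: int, t: int, s: np.ndarray) -> np.ndarray:
        if self.layers is not None and layer_index not in self.layers:
            return s
        if self.p == 0:
            return s
        keep = self.rng.random(s.shape) >= self.p
        return s * keep


class JitterInjector:
    """Delays hidden-layer spike delivery by a uniform draw from [-j, +j].

    The simulation is causal, so a draw that would deliver a spike before
    it was emitted is clipped to immediate delivery; late draws land in a
    per-layer schedule buffer.  The emitting neuron's own reset is
    unaffected (jitter models transmission, not firing).
    """

    def __init__(self, j: int, seed: int = 0, layers: Optional[set] = None):
        if j < 0 or j != int(j):
            raise ValidationError("jitter intensity must be a non-negative integer")
        self.j = int(j)
        self.seed = seed
        self.layers = layers
        self._buffers: dict = {}
        self._T = 0
        self.rng = np.random.default_rng(seed)

    def reset(self, net: Network, T: int) -> None:
        self.rng = np.random.default_rng(self.seed)
        self._T = T
        self._buffers = {}

    def transform(self, layer_index: int, t: int, s: np.ndarray) -> np.ndarray:
        if self.layers is not None and layer_index not in self.layers:
            return s
        if self.j == 0:
            return s
        if layer_index not in self._buffers:
            self._buffers[layer_index] = np.zeros(s.shape + (self._T,))
        buf = self._buffers[layer_index]
        idx = np.nonzero(s)
        if idx[0].size:
            shifts = self.rng.integers(-self.j, self.j + 1, size=idx[0].size)
            t_new = np.clip(t + shifts, t, self._T - 1)
            buf[idx + (t_new,)] = 1.0
        return buf[..., t].copy()


def run_noise_sweep(
    net: Network,
    samples: Sequence,
    configs: Sequence[NoiseConfig],
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Relative accuracy of the network under each noise configuration.

    The evaluation subset is restricted to samples the clean network
    classifies correctly (clean accuracy 1 on the subset by construction),
    and relative accuracy = perturbed accuracy / clean accuracy.  Each
    config is averaged over ``n_repeats`` seeded repetitions.
    """
    subset = filter_correct(net, samples)
    if not subset:
        raise ValidationError("clean accuracy is 0; relative accuracy undefined")
    rows = []
    for cfg in configs:
        rels = []
        for rep in range(n_repeats):
            seed = cfg.seed + rep
            hits = 0
            for spikes, label in subset:
                if cfg.site == "input":
                    if cfg.kind == "jitter":
                        pert = apply_jitter(spikes, int(cfg.level), seed)
                    else:
                        pert = apply_deletion_noise(spikes, cfg.level, seed)
                    winner, _ = _predict(net, pert)
                else:
                    if cfg.kind == "jitter":
                        inj = JitterInjector(int(cfg.level), seed)
                    else:
                        inj = DeletionInjector(cfg.level, seed)
                    record = net.simulate(spikes.values, mode="spike", noise=inj)
                    winner = class_scores(record).winner
                hits += winner == label
                seed += 1
            rels.append(hits / len(subset))
        rows.append(
            {
                "kind": cfg.kind,
                "level": cfg.level,
                "site": cfg.site,
                "relative_accuracy": float(np.mean(rels)),
                "sd": float(np.std(rels)),
                "n_seeds": n_repeats,
            }
        )
    return pd.DataFrame(rows)
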