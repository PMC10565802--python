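# Methods

## The problem

Spiking neural networks (SNNs) communicate through binary events over
discrete time, so a classifier's input is a spike volume indexed
`(channel, y, x, t)` rather than a pixel grid, and explaining a decision
means scoring the contribution of every *spike cell* — a 3D attribution
map — and, for image inputs that were encoded into spikes, mapping those
scores back onto the pixels.  This package implements that stack:
a differentiable LIF substrate, neural encoders, gradient-based
attribution (saliency and integrated-gradients variants), activation-map
baselines, and a perturbation protocol that judges whether a map really
found the features the network uses.

## Neuron model and simulation

Neurons follow a discrete-time leaky integrate-and-fire recurrence.  With
membrane potential `U`, leak `lam ∈ (0, 1]`, threshold `theta > 0` and
per-timestep synaptic current `I(t)` (a convolution, pooling average, or
dense product over the previous layer's spikes):

```
subtract reset:  U(t) = lam * (U(t-1) - theta * s(t-1)) + I(t)
zero reset:      U(t) = lam * U(t-1) * (1 - s(t-1))     + I(t)
spike:           s(t) = [U(t) >= theta]
```

Soft (subtract) reset is the default: it retains supra-threshold charge
and is the common choice in surrogate-gradient training.  Time is
abstract — one simulation step per timestep, all time constants in
timesteps.  Pooling layers are average pools feeding a spiking neuron per
cell (default threshold 0.5), so every layer's recorded train is binary.

### Surrogate gradient

The spike function's derivative is replaced by a smooth surrogate
`rho(u)`, maximal at threshold.  Default family (exponential):

```
rho(u) = alpha/2 * exp(-alpha * |u - theta|)
```

with a fast-sigmoid alternative `alpha / (2 (1 + alpha |u - theta|)^2)`.
The sharpness `alpha` controls how tightly gradient flow concentrates
around near-threshold neurons.  The library default is `alpha = 2`
(forgiving, good for training); the toy-model factory uses `alpha = 10`
so attribution maps concentrate on cells that actually matter rather
than spreading over silent regions — with a flat surrogate, a cell far
below threshold still receives substantial gradient, which blurs the
resulting maps.

### Exactness of the backward pass

Backprop-through-time is hand-written (no autodiff dependency) and is
verified against an oracle: in **relaxed mode** the hard threshold is
replaced by the surrogate's integral `sigma(u)` (so `sigma' = rho`
exactly), making the forward pass smooth; the same backward code is then
the exact gradient of that computation and agrees with central finite
differences to ~1e-10 relative (the test bound is 1e-3).  In **spike
mode** the identical code implements the standard surrogate-gradient
approximation used by the attribution methods.

## Class score and training

The class score `S_C` of output neuron `c` is its spike count over the
window; the decision is the most-spiking neuron, ties broken toward the
lowest index.  Training minimises the squared error between per-class
counts and targets — a high count (default `0.5 T`) for the true class
and a small positive count (`0.05 T`) for the rest, which keeps losing
neurons trainable — using Adam (default learning rate 0.02) on
surrogate BPTT gradients.  Training is bit-deterministic given the
config seed.

## Encoders

All encoders emit binary single-channel tensors; `T` defaults to 256 so
every coding shares TTFS's time axis.

- **TTFS** — pixel value `v` spikes once at `t = v` (window 0..255).
  Dark-first: a black pixel fires earliest, which makes an all-black
  baseline the "earliest spike" stream.  An inverted (bright-first) mode
  sits behind a flag.  Exactly invertible; `ttfs_decode` enforces the
  at-most-one-spike precondition.
- **Poisson** — each `(y, x, t)` cell spikes independently with
  `p = v/255`; seeded, bit-reproducible.
- **Phase** — the 8-bit binary expansion of `v`, most-significant bit
  first, one bit per phase, repeating every `period` (default 8)
  timesteps.  Spikes per period = popcount(v).
- **Burst** — `N(v) = ceil(max_spikes * v/255)` spikes from `t = 0` with
  inter-spike interval `ISI(v) = ceil((T-1)(1 - v/255))`, clamped to
  `>= 1` and capped at `floor((T-1)/(N-1))`.  The cap is a deliberate
  repair: the uncapped interval makes midrange intensities infeasible in
  *any* window length (e.g. `v = 103`, `max_spikes = 5` puts the third
  spike beyond `T` for every `T`), while the cap preserves the intended
  behaviour — count and density both grow with intensity, and `v = 255`
  yields `max_spikes` consecutive spikes.

Phase and burst are canonical literature forms; their parameters are
exposed in `EncoderConfig` rather than hard-coded.

## Attribution methods

- **SNN-Grad3D** — the surrogate gradient of `S_C` w.r.t. every input
  cell; the target defaults to the winning class.  **SNN-Grad2D** is the
  same map followed by the time collapse.
- **SNN-IG2D** — integrated gradients for images: `n_steps` images
  interpolate from a baseline (default all-black) to the input, each is
  rounded (half-up, since encoders need integers), encoded, and the
  gradient of the *original* input's winning class computed; the map is
  the plain average of the step gradients (left-Riemann).  Elementwise
  weighting of the collapsed map by `(I - B)/255` — the classical IG
  completeness factor — is a config switch, default off, applied after
  the time collapse.
- **SNN-IG3D** — integrated gradients for native event streams.  Spikes
  cannot be dimmed, so the path runs along time: step `k` of `n` keeps
  `ceil(T k / n)` timesteps of the input, either the leading prefix
  (`prefix`) or evenly spaced (`stride`, the default), from the empty
  "no spike" baseline up to the full stream.
- **SAM / ISAM** — the forward-only spike activation map: each neuron's
  score at `t` sums `exp(-(t - t')/gamma)` over its previous spike times
  `t' < t` (default `gamma = 1`), channel-summed onto the conv layer's
  spatial grid; restricted to convolutional layers by construction.
  ISAM is its exact elementwise negative.  Layer-resolution maps are
  upscaled to image size with corner-aligned bilinear interpolation.

`collapse_time` reduces channel and time with sum (default), max or avg;
summation conserves total attribution mass.  `normalize_map` applies
`H' = |(H - Hmin)/(Hmax - Hmin)|`; constant maps return zeros by
convention.

Both IG variants equal the plain gradient exactly when `n_steps = 1` or
when the baseline is the input itself — these identities are tested and
serve as internal consistency checks.

## Evaluation protocol

`rank_features` orders all feature coordinates by raw (`signed`) or
absolute (`abs`) score, ties broken lexicographically.  "Potential spike
locations" are *all* tensor cells, so deletion budgets are spent on the
ranking, not only on active spikes.  Deletion zeroes the top `k`
fraction; insertion rebuilds the input's values at the top cells from an
empty stream (spikes) or from a black/gray(128)/white baseline (pixels).
Experiments run only on correctly-classified samples, so deletion curves
start at accuracy exactly 1; the per-fraction metrics are mean recall
and the mean spike count of the originally winning neuron.  Curves are
summarised by trapezoidal AUC, and a seeded uniform-random ranking is
the control.

Noise robustness: jitter shifts each spike uniformly in `[-j, +j]`
(clipped to the window, colliding spikes OR-merged); deletion drops each
spike with probability `p`.  Both can also be injected into every hidden
layer's emitted trains during simulation ("network" site).  Network-site
jitter cannot deliver a spike before it was fired in a causal online
simulation, so negative draws clip to immediate delivery and the firing
neuron's own reset is unaffected (jitter models transmission, not
firing); deletion at the network site removes the fired spike itself.
Relative accuracy is perturbed accuracy divided by clean accuracy on the
clean-correct subset.

## Synthetic fixtures

Full-scale image and event-camera benchmarks need external downloads and
long training, so two generated families stand in:

- **Oriented-bar images** (one bar angle per class, foreground 200 on
  background 30, salt noise) — linearly separable, verified by a
  nearest-template oracle classifier (>= 95 % at noise 0.1).
- **Moving-dot event streams** — a 2x2 bright pattern crossing a 10x10
  sensor in a class-specific direction over 16 timesteps, emitting ON
  events at newly covered cells and OFF events at vacated ones (the
  change-detection behaviour of an event camera), plus
  Binomial(image_size, noise_level) uniform noise events per timestep.
  The defaults give a few-percent cell occupancy, comparable to real
  event data; the study configuration uses `noise_level = 0.3` so that
  separating signal from nuisance events is a non-trivial attribution
  problem.

What these fixtures do **not** emulate: natural-image statistics,
classwise intra-class variability beyond noise, sensor refractoriness,
or realistic event-camera timing jitter.  Passing the perturbation
ordering on them shows the method stack is internally correct and
discriminative at toy scale, not that it matches any particular
benchmark number.

Problem sizes were chosen so a full study (20 seeds x train + curves)
completes in about a minute on one core: 3 classes x 8 samples, 10x10
sensor, T = 16, one conv layer (4 channels, 3x3, stride 2) plus a dense
readout, 10 epochs, IG with 4 path steps, 12 evaluation samples per
seed.

## Statistical acceptance

The headline check is ordering, not a point value: over 20 independent
seeds, deletion guided by SNN-Grad3D(ABS) or SNN-IG3D(ABS) must yield a
smaller accuracy AUC than the random control and insertion a larger one,
under a one-sided sign test at p < 0.05.  Typical runs win 19–20 of 20
seeds (p ≈ 1e-6).  The deletion-noise sweep must be monotone
non-increasing within two standard errors across 0–0.9.

## Numerical and design notes

- Argmax ties (class decision) resolve to the lowest index; ranking ties
  resolve lexicographically — both deterministic and tested.
- Weight init: uniform on `±sqrt(1/fan_in)`, seeded from the spec, so a
  spec fully determines a network.
- IG path images round half-up to stay valid 8-bit inputs.
- Perturbation never mutates inputs; all generators are pure functions
  of their configs.
- Event CSV dialect: `# height width T` preamble, `x,y,t,polarity`
  header, one record per line; parse errors carry line numbers.  The
  canonical record order is `(t, y, x, polarity)`.

## Known limitations

- The simulator is plain NumPy and scales to toy problems, not to
  benchmark-size networks; there is no batching or GPU path.
- Surrogate-gradient attributions inherit the approximation error of the
  surrogate itself in spike mode; only relaxed mode has exact gradients.
- SAM is computed at layer resolution; mapping it to input cells for
  spike-level perturbation is not implemented (it participates at pixel
  level via upscaling).
- Network-site jitter is delay-biased by causality, as discussed above.
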