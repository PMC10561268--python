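# Methods

## Model

The network is a stack of L+1 areas (default sizes 784, 2000, 500, 30; the
bundled experiments use a scaled-down 784, 160, 60, 30 — see *Problem
sizes* below). Area 0 is the input: its rates are clamped linearly to pixel
intensities in [0, 1]. Every higher area *l* holds representation neurons
with activation state **x**_l (membrane potential) and rate

    y_l = φ(x_l + Δx),        φ = logistic sigmoid, Δx a threshold offset,

and every area below the top holds one error neuron per representation
neuron. A single weight matrix **W**_l (shape n_l × n_{l+1}) couples areas
l and l+1 and is used symmetrically: top-down it generates the prediction
ŷ_l = W_l y_{l+1}, bottom-up its transpose routes errors.

One inference step (synchronous across areas):

    β_l = y_l − W_l y_{l+1}                     (error neurons, l = 0..L−1)
    x_l ← x_l + ε_inf (W_{l−1}ᵀ β_{l−1} − β_l)  (interior areas)
    x_L ← x_L + ε_inf  W_{L−1}ᵀ β_{L−1}         (top area: no own error)
    y_l = φ(x_l + Δx)

After every `inference_steps_per_cycle` (default 10) such steps one Hebbian
update runs:

    W_l ← W_l + ε_learn β_l y_{l+1}ᵀ

with no decay, clipping or normalization. The summed squared prediction
error E = Σ_l ‖β_l‖² is the implicit objective: the weight update is the
exact gradient −(ε_learn/2) ∂E/∂W_l, and the activation update moves each
x component in the descent direction of E (the sigmoid's positive slope is
used in sign only). Both facts are verified numerically in the test suite
by central finite differences.

The top area has no error population: an error neuron needs a prediction
from above to compare against. Weights are initialized entrywise as
max(0, g)/n_{l+1}, g ~ N(0, 0.5) — non-negative at birth, free to change
sign during learning.

## Training paradigms

Training iterates epochs over sequences; each sequence is repeated 10
times; each frame is presented for `cycles_per_frame` inference-learning
cycles. The two paradigms differ only in the reset placement:

* **continuous** — activity resets to the uniform low rate `reset_rate`
  once at the start of each sequence's repetition block and otherwise
  carries over between frames and repetitions. The lingering state acts as
  a temporal prior: consecutive views of one object are inferred from
  similar starting points and the Hebbian rule binds them to a common
  higher-level cause. A config switch (`reset_per_repetition`) moves the
  reset to every repetition; whether replayed repetitions share one
  percept is a modelling choice, and the default treats the 10 repetitions
  as one ongoing percept.
* **static** — activity resets before every frame; no temporal structure
  reaches the learning rule. This is the control that isolates the role of
  temporal continuity.

Stimulus speed scales the dwell time: speed *s* divides the per-frame
cycles by *s* (speed 2 = half the inference steps per frame).

## Parameters

| name | default | meaning |
|---|---|---|
| `inference_rate` ε_inf | 0.05 | activation step size |
| `learning_rate` ε_learn | 0.01 | Hebbian step size; stable error descent on the bundled stimuli |
| `activation_offset` Δx | −2.0 | keeps resting rates low (φ(Δx) ≈ 0.12) |
| `reset_rate` | 0.1 | the uniform low rate installed at a reset |
| `inference_steps_per_cycle` | 10 | steps between weight updates |
| `cycles_per_frame` | 100 (fixture: 10) | per-frame dwell during training |
| `convergence_tol` | 1e-4 | relative change of E between cycles |
| `max_convergence_steps` | 5000 | cycle cap when running to convergence |

Convergence on a still image is declared when the relative change of E
between consecutive cycles falls below `convergence_tol`; the baseline for
the first comparison is the error of the freshly clamped state, so an
infinite tolerance degenerates to exactly one cycle.

## Synthetic stimuli

The generator draws one "glyph" per object class — a connected chain of
3–5 thickened strokes between random control points, lightly smoothed and
centred — and animates it over 6 frames: integer-pixel translation (1
px/frame at speed 1), rotation (12°/frame) or centred scaling (+0.06
scale/frame), all bilinear where interpolation is needed and clipped to
[0, 1]. Optional background noise adds a fresh uniform pattern (amplitude
0.2) to background pixels of every frame. Moving full-width bars serve as
a minimal sanity stimulus. For occlusion experiments the glyph starts with
its right edge one pixel short of a static occluder covering the right 40%
of the canvas and translates 3 px/frame behind it, so only frame 0 is
fully unoccluded and the hidden part grows monotonically.

What the glyphs do not emulate: the stroke statistics and intra-class
variability of handwritten digits, photographic toy objects, 3D
out-of-plane rotation, clutter, or luminance gradients. Passing tests show
that the mechanisms (invariance from continuity, generativity, timescale
hierarchy) operate on temporally continuous transformation sequences; they
do not certify performance on natural images.

## Analyses

All analyses freeze the weights (asserted bit-identical afterwards).

**Representations and RDMs.** For every frame of a dataset the network is
reset, the still frame clamped, inference run to convergence, and the
chosen area's rate vector recorded (frames run as one batch sharing the
frozen weights). Pairwise cosine dissimilarity d(r1, r2) = 1 − r1·r2/
(‖r1‖‖r2‖) fills the RDM, ordered sequence-major. The block-structure
score summarizes it as (mean within-sequence off-diagonal d, mean
across-sequence d).

**Decoding.** Multinomial logistic regression (fixed L2 regularization,
C = 1) under stratified 3-fold cross-validation; accuracy is the held-out
fraction correct. Baselines share the fold splitter: k-means on raw pixels
(k = classes, clusters mapped to labels by majority vote on the training
folds, empty clusters to the overall majority), direct linear decoding of
raw pixels, and linear slow feature analysis — PCA-whitened pixels,
eigendecomposition of the temporal-difference covariance, slowest 10
features decoded with the same logistic read-out.

**Timescales.** Activity of a subpopulation (rates of area 1..3, errors of
area 0..2) is recorded at every inference step during one continuous
sequence presentation (reset once), block-averaged over 10 steps. The
autocorrelation is un-centred, exactly as defined:
R(Δ) = Σ_t z(t)·z(t+Δ) / (N (T′−Δ)) on the block grid, with lags reported
in inference steps. No mean is subtracted, so persistently active
populations keep a high baseline. The decay constant τ is the lag where
R/R(0) first reaches 1/e (linear interpolation between lag samples); if
the curve never crosses, a line through (0, R(0)) and (T, R(T)) is
extended to the crossing, and if even that line does not fall (slope ≥ 0)
τ is censored at 10·T and excluded from statistics. R curves are averaged
across the dataset's sequences before τ extraction. Group comparisons use
Welch's ANOVA over the six (population, area) groups followed by
Games-Howell post-hoc tests (pingouin).

The dynamics probe presents frames at the *training* dwell time. A network
trained at 100 steps/frame never visited the frame-specific attractors it
settles into when a frame is held ten times longer; probing far off the
training statistics lets the top area hop between those attractors and
destroys the very persistence the continuous paradigm creates. Matching
the probe to the training presentation is therefore part of the
experimental design, not a free parameter.

**Reconstruction.** The generative read-out installs rates area by area as
the raw linear prediction y_l := W_l y_{l+1} from the source area down to
the input image (a cascade exactly linear in the source representation; a
config flag routes intermediate predictions through φ instead).
Blank-and-reconstruct presents a frame to convergence, removes it, and
cascades the converged representation down; MSE compares the raw
reconstruction to the original frame.

**Occlusion.** Occluded sequences are presented continuously with frozen
weights; after each frame's inference the input-area prediction W_0 y_1 is
compared to the unoccluded ground truth *inside the occluded region only*,
averaged across sequences per frame index (empty regions score 0). Scoring
uses the raw prediction: min-max normalization (available for display and
as an option) rescales the image by its extremes, so one negative
background pixel shifts the whole empty region away from zero and
dominates the region MSE. The feedforward baseline is the occluded input
itself — its region MSE is the mean squared ground-truth intensity there.
Per-frame Welch t-tests across seeds compare conditions.

## Problem sizes

The bundled experiment battery (tests and the `reproduce` driver) runs a
scaled-down standard fixture chosen so the whole suite fits in minutes on
one CPU core: hidden areas 160/60/30 (instead of 2000/500/30), 10 glyph
classes, 6 frames, 10 cycles/frame during training, 6 epochs, four
independently seeded networks. All fixture claims are ordinal
(orderings, inequalities), which survive this scaling; the full-size
architecture remains the config default and is used for the untrained
collapse measurement, which needs no training.

## Known limitations

* Learning can be destabilized by large ε_learn (no weight decay or
  normalization exists to absorb it); the default is conservative.
* The un-centred autocorrelation conflates persistence with a constant
  activity baseline; timescale comparisons are meaningful within this
  definition but are not mean-subtracted intrinsic timescales.
* Censored decay constants (curves that never fall to 1/e even after
  linear extension) are reported with a flag and excluded from statistics.
* The generative cascade is a pure top-down sweep; lower areas do not
  settle dynamically during reconstruction.
* Weight symmetry is built in, not learned; the weight-transport question
  is out of scope.
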