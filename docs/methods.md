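# Methods

`gaborpath` implements a complete pipeline for studying contour
integration in feedforward convolutional networks: parametric Gabor
contour-path stimuli, architectures whose receptive-field (RF) progression
is the controlled variable, linear probing of intermediate layers,
guided-backpropagation sensitivity metrics, a 2-IFC psychophysics
framework with simulated observers, and a vernier/flanker uncrowding
protocol. This note records the models, their assumptions, the defaults,
and the numerical choices.

## Stimuli: Gabor contour paths

Each display is a 512x512 grayscale raster holding a jittered 16x16 grid
of 256 Gabor elements (32x32-px cells). A Gabor is an odd-symmetric
grating under a Gaussian envelope,

    I(x, y) = b + A * exp(-(x^2+y^2) / (2 sigma^2)) * cos(2 pi u / lambda + phi),

with wavelength `lambda = 8` px, envelope `sigma = 4` px, phase
`phi = -90 deg`, patch size 28 px, and `u` the coordinate perpendicular to
the stripes. Contrast is unspecified in the paradigm's usual description;
we use background `b = 0.5` and amplitude `A = 0.5` (maximum symmetric
visibility about mid-gray), clip to [0, 1], and quantize to 8-bit levels.
Because `phi = -90 deg` makes the carrier odd, a literal rendering at
orientation `theta` and `theta + 180` would flip contrast polarity even
though a grating's orientation is only defined modulo 180 degrees; the
renderer therefore canonicalizes orientation mod 180 before evaluating
the closed form.

The contour path places 13 anchor points: the first 64 px from the image
center at a random polar angle, heading toward the center turned by a
random-signed global-curvature angle `beta`; each subsequent segment
turns by signed `beta` plus a uniform random integer perturbation in
[-10, 10] deg. Anchors are spaced `D = 32` px apart, stretched in
`dD = 8`-px steps whenever the segment midpoint lands in an occupied grid
cell (at most 20 stretches per segment, at most 50 whole-path restarts
per seed). One element sits at each segment midpoint, oriented along its
segment (the local-orientation offset `alpha` is fixed at 0), giving 12
contour elements. Every unoccupied cell receives a background Gabor at
the cell center plus independent integer jitter in [-9, +9] px per axis,
with a uniform random orientation.

A matched pair shares every background element (position and orientation)
and every contour position; only the contour orientations differ
(path-aligned vs independently random). Overlapping patches combine by
summing signed deviations from the background level before a single
clip, so paste order cannot matter. The pixel-difference support of a
pair is therefore confined to contour-element footprints; this is
asserted on rasters in the tests.

Ambiguities resolved here (and only here): the sign of `beta` is drawn
independently per segment; the integer perturbation is added to the
signed turn; background jitter is sampled once and shared by both pair
members (forced by the identity invariant).

Element masks threshold the per-element Gaussian envelope (scaled 0-255,
combined across elements by maximum) at level 140, giving per-element
discs of radius `sqrt(2 sigma^2 ln(255/140)) ~ 4.38` px; contour and
background masks are built separately, and pixels under both are
assigned to the contour distribution in downstream scoring.

The alignment-jitter manipulation displaces each contour element 0-8 px
perpendicular to its local path segment (sign random per element,
identical in both pair members), degrading good continuation while
preserving element orientations and local density.

Dataset builders reproduce the study's compositions as manifests: 91
curvature levels x 2,500 pairs (455,000 images) for the broad training
pool; the 4,992-image balanced subset (832 images per level over
{0, 15, 30, 45, 60, 75} deg); and the 2,000-image behavioral set of
1,000 pairs over {15, ..., 75} deg, partitioned into five disjoint
200-pair splits with 40 pairs per curvature each, every trial carrying a
random rotation for display 1 in {0, 90, 180, 270} and a further
relative rotation in {90, 180, 270} for display 2. Full-scale manifests
are built without rasterization (`render=False`); rendering is exercised
at small scale and is deterministic given the per-pair seed.

## Networks and receptive fields

Models run on a small NumPy engine written for this package (im2col
convolution, rectifier, max/average/adaptive pooling, linear, dropout;
softmax cross-entropy; SGD with momentum and AdamW; one-cycle learning
rate schedule, linear warm-up over the first 40% of steps then cosine
annealing; He fan-in initialization from explicit seeds). Conv forward
and all backward passes are verified against `scipy.signal.correlate`
and finite differences. The backward pass supports the guided rule used
for saliency.

Analytic receptive fields come from the standard composition

    r_l = r_{l-1} + (k_l - 1) j_{l-1},    j_l = j_{l-1} s_l,

with `r_0 = j_0 = 1`, applied over the architecture spec. An impulse
oracle cross-checks every value: the model is rebuilt with strictly
positive weights (and max-pools replaced by mean-pools of the same
geometry, since argmax routing would under-report the influence field),
and the gradient footprint of a central unit is measured on the input.
The oracle narrows conv widths to 2 channels first; width is irrelevant
to footprint geometry and the full-width fifth-block stack would be
needlessly expensive to probe.

The reference backbone is the classic five-conv/three-maxpool topology
with a 6x6 adaptive average pool and a three-layer fully connected head
(1000-way output), exposing 21 named probe points. Its fifth conv block
has RF 163 px before and 195 px after the trailing max-pool; the
195 figure refers to the block output including that pool — the only
reading consistent with the RF recurrence.

PinholeNets keep the reference depth and channel progression
(64, 192, 384, 256, 256) but drop all pooling and use stride-1,
'same'-padded kernel plans chosen to hit the published fifth-block RFs:
P11 = (3,3,3,3,3), P17 = (5,5,5,3,3), P31 = (7,7,7,7,7),
P33 = (9,7,7,7,7). The exact kernel plans are not published; these are
the package's choice, verified by both the calculator and the oracle.
The head global-average-pools the fifth block, so it is input-size
independent and every architecture has a reduced desk-scale twin.

Two desk-scale families support CPU experiments: `make_toy_net` builds
five-block twins with a small channel budget (6, 8, 8, 8, 8) that differ
only in RF — 'full' (strided large kernels, RF 107 px on a 128-px
display) vs 'pinhole' (RF 7 px, below one element); `make_vernier_net`
is a VGG-style stack (3x3 stride-1 convs with 2x2 max-pools) whose fine
early sampling is required to resolve few-pixel vernier offsets. Both
start with a fixed input-centering layer (subtract mid-gray) so conv
stacks see zero-mean inputs; without it, desk-scale from-scratch
training does not get off the ground.

## Linear probing

A readout is a two-output linear head on the flattened activations of a
named probe point, trained with softmax cross-entropy, SGD momentum 0.9,
no weight decay, batch size 8, and a one-cycle schedule with maximum
learning rate 1e-4 over 100 epochs (the full-scale recipe; desk
presets shorten epochs and may use AdamW). Frozen mode extracts features
once and provably leaves the backbone bit-identical (SHA-256 over
parameter bytes); fine-tune mode backpropagates end to end. A 90/10
train/validation split by pair id is carved out of the training
manifest; accuracies are taken at the final epoch (no early stopping).
Evaluation reports accuracy with a normal-approximation 95% CI over
per-image correctness plus a per-curvature breakdown, and refuses
train/test pair-id overlap.

## Saliency and sensitivity

Saliency maps use guided backpropagation: the gradient of the
contour-present output node is propagated back with every rectifier
zeroing its locally-inactive paths *and* all negative incoming
gradients. The input gradient is taken in absolute value and min-max
normalized per image to [0, 1] (an all-zero gradient maps to an all-zero
raster). Normalization is required for the difference-of-means score to
live in [-1, 1]; the underlying scheme is not published, so per-image
min-max is the package's choice and A' — invariant to monotone
transforms — is the primary statistic. A' is the Mann-Whitney rank
probability U/(n1 n2) with ties at 1/2 (empirical ROC area), computed
from midranks. Alignment sensitivity takes, per position-matched pair,
the score difference between the aligned and misaligned member and
reports the mean with a normal 95% CI.

## Psychophysics

Sessions order one 200-pair behavioral split as 5 blocks x 2 mini-blocks
x 20 trials; each (curvature, present-interval) condition appears exactly
20 times overall, 4 per block, 2 per mini-block, randomized within
mini-blocks only.

Simulated observers stand in for human participants. Per-condition
accuracy follows the 2-IFC Weibull

    P(correct | beta) = 0.5 + (0.5 - lapse) * exp(-(beta/threshold)^slope),

and each trial's probability is shifted on the logit scale by a per-pair
difficulty offset ~ N(0, sd) shared across observers — the mechanism
that produces reliable trial-level variation. The default cohort
(threshold 45 deg, slope 2, lapse 0.02, difficulty SD 0.5 logits, 50
observers, 10 per split) yields mean accuracy falling from ~0.92 at
15 deg to ~0.54 at 75 deg and a split-half structure the analytic
attenuation formula predicts well (below). The shared-difficulty model
is this package's construction; only the existence of reliable
trial-level variation, not its mechanism, is documented for the human
data.

Psychometric fits are bounded least squares (guess fixed at 0.5, lapse
capped at 0.1, threshold in [0.01, 1e4], slope in [0.1, 20]); fits pinned
to bounds or fit to flat data are flagged rather than trusted. Parameter
recovery at 1,000 trials per level returns thresholds within +/-10%.

Exclusion is two-stage and recursive with a strict 2.5-sample-SD rule
(ties at exactly 2.5 SD are kept): first on overall accuracy, removing
the most deviant observer and recomputing until stable; then on the
correlation between each observer's five-dimensional curvature profile
and the leave-one-out group mean profile. The two stages repeat to a
joint fixed point, which makes the procedure idempotent on its own
output. Fewer than three survivors aborts with the audit log.

Split-half reliability randomly halves observers (stratified by split),
correlates per-trial percent correct between halves, and applies the
Spearman-Brown correction 2r/(1+r); the point estimate averages 1,000
random halvings (resampling degenerate zero-variance halves) and the CI
is the percentile interval of the corrected values. For simulated
cohorts the raw split-half correlation has the closed form
Var(p) / (Var(p) + E[p(1-p)]/n_half) in the true per-trial probabilities
p, which the tests verify.

Model decision strength for a pair is the contour signal
s = (response_present - response_absent)/2, half the difference of the
contour-present node's responses — equivalently the scaled perpendicular
distance from the identity line of the present-vs-absent response
scatter. Trial-level correspondence is the Pearson correlation between s
and per-trial percent correct with a Fisher-z 95% CI, reported alongside
the reliability ceiling.

## Uncrowding

Vernier displays are 227x227 by default (96 px in the desk preset):
two 20x2-px vertical bars separated by a 2-px gap, the lower bar offset
left or right (2 px at full scale, 4 px at desk scale where the smaller
network cannot resolve 2 px reliably); flankers are 19x19 outline shapes
(square, circle, hexagon, octagon, diamond; 1-px stroke) in rows of
1/3/5/7 at 25-px center-to-center spacing. Training displays are
non-overlapping — vernier and flanker row at free random positions with
bounding boxes at least 10 px apart; test displays center the vernier in
the flanker row (count 0 = unflanked baseline). Strokes are bright on a
dark canvas; zero-mean Gaussian noise of SD 0.1 is added last and
clipped to [0, 1] (on the dark background the clip shaves the negative
tail; the noise generator itself is verified at an unclipped mid-gray
background). Labels are exactly balanced in every manifest.

The protocol trains the two-way readout on non-overlapping stimuli
(AdamW, one-cycle max 1e-3 at desk scale, cross-entropy) and evaluates
per overlapping condition. At desk scale the robust signature is the
crowding drop — unflanked accuracy above the one-flanker condition,
checked by sign test over five seeds — not the full parametric
uncrowding rise, which even at full scale appears in only a minority of
converged runs and depends on ImageNet-pretrained backbones.

## Problem sizes and what the tests show

All learning experiments run at desk scale, chosen once: contour trends
use 128-px displays (8x8 grid, quarter-scale Gabor and path parameters),
200 training pairs at beta = 0, 15 epochs, three seeds; uncrowding uses
96-px canvases, 600 training stimuli, 12 epochs, five seeds; the
behavioral simulation uses 50 observers over the full 1,000-pair set.
These sizes demonstrate orderings and procedure correctness (RF ordering
of architectures, alignment sensitivity, jitter degradation, the
crowding drop, exclusion/reliability recovery) — not the published
full-scale accuracies, which required ImageNet-pretrained backbones and
GPU training and are out of scope here. The synthetic observers emulate
the psychometric structure of human data but not sequential effects,
learning, fatigue, or response bias; passing tests therefore validate
the analysis machinery, not claims about human observers.

## Known limitations

- The engine is CPU-only and float64; it is sized for desk-scale
  experiments, not ImageNet training.
- PinholeNet kernel plans are constrained only by the published
  fifth-block RFs; intermediate-layer RF progressions are one valid
  realization.
- Exact flanker spacing in the original uncrowding stimulus code is not
  published; spacing is a documented parameter here.
- The difficulty-offset observer model is one simple mechanism that
  produces reliable trial-level variation; alternatives (e.g.,
  per-observer thresholds, lapse heterogeneity) are supported via
  per-observer `ObserverParams` but not exercised by default.
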