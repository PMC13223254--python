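# Methods

## The descriptor

The adaptive multiscale local mesh ternary pattern characterises texture
by comparing *pairs of circle neighbours* rather than neighbours against
the centre pixel. For each pixel, P = 8 samples are taken at angles
2π(i−1)/8, i = 1…8 (i = 1 due east, counter-clockwise), at radius
R = (w−1)/2 for window w ∈ {3, 7}. Off-grid positions are bilinearly
interpolated; sampling offsets within 1e−9 of an integer are snapped so
the four axis-aligned samples are exact pixel reads. The bilinear weights
are constructed as `w00 = 1 − w01 − w10 − w11`, so they sum to exactly
one in floating point.

Neighbour i is paired with β = 1 + mod(i + P + a − 1, P); the order
a ∈ {1, 2, 3} selects how far around the circle the partner sits. The
difference γ_β − γ_i is quantised to {−1, 0, +1} against the adaptive
threshold T(x, y) = α·σ(x, y) + β₀ with inclusive boundaries (a
difference of exactly ±T is significant). σ is the *population* standard
deviation of the w×w window centred on the pixel, computed from exact
integer sums `(n·Σx² − (Σx)²)/n²` — this makes the descriptor
bit-reproducible and exactly invariant to adding a constant to the image.
The σ window equals the scale window: 3×3 SD at the 3×3 scale, 7×7 SD at
the 7×7 scale.

Two readings of the ternary comparison circulate for mesh patterns:
thresholding the *mesh-pair* differences, or bracketing the *centre*
pixel at centre ± T. The canonical path here thresholds mesh-pair
differences (that is what the pairing rule produces); the centre-bracket
arithmetic is still exposed verbatim through `center_bounds` because it
is the clearest way to illustrate the threshold (σ = 20 → T = 9,
centre 72 → [63, 81]).

The +1 codes pack into an 8-bit "upper" pattern with weights 2^(i−1), the
−1 codes into a "lower" pattern; at T > 0 the two are bitwise exclusive
by construction. Three orders × two polarities = six pattern images per
scale. The per-pattern mean image (`lmtp_visualization`) is provided for
figures only — the feature path keeps the six images separate because
averaging destroys the code histogram. Pattern codes are computed only on
the valid region inset R_max = 3 from every border (shared across scales
so all histograms describe the same pixels); no padding is used inside
the descriptor.

Features are the L1-normalised 256-bin histograms of all six images at
both scales, concatenated in the fixed order (1,up), (1,low), (2,up),
(2,low), (3,up), (3,low), with the 3×3-scale block before the 7×7 block
inside each pair: 6 × 512 = 3072 values. Frequencies (not raw counts)
make images of different sizes comparable; raw counts are available via
a flag.

### Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.2 | threshold gain on local SD; higher suppresses codes in busy regions |
| β₀ | 5 | threshold floor (intensity levels); keeps flat regions from coding noise — 3–10 is typical for 8-bit images |
| windows | 3, 7 | analysis scales; P = 8 and bilinear sampling keep codes 8-bit at both |
| bins | 256 | one bin per possible 8-bit code |

## Preprocessing

CLAHE is implemented in-package: per-tile 256-bin histograms, clipped at
`clip_limit ×` the mean bin height, the excess redistributed uniformly,
tile CDFs mapped to [0, 255] and blended bilinearly between tile centres.
`clip_limit = 2.0` with an 8×8 grid is the default. The tile-less
closed-form alternative (`clahe_mode="minmax"`, a per-tile min–max
stretch) is kept for fidelity experiments because the two formulations
disagree in the literature this design follows; CLAHE proper is the
default since the clip limit is only meaningful there. Gamma correction
uses a 256-entry lookup table of `round(N·(v/N)^0.4)`; sharpening
subtracts the 4-neighbour Laplacian `[[0,1,0],[1,−4,1],[0,1,0]]`
(reflect borders) scaled by `sharpen_strength`. Stage order is CLAHE →
gamma → sharpen; every stage rounds and clamps to [0, 255] at its
boundary so intermediates are valid 8-bit images. The pipeline is
deterministic but deliberately not idempotent.

## Grey Wolf Optimization

Positions live in a continuous box; integer dimensions decode by
rounding, categorical ones by rounding into the category list — this
keeps the update rule identical across mixed spaces. Each iteration the
three fittest wolves (alpha, beta, delta; ties broken by lowest wolf
index) produce one candidate each per wolf via `X' = L − B·E` with
`B = 2a·r₁ − a`, `E = |2r₂·L − X|`; candidates are averaged and clipped
to bounds. The exploration scalar decays linearly `a = 2(1 − t/n_iters)`.
An `alpha_only` mode uses just the best wolf, matching the single-leader
update some formulations print; the three-leader form is the default
because it preserves pack diversity. Budget: `n_wolves × (n_iters + 1)`
fitness evaluations; defaults 10 wolves × 20 iterations are sized for
desk-scale tuning. Runs are reproducible from the seed alone, and the
best-so-far history is non-decreasing by construction.

For classifier tuning the fitness is mean stratified k-fold validation
accuracy computed on the *training split only* (k = 5 by default).
The classifier's default hyperparameters are encoded and seeded into the
initial pack, so the tuned fitness is ≥ the default-configuration
fitness by construction — the with/without-tuning comparison is an
inequality the implementation guarantees.

## Evaluation protocol

80:20 stratified train–test split of original images; augmentation (two
label-preserving geometric variants per original: horizontal flip, +15°
rotation with reflect padding) applies to the training side only. Every
variant records the index of its source original; tuning folds are built
over originals and each fold's training side absorbs exactly the
variants of its own originals, so validation folds and the test set
contain originals only and no variant ever faces its source across a
boundary. Precision, recall (0 with a warning on an empty denominator),
accuracy in percent, per-class confusion counts, and one-vs-rest ROC
staircases are reported; multi-class ROC is one-vs-rest because the
per-class curves are what the protocol plots.

## Synthetic fixtures

Three seeded texture generators stand in for lesion photographs:
`smooth` (Gaussian noise low-passed at σ = 4 px), `speckle` (25%
impulsive salt-and-pepper on a mid-grey field plus mild noise), and
`grating` (an oriented sinusoid, random orientation 30–60° and spatial
frequency 0.25–0.45 rad/px, plus noise). They differ strongly in
second-order statistics, which is exactly what the descriptor measures,
so the demo pipeline (30 images per class at 32×32, 6 wolves × 8
iterations over the random-forest space, 5 tuning folds) reaches ≥ 90%
held-out accuracy — sizes chosen so the whole suite runs in about a
minute on one CPU. What passing shows: every stage composes correctly,
the features separate genuinely different textures, tuning never
degrades the default configuration, and nothing leaks across
train/validation/test boundaries. What it does not show: performance on
real lesion photographs, whose class differences are subtler, correlated
with colour and illumination, and not guaranteed to survive at these
parameter settings; published real-data accuracies require the original
datasets and are out of scope.

## Numerical conventions and edge cases

- All descriptor arithmetic is float64 after exact-integer window sums;
  features are deterministic across runs and platforms.
- Ternary boundaries inclusive; precision/recall return 0 with a warning
  on 0/0; CLAHE on a constant image returns a (possibly shifted) constant.
- Grayscale conversion is BT.601 luminance (0.299 R + 0.587 G + 0.114 B),
  rounded; PNG is used for all written intermediates (lossless), JPEG is
  read-only.
- Images must be at least 7×7 (descriptor support) and fixtures at least
  16×16; undersized inputs raise immediately.
- The MLP adapter defaults to 10 hidden layers of a tunable width, with
  small widths intended at desk scale.

## Known limitations

- No rotation-invariant or uniform-pattern code mappings; codes change
  under image rotation (the augmentation relies on histograms being only
  mildly affected).
- Scales are fixed to those configured; no automatic scale selection.
- The GWO pack size, iteration count and search-space bounds are package
  defaults, not values inherited from any reference experiment.
- No segmentation or colour features: the pipeline assumes the lesion
  dominates the frame, as its source protocol does.
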