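# Methods

This note documents the models, geometry, defaults and numerical choices
behind `discsal`, and what the synthetic setting does and does not show.

## Sector geometry

The optic disc is partitioned into six angular sectors plus background.
Angles are measured from the temporal horizontal axis of the disc,
increasing toward superior, so one scheme serves both eyes; for a right
eye (OD) the temporal side of a disc-centered image is the left side of
the frame (the fovea lies temporal to the disc), and a left eye (OS) is
the exact horizontal mirror. The default spans follow the standard
clinical sectorization used in glaucoma imaging:

| sector | span (deg) | width |
|--------|-----------|-------|
| T  | [315, 45)  | 90  |
| TS | [45, 85)   | 40  |
| NS | [85, 125)  | 40  |
| N  | [125, 235) | 110 |
| NI | [235, 275) | 40  |
| TI | [275, 315) | 40  |

An equal-60° alternative (`SectorScheme.equal_sixths`) is selectable.
Each disc pixel is assigned by the angle of its raster offset to the
disc-ellipse center (no ellipse-axis normalization; synthetic discs are
near-circular). Arcs are half-open so the tiling is pixel-exact:
sector masks are pairwise disjoint and, with B = the disc complement,
cover every pixel. Pixel centers sit at integer (row, col) coordinates;
signed zeros in the offset are normalized so the disc-center pixel lands
deterministically in T. Sectors span the whole disc including the cup
(rim-only masks are available via `rim_only=True`).

## Discretization

A saliency map is thresholded at `tau = 0.75` of its maximum; the
maximizing pixel is always retained, so the mask is never empty even
when the maximum is negative. A constant map keeps every pixel and emits
a warning (the thresholding rule admits it; downstream scores then equal
sector area fractions). The sector score is the fraction of retained
pixels inside each sector, so scores sum to 1 and are invariant under
any positive rescaling of the map.

## The toy classifier

Full-scale transfer-learned CNNs are out of scope; the attribution
methods instead run against a compact numpy network satisfying the same
differentiable-model contract:

- three strided 3×3 conv + ReLU blocks (8, 16, 32 channels, stride 2),
  global average pooling, a 2-class dense head; float64 throughout;
- inputs are centered by −0.5 inside the network. All-positive pixel
  intensities otherwise make optimization ill-conditioned (training
  sporadically collapses to one class); the offset has derivative 1 and
  changes no input gradient;
- the CAM layer is the post-activation output of the last conv block
  (8×8 at the default 64×64 input). Three blocks rather than two keep
  randomly initialized copies from producing degenerately smooth
  saliency, while a fourth block would shrink the CAM layer to 4×4 and
  rob GradCAM of spatial meaning;
- training: Adam (lr 1e-2, batch 32, 120 epochs, seeded shuffling),
  categorical cross-entropy. On the default separable task this reaches
  training balanced accuracy ≥ 0.99 across seeds;
- the adapter exposes `predict` (logit and probability views),
  `input_gradient` (optionally with the guided-ReLU backward rule),
  `cam_layer_activations` / `cam_layer_gradients`, and seeded
  `reinitialize`. Input gradients are verified against central finite
  differences at rtol 1e-3 in the test suite.

## Attribution methods

All nine methods explain the predicted class (argmax of the logits),
whether or not that prediction is correct. Defaults, each exposed in
`SaliencyConfig`:

- **score target**: the pre-softmax logit of the predicted class
  (probability view available). Logits avoid vanishing gradients at
  saturated softmax outputs;
- **channel reduction** (gradient-family methods): max of absolute
  values over the three color channels, applied last; `mean_abs` and
  `sum_then_abs` cover the signed reading;
- **SmoothGrad family**: N = 25 noise samples, Gaussian sd = 0.15 × the
  input's dynamic range (the method's original recommendation); mean,
  squared-mean and variance aggregation give SGrad, SGrad2 and VGrad.
  At zero noise one evaluation is used, so SGrad is then exactly the
  plain gradient; VGrad at N = 1 is identically zero (with a warning);
- **Integrated Gradients**: black baseline, 50 steps, midpoint-rule
  Riemann sum; signed per-channel attributions are kept for the
  completeness check (≤ 1% error at 256 steps on the toy model) before
  channel reduction;
- **Occlusion**: square patch of ⌈min(H, W)/14⌉ px (5 px at 64×64),
  stride ⌈patch/2⌉ with a tail window so every pixel is covered, fill =
  the image's mean intensity; a pixel's value is the mean of
  score(original) − score(occluded) over all windows covering it;
- **GradCAM**: channel weights are the spatial mean of CAM-layer
  gradients; the map is ReLU of the weighted activation sum at native
  resolution, bilinearly upsampled for sector alignment (nearest
  selectable; the native map is preserved on the result);
- **ScoreCAM**: each activation map is min-max normalized, upsampled,
  and used to modulate the input; the predicted-class score of the
  masked input is that channel's weight. Constant activation maps are
  skipped with a warning (their normalization is undefined — common for
  dead ReLU channels).

## Agreement and sanity checks

Discrete maps over a fixed image list are flattened image-by-image in
canonical (N, NI, TI, T, TS, NS, B) order — 148 images give a
1036-element vector — and compared with Spearman's rank correlation
(average ranks for ties, large-sample two-sided p; constant vectors
return NaN with a warning; no multiple-testing correction, matching how
such correlations are conventionally reported raw). The parameter
randomization test compares a trained model against freshly
reinitialized copies (default 5 replicates, one init each, seeded); low
|ρ| is the desired outcome. The label randomization test retrains the
same architecture after flipping 50% of the training labels; a method
is flagged for discard when its median |ρ| reaches 0.5. Guided Backprop
and ScoreCAM are excluded from default analysis lists on this basis but
remain computable.

## Synthetic data

The generator emulates the structure that drives disc photography:
low-frequency orange-red textured background, a brighter disc ellipse,
a brightest cup ellipse, optional dark curvilinear vessels radiating
from the disc center, and pixel noise — preserving the intensity
ordering cup > disc > background of real retinographs. Defaults:
64×64 disc-centered frame with ±2 px center jitter, disc radius
13–17 px, healthy CDR 0.3–0.5, glaucoma CDR 0.6–0.8, texture noise sd
0.02, 3 vessels, OS probability 0.5. Target CDRs are drawn from the
configured interval shrunk by a 0.01 rasterization margin, and the cup
scale is bisected so the mask-measured CDR — defined as
√(cup area / disc area), far less quantization-sensitive than
extent-based diameters — lands inside the configured band for every
sample. Sectoral rim loss is modeled by displacing the cup center
toward the chosen sector's mid-angle by strength × (disc radius − cup
radius), applied to glaucomatous samples; the cup mask is intersected
with the disc mask so containment holds pixel-exactly. An OS sample is
the exact horizontal mirror of the OD sample generated from the same
seed. Every operation is a pure function of (config, seed).

## Desk-scale experiments and their limits

Two library-level experiments validate the pipeline end to end:

- **planted-signal recovery**: with identical CDR ranges in both
  classes and TI rim loss (strength 0.9) as the only difference, the
  occlusion method's global relevance for glaucoma-predicted images is
  modal in TI. Training uses 100 images/class: with substantially fewer
  the ~10k-parameter net memorizes texture noise (perfect training,
  chance test accuracy) and the question of *where a trained model
  looks* becomes vacuous. Problem sizes (100+100 train, 30+30 test)
  keep one replicate around half a minute on one CPU.
- **parameter-randomization ceiling**: 50 images/class training,
  75/class (150) test images, 5 reinitialized replicates, 7 retained
  methods. On clinical data this trained-vs-untrained agreement is
  reported to stay within about ±0.25; on the synthetic fixtures it
  does not, and the package reports the honest value (≈0.49 at seed 1).
  The cause is a known limit of the synthetic setting, not of the
  metric: synthetic test images are structurally homogeneous (one
  disc/cup complex, few vessels), so an untrained network's
  top-quartile pixels land in a consistent region across *all* images
  and each replicate's pooled 1050-element correlation degenerates to a
  single heavy-tailed draw — the alignment between two nearly constant
  per-image sector profiles — instead of averaging over the per-image
  variation that heterogeneous clinical photographs provide. The
  trained model's profile is close to the in-disc area profile (its
  signal is the whole cup boundary), so random copies that concentrate
  in-disc correlate positively and background-concentrating ones
  negatively, with |ρ| far above what per-image-varying maps would
  give.

More generally, passing tests on these fixtures demonstrate the
*metric machinery* — exact discretization, geometry, vectorization,
agreement statistics, recoverability of a planted localized signal —
not photorealism: real fundus images add vessel trees, peripapillary
atrophy, illumination gradients and annotation noise that no ellipse
model reproduces, and real CNNs attend to background texture in ways
the toy classifier, trained on clean separable signal, does not.
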