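# Methods

`beakid` implements an automated species-identification pipeline for
cephalopod beaks photographed in left-lateral view on a white lightbox.
Its stages are: (synthetic) image generation, preprocessing and
segmentation, feature extraction (grey/colour HOG, ten morphological shape
descriptors, deep-feature adapters), classification with eight configured
learners, and repeated stratified shuffle-split evaluation with
precision–recall reporting.  This note records the models, the parameter
choices that matter, the numerical decisions, and the limits of what the
synthetic experiments demonstrate.

## Synthetic beak photographs

Real material consists of single dark, hook-shaped chitinous silhouettes on
a near-white lightbox, photographed at 5312×2988 px.  The generator
(`beakid.synthetic`) emulates exactly that structure:

- **Silhouette.**  A closed hooked-crescent polygon built from four cubic
  Bézier arcs — dorsal hood dome, hooked rostrum, concave crescent notch,
  ventral wing lobe — parameterised per species by `rostrum_curvature`,
  `hood_to_wing_ratio` (the main driver of the silhouette aspect ratio),
  and `wing_length_frac`.  The upper beak is the dorsoventral mirror of the
  lower-beak construction.
- **Pigmentation.**  Chitin is darkest at the rostrum: grey level
  `base_darkness + darkness_gradient × (distance from rostrum tip /
  beak length)`, modulated by a per-species RGB tint (`tint_rgb`).  The
  tint is species-specific because chitin hue varies with the species'
  darkening stage, so colour descriptors see structure a single grey
  channel does not.
- **Background.**  A lightbox level drawn per image from
  `background_level_range` (default 244–252), plus Gaussian sensor noise
  (`noise_sd`, default 3 grey levels), clipped to the configured range.
  Object channels are clipped at 235, so min(background grey) ≥ 240 >
  max(object grey) by construction and grey-level thresholding at 240
  recovers the true mask exactly.
- **Placement.**  Beak length is drawn from the species' `size_mm_range`
  and converted to pixels through a fixed 160 mm lightbox field of view;
  placement jitters by ±3% of the frame and rotation by a 2° s.d. normal —
  samples are hand-placed but roughly aligned, as in a lightbox protocol.
- **Cohort.**  `default_study_config()` reproduces the study cohort: 174
  samples over 7 species — four squids (24 each), two cuttlefish (25 + 24;
  per-species numbers within a taxon are not published, so taxon totals are
  split evenly with the odd sample assigned to *Sepia aculeata*), one
  octopus (29).
- **Determinism.**  Every image draws from a seed derived from
  `(config.seed, species index, sample index)` via `SeedSequence`;
  identical configs produce byte-identical PNGs and manifest CSVs.  PNG is
  the default output (lossless); JPEG with configurable quality is
  available to mimic the original capture format.

**What the generator does not emulate:** photographic perspective, shadows
and specular highlights, erosion of beak material, intra-species shape
allometry, occlusions, or manual cropping artefacts.  Synthetic species
are far better separated than real congeners — end-to-end accuracies near
1.0 here say the pipeline wiring is correct, not that real beaks are this
easy (the original study reports 73% for the same traditional-feature
configuration).

## Preprocessing and segmentation

Photographs are downscaled bilinearly to 10% (round-half-up per
dimension: 5312×2988 → 531×299), Gaussian-smoothed (σ = 1 px, radius 3σ —
conventional light denoising; the original work does not state σ),
converted to grey by the luma weights Y = 0.299 R + 0.587 G + 0.114 B
(kept in floating point), and thresholded at grey level 240.  Both
threshold polarities are implemented: `dark` (object below threshold) is
the default because a dark beak on a bright lightbox lies below 240;
`bright` matches the printed orientation of the original protocol
description verbatim.  Object pixels are 8-connected; one closed outer
contour per component is traced at the half-level crossing (sub-pixel,
holes ignored), and the region of interest is the largest contour passing
`min_area` (default 100 px²), with areas by the shoelace formula.

**Contour regularisation.**  A marching-squares trace of a digitised
smooth boundary carries staircase ripple that inflates arc length by ~6%
(a digitised disc would read form factor 0.89 instead of 1).
`smooth_contour` resamples the closed polygon at ~1 px arc spacing and
applies a periodic Gaussian (σ = 2 px) to the coordinate sequences; a
digitised disc then measures form factor 0.998.  The raw trace is kept as
the output of `extract_contours` so that filling a traced contour
reproduces its component exactly; the pipeline applies the regularisation
only where metric measurements are taken (before MSD extraction).
Contours shorter than 16 px are left untouched.

## HOG descriptors

Gradients are centred differences with the (−1, 0, 1) kernel and
replicated borders; magnitude |G| = √(Gx² + Gy²).  Orientation is the
unsigned angle of (Gx, Gy) folded to [0°, 180°).  The protocol description
prints the orientation ratio transposed (arctan Gx/Gy); the standard
convention is the default and `as_printed_orientation=True` reproduces the
printed form.  Cells are 128×128 px (partial edge cells dropped), 9 bins
at 0°, 20°, …, 160°; each pixel votes its magnitude, split linearly
between the two nearest bin centres, circularly over 180° (hard
assignment available).  2×2-cell blocks slide with stride one cell; each
36-vector is L2-normalised (zero blocks pass through — block
normalisation is not described in the original protocol, but without it
the hybrid concatenation scales are arbitrary) and blocks concatenate
row-major.  At the 532×299 working resolution this yields a 4×2 cell
grid, 3 blocks, and 108 features.  Colour HOG computes gradients per RGB
channel and lets the channel with the largest magnitude at each pixel
supply the vote (ties to the lowest channel index), so its length equals
the grey variant's.  A note on the dominant-channel rule: on a flat noisy
background the maximum of three channel magnitudes is noisier than the
channel-averaged grey gradient, so on synthetic data colour HOG is not
automatically stronger than grey HOG.

## Morphological shape descriptors

Ten scalars from the ROI contour polygon (sub-pixel geometry, not pixel
counts — this removes connectivity ambiguity from the formulas; a
pixel-count cross-check path exists in tests via component areas):
area, perimeter, aspect ratio (axis-aligned bounding-box w/h), extent,
solidity, equivalent diameter, circularity (4π·area / convex-perimeter²),
rectangularity, form factor (4π·area / perimeter²), narrow factor
(equivalent diameter / box height).  Two deliberate fidelity choices:

- **Equivalent diameter** follows the printed formula (4·area)/π, which is
  4r² for a disc of radius r (px² units), not the conventional
  √(4·area/π); `standard_equivalent_diameter=True` switches to the square
  root (narrow factor follows).
- **Rectangularity** as printed, (w×h)/bounding-box-area, is identically 1
  for an axis-aligned box; it is therefore computed as
  area/bounding-box-area and so coincides with extent.  Both entries are
  kept so the vector stays ten-dimensional as published.

The hybrid descriptor concatenates HOG first, then the MSD block:
108 + 10 = 118 features.

## Deep-feature adapters

Three backbone geometries: vgg19 (224×224 input, 4096 features, second
fully connected layer), inceptionv3 (299×299, 2048, global average pool),
resnet50 (224×224, 2048, global average pool) — the only standard tap
points that produce those dimensionalities.  Shared preprocessing:
bilinear resize to the square input, subtraction of the conventional
ImageNet channel means (123.68, 116.779, 103.939).  The default `random`
weights mode instantiates a seeded random-feature map (average-pool to
32×32×3, fixed Gaussian projection, rectified-linear) with the backbone's
exact input/output geometry: deterministic, offline, and sufficient for
shape/determinism/plumbing guarantees, but carrying no learned semantics —
accuracy claims require `pretrained` weights, which need torchvision and
downloaded checkpoints and raise a named `BackboneUnavailableError`
otherwise.

## Classifiers

Eight learners behind one train/score contract, configured with the
published hyperparameters (see `classify.DEFAULT_HYPERPARAMETERS`); all
other settings are scikit-learn defaults.  Choices the publication leaves
open: features are z-score standardised by default (fitted on training
rows only; ANN/SVM/kNN are scale-sensitive), the ANN uses rectified-linear
hidden units with the adam optimiser ("stochastic gradient-based"), and
the SVM's PR scores are one-vs-one vote shares min-max normalised per row
(no probability calibration is described, so none is added).  The LDA
configuration lists a `C` it cannot use; it is ignored with a warning.
Hard labels are the score argmax with ties to the lowest class index.

## Evaluation protocol

"Five-fold cross-validation stratified shuffle split, tested 10 times" is
read as 5 independent stratified 80/20 shuffle splits per run × 10 runs =
50 fits (shuffle splits are not partitions, so a literal 5-fold partition
reading is impossible).  Stratification allocates the total test size
(round-half-up of 0.2 n) across classes by largest-remainder rounding of
class_count × 0.2 (ties: larger class, then label order); every class's
test share is within one sample of 20% on every fold.  For the 174-sample
cohort the test set is 35 samples.  Fold f of run r is seeded
`base_seed + 1000 r + f`.  Every fold trains a fresh model: stochastic
learners (ANN, RF, DT) re-initialise per fold with a seed derived
deterministically from the classifier seed plus the fold counter, so the
reported mean averages over independent initialisations while the whole
experiment stays reproducible from one number.  Metrics per fold: confusion matrix, accuracy
(trace/total), one-vs-rest precision/recall per class (zero denominators
return 0 with a degenerate flag), and per-class PR curves summarised by
average precision (step-wise summation; linear PR interpolation is known
to be optimistic).  Accuracy aggregates as mean ± sd (sample sd, ddof 1)
over all 50 folds; the publication does not state whether its ±
dispersion is over folds or runs, so over-all-folds is used and reports
state the unit (proportions, not percent).  Per-class AUCs macro-average.

## Pipeline seeds and problem sizes

One global seed fans out with fixed offsets: synthetic data +0, classifier
+1, split plan +2, deep adapter +3.  Tests and the end-to-end checks run
the full 174-sample cohort at a reduced raster (1064×598 originals,
rescale factor 0.5), which lands on the same 532×299 working resolution —
and hence the same descriptor geometry — as 10% of the native 5312×2988.

## Known limitations

- Synthetic separability is optimistic; passing end-to-end checks
  validates plumbing and protocol, not field performance.  All traditional
  descriptors score near ceiling on the synthetic cohort, so
  descriptor-to-descriptor differences there are small and say little
  about their relative merit on real photographs.
- Random-weight deep features are placeholders for architecture plumbing;
  they are weaker descriptors than HOG/MSD on the synthetic cohort.
- The published per-descriptor accuracies are not reproduction targets:
  they depend on the real photographs and pretrained weights.
- MSD values depend mildly on the contour-regularisation σ; σ = 2 px is
  calibrated on analytic shapes (disc, rectangle), not fitted to data.
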