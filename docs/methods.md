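# Methods

## The screening model

The pipeline is a two-stage composite. Stage one is per-gland instance
segmentation: a model emits, per slide, polygons in slide pixel
coordinates, each with one of seven histological categories (benign
glands; adenocarcinoma or high-grade dysplasia; low-grade dysplasia;
blood vessels; necrosis; mucin; inflammation) and a per-object prediction
certainty in [0, 1]. Stage two aggregates those objects into four
slide-level features and classifies the slide high/low risk with a
gradient-boosted decision-tree model. The two high-risk categories are
adenocarcinoma/high-grade dysplasia and low-grade dysplasia; this set is
configurable (`FeatureConfig.high_risk_categories`) so the stricter
malignancy-only reading is one config change.

The deep segmentation network itself is deliberately out of scope: stage
one is a *contract* (`SegmentationBackend`), and the reference backend is
an oracle that corrupts ground-truth annotations. This replaces an
unavailable trained network with a component whose error structure is
fully controllable, which is exactly what the downstream stages need for
testing: with corruption switched off the pipeline must reproduce
truth-derived features exactly, and with calibrated corruption it must
still recover the slide labels.

## Tissue masking and tiling

Tissue is separated from glass by HSV saturation and brightness: a pixel
is tissue if its saturation exceeds an Otsu threshold (stained tissue is
colourful) or its brightness falls below 0.92 (clearly darker than
background). On images whose saturation is near-constant, where Otsu is
undefined, a fixed 0.15 saturation threshold is used so all-glass and
all-tissue images behave sensibly. Connected components smaller than
`min_object_px` (default 64) are removed as debris. No heuristic of this
kind is canonical; this one is standard whitespace behaviour for H&E and
is validated against the generator's known tissue blob (Jaccard ≥ 0.9).

The tile grid is 775 × 522 px, anchored at the image origin with 0-based
half-open extents; partial tiles at the right/bottom edges are dropped
because downstream consumers need fixed-size tiles. "Contains no tissue"
is read strictly: a tile is kept iff its tissue fraction is > 0 (the
threshold is exposed as `min_tissue_fraction` for practical use). The
90/5/5 partition uses the rounding rule `n_train = floor(0.9·N)`, with
the remainder split ceil/floor between the selection and final sets —
the unique simple rule that maps 73,546 items to 66,191 / 3,678 / 3,677.
Membership is a seeded uniform permutation, so sizes are seed-invariant.

## Augmentations

All seven augmentations are applied jointly per image, in a fixed order
(rotation, mirror, contrast, brightness, H&E colour, noise, blur), each
with a freshly sampled parameter; rotation and mirror may sample the
identity. Parameters: rotations {0°, 90°, 180°, 270°} equiprobable
(clockwise convention); mirror {left-right, top-bottom, none};
contrast/brightness multiplicative factors uniform on [0.7, 1.3]
(contrast scales deviations from the per-image mean intensity);
H&E concentration deltas uniform on [−0.05, 0.05], sampled once per image
per channel; additive Gaussian noise with σ = 0.1 on the normalized
intensity scale, iid per pixel and channel; Gaussian blur with "radius"
interpreted as the kernel standard deviation in pixels, 0.1 by default
(a near-identity, consistent with "slightly out of focus").

The colour augmentation uses the Beer–Lambert optical-density transform
`OD = −log10((p + ε)/I0)` with ε = 10⁻⁶ and I0 = 1 on the normalized
scale, projected onto the Ruifrok–Johnston H&E stain vectors completed
with an orthogonal residual direction — the de facto standard basis when
no slide-specific stain matrix is available. One numerical subtlety:
arbitrary RGB colours can project to slightly negative stain
concentrations (they are not physical H&E mixtures). The augmentation
therefore floors each shifted concentration at `min(original, 0)` rather
than at 0 — the shift can never push a concentration below blank glass,
but pixels that start negative pass through unchanged, keeping the
δ = 0 case an exact round-trip identity on every input.

## The oracle segmentation backend

`OracleCorruption` specifies: a 7 × 7 row-stochastic label-flip matrix
(row = true category, column = predicted), a per-annotation drop
probability, a Poisson rate of spurious high-risk objects placed at
random tissue pixels, and certainty laws — constants or Beta(α, β) —
keyed by (predicted category, whether the prediction matches truth).
Object polygons are taken from the annotations unperturbed; the oracle
corrupts labels and confidences, not geometry. All draws come from a
stream keyed by (seed, slide id), so per-slide outputs are reproducible
in isolation.

## Synthetic slides

Each slide is a near-white canvas (0.97 gray) with one pale-pink
elliptical tissue blob (~44% of each image dimension, jittered) on which
gland-like ellipses are placed by rejection sampling (≤ 100 attempts,
non-overlapping, fully inside the blob) and filled with fixed
per-category colours. Defaults: 2325 × 1566 px (a 3 × 3 grid of
775 × 522 tiles) at 4.0 µm/px (so 0.1 mm² = 6250 px); Poisson(12) glands
on high-risk slides and Poisson(10) on low-risk ones; log-normal gland
areas with median 0.12 mm²; high-risk prevalence 0.5. Low-risk slides
draw categories from a mixture with zero mass on the two high-risk
categories, so the label bookkeeping invariant (high risk ⇔ at least one
high-risk region) holds by construction; high-risk slides are forced to
place at least one high-risk gland, shrinking it if placement fails.

The simulated segmentation attached to each slide is produced by the
oracle under a default corruption that encodes the study conditions:
benign glands are mislabelled as a high-risk category with probability
0.3 (split evenly between the two), correct high-risk detections draw
certainty from Beta(16, 2) (mean ≈ 0.89) and incorrect ones from
Beta(2, 8) (mean 0.2), all other objects from Beta(6, 3). The
configuration surface keys certainties by (true slide label, category)
in effect: because low-risk slides contain no true high-risk glands, a
single corruption model keyed by (predicted category, correctness)
realizes exactly the intended per-label laws, without the oracle ever
seeing the slide label. This yields cohorts that are clearly but not
perfectly separable — low-risk slides usually carry a few low-certainty
false high-risk objects, and roughly one in ten carries none at all.

What the generator does *not* emulate: nuclei-level texture, staining
variability, scanner artifacts, pyramid/multi-resolution formats, or
annotation noise in the polygons themselves. Passing recovery tests
therefore demonstrates that the aggregation + classification machinery
recovers labels from segmentations with the modelled error structure;
it says nothing about segmentation accuracy on real tissue.

## Features, classifier, evaluation

Feature definitions and conventions, where the verbal definitions are
ambiguous, were resolved as follows: the > 70% certainty filter applies
only to the area feature (the weighted mean and percentile use all
high-risk objects); the 0.1 mm² flag area is cumulative over qualifying
objects, not per object; the tissue denominator is the tissue-mask area,
not the sum of object areas; the weighted percentile is the
left-continuous inverse CDF without interpolation (parameter-free and
reproducible), cross-checked against a replicate-expansion oracle. All
four features are exactly 0 for slides without high-risk objects. Tile
labelling uses the "any amount" rule: any positive-area overlap of the
half-open tile extent with a high-risk geometry makes the tile high risk.

The classifier is scikit-learn's `GradientBoostingClassifier`, grid
searched over trees {50, 200} × depth {2, 3} × learning rate
{0.1, 0.3} × min leaf {1, 5} — a small grid is appropriate for a
4-feature space — with stratified fivefold CV accuracy as the selection
metric (stratification avoids degenerate folds on imbalanced cohorts).
Ties break towards fewer, then shallower trees. The decision rule is
`P(high) ≥ threshold` with the boundary inclusive; the default 0.7
favours sensitivity. Models persist to versioned JSON (trees as nested
split records) and a pure-numpy predictor reproduces the library's
probabilities exactly, so saved models are platform-portable.

Evaluation treats high risk as the positive class. Rates with an empty
denominator are reported as missing, never coerced to 0. The ROC sweeps
all distinct scores as thresholds, grouping ties, and the trapezoid AUC
then equals the pairwise concordance statistic with ties counted ½ — the
two routes are required to agree to 10⁻¹² in tests. AUC is always
reported on the [0, 1] scale.

## Problem sizes and determinism

The pipeline's default cohorts are 105 resection-like training slides
and 150 biopsy-like validation slides (biopsy-like = tissue blob scaled
to 0.6); recovery experiments in the test suite and acceptance script
use 300 training / 150 validation slides at full slide geometry, which
completes in a few minutes on one CPU. Miniature geometries (e.g.
320 × 240 px slides with proportionally small glands) are used for tests
of size-free properties such as label bookkeeping and seeded
determinism. One global seed derives per-stage streams (CRC-keyed), and
identical configurations yield byte-identical artifacts, down to the
PNG encoder.

## Known limitations

* The tissue heuristic is tuned for H&E-like colour statistics; slides
  with faint stain or heavy artifacts would need the thresholds exposed
  in `TilingSpec`.
* The oracle backend cannot surface failure modes a real detector has
  (geometry errors, merged/split instances, confidence miscalibration
  correlated with morphology).
* Classifier probabilities are uncalibrated; the decision threshold is
  an operating point, not a posterior.
* Only flat rasters with an mpp sidecar are ingested; vendor WSI pyramid
  formats are out of scope.
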