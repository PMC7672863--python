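# Methods

## The model

A pain drawing is treated as a binary vector x over a fixed pixel canvas
(1 = the patient marked that pixel).  A disease's *pain profile* is the
arithmetic mean P of all binary drawings from that disease; its cells are
exact rationals (stored as an integer count grid over the contributor
count), so a pixel marked by 7 of 10 patients is exactly 0.7.

Similarity between a drawing and a profile uses the Ružička coefficient

    R(x, P) = Σ min(xᵢ, Pᵢ) / Σ max(xᵢ, Pᵢ),

the standard continuous extension of the Jaccard index: on two binary
inputs it is |intersection| / |union| exactly (property-tested against a
set-based oracle).  The source study names the coefficient without
printing a formula; this definition is the one standard in the similarity
literature and is adopted here.  A normalized score

    s = R(x, P_A) / (R(x, P_A) + R(x, P_B))

is thresholded at a cut-off (default 0.5; s ≥ cutoff predicts disease A).
Two deliberate conventions: the tie s = cutoff predicts A (some rule is
required; this one is deterministic and documented), and a drawing with
both similarities zero scores 0.5 with a warning.  Pixels outside the body
outlines participate in the sums like any others (no clipping by default;
`clip_to_body` is available).

Evaluation is leave-one-out: each drawing is scored against profiles from
which it has been removed (implemented incrementally as count-grid
subtraction, which equals recomputation exactly and is asserted so in
tests).  Excluded drawings contribute to no profile and receive no score.

## Classifier evaluation

* Confusion matrix with EDS as the positive class, so sensitivity = 51/59
  and specificity = 28/29 on the published table.
* Fisher's exact test, two-sided by the "tables no more probable than
  observed" rule (scipy's convention, matching R's `fisher.test`); tested
  against exhaustive hypergeometric enumeration over all tables at the
  observed margins.
* ROC over all distinct score thresholds (call positive when score ≥ t,
  the same tie rule the classifier uses) plus sentinels; AUC by the
  Mann-Whitney pairwise identity with ties counted ½, tested against the
  brute-force pairwise estimator and scikit-learn.
* AUC confidence interval: stratified nonparametric bootstrap (resampling
  within each class, sizes preserved), percentile interval, 2000
  replicates at level 0.95, seeded.  Stratification makes one-class
  resamples impossible.
* "Optimal" cut-off: the threshold maximizing Youden's J, reported as the
  midpoint between adjacent distinct scores, the default criterion of the
  common ROC packages.

## The drawing sheet

The original printed sheet is replaced by a stylized programmatic template
with the same structural features: anterior and posterior humanoid
silhouettes, two lateral profiles, magnified panels for both hands (palmar
and dorsal), both feet (dorsal and plantar) and the head, and four solid
black calibration bars near the corners.  Nineteen named anatomical
regions (spine-with-neck, tailbone, knees front/back, shoulders, elbows,
thumb saddle joints, umbilical, groin, ankles, hand/finger joints,
metatarsophalangeal, heel, dorsal/plantar foot, palmar fingertips, left
and right dorsal palm, lower leg) are polygon patches inside those
outlines.  Geometry is defined in canvas fractions and scaled to pixels
(default 1200×900 portrait, 2 px line width), so a canvas override
rescales everything; coordinates are 0-based row-major with origin at the
top-left and pixel-center sampling.

Two geometric guarantees are engineered in and verified by tests: regions
are pairwise disjoint and strictly inside the body outlines, and every
region keeps ≥ 7 px clearance from any printed outline at the default
canvas so that template subtraction (below) cannot eat into marked areas.
The bars sit ≥ 45 px from the canvas edges — the supported distortion
budget (±10 px shift, ±3° rotation) cannot push them off the page — and
the printed content keeps enough vertical clearance that each bar's
detection window contains nothing else.

## Synthetic cohorts

Each subject's mask is sampled by including each region independently with
a disease-specific Bernoulli probability; the defaults are the midpoints
of the published per-region frequency bands (EDS: spine/tailbone/knees
0.70, shoulders/elbows/thumb saddle 0.45, seven further joint regions
0.35; GBS: dorsal/plantar feet 0.65, palmar fingertips and tailbone 0.45,
left dorsal palm 0.30, right dorsal palm and thumb saddle 0.25; unlisted
regions 0).  Midpoints are the unbiased point choice given only bands;
tables are overridable in the config.  One documented source discrepancy:
the study's summary table gives GBS lower legs 0% while its running text
mentions the lower legs among 40–50% regions; the table value (0) is
followed here.  Cohort sizes default to the study's 60 EDS + 32 GBS.

Regions are sampled independently because only marginal frequencies are
published; no co-occurrence structure is modeled.  A per-drawing stroke
jitter (±1 px dilation/erosion) emulates pen-width variability.  Empty
sampled masks are kept but flagged, and later excluded by the quality
check — mirroring the study's unexplained attrition (60 collected vs 59
classified EDS; 32 vs 29 GBS) without claiming its cause.

Scans are rendered by compositing the mask in black over the printed
sheet, rotating about the canvas center and shifting by amounts drawn
uniformly within the noise model (defaults ±10 px, ±3°), then flipping a
fraction of pixels to black (default speckle density 5×10⁻⁴).  The true
transform is recorded for round-trip testing.

**What passing the synthetic benchmark shows.**  The generator produces
region-aligned, sharply bounded marks; real drawings have free-hand
strokes, partial region coverage, intensity variation and correlated
marking behaviour.  The synthetic EDS/GBS patterns share only two regions
(tailbone, thumb saddle), so the two synthetic diseases are almost
linearly separable and the leave-one-out classifier reaches accuracy and
AUC near 1.0 — comfortably above the acceptance floor (accuracy ≥ 0.85,
AUC ≥ 0.90) but *not* a reproduction of the study's AUC 0.954, CI
0.887–0.996, or best cut-off 0.532 (sensitivity 94.9% / specificity
89.7%): those depend on the undeposited per-patient drawings and are
documented as non-reproducible.  What the benchmark does establish is
that digitization, profile averaging, similarity scoring, cross-validation
and ROC machinery are each correct (they are also tested against
independent oracles) and that the full chain preserves the generator's
statistical structure.

## Preprocessing

1. **Bar detection** — around each expected bar box, a window (box dilated
   by 5.5% of the canvas height) is thresholded at intensity < 128;
   connected components smaller than 30% of the printed bar's area are
   ignored (speckle immunity) and the component whose centroid is nearest
   the expected center wins; its center of mass is the sub-pixel centroid.
   A missing bar raises a calibration error naming the bar.  Scans whose
   dimensions differ from the canvas by ≤ 10% are bilinearly rescaled
   first (scanner DPI is not assumed).
2. **Rigid fit** — closed-form least-squares rotation + translation (SVD /
   Kabsch, no scaling) mapping expected bar centers onto detected
   centroids; RMS residual above 3 px raises a calibration-quality error.
   Rotation is reported about the expected-bar centroid; with the default
   symmetric bar layout this coincides with the canvas center to within
   half a pixel.
3. **Template subtraction** — the scan is resampled to the template frame
   by the inverse fitted transform (bilinear); pixels under the printed
   content dilated by line_width + 1 (absorbing sub-pixel registration
   error) are cleared; the remainder is thresholded at < 128 of 255 and
   connected components under 9 px are removed.  Subtraction never adds
   ink.  The binarization threshold and component-area minimum are config
   values; "standard image processing" is all the source specifies.
4. **Quality check** — drawings with < 5 px marked are flagged
   `empty_after_preprocessing` and excluded downstream.

Round-trip performance at the default canvas (measured by the acceptance
run): zero-noise recovery is exact (Dice 1.0), and under the full default
noise budget mean Dice ≈ 0.997 with mean transform error ≈ 0.04 px /
0.005°, against required floors of 0.95 / 1 px / 0.5°.  At strongly
reduced resolutions the fixed-pixel clearing margin grows relative to limb
width and recovery degrades — the third-scale canvas used in fast unit
tests is below the guaranteed regime, which is why the round-trip
contracts are stated at the default resolution.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through numpy
Generators; cohorts, bootstrap intervals and the full pipeline are
bit-reproducible at a fixed seed.  The shipped study-scale runs use the
full 1200×900 canvas with 60 + 32 subjects (seconds to tens of seconds on
one CPU); statistical law-recovery tests use 500 samples at a third-scale
canvas, where the ±0.06 tolerance is the binomial 99% envelope.

## Known limitations

* Profiles are binary-mask averages; pen pressure / intensity is not
  modeled, matching the marked/unmarked semantics of the source method.
* Only the two-disease classifier is implemented; k-disease extension is
  out of scope.
* The colormap for profile rendering fixes RGB anchors (white → blue
  gradient below the 50% mark, green at 50% within half a count step,
  yellow → red above); the published figures specify band semantics, not
  exact colors, and the 50% band width is an artifact choice.
* The source study reports one internal inconsistency (its methods text
  says 49/59 EDS correct, its confusion table 51/59); the table is taken
  as authoritative throughout.
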