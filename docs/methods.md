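# Methods

This note records the measurement conventions, the numerical choices, what
the phantom generator does and does not emulate, and the design decisions
taken where more than one reasonable construction existed.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and angle conventions

All rasters use 0-based pixel indices with x increasing rightward (columns)
and y increasing downward (rows); a pixel's location is its center.  Any
nonzero sample is foreground on input; masks are written as 0/255
single-channel PNG.  Angles are reported in degrees.  The thorax tilt θ is
the signed angle from image-vertical to the spine-to-anterior direction of
the bisecting line.

## Landmark construction

**Spine (S).**  The thorax label excludes the spine, so the spine region is
recovered as the largest connected component of (convex envelope of the
thorax − thorax).  Thin slivers that rasterized convexity leaves along
curved boundaries are rejected by requiring the residual to contain a pixel
at least 1.5 px from its own boundary; S is the residual's centroid.

**Anteroposterior line (RS).**  The line through S bisecting the
whole-thorax area.  The signed half-plane imbalance (left fraction minus
right fraction of foreground pixel centers) is swept at 1° resolution over
the tilt from vertical; each sign change is refined by bisection (40
iterations) and the candidate with the smallest |imbalance| wins, ties
broken toward the smallest tilt from vertical.  Pixels within 1e-7 of the
line count for neither side, so a line aligned exactly with a pixel row
stays balanced.  Success requires |imbalance| ≤ 0.5 % of the total area.
A line through *any* anchor can bisect a region (the imbalance is
continuous in angle and changes sign over a half turn), so failures can
arise only from extreme quantization; they raise rather than silently
degrade.  The refinement is checked against an exhaustive 0.05° sweep in
the acceptance suite.  R is the contour crossing of this line farthest
from S.

**Septal line, I, V.**  The septal line is the orthogonal least-squares
(principal) axis of the ventricular septum — not a regression of y on x,
which would be ill-posed for near-vertical septa; the principal axis is
rotation-invariant.  Isotropic regions (relative eigenvalue gap below
1e-6) raise a degenerate-fit error.  I is the septal ∩ RS intersection; V
is the septal-line crossing of the thoracic contour nearer the septum
centroid (the apex substitute).

**Contours.**  Outer boundaries are traced by marching squares at the 0.5
level of the lightly smoothed (σ = 1 px Gaussian) indicator of the largest
8-connected component.  The smoothing leaves straight-edge boundaries in
place while removing the staircase bias that binary marching squares puts
on curved-boundary lengths.  Line/contour intersections are deduplicated
within 0.5 px and ordered along the line.

**Cardiac axis.**  ∠RIV in [0°, 180°], from the arccosine of the
normalized dot product of the rays I→R and I→V, measured the same way
whichever side the apex points.

**Apex side and situs.**  The apex side is the sign of cross(R−S, V−S):
negative (image-left of the S→R direction) is the left thoracic cavity and
implies the cephalic presentation.  Situs uses the side-of-line test for V
and A (the contour crossing of the ray S → aorta centroid beyond the
aorta): same side solitus, opposite inversus.  The equivalent angle
identity (∠VSA vs ∠RSV + ∠RSA, with a 1° epsilon for the degenerate
alignment) is exposed separately and asserted as a consistency property;
the sign test is authoritative.  Points within 0.5 px of line RS make the
side indeterminate.  A missing aorta yields laterality "indeterminate",
which is noted but never flagged abnormal.

**Cardiac position (point P).**  P is the septal-line crossing of the
cardiac circumference on the opposite side of I from V (the base-ward
crossing); if the heart lies entirely on V's side of I, the crossing
farthest from V is taken.  The transform to thorax-relative units:
translate by −O′ (whole-thorax centroid), rotate by −θ, flip the vertical
sign (anterior positive), scale by dx = |B₁B₂|/divisions and
dy = |A₁A₂|/divisions, and fold gx = |p′x|.  The chords B₁B₂ and A₁A₂ are
the thoracic-contour crossings of the lateral and anteroposterior axes
through O′.  `divisions` defaults to 8 ("divided into eight equal parts"),
so the semi-chord spans 4 units and the normal box (0 ≤ gx ≤ 2,
−1 ≤ gy ≤ 1) sits strictly inside the thorax; a printed alternative with
dx = ½|B₁B₂| would place gx = 2 a full chord off-center, outside the
thorax, and is therefore not used.  The fold makes mirrored images agree
and matches the one-sided normal range.

## Screening

Normal ranges: CTAR < 0.35 (exactly 0.35 is abnormal — the *normal* range
is the open "< 35 %"), axis 45 ± 20°, position box above; all overridable
via a flat YAML config (`ctar_max`, `axis_center`, `axis_halfwidth`,
`pointp_box`, `pointp_divisions`).

Aggregation: continuous parameters are averaged across a video's images
(two per video in the intended workflow); categorical outcomes go by
majority with ties treated as abnormal — screening is a triage step, so
the design favors sensitivity.  A patient without an extractable 4CV is
positive by rule.  The overall call is positive iff any abnormality flag
fires (including orientation mismatch and inversus) or the
non-extractable rule fires; the ordinal score used for ROC counts only the
three quantitative parameters (CTAR, axis, point P), because orientation
and situs are binary side-checks rather than scored measurements.  The
score is the abnormal count among an includable subset, with
non-extractable patients at the maximum — this makes the with/without
parameter ROC grid transparent and monotone.

## The phantom generator

Each phantom is an analytic scene rasterized by a pixel-center-inside test
(no anti-aliasing, so areas are exact pixel counts and rasters are
platform-stable): an elliptical whole thorax; a spine disk just inside the
posterior boundary (the thorax label is the ellipse minus this disk, which
reproduces the spine hollow); an interior heart ellipse whose long axis at
`heart_axis_angle` to the anteroposterior direction carries the septum
strip (5 px wide, clipped to the heart); and a descending-aorta disk
beside the spine on the apex or contralateral side.  The heart semi-axes
are scaled by a ≤ 6-step bisection against the rasterized whole-thorax
count so the pixel CTAR matches the target within quantization.

Ground truth is computed from the final analytic geometry by replicating
the measurement's own selection rules (which thoracic crossing becomes V,
which heart pole becomes P) in closed form — so the truth stays valid even
when a configuration places the heart unusually.  Two diagnostics are
carried with the truth: how much nearer V is than the rival crossing, and
V's lateral distance from the midline; cohort sampling rejects draws where
either is small enough to make the construction ambiguous.

**Geometric feasibility of the normal draws.**  Normal cohorts draw
CTAR ~ U(0.20, 0.32) and axis ~ U(30°, 60°) — inside the guideline normal
ranges with at least twice the measurement tolerance as margin.  These
marginals interact with the geometry: an elliptical heart whose posterior
septal pole sits *at* the thorax center cannot fit inside the thorax once
CTAR is large and the axis steep (the apex pole would cross the thoracic
boundary).  The sampler therefore (a) grows the heart-roundness floor with
the CTAR target, and (b) slides the heart base posteriorly along the
septal chord as far as the normal position box allows (true gy down to
−0.7, twice the 0.15 measurement tolerance inside the box), redrawing
combinations that remain infeasible.  The realized cohort follows the
stated marginals truncated to realizable anatomy.  Abnormality presets
place their driving parameter at least twice its measurement tolerance
outside the normal range (CTAR ≥ 0.42; axis ≤ 13° or ≥ 77°; position
≥ 0.3 units outside the box), and the sampler verifies on generation that
each draw realizes its preset's semantics (a dextrocardia draw really is
mirror-imaged, an inversus draw really has the aorta contralateral, and so
on).

**What the phantoms do not emulate.**  Ultrasound appearance (speckle,
shadowing, B-mode texture), real cardiac shape (four chambers, asymmetric
atria/ventricles — the phantom heart is a septum-symmetric ellipse),
systole/diastole variation, and segmentation-network failure modes beyond
the provided boundary-jitter and dropout perturbations.  Passing the
phantom suites therefore demonstrates that the *measurement chain* is
correct and stable on the geometry it assumes; it says nothing about
segmentation quality on clinical images.

`perturb_masks` emulates segmentation imperfection: a smooth random field
(correlation length 4 px) added to the signed distance transform displaces
each boundary by the requested amplitude, and dropout removes a random
fraction of foreground pixels; containment (septum ⊆ heart ⊆ whole
thorax) is re-imposed so perturbed sets still validate.

## Evaluation

Dice is the standard 2·TP/(2·TP + FP + FN); two empty masks score 1.0
(perfect-agreement convention) so legitimately absent structures do not
poison per-structure means, and pairs with an empty prediction against a
non-empty reference are excluded from the mean and reported, never
silently dropped.  ROC curves sweep the distinct score values; the
trapezoid AUC equals the Mann–Whitney pair statistic (ties one half),
asserted against exhaustive pair counting in the tests.  The Youden point
maximizes TPR − FPR with ties broken toward the lower FPR.  An optional
seeded case-resampling bootstrap (2000 replicates) provides percentile
AUC intervals; it is this package's convention, not a reproduction of any
particular interval method.

## Problem sizes and runtime

The acceptance suites use 200 normal phantoms for parameter recovery, 50
per preset for classification, 20 fixtures each for the bisection oracle
and the invariance checks (scale 256²→512², 90° rotation, mirror), and 100
phantoms for the laterality-rule consistency check — sizes chosen so the
whole suite completes in a few minutes on one CPU while keeping the
statistical checks comfortably away from their tolerances.

## Known limitations

* The whole-thorax/thorax label distinction is fixed as "with/without the
  spine region"; other conventions would change the spine recovery.
* The worked-example cohort reconstruction takes published accounting
  counts as inputs; it validates the aggregation arithmetic, not the
  segmentation models that produced those counts.
* Laterality cannot distinguish right from left isomerism — it only
  detects apex/aorta side discordance.
* Measurements assume one connected structure per mask; multiple
  components are resolved by largest-component selection, not repaired.
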