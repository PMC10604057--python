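# Methods

## Geometric model

All angles are planar and signed. Landmark coordinates are image pixels
(origin top-left, x rightward, y downward); patient orientation is an
explicit frame parameter (`anterior_direction` ∈ {+x, −x}, default +x)
and is never inferred from pixel content, because lateral radiographs
are acquired facing either way and a silent guess corrupts every sign.
Internally each vector is mapped to an anatomical frame with X =
anterior, Y = up, where:

- **slope** of an endplate (SS, L1S, T1S, C2S) = signed angle between
  the posterior→anterior endplate vector and the horizontal, positive
  when the anterior end is inferior;
- **PT** = signed angle between the vertical and the PT line
  (femoral-head midpoint → S1 superior-endplate midpoint), positive for
  posterior tilt of the S1 midpoint;
- **incidence** (PI, L1I, T1I, C2I) = signed angle between the endplate
  perpendicular and the PT line, positive when the perpendicular lies
  anterior to the line. The perpendicular is the posterior→anterior
  endplate vector rotated 90° toward "up", which fixes the otherwise
  ambiguous branch.
- **regional angles** (LL, TK, C2–7L) = signed Cobb angles between the
  named endplates, oriented as differences of slopes, so lordosis is
  negative and kyphosis positive.

The sign orientation is the unique one under which the identities
`PI = PT + SS`, `XI = XS + PT` and the six derivation equations hold for
*every* configuration, given that the femoral heads lie anterior-inferior
to the sacral plateau. A consequence worth stating explicitly: with
positive sacral slope the anterior endplate end is the inferior one
(equivalently, the S1 endplate normal tilts anteriorly); the opposite
choice would make PI equal |PT − SS| and is inconsistent with an
all-positive PI/PT/SS population. Angle magnitudes come from
`atan2`-based arccosine of the normalized dot product; signs from the 2-D
cross product in the anatomical frame. Results are wrapped to
(−180°, 180°]. Angles are kept in full double precision everywhere;
rounding to 2 decimals happens only when writing human-facing CSV
reports. Degenerate geometry (coincident endplate endpoints, a zero PT
line) raises an error naming the offending landmarks rather than
propagating NaN into cohort statistics.

The S1 superior-endplate *midpoint* (not the separate sacrum-center
landmark) defines the PT-line endpoint; the sacrum center is carried as
an additional detection target only.

## Phantom forward model

The phantom parameterizes exactly the five independent angles the method
measures — PI, PT, L1I, T1I, C2I — and derives everything else (SS =
PI − PT, the six test parameters) inside each subject, so every synthetic
subject satisfies the deterministic identities by construction.
Construction is anchored at the femoral-head midpoint; the S1 midpoint
sits at 22% of the spine length along the PT direction; L1, T1 and C2
endplate midpoints sit at 42%, 78% and 100% of the spine length with
small slope-dependent anterior offsets. The midpoints affect no measured
angle (only endplate orientations and the PT line do); they exist so the
rendered spine looks like a spine. Default endplate half-widths are
26/24/18/11 px (S1/L1/T1/C2) at the default image scale.

Cohort sampling draws the five independent angles from independent
normals truncated to the observed min/max of a published 63-subject
standing-radiograph cohort (means ± SD: PI 51.76 ± 12.47, PT 14.21 ±
8.94, L1I −0.56 ± 13.30, T1I 39.07 ± 11.74, C2I 26.21 ± 11.26 degrees).
Real cohorts correlate these parameters (e.g. PI with LL); those
correlations are not published for this cohort, so independence is a
documented synthetic assumption, not a clinical claim. Geometrically
infeasible draws are resampled with a bounded retry count.

Rendering paints femoral-head discs and vertebral-body quadrilaterals —
the four named vertebrae with one quad edge exactly on the endplate
segment, plus intermediate bodies along a PCHIP curve through the
endplate midpoints with disc-space gaps — then applies Gaussian blur and
additive Gaussian noise. The default image is 270 × 810 px, a 4×
downscale of a full-length lateral film (1080 × 3240 px); resolution is
a rendering detail. Everything is deterministic under the spec's seed.

What the phantom does *not* emulate: ribs, shoulder girdle and soft
tissue (the overlaps that degrade T1 detection clinically), scoliosis,
implants, exposure variation. Tests passing on phantoms therefore
validate the geometry, the training machinery and the statistics — they
do not certify clinical-image accuracy, which requires retraining and
validation on real radiographs.

## Detection cascade

Order 1 regresses the three region centers (hip = femoral heads;
lumbosacral = sacrum + S1 + L1 landmarks; cervical = T1 + C2 landmarks —
T1 is grouped with the cervical region) from the full downscaled image.
Order 2 regresses vertebra-group centers inside each region crop; order
3 regresses the named landmark coordinates inside each vertebra crop.
Crop transforms are exact affine maps, so predictions round-trip to
full-image coordinates to machine precision.

The default regressor is a deliberately small fully-connected network
(flattened resized crop → 64 ReLU units → linear coordinates, outputs
normalized to the crop and clipped to [0, 1]) trained with Adam directly
on the MAE loss — the loss the cascade is defined by, where squared-error
defaults would subtly change the objective. The cascade accepts any
regressor with the same `fit`/`predict` contract; the published
contribution is the decentralized ordering and the loss, not a specific
architecture. Defaults: learning rate 3e-3, 30 epochs, batch 16, 9:1
train:validation split, crop-center jitter of 8% of the box extent
during training (standard cascade practice: ground-truth-centered crops
with jitter for training, previous-order predictions for inference).
Input resolutions are 64 × 24 (order 1) and 32 × 32 (orders 2–3).
Training runs, splits, jitter and initialization all derive from one
seed; identical seed and cohort give identical loss curves and weights,
and a saved/reloaded model predicts bit-identically.

Training demonstrations and tests use 112 × 336 px renderings and
cohorts of 24–200 subjects, sizes at which the full cycle runs
comfortably on one CPU core while still exercising every stage; on 200
phantoms the held-out success-rate curves reach 80% within a few degrees
for most parameters (the cervical parameters are the hardest, matching
the small pixel extent of the C2 endplate).

## Agreement statistics

- Success rate: fraction of cases with error strictly below the
  threshold ("fell below"); an inclusive variant is available because
  ties matter on gridded synthetic errors. Curves default to a
  0.5°–10° grid in 0.5° steps and are computed per parameter, not
  pooled.
- Bland–Altman: differences x − y, limits mean ± 1.96 × sample SD
  (n − 1 denominator — standard practice).
- Agreement summary: MAE, SD of absolute error, Pearson r with
  two-sided p, R² = r². Zero-variance input makes r undefined and is
  reported as `None`, never silent NaN.
- ICC(2,1): two-way random effects, absolute agreement, single measure,
  from the ANOVA mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`, with the standard
  F-based 95% CI and the between-subject F-test p-value. When MSE = 0
  the CI degenerates to the point estimate. The implementation is
  cross-checked in the test suite against an independent statistical
  package on random matrices.

## Numerical and design notes

- Wrap-around: all angle arithmetic wraps to (−180°, 180°]; clinical
  configurations sit far from the branch cut.
- Whole-pixel quantization of landmarks perturbs each measured angle,
  but perturbs the direct and equation-derived routes identically — the
  discrepancy between routes stays at rounding level, which is the
  practical content of the derivation identities.
- The femoral heads may coincide (perfect lateral projection); their
  midpoint is used throughout. Default head separation in the phantom
  is 10 px to emulate slight projection offset.
- Known limitations: no distance parameters (e.g. sagittal vertical
  axis), no vertebral numbering from images, no DICOM ingestion (PNG and
  TIFF only; DICOM is an extension point), no claim of accuracy on real
  radiographs without retraining.
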