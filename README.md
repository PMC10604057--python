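# spinemetrics

Measurement of spinopelvic sagittal alignment from eleven anatomical
landmarks on lateral whole-spine radiographs, built around the incidence
angles of the spinal inflection points.

## The problem and who this is for

Sagittal balance of the spine is described by a dozen angular parameters
— pelvic incidence (PI), pelvic tilt (PT), sacral slope (SS), regional
curvatures such as lumbar lordosis (LL) and thoracic kyphosis (TK), and
the slopes of individual vertebrae. Measuring them by hand requires a
surgeon to place two vectors per angle, so 12 parameters need 24 vectors
and each placement is a chance for error and for sign confusion
(lordosis is negative by convention but is often recorded as an absolute
value). This package is for researchers building or validating automated
spine-measurement pipelines: it provides the geometric engine, a
synthetic phantom generator with exact ground truth, a trainable
coarse-to-fine landmark detector, and the agreement statistics used to
validate such systems.

## The core idea

Only eleven landmarks are needed: the centers of both femoral heads and
of the sacrum, and the anterior/posterior endpoints of the S1, L1 and T1
superior endplates and the C2 inferior endplate. From these, five
independent angles are measured — PI, PT and the *incidence angles of the
inflection points* L1, T1 and C2:

```
XI = angle( PT line , perpendicular of vertebra X's endplate ),   X ∈ {L1, T1, C2}
```

where the PT line runs from the femoral-head midpoint to the S1
superior-endplate midpoint. Each incidence aggregates the vertebra's
slope with the pelvic tilt, `XI = XS + PT`, exactly as `PI = PT + SS`.
The six test parameters then follow by pure arithmetic:

```
LL    = L1I − PI        L1S = L1I − PT
TK    = T1I − L1I       T1S = T1I − PT
C2–7L = T1I − C2I       C2S = C2I − PT
```

Under consistent sign conventions (lordosis negative, kyphosis positive;
a slope positive when the anterior endplate end is inferior; an
incidence positive when the endplate perpendicular lies anterior to the
PT line) these are exact signed identities, not approximations: the
derived and directly measured values agree to floating-point rounding on
every landmark set.

The landmark detector is a decentralized three-order cascade: order 1
finds the cervical, lumbosacral and hip regions on the full image, order
2 finds vertebrae inside each region crop, order 3 localizes the named
landmarks inside each vertebra crop. Each order is a small coordinate
regressor trained on the mean-absolute-error loss; narrowing the region
of interest per order removes unrelated features and lets the cascade
train on modest cohorts.

## Worked example

Applying the derivation equations to the measured cohort means of the
five independent angles (PI 52.16°, PT 14.99°, L1I 2.46°, T1I 39.77°,
C2I 26.87°):

```
$ python examples/02_derive_from_incidences.py
    LL:   -49.70 deg
    TK:    37.31 deg
 C2_7L:    12.90 deg
   L1S:   -12.53 deg
   T1S:    24.78 deg
   C2S:    11.88 deg
```

LL = −49.70° is the cohort-mean lumbar lordosis implied by L1I − PI
(negative: lordotic); TK = 37.31° the thoracic kyphosis from T1I − L1I
(positive: kyphotic). Measuring a synthetic subject built from the same
targets (`examples/01_measure_from_landmarks.py`) returns the identical
twelve values from raw landmark coordinates, with a direct-vs-derived
discrepancy of zero to two decimals, and `52.16 = 14.99 + 37.17`
confirming PI = PT + SS.

Other examples: `03_synthetic_cohort.py` (cohort sampling and the
identity at scale), `04_train_detector.py` (cascade training and the
80%-success thresholds on held-out phantoms), `05_agreement_statistics.py`
(Bland–Altman, success rates, ICC(2,1)).

A thin CLI wraps the same functions:

```
spinemetrics derive --pi 52.16 --pt 14.99 --l1i 2.46 --t1i 39.77 --c2i 26.87
spinemetrics phantom --n 5 --seed 7 --out-dir cohort/
spinemetrics measure cohort/subject_0000.csv
```

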