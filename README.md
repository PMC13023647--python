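# fourcv

Automated biometry of the fetal four-chamber view (4CV) from segmentation
masks, for prenatal screening of congenital heart disease (CHD).

Fetal cardiac screening hinges on a handful of measurements made on the 4CV
— the transverse plane showing both atria, both ventricles, the crux and
the descending aorta — but their manual measurement is operator-dependent.
Given per-structure segmentation masks of the fetal thorax (heart,
ventricular septum, whole thorax, thorax, descending aorta), this package
computes the guideline screening parameters fully automatically, classifies
each against its normal range, and aggregates image → video → patient
screening calls.  A synthetic phantom generator with analytic ground truth
stands in for the deep-learning detection/segmentation front end, so the
whole pipeline is testable without clinical data.

## The measurements

All constructions operate on binary rasters in image coordinates (x right,
y down, pixel centers at integer coordinates):

* **CTAR** (cardiothoracic area ratio): heart foreground pixels divided by
  whole-thorax foreground pixels; normal **CTAR < 35 %**.
* **Cardiac axis**: the spine centroid *S* is recovered by filling the
  hollow in the thorax mask (convex envelope minus thorax); the
  anteroposterior line through *S* bisects the whole-thorax area and meets
  the thoracic contour at *R* (the farther crossing).  The septal line is
  the orthogonal-least-squares long axis of the ventricular septum; it
  meets line *RS* at *I* and the thoracic contour at *V* (the crossing
  nearer the septum).  The cardiac axis is
  ∠RIV = arccos(I⃗R·I⃗V / |I⃗R||I⃗V|); normal **45 ± 20°**.
* **Apex orientation / presentation**: the side of *V* relative to line
  *RS* places the apex in the left (cephalic) or right (breech) thoracic
  cavity; a mismatch with the examiner-declared presentation is flagged.
* **Laterality (situs)**: with *A* the thoracic-contour crossing of the ray
  from *S* through the descending-aorta centroid, apex and aorta on the
  same side of *RS* is solitus (equivalently ∠VSA < ∠RSV + ∠RSA); opposite
  sides — e.g. right aortic arch — is inversus (∠VSA = ∠RSV + ∠RSA).
* **Cardiac position (point P)**: the septal-line crossing of the cardiac
  circumference opposite the septum, expressed in a thorax-centered frame:
  translate by the whole-thorax centroid O′, rotate by the thorax tilt θ,
  flip the vertical axis, scale by dx = |B₁B₂|/8 and dy = |A₁A₂|/8 (the
  thoracic chords divided into eight parts), and fold gx = |p′x| onto the
  apex side; normal box **0 ≤ gx ≤ 2, −1 ≤ gy ≤ 1**.

Screening calls: a video's two images are averaged before classification; a
patient whose video yields no extractable 4CV is screened positive by rule;
the ordinal screening score (abnormal count among CTAR / axis / point P)
feeds ROC analysis.  Segmentation quality is evaluated with the Dice
coefficient 2·TP/(2·TP+FP+FN).

## Worked example

```python
from fourcv import phantom, biometrics, screening

mask_set, truth = phantom.generate_phantom(phantom.PhantomSpec())
record = biometrics.compute_biometrics(mask_set)
result = screening.classify_parameters(record, declared_presentation="cephalic")
print(f"ctar {record.ctar:.3f}  axis {record.cardiac_axis:.1f}  "
      f"P ({record.point_p[0]:.2f}, {record.point_p[1]:.2f})  "
      f"{record.laterality}  -> {result.overall}")
```

prints

```
ctar 0.270  axis 45.0  P (0.69, -0.61)  solitus  -> negative
```

i.e. the default phantom (true CTAR 0.27, true axis 45°, true position
(0.68, −0.62), aorta on the apex side) is measured to within 0.001 / 0.1° /
0.01 units and correctly screened negative: CTAR below 35 %, axis inside
45 ± 20°, position inside the normal box, situs solitus.

The same pipeline is available from the shell:

```
fourcv phantom --preset inversus -n 5 --seed 1 --out cohort/
fourcv measure --masks cohort/phantom_1_0000 --out record.json
fourcv screen  --cohort cohort/manifest.jsonl --out calls/ --roc
fourcv evaluate --pred predicted/ --truth labels/ --out dice.json
```

## Layout

| module | contents |
| --- | --- |
| `fourcv.mask_io` | mask-set PNG+JSON I/O and validation |
| `fourcv.geometry` | centroids, contours, principal axes, area bisection, intersections |
| `fourcv.biometrics` | landmark construction and the five parameters |
| `fourcv.screening` | normal ranges, flags, video/patient aggregation, scores |
| `fourcv.phantom` | synthetic 4CV phantoms with analytic ground truth |
| `fourcv.evaluation` | Dice, MAE, ROC/AUC, Youden point |
| `fourcv.cli` | `fourcv measure / screen / phantom / evaluate` |

See `docs/methods.md` for the measurement conventions, the phantom's
geometry and its limits, and the numerical choices.
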