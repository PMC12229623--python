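# maxdex

Landmark-based computation of the **acromial index (AI)** and its ultrasound
analogue, the **modified acromial index (mAX)**, together with the full
method-agreement analysis used to compare the two — and a synthetic shoulder
cohort generator so the whole study design can be exercised end-to-end
without clinical images.

**Who it is for.** Musculoskeletal-imaging researchers evaluating whether
radiation-free ultrasound can stand in for MRI when measuring the lateral
acromial roofing of the humeral head, a morphometric risk marker for rotator
cuff tears (indices above 0.7 are conventionally flagged pathological); and
methodologists who need a reproducible reference implementation of the
reliability battery (ICC, Bland–Altman, Landis–Koch interpretation) for a
two-rater × three-repeat × two-modality design.

## The indices

With vertical reference lines on the medio-lateral axis,

* **AI** (MRI): `AI = GA / GH`, where GA is the distance from the glenoid
  plane to the lateral acromion edge and GH the distance from the glenoid
  plane to the lateral humeral edge.
* **mAX** (ultrasound): the glenoid is not visible sonographically, so a
  circle is fit to the visible humeral-head arc (Kåsa initializer +
  Levenberg–Marquardt orthogonal-distance refinement) and its **medial
  vertical tangent** serves as the glenoid surrogate:
  `mAX = (AE_x − c_x + r) / (2r)` for circle center `c`, radius `r`,
  acromion edge `AE`. Its GH is exactly the circle diameter.

Because the medial tangent lies medial to the true glenoid plane by an
offset δ ≥ 0, mAX exceeds AI systematically:
`mAX − AI = δ(1 − AI)/(2r)` at noiseless geometry. The synthetic cohort
calibrates δ so this gap matches the clinically observed ≈ 0.09
(index means ≈ 0.74 ultrasound vs ≈ 0.65 MRI).

## Worked example

```python
import numpy as np
from maxdex import (Point2D, UltrasoundAnnotation, compute_max,
                    SimulationConfig, generate_measurement_table, run_study)

# one ultrasound measurement: 5 arc points on the humeral head + acromion edge
arc = [Point2D(10*np.cos(t), 10*np.sin(t)) for t in np.radians([20, 50, 80, 110, 140])]
ann = UltrasoundAnnotation(arc_points=tuple(arc), acromion_edge=Point2D(4.8, 12.0),
                           side="left", patient_id="P001", rater_id="R1", repeat_index=1)
m = compute_max(ann)
print(f"mAX = {m.value:.3f} (GA = {m.ga:.1f} mm, GH = {m.gh:.1f} mm) -> {m.classification}")

# a full simulated study: 115 patients x 2 raters x 3 repeats x 2 modalities
df = generate_measurement_table(SimulationConfig(n_patients=115, seed=99))
rep = run_study(df)
ba = rep.comparison["bland_altman"]
print(f"mean AI (MRI) = {rep.indices['MRI']['mean']:.3f} (SD {rep.indices['MRI']['sd']:.3f})")
print(f"mean mAX (US) = {rep.indices['US']['mean']:.3f} (SD {rep.indices['US']['sd']:.3f})")
print(f"Bland-Altman: mean diff {ba['mean_diff']:.3f}, "
      f"LoA [{ba['loa_low']:.3f}, {ba['loa_high']:.3f}], {ba['outlier_count']} outliers")
```

prints

```
mAX = 0.740 (GA = 14.8 mm, GH = 20.0 mm) -> pathological
mean AI (MRI) = 0.631 (SD 0.057)
mean mAX (US) = 0.734 (SD 0.048)
Bland-Altman: mean diff 0.103, LoA [0.055, 0.152], 7 outliers
```

The circle extrapolated from the arc has its medial tangent at x = −10, so
GA = 4.8 − (−10) = 14.8 mm over the 20 mm diameter gives 0.74 — above the
0.7 cut-off. The simulated study reproduces the structure of the clinical
comparison: MRI indices near 0.65, ultrasound indices shifted up by ≈ 0.1,
and a handful of patients outside the 95% limits of agreement.

## Command line

```sh
maxdex simulate --seed 99 --n-patients 115 --out sim.csv   # synthetic session
maxdex measure  --annotations ann.json --out meas.csv      # landmarks -> indices
maxdex analyze  --measurements sim.csv --out report.json   # full agreement report
maxdex report   --report report.json --format md           # rendered tables
```

Annotation files are versioned JSON (`maxdex-annotation-1`); measurement
tables are long-format CSV (patient × rater × repeat × modality × value).
See `docs/methods.md` for the model, parameter meanings and limitations.

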