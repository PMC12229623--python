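# Methods

## The indices

The **acromial index (AI)** quantifies how far the acromion roofs the humeral
head laterally. In a coronal view with a medio-lateral axis, three vertical
reference lines are drawn: through the glenoid plane, tangent to the lateral
acromion edge, and tangent to the lateral edge of the humeral head. With
GA = glenoid→acromion distance and GH = glenoid→lateral-humerus distance,

    AI = GA / GH.

Values above 0.7 are conventionally associated with rotator cuff tears; the
package classifies with a **strict** inequality (`value > threshold` is
pathological, so exactly 0.7 is normal). The threshold is configurable
everywhere it appears.

The **modified acromial index (mAX)** is the ultrasound analogue. The glenoid
is not directly visible on ultrasound, so the visible arc of the humeral-head
contour is extrapolated to a full circle and the circle's *medial vertical
tangent* serves as a glenoid surrogate. Then GA runs from that tangent to the
acromion edge and GH is the tangent separation, i.e. the circle diameter:

    mAX = (AE_x − c_x + r) / (2r)

for circle center `c`, radius `r` and acromion edge `AE`. Because the medial
tangent lies medial to the true glenoid plane by some offset δ ≥ 0, mAX is
systematically larger than AI; at noiseless geometry

    mAX − AI = δ (1 − AI) / (2r).

## Coordinate convention and laterality

All landmark math runs in a canonical frame: millimetres, +x lateral,
+y superior. Right shoulders are mirrored about the y-axis
(`normalize_laterality`, idempotent) before any computation, so no downstream
code branches on side. Inputs are assumed already metric; no pixel-spacing
handling exists.

## Circle fitting

`fit_circle` uses the Kåsa algebraic fit (linear least squares on
x² + y² = 2ax + 2by + c) as an initializer and refines it with a
Levenberg–Marquardt minimization of the orthogonal distances
(`scipy.optimize.least_squares`, relative parameter tolerance 1e-10, at most
100 iterations). Collinearity is detected when the smallest singular value of
the algebraic design matrix falls below 1e-9 times the largest; that raises a
degenerate-geometry error. Residual RMS below 1e-12 is reported as exactly 0.
A warning is logged when the subtended arc is under 60°, where extrapolation
to the full circle becomes ill-conditioned; three non-collinear points are
the hard minimum.

## Agreement statistics

* **ICC** is computed from two-way ANOVA mean squares using the
  Shrout–Fleiss forms: one-way random ICC(1), two-way random with absolute
  agreement ICC(2), two-way mixed with consistency ICC(3), each as single or
  average measures. Pipeline defaults: inter-rater reliability uses ICC(2,1)
  on per-rater means of the repeats; intra-rater reliability uses ICC(3,1)
  across the repeats within a rater, per modality. A table with zero
  between-subject variance carries no reliability signal and returns 0 with
  a degenerate flag rather than an undefined ratio.
* **Landis–Koch bands**: below 0.01 (including negative estimates) "poor",
  then slight (0.01–0.20), fair (–0.40), moderate (–0.60), substantial
  (–0.80), almost perfect (–1.00); upper edges inclusive. The assignment of
  (−∞, 0.01) to "poor" makes the mapping total.
* **Bland–Altman**: differences a−b, sample SD (n−1), limits of agreement
  mean ± 1.96·SD by default, outliers strictly outside the closed interval.
* **Paired comparison** runs a paired t-test when the differences pass
  Shapiro–Wilk at p > 0.05, otherwise Wilcoxon signed-rank; the branch taken
  is recorded in the report. Both Shapiro–Wilk and Lilliefors-corrected
  Kolmogorov–Smirnov normality tests are available.
* **Proportions** round half-up to one decimal; counts are authoritative and
  percentages are always recomputed from them, with subgroup denominators.
* **Sample size**: the effect size η² is converted to Cohen's
  f² = η²/(1−η²) and the smallest n reaching the requested power is solved
  for the configured test family. The default family is a one-way ANOVA with
  two groups (equivalently a two-sample t-test); this is an explicit
  configuration choice recorded on the `SampleSizeSpec`, since an a-priori
  calculation quoted only as "η², power, α" does not identify its test.

## Outlier rule

The pipeline's opt-in exclusion uses the modified z-score rule: flag
differences with |d − median| > 3.5 × 1.4826 × MAD. When the MAD is zero
(over half the differences identical) it falls back to 1.2533 × the mean
absolute deviation about the median (the Iglewicz–Hoaglin convention); if
that is also zero nothing is flagged. Under Gaussian differences at n ≈ 113
this flags ≤ 2 points in well over 90% of samples. Exclusion is **opt-in**
and logged because an observed-data analysis that mentions removing "minor
outliers" without stating a rule cannot be mirrored exactly; the rule here
is a defined, testable stand-in.

## Synthetic cohort model

`SimulationConfig` defaults describe an adult shoulder-complaint cohort:

| parameter | default | meaning |
|---|---|---|
| n_patients | 115 | joints, one per patient |
| ai_mean / ai_sd | 0.65 / 0.065 | true AI ~ Normal, truncated to (0.3, 1.1) |
| radius_mean / sd | 24 / 2 mm | humeral-head radius (literature-plausible) |
| delta_mean | calibrated | surrogate-glenoid offset δ, see below |
| delta_sd | 2 mm | between-patient δ spread (truncated to [0, r]) |
| landmark_noise_us / mri | 0.5 / 0.3 mm | isotropic digitization noise |
| rater_bias_sd | 0.6 mm | systematic per-(rater, landmark) bias |
| rater_within_sd | 0.4 mm | per-repeat jitter |
| arc_center / span | 45° / 100° | visible supero-lateral arc window |
| n_raters × n_repeats | 2 × 3 | per modality: 12 measurements per joint |
| sex_p_male / side_p_left | 0.687 / 0.635 | demographics |
| age_mean / sd | 53.15 / 13.65 y | truncated to [18, 95] |

δ defaults to the closed-form calibration δ = 0.09 · 2r̄ / (1 − ĀI)
(≈ 12.3 mm), which makes the expected mAX − AI gap ≈ 0.09 at the mean
geometry — the size of the modality offset observed clinically (0.74 vs
0.65). The bias/jitter split 0.6 / 0.4 mm was chosen once from the variance
decomposition: the inter-rater table averages the repeats, so per-rater bias
must exceed within²·(1 − 1/k) for intra-rater ICC to exceed inter-rater ICC
in expectation, as reliability studies of this design observe; the defaults
give inter ≈ 0.88 and intra ≈ 0.92 on MRI.

What the generator does **not** emulate: image formation (speckle, shadowing,
slice selection), skewed or patient-correlated δ (δ is independent of AI, so
simulated mAX and AI correlate strongly *positively*, unlike the weak
negative correlation one clinical study reports), rater drift over time, and
missing data (designs are complete by construction). Passing tests therefore
demonstrate correctness of the computational chain and the stated statistical
structure, not clinical performance.

## Numerical and design choices

* Degenerate inputs: < 3 arc points, collinear arcs, GA ≤ 0, GH ≤ 0,
  unknown side/sex/modality labels all raise typed errors early.
* Percent rendering keeps raw counts; 18/115 renders as 15.7 under
  round-half-up (printed clinical tables occasionally truncate instead; the
  counts disambiguate).
* Consensus collapse: mean of each rater's repeats, then mean of rater
  means. With a complete design this equals the grand mean but is robust to
  unbalanced repeat counts.
* Determinism: one `numpy` Generator seeded from the config covers cohort,
  rater effects and every measurement; identical config ⇒ byte-identical
  measurement tables, and `run_study` is a pure function of its input table.
* Monte-Carlo problem sizes in the test suite (replicate counts of 40–200,
  per-replicate cohorts of 12–15, large-sample checks at n = 10 000) were
  chosen to keep Monte-Carlo error well below the asserted bands while the
  full suite stays in the tens of seconds.

## Known limitations

* The δ offset is a one-parameter abstraction of everything that separates
  the ultrasound surrogate from the true glenoid plane; it absorbs both
  geometry and acquisition effects and is not anatomically validated.
* ICC confidence intervals are not computed (point estimates and bands only).
* The sample-size helper covers a single test family; an a-priori
  calculation from a different family will disagree.
* Only complete rating designs are accepted; incomplete tables are rejected
  rather than imputed.
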