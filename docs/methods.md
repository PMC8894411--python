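# Methods

## Geometry and conventions

The object of study is the longitudinal axis of the neck of a femoral THA
component, represented as a unit 3-vector in a right-handed orthonormal
frame: `e_x` medio-lateral and horizontal (positive toward the side the
neck points to, so `x > 0` always), `e_y` antero-posterior (anterior
positive), `e_z` vertical (superior positive). Two frames are supported:
the *scanner frame* (identity axes, supine scanning position) and the
*mechanical femoral frame*, built from landmarks as `e_z` along the
mechanical femoral axis (knee center → femoral head center), `e_x` the
posterior condylar direction (lateral → medial condyle) Gram–Schmidt
orthogonalized against `e_z`, and `e_y = e_z × e_x`.

The three projected angles of an axis `(x, y, z)` are

- coronal inclination `CI = atan2(z, x)` — coronal projection vs the
  horizontal; range (0°, 90°); low = varus, high = valgus;
- sagittal inclination `SI = atan2(y, z)` — sagittal projection vs the
  vertical; range (−90°, 90°); high = ante-inclination;
- transverse version `TV = atan2(y, x)` — transverse projection vs the
  horizontal; range (−90°, 90°); positive = anteversion, negative =
  retroversion (retroversion is represented as a signed negative angle,
  never folded to an absolute value).

These conventions make the product identity `tan TV = tan SI · tan CI`
exact, so each angle has a closed form in the other two. The angle-only
API (`tv_from_ci_si` and friends) exposes exactly those closed forms; the
vector API (`angles_from_axis`) evaluates `atan2` on components, which is
numerically robust as CI approaches 90°.

## Degeneracy handling

The tangent forms collapse when CI approaches 0° or 90°, when SI
approaches 0° in the CI equation, or when the axis is (anti)parallel to a
projection plane's normal. Accuracy is known to degrade in near-degenerate
configurations, so inputs within **0.01°** of a tangent pole or zero raise
a `DegenerateInputError` instead of returning huge or undefined values;
the table-conversion path (`convert_table`) flags such rows in a `status`
column rather than raising, so one bad row never aborts a batch. A TV/SI
pair with opposite signs is geometrically inconsistent with CI ∈ (0°, 90°)
and raises `InconsistentAnglesError`.

`OrientationAngles` validates the product identity at construction with a
relative tolerance of 1e-9 in tangent space. The tolerance is relative
because the absolute tangent error of a degree-rounded angle grows with
sec², which near CI = 90° exceeds any fixed absolute bound even at machine
precision; angle-level round-trip accuracy remains below 1e-9 degrees
across the guarded domain.

## Non-orthogonal imaging model

Biplanar acquisitions are rarely perfectly orthogonal. The model rotates
*only the sagittal viewing plane*, by δ degrees about the vertical axis,
with the sign chosen so positive δ reduces apparent anteversion (δ = 5°
corresponds to an 85° angle between the views). Projecting the axis onto
the rotated plane gives

    tan SI' = tan SI · cos δ − sin δ / tan CI,

and recomputing TV from the mismatched (CI, SI') pair yields the closed
form

    tan TV' = tan TV · cos δ − sin δ.

The vector path and the closed form agree to 1e-9°, which the property
suite checks with an independent rotation-matrix oracle. The choice of
rotation axis (vertical) and sign is an assumption of this package: the
direction is the one that shifts apparent version downward, matching the
reported behaviour of out-of-plane series. δ is limited to |δ| < 45°.

## Synthetic cohorts

No public dataset exists for this measurement problem, so validation runs
on virtual cohorts that emulate a published 22-hip THA cohort summary:

| angle | untruncated mean ± SD | truncation range |
|-------|----------------------|------------------|
| CI    | 50.0° ± 9°           | 26.1° – 72.0°    |
| TV    | 10.8° ± 9°           | 0.4° – 29.7°     |

CI and TV are drawn **independently** (no correlations are reported) from
truncated normals via inverse-CDF sampling (exact and bit-reproducible for
a fixed seed); SI is **derived** from the identity, never sampled, so every
simulated hip is geometrically consistent. Note that truncation shifts the
realized moments away from the loc/scale parameters: with these ranges the
realized TV mean is ≈ 12.5° and its SD ≈ 6.9°. The sampler is tested
against truncated-normal moments obtained by direct numerical integration.

Manual measurement is modelled as additive Gaussian noise with one common
SD σ for every angle and every series (no per-plane error estimates are
available to justify more structure). For the non-orthogonal series the
apparent SI is computed from the *true* axis first and noise is added
afterwards — the observer measures the distorted image. Noisy values are
clipped into the open valid domains; clips are logged and essentially never
occur at realistic σ.

`calibrate_noise` inverts σ from an observed median absolute difference
between the manually measured TV and the TV calculated from manually
measured (CI, SI). It root-finds (Brent) on a forward simulation with
200,000 hips and common random numbers across σ values, which makes the
objective smooth and strictly monotone; convergence to within 0.02° of the
target is verified and the calibrated σ is stable across seeds to well
under 5%. Calibrating to the reported 1.3° median gives σ ≈ 1.17°.

What the generator does *not* emulate: correlations between angles,
per-observer bias, heavier-than-Gaussian reading errors, implant-geometry
effects (head size, offset), and the small real-cohort sample size.
Passing tests therefore demonstrate the mathematics and the statistical
machinery, not the human measurement process; reliability statistics of
real observers are out of reach of this simulation (see Limitations).

## Agreement statistics

Validity is summarized the way method-comparison studies report it:

- **ICC(A,1)** — single-rater, absolute agreement, from the two-way ANOVA
  mean squares (subjects × raters),

      ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n),

  with the F-distribution confidence interval using Satterthwaite degrees
  of freedom. The estimator is identical under the two-way *random* and
  two-way *mixed* designs; the `model` flag records the intended
  interpretation. Zero between-subject variance raises an error (the ICC
  is undefined); perfect agreement returns 1.0 with a degenerate CI.
  The implementation is cross-checked in the tests against an explicit
  loop-and-sums ANOVA oracle (1,000 random tables) and against pingouin.
- **Bland–Altman**: bias = mean(a−b), limits of agreement = bias ±
  1.96·SD(a−b) with the n−1 sample SD. The 1.96 multiplier and the
  linear-interpolation percentile rule are the conventional choices.
- **Median absolute difference** with 25th/75th percentiles.

Distributional screening (normal vs lognormal) is not used as a gate: the
statistics are computed unconditionally.

## Validation study design

`run_validation_study` simulates the three-series measurement design:

1. sample a cohort of true triples;
2. "measure" CI, SI, TV on the orthogonal series (noise added to each
   independently) and CI, SI' on the non-orthogonal series;
3. compare **manual TV vs calculated TV** (TV measured directly vs
   `tv_from_ci_si` of the measured CI, SI — all three angles are measured
   independently, so this is a genuine method comparison), and
   **orthogonal-calculated vs non-orthogonal-calculated TV**;
4. report ICC + CI, Bland–Altman bias/LoA and median absolute difference
   (IQR) per series, with full precision in the CSV and rounding to 0.1°
   (ICC 0.01) only at presentation.

With σ = 0 and δ = 0 the study returns ICC = 1 and all-zero differences:
the algorithm itself introduces no error. Agreement degrades monotonically
in both σ and |δ|, which the suite checks with replicate-averaged runs.

Problem sizes: the standard study runs at n = 10,000 hips (seconds on one
CPU); noise calibration uses n = 200,000; the percentile/ICC validity
analysis uses n = 100,000. `scripts/acceptance.py` recomputes, from
scratch: the median orthogonal-vs-85° calculated-TV difference (≈ 4.9°),
the 95th percentile of the manual-vs-calculated difference at calibrated
noise (≈ 3.96°, i.e. under 4°), and the corresponding ICC (≈ 0.96).

## Limitations

- The simulated manual-vs-calculated ICC depends on the between-subject
  spread: the truncated TV distribution has a realized SD of ≈ 6.9°, which
  caps the ICC near 0.96; an untruncated 9° spread would give ≈ 0.98.
- Real-cohort and human-observer quantities (non-orthogonal ICC on 22
  hips, intra-/inter-observer ICCs) require the original patients and
  raters; the package replaces them with exactness, magnitude and
  monotone-degradation checks on synthetic cohorts.
- The non-orthogonal model rotates the sagittal plane only, about the
  vertical axis; real out-of-plane acquisitions may combine axes.
- Angles within 0.01° of a degeneracy are refused rather than estimated;
  configurations with both TV and SI near 0° are intrinsically
  ill-conditioned for the CI equation.
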