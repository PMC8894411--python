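# stemver

Tools for assessing the 3-D orientation of the femoral component of a total
hip arthroplasty (THA) from two orthogonal 2-D views.

## The problem

The orientation of the prosthetic neck matters for implant stability, but
the angle that matters most clinically — **transverse version** (TV,
anteversion) — lives in the axial plane, which plain radiographs do not
show. The two angles that *are* visible on an anterior–posterior and a
lateral film, **coronal inclination** (CI, to the horizontal) and
**sagittal inclination** (SI, to the vertical), are projections of the same
neck axis, and the three projected angles are linked by a closed-form
trigonometric identity. In a right-handed frame with `x` medio-lateral,
`y` anterior and `z` superior, a unit neck axis `(x, y, z)` gives

    tan CI = z / x,    tan SI = y / z,    tan TV = y / x,

hence

    TV = arctan( tan SI · tan CI ),
    CI = arctan( tan TV / tan SI ),
    SI = arctan( tan TV / tan CI ).

Any two of the three angles determine the third, so transverse version can
be *calculated* from a biplanar radiograph pair instead of measured on CT.
The same relations hold in the scanner frame or in a mechanical femoral
frame built from bony landmarks (femoral head center, knee center, and the
posterior condylar plane as the distal rotational reference).

The package provides, for researchers and surgeons evaluating implant
position and for methodologists studying projection error:

- `trig_core` — the three closed-form equations, the vector forward model
  (`angles_from_axis` / `axis_from_angles`), mechanical-frame construction
  from landmarks, and a non-orthogonal-imaging error model
  (`tan TV' = tan TV · cos δ − sin δ` when the sagittal view is off by δ);
- `synthetic_cohort` — virtual cohorts drawn from published angle
  distributions (CI 50.0° ± 9° truncated to 26.1–72.0°, TV 10.8° ± 9°
  truncated to 0.4–29.7°, SI derived from the identity), Gaussian
  manual-measurement noise, and calibration of the noise level to an
  observed median absolute difference;
- `agreement_stats` — single-rater absolute-agreement ICC — ICC(A,1) —
  with F-method 95% CI, Bland–Altman bias and limits of agreement, and
  median absolute differences with IQR;
- `study_pipeline` — the end-to-end synthetic validation study and the CSV
  conversion workflow, with a `stemver` command-line interface
  (`convert`, `simulate`, `validate`, `icc`).

## Worked example

Calculate transverse version from coronal and sagittal angles:

```sh
$ stemver convert angles.csv angles_tv.csv
wrote angles_tv.csv: 3 rows, 1 flagged
$ cat angles_tv.csv
hip_id,ci_deg,si_deg,tv_deg,status
1,50.0,11.3,13.394700682497255,ok
2,45.0,45.0,44.99999999999999,ok
3,90.0,10.0,,"degenerate: ci outside open (0, 90) deg"
```

Hip 1: CI 50.0° and SI 11.3° imply TV = arctan(tan 11.3° · tan 50.0°) =
13.4°. Hip 3 is rejected, not silently computed: at CI = 90° the tangent is
undefined and the reconstruction is degenerate.

Run the synthetic validation study (10,000 virtual hips, measurement noise
calibrated so the median manual-vs-calculated TV difference is 1.3°, and a
third image series with the sagittal plane at 85° to the coronal):

```sh
$ stemver validate --n 10000 --seed 1 --delta 5
noise sigma: 1.173 deg
 replicate                                 series  icc  icc_ci_low  icc_ci_high  bias  loa_low  loa_high  median_abs_diff  mad_iqr_low  mad_iqr_high     n
         0                   manual_vs_calculated 0.96        0.96         0.96  -0.0     -3.9       3.9              1.3          0.6           2.2 10000
         0 orthogonal_vs_nonorthogonal_calculated 0.77       -0.06         0.93   4.8      0.3       9.3              4.8          3.4           6.2 10000
```

Reading the table: with realistic manual noise the calculated TV agrees
with the manually measured TV almost perfectly (ICC 0.96, no bias, 95% of
errors within ±3.9°), while a 5° plane misalignment biases the calculated
TV by almost 5° median — non-orthogonal imaging, not the algorithm, is the
dominant error source.

In Python the same pieces compose directly:

```python
>>> import stemver as sv
>>> sv.tv_from_ci_si(50.0, 11.3)
13.394700682497255
>>> sv.apparent_tv(10.8, 5.0)        # 85-degree biplanar acquisition
5.873842504726907
>>> axis = sv.axis_from_angles(ci=50.0, tv=10.8)
>>> sv.angles_from_axis(axis)
OrientationAngles(ci=50.0, si=9.09400956143727, tv=10.8)
```

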