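# musclevol

Estimation of skeletal muscle volume from serial MRI cross-sectional areas,
with tools to quantify how much accuracy is lost when an analyst segments
fewer slices.

Manual segmentation of the quadriceps on axial MRI is the accurate but
laborious way to measure muscle volume (MV) — a key quantity in sarcopenia
research, e.g. in end-stage liver disease cohorts where muscle loss predicts
complications and mortality. Because each segmented slice costs minutes of
expert time, a standard workload reduction is to segment only every 2nd,
3rd or 4th slice of a 1 cm acquisition. This package implements that whole
analysis loop:

- **ACSA series handling** — read/write per-subject tables of anatomical
  cross-sectional area (ACSA, cm²) along the limb axis, digitize them from
  3-D label masks (NIfTI), and restrict them to the standard quadriceps ROI
  (from 20 % above the proximal patella to the first appearance of the
  lesser trochanter).
- **Volume estimators** — the cylindrical (Cavalieri) equation
  `MV = Σ ACSAₙ · d` and the truncated-cone equation
  `MV = Σ (d/3)(Aₙ + √(Aₙ Aₙ₊₁) + Aₙ₊₁)`, plus slice-interval subsampling
  with configurable grid offset.
- **Agreement statistics** — absolute and relative error versus the 1 cm
  reference, Bland-Altman bias and 95 % limits of agreement, two-way mixed
  ICC for inter-rater reliability, Pearson correlation (e.g. against L3
  skeletal muscle index).
- **Synthetic phantoms** — parametric muscle phantoms (constant, conical
  frustum, quadratic, and a quadriceps-like spline profile) with
  analytically known volumes, a voxelizer for mask-based tests, and a
  cohort simulator; every estimator is validated against closed-form or
  quadrature ground truth.

## Worked example

Run the full synthetic study (38 subjects, 23 ACSA slices at 1 cm each,
both equations at 1–4 cm intervals):

```python
from musclevol import CohortSpec, RunConfig, run

result = run(RunConfig(cohort=CohortSpec(seed=1), output_dir="demo_run"))
print(result.agreement.round(2).to_string(index=False))
```

```
      equation  interval_cm  n  mean_bias_cm3  loa_low_cm3  loa_high_cm3  n_within_loa  mean_abs_err_cm3  sd_abs_err_cm3  mean_rel_err_pct  sd_rel_err_pct
      cylinder          2.0 38           3.23        -0.67          7.14            37              3.29            1.89              0.35            0.19
      cylinder          3.0 38           8.18         2.27         14.09            37              8.18            3.01              0.89            0.30
      cylinder          4.0 38          13.33         4.45         22.22            36             13.33            4.53              1.44            0.41
truncated_cone          2.0 38           0.57        -3.02          4.16            36              1.53            1.13              0.17            0.13
truncated_cone          3.0 38           1.80        -3.22          6.82            37              2.53            1.82              0.29            0.22
truncated_cone          4.0 38           3.19        -3.82         10.20            37              3.88            2.79              0.44            0.30
```

Reading the table: each row is one (equation × slice interval) cell over the
cohort. `mean_bias_cm3` is the mean of (1 cm volume − coarse volume): it is
positive everywhere, i.e. coarser sampling systematically *under*-estimates
volume on these convex profiles, and it grows with the interval. The
truncated cone stays well under half the cylindrical equation's error at 3
and 4 cm — on a ~920 cm³ quadriceps, segmenting every 4th slice with the
truncated-cone equation costs only ~0.4 % accuracy. ~95 % of subjects fall
within the Bland-Altman limits of agreement (`n_within_loa` of 38).

The same experiment is available from the shell:

```sh
musclevol simulate --n 38 --seed 1 --out cohort_dir     # per-subject ACSA CSVs
musclevol volumes --input cohort_dir --intervals 1,2,3,4 --equations cylinder,cone
musclevol run --config cfg.yaml --seed 1 --out demo_run  # full configured study
```

## Layout

- `src/musclevol/acsa.py` — ACSA series type, CSV/NIfTI ingestion, ROI restriction
- `src/musclevol/volume.py` — subsampling and the two volume estimators
- `src/musclevol/agreement.py` — error records, Bland-Altman, ICC, Pearson
- `src/musclevol/phantom.py` — phantom profiles, analytic volumes, cohort simulator, voxelizer
- `src/musclevol/pipeline.py` / `cli.py` — orchestration, YAML config, `musclevol` CLI
- `docs/methods.md` — models, conventions, parameter choices and limitations
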