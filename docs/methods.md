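# Methods

## The measurement model

A subject's quadriceps is represented by its anatomical cross-sectional
area profile A(z) (cm²) along the limb axis z (cm), measured on a uniform
acquisition grid of spacing Δ (1 cm by default), indexed distal→proximal.
Muscle volume over the analyzed region is the integral ∫A(z)dz, which the
two estimators approximate from the slice samples:

- **Cylindrical (Cavalieri):** `MV = Σₙ Aₙ · dₙ` — each analyzed slice is
  extruded over the axial distance it represents.
- **Truncated cone:** `MV = Σₙ (hₙ/3)(Aₙ + √(Aₙ Aₙ₊₁) + Aₙ₊₁)` — each
  consecutive pair of slices bounds a conical frustum. For circular
  cross-sections whose radius varies linearly between slices this is exact,
  which is what makes it the stronger interpolant on smoothly tapering
  muscle.

The frustum term uses the geometric mean √(Aₙ Aₙ₊₁). A version of the
formula sometimes appears in print with a bare product Aₙ·Aₙ₊₁ in place of
the geometric mean; that form is dimensionally inconsistent (cm⁴ added to
cm²) and cannot be what any working implementation computes, so only the
geometric-mean form is provided.

## Slice-interval subsampling

Analyzing at a coarser interval k·Δ means keeping slices 0, k, 2k, …
(offset 0 retains the distal-most slice; other offsets are available for
sensitivity analysis). When the series length is not divisible by k the
**terminal (most proximal) slice is always retained**, leaving one shorter
end segment. Rationale: an analyst reducing workload still segments the
anatomical boundary slice; and only under this convention is the analyzed
extent of muscle identical at every interval, so that the error measured
between intervals is purely an interpolation error. Dropping the remainder
instead (available via `include_last=False`) truncates up to k−1 cm of
muscle at the proximal end and produces errors an order of magnitude larger
that reflect anatomy loss, not equation quality; the observed error regime
(sub-1 % at 4 cm) is only attainable with the end slice retained.

End-segment conventions per estimator, on a subsampled series:

- **Truncated cone** uses the true per-segment length hₙ, so the shorter
  terminal segment is handled natively and the estimator always covers
  exactly the span from the first to the last analyzed slice.
- **Cylinder** extrudes each slice over the gap to the next analyzed slice
  and the terminal slice over one *acquisition* slab Δ. On an unsubsampled
  series this reduces exactly to `Δ·ΣAₙ`; across intervals it keeps the
  total extruded extent constant (span + Δ), again making estimates
  comparable. A consequence worth knowing: relative to the span integral
  ∫A dz the cylindrical sum carries a systematic surplus of about
  (A_first + A_last)/2 · Δ (it extrudes N slabs over an N−1-gap span), so
  "recovery of analytic truth" statements apply to the truncated cone; the
  cylinder is compared against its own 1 cm reference, as in practice.

Both estimators are linear in area and in axial scale (volume scales as
c·MV under A→c·A or Δ→c·Δ), and both converge to ∫A dz as Δ→0, the cone at
O(Δ²), the cylinder at O(Δ) through its end terms.

## Error and agreement statistics

The comparator is always the same-equation estimate at the smallest
analyzed interval (1 cm). Per subject and interval: signed difference
d = MV_ref − MV_k, absolute error |d|, relative error 100·|d|/MV_ref.
Bland-Altman: mean bias d̄ and 95 % limits of agreement d̄ ± 1.96·SD(d)
(sample SD, ddof 1); points on the boundary count as within the limits.
Inter-rater reliability uses the two-way mixed-model ICC for fixed raters,
single-rater **consistency** form ICC(3,1) = (MS_subjects − MS_error) /
(MS_subjects + (k−1)·MS_error), with exact F-based 95 % confidence bounds;
consistency (invariant to a constant offset between two fixed
investigators) is the natural choice for a two-investigator reliability
check, and the absolute-agreement form ICC(2,1) is available behind
`form="agreement"` (Satterthwaite CI). Negative ICC point estimates are
clipped to 0 with a warning. Pearson correlation (scipy) relates volume to
an externally supplied L3 skeletal muscle index column; the default cell is
the truncated-cone 4 cm estimate, the cheapest estimate the error analysis
supports.

## The synthetic cohort

No patient ACSA data are distributable, so validation uses phantoms with
known volume. The default cohort emulates a restricted-ROI quadriceps
study at desk scale:

- **Profile**: a natural cubic spline through control areas
  (31.5, 37.8, 41.4, 43.2, 41.4, 36.9) cm² at (0, 20, 40, 60, 80, 100) % of
  a 22 cm ROI — a smooth convex profile rising from the distal cut to a
  peak at 60 % of ROI length with a mild decline toward the lesser
  trochanter, integrating to ≈905 cm³. The proximal end sitting ~5 cm²
  above the distal end reflects that the distal cut (20 % above the
  patella) removes more muscle than the proximal cut; this asymmetry is
  what gives the cylindrical equation its characteristic extra
  underestimation at coarse intervals, while the profile's curvature drives
  the (smaller) truncated-cone error.
- **Slices**: 23 contiguous slices at 1 cm (offset 0 = distal cut).
- **Between-subject variability**: a lognormal size factor
  exp(N(0, 0.15)) scaling the whole profile — cohort volumes ≈900 ± 140 cm³,
  a realistic spread for a mixed-sex patient cohort. Shape is deliberately
  held fixed; size variation dominates between-subject ACSA differences and
  keeps the ground truth analytic.
- **Measurement noise**: i.i.d. Gaussian area noise with SD 0.4 cm²
  (≈1 % of mean slice area), matching the near-perfect (ICC ≈ 0.999)
  repeatability reported for careful manual segmentation; clipped at 0.
- **IMAT dropout** (off by default): each slice's area multiplied by an
  independent (1−U) factor, U ~ Uniform(0, d), modeling slice-wise
  exclusion of fat-infiltrated tissue in myosteatotic muscle.
- **Seeding**: subject i uses `SeedSequence(cohort_seed, spawn_key=(i,))`,
  so any subject regenerates in isolation; a cohort is bit-reproducible.

Ground truth per subject is the analytic volume of the scaled noiseless
profile over the sampled span (closed form for polynomial/frustum families,
adaptive quadrature at 1e-12 relative tolerance for the spline).

What the phantoms do **not** model: MRI signal formation (no T1 contrast,
partial-volume or bias-field effects), non-circular cross-sections in the
voxelizer, shape variation between subjects, spatially correlated
segmentation error, and systematic inter-rater disagreement. Passing tests
therefore demonstrate the estimators' numerical behavior on smooth convex
profiles of the study's geometry — not segmentation accuracy on real
images.

## ROI restriction

Landmarks are slice indices: the first slice showing the lesser trochanter
(proximal limit, inclusive) and the slice at the proximal aspect of the
patella. The distal cut is "20 % above the patella", interpreted as 20 % of
the patella→trochanter distance — the only reference length defined by the
two landmarks; the fraction is configurable. The cut rounds *up* to the
first slice at or above the cut position (no partial slices). Output is a
contiguous sub-series with areas untouched and cut indices recorded in
provenance.

## Numerical choices and degenerate inputs

- Spacing uniformity is enforced at relative tolerance 1e-9; the single
  shorter terminal gap is the only sanctioned non-uniformity.
- Zero-area slices are legal everywhere (√(0·A) = 0 exactly); interior
  zeros are retained by mask digitization (they occur under severe IMAT
  exclusion), while leading/trailing empty slices are trimmed.
- Voxelization uses a center-of-voxel inclusion rule on circular sections
  of radius √(A/π); in-plane resolution coarser than the maximal radius is
  rejected. Rasterized areas converge to A(z) as the in-plane step shrinks
  (≈2 % at 0.5 mm for decimeter-scale muscles).
- Volume estimates carry provenance (equation, interval, offset, slice
  count); tables round-trip through CSV bit-exactly (shortest round-trip
  float formatting, `float_precision="round_trip"` parsing).
- Bland-Altman requires n ≥ 3 (sample SD unstable below), ICC requires
  ≥ 5 subjects and no missing cells.

## Problem sizes

The default experiment (38 subjects × 23 slices × 4 intervals × 2
equations) runs in well under a second; the seed-robustness property is
checked across 10 cohort seeds, the limits-of-agreement coverage on 10⁴
synthetic differences, and the reliability regime on 1000 replicated 8×2
rating matrices — sizes chosen so the whole suite stays interactive while
the Monte-Carlo standard errors remain far below the asserted tolerances.

## Known limitations

- The cylindrical estimator's end-slab surplus means it does not estimate
  the span integral but the N-slab extrusion; this is the printed equation's
  behavior, kept deliberately, and documented above.
- The ICC confidence interval for the agreement form uses the Satterthwaite
  approximation (exact only for consistency); both forms are cross-checked
  against an independent implementation in the tests.
- The factorial (interval × equation) inferential analysis (two-way ANOVA)
  is out of scope; `summarize_by_cell` emits the per-cell table such an
  analysis would consume.
- `correlate_with_smi` treats L3 SMI as a given numeric column; computing
  SMI from L3 images is out of scope.
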