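"""Parametric muscle phantoms with analytically known volumes.

The study data (serial quadriceps ACSA measurements from patient MRI) are
not publicly available, so validation rests on synthetic phantoms: smooth
area profiles A(z) with closed-form or quadrature-exact volumes, sampled
onto a slice grid the way a segmenter would measure them, optionally with
Gaussian area noise and slice-wise fat-infiltration (IMAT) dropout.

Profile families
----------------
* ``constant`` — A(z) = A; the trivial sanity case.
* ``frustum`` — circular cross-section, radius linear in z; the truncated
  cone estimator is exact on it at any interval, making it the oracle for
  estimator exactness.
* ``quadratic_area`` — A(z) a quadratic polynomial; closed-form volume and a
  smooth convex profile for convergence studies.
* ``quadriceps_spline`` — a natural cubic spline through fixed control
  areas: monotone rise from the distal ROI cut to a peak at 60 % of the ROI
  length, mild decline to the proximal (lesser trochanter) end.  This is the
  default cohort profile, emulating a restricted-ROI quadriceps of ~900 cm³.

The default cohort emulates the study geometry: 38 subjects, 23 contiguous
1 cm slices (a 22 cm restricted ROI), between-subject size variation as a
lognormal scale factor, and mild segmentation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

from .acsa import ACSASeries

FAMILIES = ("constant", "frustum", "quadratic_area", "quadriceps_spline")

#: default quadriceps template: control areas (cm²) at fixed fractions of the
#: ROI length.  Peak at 60 % of ROI length; proximal end ~5 cm² above the
#: distal cut.  Integrates to ~905 cm³ over the default 22 cm ROI.
QUADRICEPS_CONTROL_FRACTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
QUADRICEPS_CONTROL_AREAS = (31.5, 37.8, 41.4, 43.2, 41.4, 36.9)
DEFAULT_ROI_LENGTH_CM = 22.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric muscle phantom: an area profile A(z) ≥ 0 on [0, length]."""

    family: str
    parameters: dict
    length: float
    name: str = "phantom"
    scale: float = 1.0  # multiplies A(z); used for between-subject size

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def area_function(self) -> Callable[[np.ndarray], np.ndarray]:
        """Vectorized A(z) in cm² for z in cm."""
        p = self.parameters
        c = self.scale
        if self.family == "constant":
            a0 = float(p["area"])
            return lambda z: c * a0 * np.ones_like(np.asarray(z, dtype=float))
        if self.family == "frustum":
            r0, r1, L = float(p["r0"]), float(p["r1"]), self.length
            return lambda z: c * np.pi * (r0 + (r1 - r0) * np.asarray(z, dtype=float) / L) ** 2
        if self.family == "quadratic_area":
            c0, c1, c2 = (float(p[k]) for k in ("c0", "c1", "c2"))
            return lambda z: c * np.polyval([c2, c1, c0], np.asarray(z, dtype=float))
        # quadriceps_spline
        fr = np.asarray(p["control_fractions"], dtype=float)
        ar = np.asarray(p["control_areas"], dtype=float)
        cs = CubicSpline(fr * self.length, ar, bc_type="natural")
        return lambda z: c * cs(np.asarray(z, dtype=float))

    def area(self, z) -> np.ndarray:
        return self.area_function()(z)


def default_quadriceps(
    length: float = DEFAULT_ROI_LENGTH_CM, scale: float = 1.0
) -> PhantomSpec:
    """The default restricted-ROI quadriceps template (see module docstring)."""
    return PhantomSpec(
        family="quadriceps_spline",
        parameters={
            "control_fractions": QUADRICEPS_CONTROL_FRACTIONS,
            "control_areas": QUADRICEPS_CONTROL_AREAS,
        },
        length=length,
        name="quadriceps_template",
        scale=scale,
    )


def analytic_volume(spec: PhantomSpec, z0: float, z1: float) -> float:
    """Ground-truth volume ∫ A(z) dz over [z0, z1] (cm³).

    Closed form for constant / frustum / quadratic families; adaptive
    quadrature (relative tolerance 1e-12) for the spline family.
    """
    if not (0 <= z0 < z1 <= spec.length):
        raise ValueError(
            f"invalid bounds [{z0}, {z1}] for phantom of length {spec.length}"
        )
    p, c = spec.parameters, spec.scale
    if spec.family == "constant":
        return c * float(p["area"]) * (z1 - z0)
    if spec.family == "frustum":
        r0, r1, L = float(p["r0"]), float(p["r1"]), spec.length
        s = (r1 - r0) / L

        def r3(z: float) -> float:
            return (r0 + s * z) ** 3

        if s == 0:
            return c * np.pi * r0**2 * (z1 - z0)
        return c * np.pi * (r3(z1) - r3(z0)) / (3 * s)
    if spec.family == "quadratic_area":
        c0, c1, c2 = (float(p[k]) for k in ("c0", "c1", "c2"))

        def antideriv(z: float) -> float:
            return c0 * z + c1 * z**2 / 2 + c2 * z**3 / 3

        return c * (antideriv(z1) - antideriv(z0))
    f = spec.area_function()
    val, _ = quad(f, z0, z1, epsabs=1e-12, epsrel=1e-12, limit=500)
    return float(val)


def sample_series(
    spec: PhantomSpec,
    spacing: float = 1.0,
    noise_sd: float = 0.0,
    imat_dropout: float = 0.0,
    seed=None,
    n_slices: int | None = None,
    subject_id: str | None = None,
) -> ACSASeries:
    """Measure the phantom on a uniform slice grid, as a segmenter would.

    Areas are A(z_i) + ε_i with ε_i ~ N(0, noise_sd), clipped at 0.  IMAT
    dropout multiplies each slice area by an independent (1 − U_i) factor,
    U_i ~ Uniform(0, imat_dropout), modeling slice-wise exclusion of
    fat-infiltrated tissue.  Deterministic given ``seed`` (int, SeedSequence
    or Generator).
    """
    if spacing <= 0 or spacing > spec.length / 2:
        raise ValueError(
            f"spacing must lie in (0, length/2] = (0, {spec.length / 2}], got {spacing}"
        )
    if not 0 <= imat_dropout < 1:
        raise ValueError("imat_dropout must lie in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_slices is None:
        n_slices = int(np.floor(spec.length / spacing + 1e-12)) + 1
    z = np.arange(n_slices) * spacing
    if z[-1] > spec.length * (1 + 1e-12):
        raise ValueError(f"{n_slices} slices at {spacing} cm exceed phantom length")
    areas = np.asarray(spec.area(z), dtype=float)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        areas = areas + rng.normal(0.0, noise_sd, size=areas.shape)
    if imat_dropout > 0:
        areas = areas * (1.0 - rng.uniform(0.0, imat_dropout, size=areas.shape))
    areas = np.clip(areas, 0.0, None)
    return ACSASeries(
        subject_id=subject_id or spec.name,
        positions=z.astype(float),
        areas=areas,
        spacing=float(spacing),
        provenance={
            "phantom_family": spec.family,
            "noise_sd": noise_sd,
            "imat_dropout": imat_dropout,
        },
    )


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort configuration (defaults emulate the study geometry)."""

    n_subjects: int = 38
    base_profile: PhantomSpec = field(default_factory=default_quadriceps)
    between_subject_scale_sd: float = 0.15  # lognormal sigma of size factor
    roi_slices: int = 23
    spacing: float = 1.0
    area_noise_sd: float = 0.4  # cm², ~1 % of mean slice area
    imat_dropout: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.roi_slices < 2:
            raise ValueError("roi_slices must be >= 2")
        for name in ("between_subject_scale_sd", "area_noise_sd", "imat_dropout"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def subject_seed_sequence(cohort_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Per-subject sub-seed: SeedSequence(cohort_seed, spawn_key=(i,)).

    Documented so any subject can be regenerated in isolation.
    """
    return np.random.SeedSequence(entropy=cohort_seed, spawn_key=(subject_index,))


def generate_cohort(spec: CohortSpec) -> list[tuple[ACSASeries, float]]:
    """Simulate a cohort of (ACSA series, true volume) pairs.

    Each subject is the base profile scaled by an independent lognormal size
    factor exp(N(0, between_subject_scale_sd)), then sampled on the slice
    grid with the configured noise/dropout.  The true volume is the analytic
    volume of the scaled *noiseless* profile over the sampled span.
    """
    out = []
    span = (spec.roi_slices - 1) * spec.spacing
    if span > spec.base_profile.length * (1 + 1e-12):
        raise ValueError(
            f"{spec.roi_slices} slices at {spec.spacing} cm exceed the "
            f"base profile length {spec.base_profile.length} cm"
        )
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(subject_seed_sequence(spec.seed, i))
        size = float(np.exp(rng.normal(0.0, spec.between_subject_scale_sd)))
        profile = replace(spec.base_profile, scale=spec.base_profile.scale * size)
        series = sample_series(
            profile,
            spacing=spec.spacing,
            noise_sd=spec.area_noise_sd,
            imat_dropout=spec.imat_dropout,
            seed=rng,
            n_slices=spec.roi_slices,
            subject_id=f"S{i + 1:03d}",
        )
        true_volume = analytic_volume(profile, 0.0, span)
        out.append((series, true_volume))
    return out


def voxelize(
    spec: PhantomSpec, in_plane_mm: float = 0.5, slice_mm: float = 10.0
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Rasterize the phantom as a 3-D integer label mask.

    Each axial slice is a filled circle of area A(z) (radius √(A/π)) on a
    square grid; a voxel belongs to the muscle when its *center* falls
    inside the circle.  Returns ``(mask, (dx, dy, dz))`` with voxel
    dimensions in mm, label 1 inside and 0 outside — a fixture generator for
    :func:`musclevol.acsa.series_from_mask`.
    """
    if in_plane_mm <= 0 or slice_mm <= 0:
        raise ValueError("resolutions must be positive")
    n_slices = int(np.floor(spec.length / (slice_mm / 10.0) + 1e-12)) + 1
    z = np.arange(n_slices) * (slice_mm / 10.0)
    areas = np.asarray(spec.area(z), dtype=float)
    r_max_mm = np.sqrt(max(areas.max(), 0.0) / np.pi) * 10.0
    if r_max_mm <= 0:
        raise ValueError("phantom has zero area everywhere")
    if in_plane_mm > r_max_mm:
        raise ValueError(
            f"in-plane resolution {in_plane_mm} mm coarser than the maximum "
            f"phantom radius {r_max_mm:.2f} mm"
        )
    half = int(np.ceil(r_max_mm / in_plane_mm)) + 2
    nxy = 2 * half + 1
    coords = (np.arange(nxy) - half) * in_plane_mm  # voxel centers
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    rho2 = xx**2 + yy**2
    mask = np.zeros((nxy, nxy, n_slices), dtype=np.int16)
    for j, a in enumerate(areas):
        if a <= 0:
            continue
        r_mm = np.sqrt(a / np.pi) * 10.0
        mask[:, :, j] = np.where(rho2 <= r_mm**2, 1, 0)
    return mask, (in_plane_mm, in_plane_mm, slice_mm)


def write_cohort(cohort, out_dir) -> None:
    """One ACSA CSV per subject plus a cohort_manifest.csv with true volumes."""
    from pathlib import Path

    import pandas as pd

    from .acsa import write_acsa_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for series, true_volume in cohort:
        write_acsa_table(series, out_dir / f"{series.subject_id}.csv")
        rows.append((series.subject_id, true_volume))
    pd.DataFrame(rows, columns=["subject_id", "true_volume_cm3"]).to_csv(
        out_dir / "cohort_manifest.csv", index=False
    )
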