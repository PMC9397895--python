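"""Anatomical cross-sectional area (ACSA) series: construction, IO, ROI handling.

An ACSA series is an ordered sequence of muscle cross-sectional areas (cm²)
measured on axial slices along the limb axis, indexed distal→proximal.  It is
the universal currency of the volume-estimation pipeline: estimators consume
it, the phantom generator produces it, and tabular/mask readers construct it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("musclevol")

#: relative tolerance for judging two slice gaps equal
SPACING_RTOL = 1e-9

MM2_PER_CM2 = 100.0
MM_PER_CM = 10.0


@dataclass(frozen=True)
class SliceRecord:
    """One axial slice: 0-based index (distal→proximal), position (cm), area (cm²)."""

    index: int
    position_cm: float
    area_cm2: float

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"slice index must be >= 0, got {self.index}")
        if self.area_cm2 < 0:
            raise ValueError(f"slice area must be >= 0, got {self.area_cm2}")


@dataclass
class ACSASeries:
    """Uniformly spaced ACSA sequence along the limb axis.

    Positions are in cm and strictly increasing distal→proximal.  All
    consecutive gaps must equal ``spacing`` (relative tolerance 1e-9), with
    one sanctioned exception: a series produced by interval subsampling may
    carry a single *shorter* terminal gap, so that the proximal end slice is
    retained when the span is not divisible by the sampling interval.

    ``source_spacing`` records the spacing of the underlying acquisition
    grid (equals ``spacing`` for unsubsampled series); the cylindrical
    estimator uses it to extrude the terminal slice consistently across
    sampling intervals.
    """

    subject_id: str
    positions: np.ndarray
    areas: np.ndarray
    spacing: float
    units_note: str = "positions cm, areas cm^2"
    source_spacing: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.areas.shape:
            raise ValueError("positions and areas must be 1-D arrays of equal length")
        if self.positions.size == 0:
            raise ValueError("empty ACSA series")
        if np.any(self.areas < 0):
            bad = np.flatnonzero(self.areas < 0)
            raise ValueError(f"negative areas at slice indices {bad.tolist()}")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.source_spacing is None:
            self.source_spacing = self.spacing
        gaps = np.diff(self.positions)
        if np.any(gaps <= 0):
            raise ValueError("positions must be strictly increasing")
        if gaps.size:
            interior = gaps[:-1]
            if not np.allclose(interior, self.spacing, rtol=SPACING_RTOL, atol=0):
                bad = np.flatnonzero(
                    ~np.isclose(interior, self.spacing, rtol=SPACING_RTOL, atol=0)
                )
                raise ValueError(
                    f"non-uniform spacing: gaps after slices {bad.tolist()} "
                    f"differ from spacing {self.spacing}"
                )
            # terminal gap may be shorter (subsampled partial end segment)
            if gaps[-1] > self.spacing * (1 + SPACING_RTOL):
                raise ValueError(
                    f"terminal gap {gaps[-1]} exceeds spacing {self.spacing}"
                )

    # -- views -----------------------------------------------------------

    @property
    def n_slices(self) -> int:
        return int(self.positions.size)

    @property
    def span(self) -> float:
        """Axial extent from first to last slice (cm)."""
        return float(self.positions[-1] - self.positions[0])

    @property
    def has_partial_end(self) -> bool:
        """True when the terminal gap is shorter than the nominal spacing."""
        if self.n_slices < 2:
            return False
        last = self.positions[-1] - self.positions[-2]
        return not np.isclose(last, self.spacing, rtol=SPACING_RTOL, atol=0)

    @property
    def slices(self) -> list[SliceRecord]:
        return [
            SliceRecord(i, float(p), float(a))
            for i, (p, a) in enumerate(zip(self.positions, self.areas))
        ]

    def __len__(self) -> int:
        return self.n_slices


@dataclass(frozen=True)
class RoiLandmarks:
    """Restricted-ROI landmarks on a distal→proximal series.

    ``trochanter_index`` is the first slice showing the lesser trochanter
    (proximal cut, inclusive); ``patella_index`` the slice at the proximal
    aspect of the patella.  The distal cut sits ``distal_fraction`` of the
    patella→trochanter distance above the patella.
    """

    trochanter_index: int
    patella_index: int
    distal_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.trochanter_index <= self.patella_index:
            raise ValueError(
                "trochanter_index must exceed patella_index on a "
                "distal→proximal series (empty ROI otherwise)"
            )
        if not 0 <= self.distal_fraction < 1:
            raise ValueError("distal_fraction must lie in [0, 1)")


# -- tabular IO ------------------------------------------------------------

TABLE_COLUMNS = ["subject_id", "index", "position_cm", "area_cm2"]


def read_acsa_table(path: str | Path) -> ACSASeries:
    """Read one subject's ACSA series from a CSV table.

    Required columns: ``index``, ``position_cm``, ``area_cm2`` (``subject_id``
    optional; defaults to the file stem).  Rows are sorted by position; the
    spacing is inferred as the median consecutive difference and every gap
    must match it to relative tolerance 1e-9.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"index", "position_cm", "area_cm2"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty table")
    subject = (
        str(df["subject_id"].iloc[0]) if "subject_id" in df.columns else path.stem
    )
    df = df.sort_values("position_cm", kind="stable").reset_index(drop=True)
    if np.any(df["area_cm2"].to_numpy() < 0):
        bad = df.index[df["area_cm2"] < 0].tolist()
        raise ValueError(f"{path}: negative areas at rows {bad}")
    pos = df["position_cm"].to_numpy(dtype=float)
    gaps = np.diff(pos)
    if gaps.size == 0:
        spacing = 1.0
    else:
        spacing = float(np.median(gaps))
        ok = np.isclose(gaps, spacing, rtol=SPACING_RTOL, atol=0)
        if not ok.all():
            bad = np.flatnonzero(~ok)
            raise ValueError(
                f"{path}: non-uniform spacing at rows {bad.tolist()} "
                f"(expected gap {spacing})"
            )
    return ACSASeries(
        subject_id=subject,
        positions=pos,
        areas=df["area_cm2"].to_numpy(dtype=float),
        spacing=spacing,
        provenance={"source": str(path)},
    )


def write_acsa_table(series: ACSASeries, path: str | Path) -> Path:
    """Write a series to CSV (full float precision; round-trips bit-exactly)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "index": np.arange(series.n_slices),
            # shortest round-trip float representation: bit-exact re-read
            "position_cm": [repr(float(v)) for v in series.positions],
            "area_cm2": [repr(float(v)) for v in series.areas],
        }
    )
    df.to_csv(path, index=False)
    return path


# -- mask digitization -----------------------------------------------------


def series_from_mask(
    mask,
    label: int,
    voxel_dims_mm: Sequence[float],
    axis: int = 2,
    subject_id: str = "mask",
) -> ACSASeries:
    """Per-slice label areas from a 3-D integer label mask.

    ``mask`` may be an integer array or a path to a NIfTI file.  Per axial
    slice (along ``axis``), area = voxel count × dx·dy in cm²; positions are
    slice_index × dz in cm.  Leading/trailing all-background slices are
    trimmed; interior zero-area slices are kept as genuine zeros.
    """
    if isinstance(mask, (str, Path)):
        img = nib_load(Path(mask))
        data = np.asanyarray(img.dataobj)
    else:
        data = np.asarray(mask)
    if data.ndim != 3:
        raise ValueError(f"mask must be 3-D, got {data.ndim}-D")
    dx, dy, dz = (float(v) for v in voxel_dims_mm)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("voxel dimensions must be positive")
    if not np.isclose(dx, dy):
        logger.warning(
            "anisotropic in-plane voxels (dx=%g mm, dy=%g mm); "
            "areas use dx*dy regardless",
            dx,
            dy,
        )
    hit = data == label
    if not hit.any():
        raise ValueError(f"label {label} absent from mask")
    # move the axial axis last, flatten in-plane
    hit = np.moveaxis(hit, axis, -1)
    counts = hit.sum(axis=(0, 1))
    nz = np.flatnonzero(counts)
    lo, hi = nz[0], nz[-1]
    counts = counts[lo : hi + 1]
    areas = counts * dx * dy / MM2_PER_CM2
    spacing_cm = dz / MM_PER_CM
    positions = (np.arange(lo, hi + 1) * spacing_cm).astype(float)
    # re-zero origin at the first retained slice
    positions = positions - positions[0]
    return ACSASeries(
        subject_id=subject_id,
        positions=positions,
        areas=areas.astype(float),
        spacing=spacing_cm,
        provenance={"label": label, "trimmed_leading": int(lo)},
    )


def nib_load(path: Path):
    import nibabel as nib

    return nib.load(str(path))


# -- ROI restriction -------------------------------------------------------


def restrict_roi(series: ACSASeries, landmarks: RoiLandmarks) -> ACSASeries:
    """Restrict a series to the analyzed region of interest.

    Keeps the contiguous sub-series from the distal cut up to (and
    including) ``trochanter_index``.  The distal cut is the smallest slice
    index whose position is at least ``distal_fraction`` of the
    patella→trochanter distance above the patella slice.
    """
    n = series.n_slices
    lm = landmarks
    if not (0 <= lm.patella_index < n and 0 <= lm.trochanter_index < n):
        raise ValueError(
            f"landmark indices ({lm.patella_index}, {lm.trochanter_index}) "
            f"outside series of {n} slices"
        )
    p_pat = series.positions[lm.patella_index]
    p_tro = series.positions[lm.trochanter_index]
    cut_position = p_pat + lm.distal_fraction * (p_tro - p_pat)
    cut_index = int(np.searchsorted(series.positions, cut_position, side="left"))
    sub_pos = series.positions[cut_index : lm.trochanter_index + 1]
    sub_area = series.areas[cut_index : lm.trochanter_index + 1]
    if sub_pos.size < 2:
        raise ValueError(
            f"restricted ROI has {sub_pos.size} slice(s); at least 2 required"
        )
    return ACSASeries(
        subject_id=series.subject_id,
        positions=sub_pos.copy(),
        areas=sub_area.copy(),
        spacing=series.spacing,
        source_spacing=series.source_spacing,
        units_note=series.units_note,
        provenance={
            **series.provenance,
            "roi_cut_index": cut_index,
            "roi_trochanter_index": lm.trochanter_index,
            "roi_distal_fraction": lm.distal_fraction,
        },
    )
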