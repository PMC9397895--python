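"""End-to-end study orchestration.

``run(config)`` loads or simulates a cohort of ACSA series, optionally
restricts each series to the landmark ROI, runs the slice-interval ×
equation experiment, and writes the volume, error and agreement tables
(plus optional Bland-Altman plots).  Outputs are deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .acsa import ACSASeries, RoiLandmarks, read_acsa_table, restrict_roi, series_from_mask
from .agreement import (
    PairedVolumes,
    bland_altman_plot,
    compute_errors,
    errors_to_frame,
    pearson_correlation,
    summarize_by_cell,
    summary_to_frame,
)
from .phantom import CohortSpec, generate_cohort
from .volume import EQUATIONS, estimates_to_frame, run_interval_experiment

logger = logging.getLogger("musclevol")

DEFAULT_INTERVALS = (1.0, 2.0, 3.0, 4.0)


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class RunConfig:
    """Full description of one pipeline run (YAML-serializable)."""

    input_mode: str = "synthetic"  # synthetic | csv_dir | mask_dir
    input_dir: str | None = None  # for csv_dir / mask_dir modes
    mask_label: int = 1
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 10.0)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    intervals: Sequence[float] = DEFAULT_INTERVALS
    equations: Sequence[str] = EQUATIONS
    offset_policy: str = "first"
    roi: RoiLandmarks | None = None  # None = series are pre-restricted
    output_dir: str = "musclevol_run"
    seed: int | None = None  # overrides cohort.seed when given
    make_plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "csv_dir", "mask_dir"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if min(self.intervals) <= 0:
            raise ValueError("intervals must be positive")
        if self.input_mode != "synthetic" and not self.input_dir:
            raise ValueError(f"input_mode {self.input_mode!r} requires input_dir")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (fields mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "cohort" in raw and isinstance(raw["cohort"], dict):
        raw["cohort"] = CohortSpec(**raw["cohort"])
    if "roi" in raw and isinstance(raw["roi"], dict):
        raw["roi"] = RoiLandmarks(**raw["roi"])
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    output_dir: Path
    volumes: pd.DataFrame
    errors: pd.DataFrame
    agreement: pd.DataFrame
    manifest: pd.DataFrame | None = None


def _load_series(config: RunConfig) -> tuple[list[ACSASeries], pd.DataFrame | None]:
    if config.input_mode == "synthetic":
        cohort_spec = config.cohort
        if config.seed is not None:
            from dataclasses import replace

            cohort_spec = replace(cohort_spec, seed=config.seed)
        cohort = generate_cohort(cohort_spec)
        manifest = pd.DataFrame(
            [(s.subject_id, tv) for s, tv in cohort],
            columns=["subject_id", "true_volume_cm3"],
        )
        return [s for s, _ in cohort], manifest
    root = Path(config.input_dir)
    series = []
    if config.input_mode == "csv_dir":
        paths = sorted(p for p in root.glob("*.csv") if p.name != "cohort_manifest.csv")
        if not paths:
            raise ValueError(f"no ACSA CSV files found in {root}")
        for p in paths:
            try:
                series.append(read_acsa_table(p))
            except Exception as exc:
                raise ValueError(f"failed to read {p}: {exc}") from exc
    else:  # mask_dir
        paths = sorted(list(root.glob("*.nii")) + list(root.glob("*.nii.gz")))
        if not paths:
            raise ValueError(f"no NIfTI masks found in {root}")
        for p in paths:
            try:
                series.append(
                    series_from_mask(
                        p, config.mask_label, config.voxel_dims_mm, subject_id=p.stem
                    )
                )
            except Exception as exc:
                raise ValueError(f"failed to digitize {p}: {exc}") from exc
    return series, None


def run(config: RunConfig) -> RunResult:
    """Execute the full experiment and write artifacts to ``output_dir``.

    On any per-subject failure the partial outputs are removed and the error
    re-raised with the subject named.
    """
    configure_logging(config.log_level)
    out = Path(config.output_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        seed = config.seed if config.seed is not None else config.cohort.seed
        logger.info("run config hash %s, seed %s", _config_hash(config), seed)
        series_list, manifest = _load_series(config)
        estimates = []
        for series in series_list:
            try:
                if config.roi is not None:
                    series = restrict_roi(series, config.roi)
                estimates.extend(
                    run_interval_experiment(
                        series,
                        intervals=config.intervals,
                        equations=config.equations,
                        offset_policy=config.offset_policy,
                    )
                )
            except Exception as exc:
                raise RuntimeError(
                    f"estimation failed for subject {series.subject_id!r}: {exc}"
                ) from exc
        volumes = estimates_to_frame(estimates)
        errors = errors_to_frame(compute_errors(estimates))
        agreement = summary_to_frame(summarize_by_cell(compute_errors(estimates)))

        volumes.to_csv(out / "volumes.csv", index=False)
        errors.to_csv(out / "errors.csv", index=False)
        agreement.to_csv(out / "agreement.csv", index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(config), default=str)), fh)
        if manifest is not None:
            is_ref = (volumes["interval_cm"] == volumes["interval_cm"].min()) & (
                volumes["offset_cm"] == 0
            )
            ref = (
                volumes[is_ref]
                .pivot(index="subject_id", columns="equation", values="volume_cm3")
                .reset_index()
            )
            oracle = manifest.merge(ref, on="subject_id")
            oracle.to_csv(out / "oracle_vs_estimate.csv", index=False)
        if config.make_plots:
            _write_plots(estimates, out)
        return RunResult(out, volumes, errors, agreement, manifest)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _write_plots(estimates, out: Path) -> None:
    from .agreement import pair_with_reference

    pairs = pair_with_reference(estimates)
    cells: dict[tuple[str, float], list[PairedVolumes]] = {}
    for p in pairs:
        cells.setdefault((p.equation, p.interval_cm), []).append(p)
    for (eq, iv), ps in cells.items():
        bland_altman_plot(ps, out / f"bland_altman_{eq}_{iv:g}cm.png")


def correlate_with_smi(
    volumes: pd.DataFrame,
    smi: pd.DataFrame,
    equation: str = "truncated_cone",
    interval_cm: float = 4.0,
) -> dict:
    """Pearson correlation between estimated muscle volume and L3 SMI.

    ``volumes`` is the estimates table; ``smi`` has columns ``subject_id``
    and ``l3_smi`` (cm²/m²).  By default the truncated-cone 4 cm volumes are
    used.  Unmatched subjects are dropped with a warning; fewer than 3
    matches is an error.  Returns r, r², p and the matched scatter data.
    """
    sel = volumes[
        (volumes["equation"] == equation)
        & (volumes["interval_cm"] == interval_cm)
        & (volumes["offset_cm"] == 0)
    ][["subject_id", "volume_cm3"]]
    merged = sel.merge(smi[["subject_id", "l3_smi"]], on="subject_id", how="inner")
    dropped = len(sel) - len(merged)
    if dropped:
        logger.warning("%d subjects without L3 SMI dropped from correlation", dropped)
    if len(merged) < 3:
        raise ValueError(f"need >= 3 matched subjects, got {len(merged)}")
    r, r2, p = pearson_correlation(
        merged["volume_cm3"].to_numpy(), merged["l3_smi"].to_numpy()
    )
    return {"r": r, "r_squared": r2, "p_value": p, "data": merged}
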