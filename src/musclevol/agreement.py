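"""Agreement and error statistics for slice-interval volume experiments.

Given volume estimates at several slice intervals, the smallest interval
(1 cm in the study design) is the reference within each (subject, equation)
group.  This module computes the per-subject error records, Bland-Altman
bias and 95 % limits of agreement, per-cell (equation × interval) summary
tables, a two-way mixed-model intraclass correlation for inter-rater
reliability, and the Pearson correlation used to relate quadriceps volume
to L3 skeletal muscle index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume import VolumeEstimate

logger = logging.getLogger("musclevol")

#: two-sided 95 % normal quantile used for limits of agreement
LOA_FACTOR = 1.96


@dataclass(frozen=True)
class PairedVolumes:
    """Reference (smallest-interval) vs. comparison volume for one subject."""

    subject_id: str
    equation: str
    interval_cm: float
    reference_volume: float
    comparison_volume: float

    def __post_init__(self) -> None:
        if self.reference_volume < 0 or self.comparison_volume < 0:
            raise ValueError("volumes must be >= 0")


@dataclass(frozen=True)
class ErrorRecord:
    """Signed/absolute/relative error of one comparison vs. its reference."""

    subject_id: str
    equation: str
    interval_cm: float
    signed_difference: float  # reference - comparison (cm^3)
    absolute_error: float  # |signed_difference| (cm^3)
    relative_error: float  # 100 * absolute_error / reference (%)


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman bias/LOA plus error moments for one (equation, interval) cell."""

    equation: str
    interval_cm: float
    n_total: int
    mean_bias: float
    loa_low: float
    loa_high: float
    n_within_loa: int
    mean_abs_error: float
    sd_abs_error: float
    mean_rel_error: float
    sd_rel_error: float


# -- pairing and per-subject errors ---------------------------------------


def pair_with_reference(estimates: Iterable[VolumeEstimate]) -> list[PairedVolumes]:
    """Pair each coarse-interval estimate with its same-equation reference.

    The reference is the offset-0 estimate at the smallest interval present
    for that (subject, equation); every estimate at a larger interval forms
    one pair.  A missing reference raises, naming the subject.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates given")
    refs: dict[tuple[str, str], VolumeEstimate] = {}
    min_interval = min(e.interval_cm for e in estimates)
    for e in estimates:
        if e.interval_cm == min_interval and e.offset_cm == 0:
            refs[(e.subject_id, e.equation)] = e
    pairs = []
    for e in estimates:
        if e.interval_cm == min_interval:
            continue
        key = (e.subject_id, e.equation)
        if key not in refs:
            raise ValueError(
                f"subject {e.subject_id!r} has no {min_interval} cm reference "
                f"estimate for equation {e.equation!r}"
            )
        ref = refs[key]
        pairs.append(
            PairedVolumes(
                subject_id=e.subject_id,
                equation=e.equation,
                interval_cm=e.interval_cm,
                reference_volume=ref.volume_cm3,
                comparison_volume=e.volume_cm3,
            )
        )
    return pairs


def compute_errors(estimates: Iterable[VolumeEstimate]) -> list[ErrorRecord]:
    """Per-subject signed, absolute and relative (%) error vs. the reference."""
    out = []
    for p in pair_with_reference(estimates):
        d = p.reference_volume - p.comparison_volume
        if p.reference_volume == 0:
            raise ValueError(f"subject {p.subject_id!r}: zero reference volume")
        out.append(
            ErrorRecord(
                subject_id=p.subject_id,
                equation=p.equation,
                interval_cm=p.interval_cm,
                signed_difference=d,
                absolute_error=abs(d),
                relative_error=100.0 * abs(d) / p.reference_volume,
            )
        )
    return out


def errors_to_frame(errors: Iterable[ErrorRecord]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in errors])


# -- Bland-Altman ----------------------------------------------------------


def bland_altman(pairs: Sequence[PairedVolumes]) -> AgreementSummary:
    """Bland-Altman agreement of one cell of paired volumes.

    Differences are reference − comparison; bias is their mean and the 95 %
    limits of agreement are bias ± 1.96 × sample SD (ddof 1).  Points on the
    LOA boundary count as within.
    """
    if len(pairs) < 3:
        raise ValueError(f"Bland-Altman needs n >= 3 pairs, got {len(pairs)}")
    eqs = {p.equation for p in pairs}
    ivs = {p.interval_cm for p in pairs}
    if len(eqs) > 1 or len(ivs) > 1:
        raise ValueError("pairs span multiple (equation, interval) cells")
    d = np.array([p.reference_volume - p.comparison_volume for p in pairs])
    rel = np.array(
        [100.0 * abs(p.reference_volume - p.comparison_volume) / p.reference_volume for p in pairs]
    )
    return _summarize_cell(eqs.pop(), ivs.pop(), d, rel)


def _summarize_cell(
    equation: str, interval_cm: float, diffs: np.ndarray, rel: np.ndarray
) -> AgreementSummary:
    n = diffs.size
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1)) if n > 1 else 0.0
    lo, hi = bias - LOA_FACTOR * sd, bias + LOA_FACTOR * sd
    within = int(np.sum((diffs >= lo) & (diffs <= hi)))
    ad = np.abs(diffs)
    return AgreementSummary(
        equation=equation,
        interval_cm=interval_cm,
        n_total=n,
        mean_bias=bias,
        loa_low=lo,
        loa_high=hi,
        n_within_loa=within,
        mean_abs_error=float(np.mean(ad)),
        sd_abs_error=float(np.std(ad, ddof=1)) if n > 1 else 0.0,
        mean_rel_error=float(np.mean(rel)),
        sd_rel_error=float(np.std(rel, ddof=1)) if n > 1 else 0.0,
    )


def summarize_by_cell(errors: Sequence[ErrorRecord]) -> list[AgreementSummary]:
    """Mean ± SD of absolute/relative error plus Bland-Altman statistics per
    (equation × interval) cell — the table a downstream factorial analysis
    would consume."""
    if not errors:
        raise ValueError("no error records")
    df = errors_to_frame(list(errors))
    out = []
    for (eq, iv), grp in df.groupby(["equation", "interval_cm"], sort=True):
        if len(grp) == 1:
            logger.warning("cell (%s, %g cm) has n=1; SD reported as 0", eq, iv)
        out.append(
            _summarize_cell(
                eq,
                float(iv),
                grp["signed_difference"].to_numpy(),
                grp["relative_error"].to_numpy(),
            )
        )
    return out


def summary_to_frame(summaries: Iterable[AgreementSummary]) -> pd.DataFrame:
    rows = [
        (
            s.equation,
            s.interval_cm,
            s.n_total,
            s.mean_bias,
            s.loa_low,
            s.loa_high,
            s.n_within_loa,
            s.mean_abs_error,
            s.sd_abs_error,
            s.mean_rel_error,
            s.sd_rel_error,
        )
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "equation",
            "interval_cm",
            "n",
            "mean_bias_cm3",
            "loa_low_cm3",
            "loa_high_cm3",
            "n_within_loa",
            "mean_abs_err_cm3",
            "sd_abs_err_cm3",
            "mean_rel_err_pct",
            "sd_rel_err_pct",
        ],
    )


# -- intraclass correlation ------------------------------------------------


def icc_two_way_mixed(
    ratings: np.ndarray, form: str = "consistency", alpha: float = 0.05
) -> tuple[float, float, float]:
    """Single-rater intraclass correlation from a two-way subjects × raters layout.

    ``form='consistency'`` (default) is ICC(3,1) for fixed raters:
    ``(MS_subjects − MS_error) / (MS_subjects + (k−1) MS_error)`` with the
    exact F-based confidence bounds.  ``form='agreement'`` is the
    absolute-agreement ICC(2,1), whose CI uses the Satterthwaite
    approximation.  Returns ``(icc, ci_low, ci_high)``.

    Missing cells are rejected; a negative point estimate is clipped to 0
    with a warning (small-sample noise around zero reliability).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects × raters matrix")
    n, k = x.shape
    if n < 5:
        raise ValueError(f"need >= 5 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need >= 2 raters, got {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells in ratings matrix")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssb = k * np.sum((row_means - grand) ** 2)  # between subjects
    ssc = n * np.sum((col_means - grand) ** 2)  # between raters
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssb - ssc
    msb = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if form == "consistency":
        if mse == 0:
            return 1.0, 1.0, 1.0
        icc = (msb - mse) / (msb + (k - 1) * mse)
        f_obs = msb / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
    elif form == "agreement":
        denom = msb + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            return 1.0, 1.0, 1.0
        icc = (msb - mse) / denom
        # Satterthwaite CI (Shrout & Fleiss / McGraw & Wong)
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msb - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msb
            )
            hi = n * (f2 * msb - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msb
            )
        else:
            lo = hi = 1.0
    else:
        raise ValueError(f"form must be 'consistency' or 'agreement', got {form!r}")

    if icc < 0:
        warnings.warn(
            f"negative ICC estimate ({icc:.4f}) clipped to 0", stacklevel=2
        )
        icc = 0.0
    return float(icc), float(min(lo, 1.0)), float(min(hi, 1.0))


# -- Pearson correlation ---------------------------------------------------


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Product-moment correlation: returns (r, r², two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


# -- plotting --------------------------------------------------------------


def bland_altman_plot(pairs: Sequence[PairedVolumes], path) -> None:
    """Write one Bland-Altman plot (difference vs. average) with bias/LOA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = bland_altman(pairs)
    mean_xy = np.array(
        [(p.reference_volume + p.comparison_volume) / 2 for p in pairs]
    )
    diff = np.array([p.reference_volume - p.comparison_volume for p in pairs])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean_xy, diff, s=18, color="k")
    ax.axhline(s.mean_bias, color="tab:blue", ls="--", label=f"bias {s.mean_bias:+.1f}")
    for v in (s.loa_low, s.loa_high):
        ax.axhline(v, color="tab:red", ls="--")
    ax.set_xlabel("mean of 1 cm and coarse estimate (cm³)")
    ax.set_ylabel("difference, 1 cm − coarse (cm³)")
    ax.set_title(f"{s.equation}, {s.interval_cm:g} cm interval")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
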