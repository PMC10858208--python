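"""Spheroid segmentation and volumetric viability quantification.

Automates the two-step procedure used for spheroid quantification: (1)
intensity thresholding of the mean-dB volume with per-B-scan connected-
region filtering, and (2) removal of the bright plate-bottom reflection
plane — here detected automatically as the dominant near-horizontal bright
plane.  From the resulting mask the spheroid volume, in-mask mean LIV and
mean OCDS_l, and the LIV- and OCDS_l-based dead-cell ratios (fractions of
voxels below empirical viability cut-offs of 3 dB^2 and 2e-4 /ms) are
computed, and conditions are compared across treatment days with Welch's
t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats
from scipy.ndimage import binary_closing
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import ball

from .scan_io import DynamicsVolume

__all__ = [
    "SegmentationConfig",
    "SegmentationMask",
    "ViabilityCutoffs",
    "SpheroidResult",
    "QuantReport",
    "SegmentationError",
    "segment_spheroid",
    "compute_volume",
    "mean_metrics",
    "dead_cell_ratio",
    "welch_ttest",
    "welch_type_i_error_rate",
    "timecourse_report",
    "evaluate_direction_expectations",
]

DAY_PAIRS = ((1, 3), (3, 6), (1, 6))
SCALARS = ("volume_mm3", "mean_liv", "mean_ocds", "dead_ratio_liv", "dead_ratio_ocds")


class SegmentationError(RuntimeError):
    pass


class SegmentationConfig(BaseModel):
    """Parameters of the automated spheroid segmentation."""

    intensity_threshold_db: float | Literal["otsu"] = "otsu"
    min_component_voxels: int = Field(default=32, ge=1)
    closing_radius: int = Field(default=1, ge=0)
    plate_removal: Literal["auto", "none"] = "auto"
    plate_slab_halfwidth: int = Field(default=2, ge=0)

    model_config = {"frozen": True}


class ViabilityCutoffs(BaseModel):
    """Dead-cell classification cut-offs (strictly-below counts as dead)."""

    liv_cutoff_db2: float = Field(default=3.0, gt=0)
    ocds_cutoff_per_ms: float = Field(default=2e-4, gt=0)

    model_config = {"frozen": True}


@dataclass
class SegmentationMask:
    mask: np.ndarray
    voxel_volume_mm3: float
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D [location, depth, lateral] array")


def detect_plate_depth(mean_intensity_db: np.ndarray) -> Optional[int]:
    """Depth index of the dominant near-horizontal bright plane, if any.

    The plate reflection spans the full lateral extent, so its depth row has
    an exceptionally high median intensity; tissue rows do not, because the
    spheroid covers only part of the field of view.
    """
    profile = np.median(mean_intensity_db, axis=(0, 2))
    z = int(np.argmax(profile))
    others = np.delete(profile, np.arange(max(0, z - 3), min(profile.size, z + 4)))
    spread = np.std(others)
    if spread == 0 or (profile[z] - np.median(others)) > 6 * spread:
        return z if profile[z] > np.median(others) else None
    return None


def segment_spheroid(
    mean_intensity_db: np.ndarray,
    cfg: SegmentationConfig | None = None,
    voxel_volume_mm3: float = 1.0,
) -> SegmentationMask:
    """Segment spheroid tissue from a mean-dB intensity volume.

    Threshold (Otsu by default) -> plate-slab exclusion -> per-B-scan
    largest connected region -> largest 3D component -> morphological
    closing -> plate slab re-excluded.  The mask is guaranteed to be a
    single connected component excluding the plate.
    """
    cfg = cfg or SegmentationConfig()
    vol = np.asarray(mean_intensity_db, dtype=np.float64)
    if not np.all(np.isfinite(vol)):
        raise ValueError("mean intensity volume must be finite")
    if cfg.intensity_threshold_db == "otsu":
        threshold = float(threshold_otsu(vol))
    else:
        threshold = float(cfg.intensity_threshold_db)
    binary = vol >= threshold

    plate_depth: Optional[int] = None
    slab = np.zeros(vol.shape[1], dtype=bool)
    if cfg.plate_removal == "auto":
        plate_depth = detect_plate_depth(vol)
        if plate_depth is not None:
            lo = max(0, plate_depth - cfg.plate_slab_halfwidth)
            hi = min(vol.shape[1], plate_depth + cfg.plate_slab_halfwidth + 1)
            slab[lo:hi] = True
            binary[:, slab, :] = False

    # Per-B-scan largest connected region.
    for loc in range(binary.shape[0]):
        frame = binary[loc]
        if not frame.any():
            continue
        lab = cc_label(frame, connectivity=2)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        binary[loc] = lab == int(np.argmax(counts))

    lab3 = cc_label(binary, connectivity=3)
    if lab3.max() == 0:
        raise SegmentationError(
            f"no spheroid found (threshold = {threshold:.2f} dB)"
        )
    counts = np.bincount(lab3.ravel())
    counts[0] = 0
    mask = lab3 == int(np.argmax(counts))
    if mask.sum() < cfg.min_component_voxels:
        raise SegmentationError(
            f"no spheroid found: largest component has {int(mask.sum())} voxels "
            f"(threshold = {threshold:.2f} dB)"
        )
    if cfg.closing_radius > 0:
        mask = binary_closing(mask, structure=ball(cfg.closing_radius))
    if slab.any():
        mask[:, slab, :] = False
    # Closing can split off crumbs; keep the largest component again.
    lab3 = cc_label(mask, connectivity=3)
    counts = np.bincount(lab3.ravel())
    counts[0] = 0
    mask = lab3 == int(np.argmax(counts))
    return SegmentationMask(
        mask=mask,
        voxel_volume_mm3=voxel_volume_mm3,
        provenance={"threshold_db": threshold, "plate_depth": plate_depth},
    )


def compute_volume(mask: SegmentationMask) -> float:
    """Spheroid volume in mm^3: voxel count times voxel volume."""
    return float(mask.mask.sum()) * mask.voxel_volume_mm3


def mean_metrics(
    mask: SegmentationMask, liv: DynamicsVolume, ocds: DynamicsVolume
) -> Tuple[float, float]:
    """Arithmetic means of LIV and OCDS_l over the in-mask voxels."""
    m = mask.mask
    if not m.any():
        raise ValueError("empty segmentation mask")
    if liv.values.shape != m.shape or ocds.values.shape != m.shape:
        raise ValueError("metric volumes must be co-registered with the mask")
    return float(liv.values[m].mean()), float(ocds.values[m].mean())


def dead_cell_ratio(
    mask: SegmentationMask,
    metric: DynamicsVolume,
    cutoffs: ViabilityCutoffs | None = None,
) -> float:
    """Fraction of in-mask voxels strictly below the metric's cut-off."""
    cutoffs = cutoffs or ViabilityCutoffs()
    m = mask.mask
    if not m.any():
        raise ValueError("empty segmentation mask")
    if metric.values.shape != m.shape:
        raise ValueError("metric volume must be co-registered with the mask")
    cutoff = (
        cutoffs.liv_cutoff_db2
        if metric.metric_name == "LIV"
        else cutoffs.ocds_cutoff_per_ms
    )
    vals = metric.values[m]
    return float(np.count_nonzero(vals < cutoff)) / vals.size


class WelchResult(NamedTuple):
    t: float
    dof: float
    p: float


def _welch_stats(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t statistic and Satterthwaite dof over axis -1."""
    n1, n2 = a.shape[-1], b.shape[-1]
    m1, m2 = a.mean(axis=-1), b.mean(axis=-1)
    v1, v2 = a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        dof = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, dof


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degenerate zero-variance groups: two identical constant groups give
    (t=0, p=1); constant groups with different means give p=0.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        fallback_dof = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return WelchResult(0.0, fallback_dof, 1.0)
        return WelchResult(math.copysign(math.inf, a.mean() - b.mean()), fallback_dof, 0.0)
    t, dof = _welch_stats(a, b)
    p = 2.0 * float(stats.t.sf(abs(float(t)), float(dof)))
    return WelchResult(float(t), float(dof), min(p, 1.0))


def welch_type_i_error_rate(
    n_per_group: int = 3,
    n_replicates: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the Welch test under a shared normal null."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_replicates, n_per_group))
    b = rng.standard_normal((n_replicates, n_per_group))
    t, dof = _welch_stats(a, b)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return float(np.mean(p < alpha))


@dataclass
class SpheroidResult:
    """Per-spheroid scalar quantities of the study."""

    drug: str
    concentration_uM: float
    treatment_day: int
    replicate: int
    volume_mm3: float
    mean_liv: float
    mean_ocds: float
    dead_ratio_liv: float
    dead_ratio_ocds: float

    @property
    def condition(self) -> str:
        if self.drug == "control":
            return "control"
        return f"{self.drug}_{self.concentration_uM:g}"


@dataclass
class QuantReport:
    """Study-level tables: per-spheroid scalars, condition summaries, tests."""

    spheroids: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame


def timecourse_report(results: Iterable[SpheroidResult]) -> QuantReport:
    """Aggregate per-spheroid scalars into time-course tables.

    ``summary`` holds the mean and standard deviation of each scalar per
    condition and day; ``comparisons`` holds Welch's t-test for every day
    pair (1 vs 3, 3 vs 6, 1 vs 6), condition and scalar.  Day pairs with a
    missing side are omitted with a warning.
    """
    rows = [
        {
            "condition": r.condition,
            "drug": r.drug,
            "concentration_uM": r.concentration_uM,
            "treatment_day": r.treatment_day,
            "replicate": r.replicate,
            **{s: getattr(r, s) for s in SCALARS},
        }
        for r in results
    ]
    if not rows:
        raise ValueError("no spheroid results supplied")
    df = pd.DataFrame(rows).sort_values(
        ["condition", "treatment_day", "replicate"], ignore_index=True
    )
    summary = (
        df.groupby(["condition", "treatment_day"], sort=True)[list(SCALARS)]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in summary.columns
    ]

    comp_rows: List[dict] = []
    for condition, grp in df.groupby("condition", sort=True):
        by_day = {day: sub for day, sub in grp.groupby("treatment_day")}
        for d1, d2 in DAY_PAIRS:
            if d1 not in by_day or d2 not in by_day:
                warnings.warn(
                    f"condition {condition}: missing day {d1} or {d2}; "
                    "comparison omitted"
                )
                continue
            if len(by_day[d1]) < 2 or len(by_day[d2]) < 2:
                warnings.warn(
                    f"condition {condition}: fewer than 2 replicates for days "
                    f"{d1}/{d2}; comparison omitted"
                )
                continue
            for scalar in SCALARS:
                res = welch_ttest(by_day[d1][scalar], by_day[d2][scalar])
                comp_rows.append(
                    {
                        "condition": condition,
                        "scalar": scalar,
                        "day_a": d1,
                        "day_b": d2,
                        "t": res.t,
                        "dof": res.dof,
                        "p": res.p,
                    }
                )
    comparisons = pd.DataFrame(comp_rows)
    return QuantReport(spheroids=df, summary=summary, comparisons=comparisons)


def evaluate_direction_expectations(
    report: QuantReport, expectations: Dict[str, Dict[str, str]]
) -> pd.DataFrame:
    """Check the sign of each condition's day-course against expectations.

    Expectations map condition -> quantity -> "+"/"-", where a plain scalar
    name refers to the change of the replicate mean from the first to the
    last treatment day and ``<scalar>_d3_d6`` to the day-3 -> day-6 change.
    Returns one row per expectation with the observed change and agreement.
    """
    summary = report.summary.set_index(["condition", "treatment_day"])
    rows: List[dict] = []
    for condition, quantities in expectations.items():
        days = sorted(
            d for (c, d) in summary.index if c == condition
        )
        if not days:
            continue
        for quantity, sign in quantities.items():
            if quantity.endswith("_d3_d6"):
                scalar, d_from, d_to = quantity[: -len("_d3_d6")], 3, 6
            else:
                scalar, d_from, d_to = quantity, days[0], days[-1]
            if d_from == d_to or d_from not in days or d_to not in days:
                continue
            if scalar == "volume":
                scalar = "volume_mm3"
            col = f"{scalar}_mean"
            delta = float(
                summary.loc[(condition, d_to), col]
                - summary.loc[(condition, d_from), col]
            )
            observed = "+" if delta > 0 else "-"
            rows.append(
                {
                    "condition": condition,
                    "quantity": quantity,
                    "expected": sign,
                    "observed": observed,
                    "delta": delta,
                    "agree": observed == sign,
                }
            )
    return pd.DataFrame(rows)
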