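"""End-to-end orchestration: simulate -> compute -> quantify -> render.

Runs the full synthetic drug-response study (by default 10 condition groups
x 3 replicates x 3 treatment days = 90 spheroids) deterministically from a
single master seed.  Per-spheroid seeds are fanned out from
``(master_seed, drug, concentration, day, replicate)`` with a counter-based
scheme, so adding conditions never changes existing spheroids' data.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
from pydantic import BaseModel

from . import __version__
from .metrics import MetricConfig, compute_dynamics
from .phantom import (
    DEFAULT_STUDY_PROTOCOL,
    expected_directions,
    scenario_spec,
    simulate_phantom,
)
from .quantify import (
    QuantReport,
    SegmentationConfig,
    SpheroidResult,
    ViabilityCutoffs,
    evaluate_direction_expectations,
    compute_volume,
    dead_cell_ratio,
    mean_metrics,
    segment_spheroid,
    timecourse_report,
)
from .scan_io import (
    ScanProtocol,
    StudyDesign,
    StudyEntry,
    enumerate_study,
    write_metric_volume,
    write_timeseries,
)
from .visualization import (
    DEFAULT_LIV_COLORMAP,
    DEFAULT_OCDS_COLORMAP,
    ColorMapSpec,
    compose_pseudocolor,
    extract_cross_section,
    extract_en_face,
    mask_center_depth,
    mask_center_location,
)

__all__ = ["RunConfig", "StudyResult", "run_study", "run_spheroid", "spheroid_seed"]

log = logging.getLogger("doct")


class RunConfig(BaseModel):
    """Complete configuration of a study run."""

    protocol: ScanProtocol = DEFAULT_STUDY_PROTOCOL
    study: StudyDesign = StudyDesign()
    metric_config: MetricConfig = MetricConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    cutoffs: ViabilityCutoffs = ViabilityCutoffs()
    liv_colormap: ColorMapSpec = DEFAULT_LIV_COLORMAP
    ocds_colormap: ColorMapSpec = DEFAULT_OCDS_COLORMAP
    master_seed: int = 0
    artifacts: Literal["full", "report"] = "report"

    model_config = {"frozen": True}


def spheroid_seed(master_seed: int, entry: StudyEntry) -> int:
    """Deterministic per-spheroid seed keyed on the study condition."""
    key = [
        int(master_seed) & 0x7FFFFFFF,
        zlib.crc32(entry.drug.encode()),
        int(round(entry.concentration_uM * 1000)),
        int(entry.treatment_day),
        int(entry.replicate),
    ]
    return int(np.random.SeedSequence(key).generate_state(1)[0]) & 0x7FFFFFFF


@dataclass
class StudyResult:
    report: QuantReport
    directions: "object"  # pandas DataFrame of expectation checks
    manifest: Dict[str, object]
    output_root: Optional[Path]


def _save_png(path: Path, rgb: np.ndarray, meta: Dict[str, object]) -> None:
    from PIL import Image
    from PIL.PngImagePlugin import PngInfo

    info = PngInfo()
    for k, v in meta.items():
        info.add_text(str(k), json.dumps(v))
    img = Image.fromarray(np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    img.save(path, pnginfo=info)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def run_spheroid(
    entry: StudyEntry,
    cfg: RunConfig,
    out_dir: Optional[Path] = None,
) -> SpheroidResult:
    """Run one spheroid through simulate -> metrics -> segment -> quantify."""
    seed = spheroid_seed(cfg.master_seed, entry)
    spec = scenario_spec(
        entry.drug, entry.concentration_uM, entry.treatment_day, seed, cfg.protocol
    )
    regions, series = simulate_phantom(spec)
    liv, ocds = compute_dynamics(series, cfg.metric_config)
    mask = segment_spheroid(
        liv.mean_intensity_db, cfg.segmentation, cfg.protocol.voxel_volume_mm3
    )
    m_liv, m_ocds = mean_metrics(mask, liv, ocds)
    result = SpheroidResult(
        drug=entry.drug,
        concentration_uM=entry.concentration_uM,
        treatment_day=entry.treatment_day,
        replicate=entry.replicate,
        volume_mm3=compute_volume(mask),
        mean_liv=m_liv,
        mean_ocds=m_ocds,
        dead_ratio_liv=dead_cell_ratio(mask, liv, cfg.cutoffs),
        dead_ratio_ocds=dead_cell_ratio(mask, ocds, cfg.cutoffs),
    )
    if out_dir is not None and cfg.artifacts == "full":
        write_timeseries(series, out_dir / "raw")
        write_metric_volume(liv, out_dir / "metrics")
        write_metric_volume(ocds, out_dir / "metrics")
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        z = mask_center_depth(mask)
        l = mask_center_location(mask)
        for vol, cmap, name in (
            (liv, cfg.liv_colormap, "liv"),
            (ocds, cfg.ocds_colormap, "ocds"),
        ):
            rgb = compose_pseudocolor(vol, cmap)
            meta = {
                "metric": vol.metric_name,
                "metric_range": list(cmap.metric_range),
                "intensity_range_db": list(cmap.intensity_range_db),
                "seed": seed,
            }
            _save_png(
                img_dir / f"enface_{name}.png",
                extract_en_face(rgb, z),
                {**meta, "plane": "enface", "index": z},
            )
            _save_png(
                img_dir / f"bscan_{name}.png",
                extract_cross_section(rgb, l),
                {**meta, "plane": "bscan", "index": l},
            )
    return result


def _plot_timecourses(report: QuantReport, out_dir: Path) -> List[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    summary = report.summary
    for scalar in ("volume_mm3", "mean_liv", "mean_ocds", "dead_ratio_liv", "dead_ratio_ocds"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for condition, grp in summary.groupby("condition"):
            grp = grp.sort_values("treatment_day")
            ax.errorbar(
                grp["treatment_day"],
                grp[f"{scalar}_mean"],
                yerr=grp[f"{scalar}_std"],
                marker="o",
                capsize=3,
                label=condition,
            )
        ax.set_xlabel("treatment day")
        ax.set_ylabel(scalar)
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        path = out_dir / f"trend_{scalar}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def run_study(cfg: RunConfig, output_root: str | Path | None = None) -> StudyResult:
    """Run the whole study and write report tables (and optional artifacts).

    Deterministic for a fixed config: rerunning with the same master seed
    reproduces byte-identical report tables.
    """
    out: Optional[Path] = Path(output_root) if output_root is not None else None
    entries = enumerate_study(cfg.study)
    log.info("running study: %d spheroids", len(entries))
    results: List[SpheroidResult] = []
    failures: List[str] = []
    for i, entry in enumerate(entries):
        name = f"{entry.drug}_{entry.concentration_uM:g}uM_day{entry.treatment_day}_rep{entry.replicate}"
        sph_dir = out / "spheroids" / name if out is not None else None
        try:
            results.append(run_spheroid(entry, cfg, sph_dir))
            log.info("[%d/%d] %s done", i + 1, len(entries), name)
        except Exception as exc:  # surfaced collectively below
            failures.append(f"{name}: {exc}")
            log.error("[%d/%d] %s FAILED: %s", i + 1, len(entries), name, exc)
    if failures:
        raise RuntimeError(
            f"{len(failures)} spheroid run(s) failed:\n" + "\n".join(failures)
        )
    report = timecourse_report(results)
    directions = evaluate_direction_expectations(report, expected_directions())
    manifest = {
        "doct_version": __version__,
        "master_seed": cfg.master_seed,
        "n_spheroids": len(results),
        "config": json.loads(cfg.model_dump_json()),
        "direction_agreement": float(directions["agree"].mean()) if len(directions) else None,
    }
    if out is not None:
        report_dir = out / "report"
        report_dir.mkdir(parents=True, exist_ok=True)
        report.spheroids.to_csv(report_dir / "report.csv", index=False)
        report.summary.to_csv(report_dir / "summary.csv", index=False)
        report.comparisons.to_csv(report_dir / "comparisons.csv", index=False)
        directions.to_csv(report_dir / "directions.csv", index=False)
        _plot_timecourses(report, report_dir)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return StudyResult(
        report=report, directions=directions, manifest=manifest, output_root=out
    )
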