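"""Acquisition data model and I/O for repeated-frame OCT time series.

Dynamic OCT acquires, at every B-scan location, a short time sequence of
cross-sectional frames; the temporal statistics of that sequence carry the
intracellular-motility contrast.  The scanning protocol modelled here rasters
the lateral field of view in blocks: each block of B-scan locations is
raster-scanned repeatedly, so that every location receives ``n_repeats``
frames with a uniform inter-frame interval.

On disk a time-series volume is one multi-page TIFF per B-scan location
(pages = repeats, 32-bit float linear intensity) plus a JSON sidecar holding
the protocol and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, NamedTuple, Tuple

import numpy as np
import tifffile
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ScanProtocol",
    "FrameTimeSeries",
    "DynamicsVolume",
    "FrameEvent",
    "StudyDesign",
    "StudyEntry",
    "frame_schedule",
    "enumerate_study",
    "write_timeseries",
    "read_timeseries",
    "write_metric_volume",
    "read_metric_volume",
    "TimeSeriesIOError",
]

SIDECAR_NAME = "protocol.json"
LOC_FILE_FMT = "loc_{index:03d}.tif"


class TimeSeriesIOError(RuntimeError):
    """Raised when a stored time series is inconsistent with its sidecar."""


class ScanProtocol(BaseModel):
    """Block-repeat raster protocol of a volumetric dynamic-OCT scan.

    Defaults follow the 1 x 1 mm, 8-block x 16-location, 32-repeat protocol
    with a 204.8 ms frame interval (6.3488 s per-location time span).
    ``a_lines_per_frame`` and ``n_depth_pixels`` are instrument settings;
    the defaults give a desk-scale grid for synthetic volumes.
    """

    n_blocks: int = Field(default=8, ge=1)
    locations_per_block: int = Field(default=16, ge=1)
    n_repeats: int = Field(default=32, ge=1)
    frame_interval_ms: float = Field(default=204.8, gt=0)
    fov_lateral_mm: Tuple[float, float] = (1.0, 1.0)
    a_lines_per_frame: int = Field(default=128, ge=1)
    n_depth_pixels: int = Field(default=256, ge=1)
    depth_pixel_size_um: float = Field(default=3.9, gt=0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_fov(self) -> "ScanProtocol":
        if self.fov_lateral_mm[0] <= 0 or self.fov_lateral_mm[1] <= 0:
            raise ValueError("fov_lateral_mm entries must be positive")
        return self

    @property
    def n_locations(self) -> int:
        return self.n_blocks * self.locations_per_block

    @property
    def frames_per_volume(self) -> int:
        return self.n_locations * self.n_repeats

    @property
    def per_location_span_ms(self) -> float:
        """Time between first and last repeat at one B-scan location."""
        return (self.n_repeats - 1) * self.frame_interval_ms

    @property
    def location_spacing_um(self) -> float:
        """Spacing of B-scan locations along the slow lateral axis."""
        return self.fov_lateral_mm[0] * 1000.0 / self.n_locations

    @property
    def lateral_pixel_size_um(self) -> float:
        """Pixel pitch along the fast lateral axis (within a B-scan)."""
        return self.fov_lateral_mm[1] * 1000.0 / self.a_lines_per_frame

    @property
    def voxel_volume_mm3(self) -> float:
        return (
            (self.location_spacing_um / 1000.0)
            * (self.depth_pixel_size_um / 1000.0)
            * (self.lateral_pixel_size_um / 1000.0)
        )

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        """Volume grid as (locations, depth, lateral)."""
        return (self.n_locations, self.n_depth_pixels, self.a_lines_per_frame)

    def timestamps_ms(self) -> np.ndarray:
        return np.arange(self.n_repeats, dtype=np.float64) * self.frame_interval_ms


class FrameEvent(NamedTuple):
    block: int
    location: int
    repeat: int
    time_ms: float


def frame_schedule(protocol: ScanProtocol) -> List[FrameEvent]:
    """Ordered acquisition schedule of the block-repeat raster protocol.

    Within a block, one full raster pass over its locations is completed per
    repeat before the next repeat starts, so all locations of repeat ``k``
    precede repeat ``k + 1``.  Every frame carries its repeat's nominal time
    ``k * frame_interval_ms``; the analysis only relies on the per-location
    uniform spacing, which this convention preserves.  Inter-block overhead
    (stage flyback/settling) is not modelled.
    """
    events: List[FrameEvent] = []
    for b in range(protocol.n_blocks):
        loc0 = b * protocol.locations_per_block
        for r in range(protocol.n_repeats):
            t = r * protocol.frame_interval_ms
            for l in range(loc0, loc0 + protocol.locations_per_block):
                events.append(FrameEvent(block=b, location=l, repeat=r, time_ms=t))
    return events


@dataclass
class FrameTimeSeries:
    """Per-B-scan-location stacks of repeated linear-intensity OCT frames.

    ``intensity`` is indexed ``[location, repeat, depth, lateral]`` and holds
    non-negative linear-scale intensity; ``timestamps_ms`` are the shared
    per-repeat acquisition times.
    """

    intensity: np.ndarray
    timestamps_ms: np.ndarray
    protocol: ScanProtocol
    provenance: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        p = self.protocol
        expected = (p.n_locations, p.n_repeats, p.n_depth_pixels, p.a_lines_per_frame)
        if self.intensity.shape != expected:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match protocol "
                f"grid {expected}"
            )
        if self.timestamps_ms.shape != (p.n_repeats,):
            raise ValueError("timestamps must have one entry per repeat")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if p.n_repeats > 1:
            steps = np.diff(self.timestamps_ms)
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(steps, p.frame_interval_ms, rtol=1e-9, atol=1e-6):
                raise ValueError(
                    "timestamps must be uniformly spaced at the frame interval"
                )

    @property
    def n_voxels(self) -> int:
        return self.intensity.shape[0] * self.intensity.shape[2] * self.intensity.shape[3]


@dataclass
class DynamicsVolume:
    """3D voxel map of a dynamics metric co-registered with mean intensity.

    ``values`` and ``mean_intensity_db`` are indexed ``[location, depth,
    lateral]``.  LIV is in dB^2 and non-negative; OCDS_l is in 1/ms (noisy
    voxels may go slightly negative, static voxels are exactly zero).
    Held in double precision in memory; stored as 32-bit float on disk.
    """

    values: np.ndarray
    metric_name: Literal["LIV", "OCDS_l"]
    units: str
    mean_intensity_db: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mean_intensity_db = np.asarray(self.mean_intensity_db, dtype=np.float64)
        if self.values.shape != self.mean_intensity_db.shape:
            raise ValueError("values and mean_intensity_db must share a shape")
        if self.values.ndim != 3:
            raise ValueError("expected a 3D [location, depth, lateral] volume")
        if self.metric_name == "LIV" and np.any(self.values < 0):
            raise ValueError("LIV values must be non-negative")


class StudyEntry(NamedTuple):
    drug: str
    concentration_uM: float
    treatment_day: int
    replicate: int


class StudyDesign(BaseModel):
    """Cross-sectional drug-response study design.

    Defaults mirror a 3-drug x 3-concentration x 3-day design with an
    untreated control group and 3 replicate spheroids per condition
    (10 groups x 3 replicates x 3 days = 90 spheroids).
    """

    drugs: Tuple[str, ...] = ("TAM", "PTX", "DOX")
    concentrations_uM: Tuple[float, ...] = (0.1, 1.0, 10.0)
    treatment_days: Tuple[int, ...] = (1, 3, 6)
    n_replicates: int = Field(default=3, ge=1)
    include_control: bool = True

    model_config = {"frozen": True}

    @property
    def n_groups(self) -> int:
        return len(self.drugs) * len(self.concentrations_uM) + int(self.include_control)


def enumerate_study(design: StudyDesign) -> List[StudyEntry]:
    """Complete cross product of study conditions.

    The control group (drug ``"control"``, 0 uM) appears once per time point
    and replicate, not once per drug.
    """
    entries: List[StudyEntry] = []
    groups: List[Tuple[str, float]] = []
    if design.include_control:
        groups.append(("control", 0.0))
    for drug in design.drugs:
        for conc in design.concentrations_uM:
            groups.append((drug, conc))
    for day in design.treatment_days:
        for drug, conc in groups:
            for rep in range(design.n_replicates):
                entries.append(StudyEntry(drug, conc, day, rep))
    return entries


# --------------------------------------------------------------------------
# Disk layout: loc_{i:03d}.tif multi-page stacks + protocol.json sidecar.


def write_timeseries(series: FrameTimeSeries, path: str | Path) -> Path:
    """Write a time-series volume as per-location TIFF stacks + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    p = series.protocol
    for loc in range(p.n_locations):
        tifffile.imwrite(
            path / LOC_FILE_FMT.format(index=loc),
            series.intensity[loc],
            photometric="minisblack",
        )
    sidecar = {
        "protocol": p.model_dump(),
        "provenance": series.provenance,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return path


def read_timeseries(path: str | Path) -> FrameTimeSeries:
    """Read a time-series volume written by :func:`write_timeseries`."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.is_file():
        raise TimeSeriesIOError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    protocol = ScanProtocol.model_validate(sidecar["protocol"])
    stacks = []
    for loc in range(protocol.n_locations):
        loc_path = path / LOC_FILE_FMT.format(index=loc)
        if not loc_path.is_file():
            raise TimeSeriesIOError(f"missing frame stack for location {loc}: {loc_path}")
        stack = tifffile.imread(loc_path)
        if stack.ndim == 2:  # single-page stack
            stack = stack[None]
        expected = (protocol.n_repeats, protocol.n_depth_pixels, protocol.a_lines_per_frame)
        if stack.shape != expected:
            raise TimeSeriesIOError(
                f"location {loc}: TIFF shape {stack.shape} does not match "
                f"sidecar protocol {expected}"
            )
        stacks.append(stack)
    return FrameTimeSeries(
        intensity=np.stack(stacks, axis=0),
        timestamps_ms=protocol.timestamps_ms(),
        protocol=protocol,
        provenance=sidecar.get("provenance", ""),
    )


def write_metric_volume(volume: DynamicsVolume, path: str | Path) -> Path:
    """Write a dynamics-metric volume as multi-page TIFFs + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stem = volume.metric_name.lower().replace("_l", "")
    tifffile.imwrite(path / f"{stem}.tif", volume.values.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(path / "mean_db.tif", volume.mean_intensity_db.astype(np.float32), photometric="minisblack")
    meta = {"metric_name": volume.metric_name, "units": volume.units}
    (path / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_metric_volume(path: str | Path, metric_name: Literal["LIV", "OCDS_l"]) -> DynamicsVolume:
    path = Path(path)
    stem = metric_name.lower().replace("_l", "")
    meta = json.loads((path / f"{stem}_meta.json").read_text())
    return DynamicsVolume(
        values=tifffile.imread(path / f"{stem}.tif"),
        metric_name=meta["metric_name"],
        units=meta["units"],
        mean_intensity_db=tifffile.imread(path / "mean_db.tif"),
    )
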