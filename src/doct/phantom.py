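"""Synthetic dynamic-speckle spheroid phantoms with known ground truth.

The phantom emulates a tumor spheroid sitting above the reflective bottom of
a multi-well plate: an ellipsoidal body with a necrotic core and a viable
shell, optional labeled sub-regions (low-motility spots, slow domains,
peripheral rims), fully developed speckle with region-wise temporal
statistics, and a shot-noise floor.

Speckle model
-------------
Each voxel carries a complex field that is a mixture of a static and a
dynamic component,

    E(t) = sqrt(1 - m) * E_s + sqrt(m) * E_d(t),

where ``m`` in [0, 1] is the motility fraction (fraction of dynamic field
power) and ``E_d`` is a stationary circular complex Gaussian process with
field correlation ``exp(-|dt| / tau_c)`` (a discrete Ornstein-Uhlenbeck
recursion across repeats).  Both components are unit-variance circular
Gaussian white noise spatially low-pass filtered with the Gaussian PSF and
renormalised, so the per-voxel marginal stays unit-variance circular
Gaussian and intensity ``|E|^2`` is exponentially distributed (fully
developed speckle).  The Siegert relation then gives the closed-form
intensity Pearson autocorrelation

    rho(tau) = ((1 - m) + m * exp(-tau / tau_c))^2,

which serves as the analytic oracle for the correlation-based contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import gaussian_filter

from .scan_io import FrameTimeSeries, ScanProtocol

__all__ = [
    "RegionDynamics",
    "RegionOverride",
    "PhantomSpec",
    "RegionLabelVolume",
    "CorrelationCurve",
    "build_phantom",
    "simulate_timeseries",
    "simulate_phantom",
    "analytic_intensity_correlation",
    "analytic_ocds",
    "scenario_spec",
    "load_scenario_table",
    "expected_directions",
    "DEFAULT_STUDY_PROTOCOL",
    "FWHM_TO_SIGMA",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Desk-scale protocol used for the synthetic drug study: full 1 x 1 mm FOV
#: and 32-repeat block raster, with a reduced 32 x 48 x 48 voxel grid so the
#: complete 90-spheroid study runs in minutes on one CPU.
DEFAULT_STUDY_PROTOCOL = ScanProtocol(
    n_blocks=2,
    locations_per_block=16,
    a_lines_per_frame=48,
    n_depth_pixels=48,
    depth_pixel_size_um=16.0,
)


class RegionDynamics(BaseModel):
    """Temporal-speckle parameters of one labeled region."""

    m: float = Field(ge=0.0, le=1.0, description="motility fraction")
    tau_c_ms: float = Field(gt=0.0, description="field decorrelation time")
    mean_reflectivity: float = Field(gt=0.0, description="linear-scale mean intensity")

    model_config = {"frozen": True}


class RegionOverride(BaseModel):
    """Labeled sub-region stamped into the spheroid after shell and core.

    ``sphere`` overrides are balls of ``radius_um`` centred at
    ``center_rel`` (coordinates in units of the spheroid radii, i.e. the
    unit ball); ``radial_band`` overrides are concentric shells covering
    relative radii ``band[0] <= r <= band[1]``.
    """

    name: str = "override"
    kind: Literal["sphere", "radial_band"] = "sphere"
    center_rel: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius_um: float = 0.0
    band: Tuple[float, float] = (0.0, 0.0)
    dynamics: RegionDynamics

    model_config = {"frozen": True}


class PhantomSpec(BaseModel):
    """Full specification of one synthetic spheroid acquisition."""

    protocol: ScanProtocol = Field(default_factory=ScanProtocol)
    center_voxel: Optional[Tuple[float, float, float]] = None
    radii_um: Tuple[float, float, float] = (200.0, 200.0, 180.0)
    boundary_perturbation: float = Field(default=0.0, ge=0.0, le=1.0)
    core_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)
    shell: RegionDynamics = RegionDynamics(m=0.85, tau_c_ms=600.0, mean_reflectivity=1.0)
    core: RegionDynamics = RegionDynamics(m=0.10, tau_c_ms=3500.0, mean_reflectivity=0.85)
    region_overrides: Tuple[RegionOverride, ...] = ()
    plate_depth: Optional[int] = None
    plate_reflectivity: float = Field(default=10.0, gt=0.0)
    noise_floor: float = Field(default=0.0, ge=0.0)
    psf_lateral_fwhm_um: float = Field(default=18.1, ge=0.0)
    psf_axial_fwhm_um: float = Field(default=14.0, ge=0.0)
    seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_geometry(self) -> "PhantomSpec":
        p = self.protocol
        center = self.resolved_center_um()
        extent = self.grid_extent_um()
        for ax, (c, r) in enumerate(zip(center, self.radii_um)):
            if r <= 0:
                raise ValueError("radii_um must be positive")
            if c - r * (1 + self.boundary_perturbation) < 0 or c + r * (
                1 + self.boundary_perturbation
            ) > extent[ax]:
                raise ValueError(
                    f"spheroid does not fit inside the grid along axis {ax}"
                )
        if self.plate_depth is not None and not (
            0 <= self.plate_depth < p.n_depth_pixels
        ):
            raise ValueError("plate_depth outside the depth grid")
        for ov in self.region_overrides:
            if ov.kind == "sphere":
                c_um = [
                    center[ax] + ov.center_rel[ax] * self.radii_um[ax] for ax in range(3)
                ]
                for ax in range(3):
                    if c_um[ax] - ov.radius_um < 0 or c_um[ax] + ov.radius_um > extent[ax]:
                        raise ValueError(
                            f"override {ov.name!r} extends outside the grid"
                        )
            else:
                if not (0 <= ov.band[0] < ov.band[1] <= 1.5):
                    raise ValueError(f"override {ov.name!r} has an invalid band")
        return self

    def voxel_sizes_um(self) -> Tuple[float, float, float]:
        p = self.protocol
        return (p.location_spacing_um, p.depth_pixel_size_um, p.lateral_pixel_size_um)

    def grid_extent_um(self) -> Tuple[float, float, float]:
        p = self.protocol
        d = self.voxel_sizes_um()
        return tuple(n * s for n, s in zip(p.grid_shape, d))

    def resolved_center_um(self) -> Tuple[float, float, float]:
        d = self.voxel_sizes_um()
        if self.center_voxel is not None:
            return tuple((c + 0.5) * s for c, s in zip(self.center_voxel, d))
        extent = self.grid_extent_um()
        return (extent[0] / 2, extent[1] / 2, extent[2] / 2)


@dataclass
class RegionLabelVolume:
    """Integer region labels plus the dynamics assigned to each label.

    Label 0 is background (noise only); 1 = viable shell; 2 = necrotic
    core; 3.. = overrides in list order; ``plate_label`` marks the static
    plate-reflection plane.
    """

    labels: np.ndarray
    label_table: Dict[int, RegionDynamics]
    plate_label: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no dynamics entry")


@dataclass
class CorrelationCurve:
    delays_ms: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.delays_ms = np.asarray(self.delays_ms, dtype=np.float64)
        self.rho = np.asarray(self.rho, dtype=np.float64)
        if np.any(self.delays_ms < 0) or np.any(np.diff(self.delays_ms) < 0):
            raise ValueError("delays must be non-negative and non-decreasing")


def _angular_noise(u: np.ndarray, rng: np.random.Generator, n_bumps: int = 8,
                   kappa: float = 8.0) -> np.ndarray:
    """Smooth random function of direction, normalised to max |g| = 1.

    A sum of von-Mises-Fisher-shaped bumps at random directions; used to
    perturb the spheroid's radial boundary (shape corruption).
    """
    dirs = rng.normal(size=(n_bumps, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.uniform(-1.0, 1.0, size=n_bumps)
    g = np.zeros(u.shape[:-1])
    for d, a in zip(dirs, amps):
        g += a * np.exp(kappa * (u @ d - 1.0))
    peak = np.max(np.abs(g))
    return g / peak if peak > 0 else g


def build_phantom(spec: PhantomSpec) -> RegionLabelVolume:
    """Rasterise the phantom geometry into a region label volume."""
    p = spec.protocol
    shape = p.grid_shape
    d = spec.voxel_sizes_um()
    center = spec.resolved_center_um()
    coords = [
        (np.arange(n) + 0.5) * s - c for n, s, c in zip(shape, d, center)
    ]
    yy, zz, xx = np.meshgrid(*coords, indexing="ij")
    uy = yy / spec.radii_um[0]
    uz = zz / spec.radii_um[1]
    ux = xx / spec.radii_um[2]
    rho = np.sqrt(uy**2 + uz**2 + ux**2)

    rng = np.random.default_rng(spec.seed)
    if spec.boundary_perturbation > 0:
        with np.errstate(invalid="ignore"):
            u = np.stack([uy, uz, ux], axis=-1) / np.maximum(rho, 1e-12)[..., None]
        g = _angular_noise(u, rng)
        boundary = 1.0 + spec.boundary_perturbation * g
    else:
        boundary = 1.0

    inside = rho <= boundary
    labels = np.zeros(shape, dtype=np.int16)
    labels[inside] = 1
    table: Dict[int, RegionDynamics] = {1: spec.shell}
    if spec.core_fraction > 0:
        core = rho <= spec.core_fraction
        labels[core] = 2
        table[2] = spec.core

    for i, ov in enumerate(spec.region_overrides):
        lab = 3 + i
        if ov.kind == "sphere":
            cy = ov.center_rel[0] * spec.radii_um[0]
            cz = ov.center_rel[1] * spec.radii_um[1]
            cx = ov.center_rel[2] * spec.radii_um[2]
            dist = np.sqrt((yy - cy) ** 2 + (zz - cz) ** 2 + (xx - cx) ** 2)
            region = (dist <= ov.radius_um) & inside
        else:
            region = (rho >= ov.band[0]) & (rho <= ov.band[1]) & inside
        labels[region] = lab
        table[lab] = ov.dynamics

    plate_label: Optional[int] = None
    if spec.plate_depth is not None:
        plate_label = 3 + len(spec.region_overrides)
        plane = labels[:, spec.plate_depth, :] == 0
        labels[:, spec.plate_depth, :][plane] = plate_label
        table[plate_label] = RegionDynamics(
            m=0.0, tau_c_ms=1e9, mean_reflectivity=spec.plate_reflectivity
        )

    return RegionLabelVolume(labels=labels, label_table=table, plate_label=plate_label)


def _complex_normal(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    return (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    ).astype(np.complex64) / np.sqrt(2.0)


def _gauss_kernel_sq_sum(sigma: float, truncate: float = 4.0) -> float:
    if sigma <= 0:
        return 1.0
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    return float(np.sum(k**2))


def _filter_field(field: np.ndarray, sigmas: Tuple[float, float, float]) -> np.ndarray:
    """Gaussian low-pass of a complex field with variance renormalisation.

    Wrap-around boundaries keep the filtered noise stationary, so dividing
    by the kernel's L2 norm restores exactly unit per-voxel variance.
    """
    if all(s <= 0 for s in sigmas):
        return field
    gain = np.sqrt(np.prod([_gauss_kernel_sq_sum(s) for s in sigmas]))
    out = gaussian_filter(field.real, sigmas, mode="wrap") + 1j * gaussian_filter(
        field.imag, sigmas, mode="wrap"
    )
    return (out / gain).astype(np.complex64)


def simulate_timeseries(
    regions: RegionLabelVolume,
    protocol: ScanProtocol,
    seed: int,
    *,
    noise_floor: float = 0.0,
    psf_lateral_fwhm_um: float = 18.1,
    psf_axial_fwhm_um: float = 14.0,
    provenance: str = "",
) -> FrameTimeSeries:
    """Simulate the repeated-frame linear-intensity series of a phantom.

    Static and dynamic unit-variance speckle fields are PSF-filtered once
    per frame, mixed voxel-wise by the motility fraction, scaled by the
    region reflectivity and topped with an independent exponential-intensity
    noise floor.  Background voxels (label 0) carry noise only.
    """
    labels = regions.labels
    if labels.shape != protocol.grid_shape:
        raise ValueError(
            f"label grid {labels.shape} does not match protocol grid "
            f"{protocol.grid_shape}"
        )
    shape = labels.shape
    dt = protocol.frame_interval_ms

    m_map = np.zeros(shape, dtype=np.float32)
    tau_map = np.ones(shape, dtype=np.float32)
    refl_map = np.zeros(shape, dtype=np.float32)
    for lab, dyn in regions.label_table.items():
        sel = labels == lab
        m_map[sel] = dyn.m
        tau_map[sel] = dyn.tau_c_ms
        refl_map[sel] = dyn.mean_reflectivity

    a = np.exp(-dt / tau_map).astype(np.float32)
    b = np.sqrt(1.0 - a**2).astype(np.float32)
    w_static = np.sqrt(1.0 - m_map).astype(np.float32)
    w_dyn = np.sqrt(m_map).astype(np.float32)

    sig_lat = psf_lateral_fwhm_um * FWHM_TO_SIGMA
    sig_ax = psf_axial_fwhm_um * FWHM_TO_SIGMA
    sigmas = (
        sig_lat / protocol.location_spacing_um,
        sig_ax / protocol.depth_pixel_size_um,
        sig_lat / protocol.lateral_pixel_size_um,
    )

    rng = np.random.default_rng(seed)
    e_static = _filter_field(_complex_normal(rng, shape), sigmas)
    e_dyn = _complex_normal(rng, shape)

    n_t = protocol.n_repeats
    out = np.empty((shape[0], n_t, shape[1], shape[2]), dtype=np.float32)
    for t in range(n_t):
        if t > 0:
            e_dyn = a * e_dyn + b * _complex_normal(rng, shape)
        e_dyn_f = _filter_field(e_dyn, sigmas)
        e = w_static * e_static + w_dyn * e_dyn_f
        frame = (e.real**2 + e.imag**2) * refl_map
        if noise_floor > 0:
            frame = frame + rng.exponential(noise_floor, size=shape).astype(np.float32)
        out[:, t] = frame
    return FrameTimeSeries(
        intensity=out,
        timestamps_ms=protocol.timestamps_ms(),
        protocol=protocol,
        provenance=provenance,
    )


def simulate_phantom(spec: PhantomSpec) -> Tuple[RegionLabelVolume, FrameTimeSeries]:
    """Build the geometry and simulate its time series from one spec.

    Geometry and speckle use independent child seeds of ``spec.seed`` so
    that either can be reproduced in isolation.
    """
    regions = build_phantom(spec)
    speckle_seed = int(np.random.SeedSequence([spec.seed, 1]).generate_state(1)[0])
    series = simulate_timeseries(
        regions,
        spec.protocol,
        speckle_seed,
        noise_floor=spec.noise_floor,
        psf_lateral_fwhm_um=spec.psf_lateral_fwhm_um,
        psf_axial_fwhm_um=spec.psf_axial_fwhm_um,
        provenance=f"phantom seed={spec.seed}",
    )
    return regions, series


def analytic_intensity_correlation(
    m: float, tau_c_ms: float, delays_ms: Sequence[float]
) -> CorrelationCurve:
    """Closed-form intensity Pearson autocorrelation of the speckle model.

    For a circular Gaussian field with normalised field correlation
    ``g1(tau) = (1 - m) + m * exp(-tau / tau_c)`` the Siegert relation gives
    the intensity correlation ``rho(tau) = |g1(tau)|^2``; rho(0) = 1.
    """
    if not (0.0 <= m <= 1.0) or tau_c_ms <= 0:
        raise ValueError("require 0 <= m <= 1 and tau_c > 0")
    delays = np.asarray(delays_ms, dtype=np.float64)
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    g1 = (1.0 - m) + m * np.exp(-delays / tau_c_ms)
    return CorrelationCurve(delays_ms=delays, rho=g1**2)


def analytic_ocds(
    m: float,
    tau_c_ms: float,
    delays_ms: Sequence[float],
    *,
    negate: bool = True,
) -> float:
    """OLS slope of the analytic correlation curve at the given delays."""
    curve = analytic_intensity_correlation(m, tau_c_ms, delays_ms)
    tau = curve.delays_ms - curve.delays_ms.mean()
    slope = float(np.sum(tau * (curve.rho - curve.rho.mean())) / np.sum(tau**2))
    return -slope if negate else slope


# --------------------------------------------------------------------------
# Drug-response scenarios.


@lru_cache(maxsize=1)
def load_scenario_table() -> dict:
    """Versioned drug-scenario parameter table shipped with the package."""
    text = resources.files("doct.data").joinpath("scenarios.json").read_text()
    return json.loads(text)


def expected_directions() -> dict:
    """Expected sign of each quantified trend per condition (ground truth)."""
    return load_scenario_table()["expected_directions"]


def _condition_key(drug: str, concentration_uM: float) -> str:
    if drug == "control":
        return "control"
    return f"{drug}_{concentration_uM:g}"


def scenario_spec(
    drug: str,
    concentration_uM: float,
    treatment_day: int,
    replicate_seed: int,
    protocol: ScanProtocol | None = None,
) -> PhantomSpec:
    """Phantom spec for one (drug, concentration, day) study condition.

    Geometry and dynamics come from the shipped scenario table, which is
    tuned to reproduce the qualitative response orderings (growth or
    shrinkage, D-OCT signal decline, dead-fraction rise) — not absolute
    image values.  ``replicate_seed`` seeds the boundary perturbation,
    sub-region placement and speckle, so replicates share a condition's
    nominal geometry but differ in realisation.
    """
    table = load_scenario_table()
    protocol = protocol or DEFAULT_STUDY_PROTOCOL
    key = _condition_key(drug, concentration_uM)
    conditions = table["conditions"]
    if key not in conditions:
        known = sorted(conditions)
        raise ValueError(f"unknown condition {key!r}; known: {known}")
    day_key = str(treatment_day)
    if day_key not in conditions[key]:
        raise ValueError(
            f"unknown treatment day {treatment_day}; known: "
            f"{sorted(conditions[key])}"
        )
    row = conditions[key][day_key]
    layout = table["layout"]

    rng = np.random.default_rng(
        np.random.SeedSequence([int(replicate_seed) & 0x7FFFFFFF, 2]).generate_state(1)
    )
    overrides: List[RegionOverride] = []
    for ov in row.get("overrides", []):
        dyn = RegionDynamics(**ov["dynamics"])
        if ov["kind"] == "sphere":
            count = int(ov.get("count", 1))
            rmax = float(ov.get("placement_radius_rel", 0.75))
            for i in range(count):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                radial = rmax * rng.uniform() ** (1.0 / 3.0)
                overrides.append(
                    RegionOverride(
                        name=f"{ov.get('name', 'spot')}_{i}",
                        kind="sphere",
                        center_rel=tuple(direction * radial),
                        radius_um=float(ov["radius_um"]),
                        dynamics=dyn,
                    )
                )
        else:
            overrides.append(
                RegionOverride(
                    name=ov.get("name", "band"),
                    kind="radial_band",
                    band=tuple(ov["band"]),
                    dynamics=dyn,
                )
            )

    grid = protocol.grid_shape
    center_voxel = (
        grid[0] * 0.5 - 0.5,
        grid[1] * layout["center_depth_rel"] - 0.5,
        grid[2] * 0.5 - 0.5,
    )
    plate_depth = int(round(grid[1] * layout["plate_depth_rel"]))
    return PhantomSpec(
        protocol=protocol,
        center_voxel=center_voxel,
        radii_um=tuple(row["radii_um"]),
        boundary_perturbation=row["boundary_perturbation"],
        core_fraction=row["core_fraction"],
        shell=RegionDynamics(**row["shell"]),
        core=RegionDynamics(**row["core"]),
        region_overrides=tuple(overrides),
        plate_depth=plate_depth,
        plate_reflectivity=layout["plate_reflectivity"],
        noise_floor=layout["noise_floor"],
        seed=int(replicate_seed) & 0x7FFFFFFF,
    )
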