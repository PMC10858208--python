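"""Per-voxel dynamics contrasts from repeated-frame OCT time series.

Two contrasts are computed from the dB-scaled intensity sequence at each
voxel:

* **LIV** (logarithmic intensity variance): the time variance of the
  dB-scaled intensity, in dB^2.  It grows with the *magnitude* of the
  intensity fluctuations and hence of the intracellular motility.
* **OCDS_l** (late OCT correlation decay speed): the negated least-squares
  slope of the temporal autocorrelation decay curve over a late delay
  window (default [204.8, 1228.8] ms), in 1/ms.  It grows with the *speed*
  of the fluctuations, until the decay saturates within the first lag.

For fully developed speckle the dB-scaled intensity is a logarithmic
transform of an exponential variate, giving the closed-form LIV
``(10/ln 10)^2 * pi^2 / 6`` (~31.0 dB^2) for temporally uncorrelated
sampling — a useful calibration point for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .scan_io import DynamicsVolume, FrameTimeSeries

__all__ = [
    "MetricConfig",
    "AutocorrelationResult",
    "to_db",
    "compute_liv",
    "compute_autocorrelation",
    "compute_ocds",
    "pooled_autocorrelation",
    "LIV_FULLY_DEVELOPED_DB2",
]

# Population (divisor-N) variance of 10*log10 of an exponential variate:
# Var[ln X] = pi^2/6 for X ~ Exp, scaled by (10/ln 10)^2 for the dB scale.
LIV_FULLY_DEVELOPED_DB2: float = (10.0 / np.log(10.0)) ** 2 * np.pi**2 / 6.0


class MetricConfig(BaseModel):
    """Configuration of the dynamics-metric computations.

    ``db_floor_rel`` is the small linear offset added before the logarithm,
    expressed relative to the series mean intensity; it keeps empty voxels
    finite without biasing in-tissue voxels.  ``ocds_window_ms`` is the late
    delay range of the autocorrelation slope fit.  ``correlation_domain``
    selects whether the autocorrelation is taken on the dB-scaled (default)
    or linear intensity; the linear domain matches the analytic Siegert
    oracle exactly and is used for calibration checks.
    """

    db_floor_rel: float = Field(default=1e-6, gt=0)
    ocds_window_ms: Tuple[float, float] = (204.8, 1228.8)
    variance_divisor: Literal["N", "N-1"] = "N"
    ocds_sign: Literal["negated_slope", "raw_slope"] = "negated_slope"
    correlation_domain: Literal["db", "linear"] = "db"
    static_var_rel_tol: float = Field(default=1e-10, gt=0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_window(self) -> "MetricConfig":
        lo, hi = self.ocds_window_ms
        if not (0 < lo < hi):
            raise ValueError("ocds_window_ms must satisfy 0 < lower < upper")
        return self


def _db_floor(series: FrameTimeSeries, cfg: MetricConfig) -> float:
    mean = float(series.intensity.mean())
    return cfg.db_floor_rel * mean if mean > 0 else cfg.db_floor_rel


def to_db(intensity_linear: np.ndarray, db_floor: float = 0.0) -> np.ndarray:
    """dB-scale a linear intensity: ``10 * log10(I + db_floor)``."""
    intensity_linear = np.asarray(intensity_linear)
    if np.any(intensity_linear < 0):
        raise ValueError("linear intensity must be non-negative")
    return 10.0 * np.log10(intensity_linear + db_floor)


def window_lags(cfg: MetricConfig, frame_interval_ms: float, n_repeats: int) -> np.ndarray:
    """Integer lags whose delays fall inside the OCDS window (inclusive)."""
    lo, hi = cfg.ocds_window_ms
    if lo < frame_interval_ms * (1 - 1e-9):
        raise ValueError("ocds window lower bound must be >= one frame interval")
    kmax = min(n_repeats - 1, int(np.floor(hi / frame_interval_ms + 1e-9)))
    lags = np.arange(1, kmax + 1)
    delays = lags * frame_interval_ms
    keep = (delays >= lo * (1 - 1e-9)) & (delays <= hi * (1 + 1e-9))
    lags = lags[keep]
    if lags.size < 2:
        raise ValueError(
            f"OCDS window {cfg.ocds_window_ms} ms contains {lags.size} lag(s) at a "
            f"frame interval of {frame_interval_ms} ms; need at least 2"
        )
    return lags


def compute_liv(series: FrameTimeSeries, cfg: MetricConfig | None = None) -> DynamicsVolume:
    """Logarithmic intensity variance per voxel, in dB^2.

    The variance is taken over the repeat axis of the dB-scaled intensity
    with the divisor selected in the config (population ``N`` by default);
    ``mean_intensity_db`` is the temporal mean of the dB intensity.
    """
    cfg = cfg or MetricConfig()
    if series.protocol.n_repeats < 2:
        raise ValueError("LIV requires at least 2 repeats per location")
    db = to_db(series.intensity.astype(np.float64), _db_floor(series, cfg))
    ddof = 0 if cfg.variance_divisor == "N" else 1
    liv = np.var(db, axis=1, ddof=ddof)
    return DynamicsVolume(
        values=liv,
        metric_name="LIV",
        units="dB^2",
        mean_intensity_db=db.mean(axis=1),
    )


@dataclass
class AutocorrelationResult:
    """Per-voxel temporal autocorrelation at integer frame lags.

    ``rho`` is indexed ``[location, lag, depth, lateral]`` with
    ``delays_ms[k]`` the physical delay of lag index ``k``.  Static voxels
    (zero temporal variance up to a relative tolerance) are flagged in
    ``static_mask`` and given a non-decaying curve (rho = 1 at all lags).
    """

    rho: np.ndarray
    delays_ms: np.ndarray
    static_mask: np.ndarray
    mean_intensity_db: np.ndarray
    frame_interval_ms: float


def compute_autocorrelation(
    series: FrameTimeSeries, cfg: MetricConfig | None = None
) -> AutocorrelationResult:
    """Sample Pearson autocorrelation of the per-voxel intensity sequence.

    The sequence (dB-scaled by default) is centred with its full-series
    temporal mean and normalised by the divisor-N variance, so rho(0) = 1 by
    construction; the lag-k numerator averages the ``N - k`` available
    products.
    """
    cfg = cfg or MetricConfig()
    p = series.protocol
    lags = window_lags(cfg, p.frame_interval_ms, p.n_repeats)
    kmax = int(lags.max())
    if p.n_repeats < 2 + kmax:
        raise ValueError(
            f"need at least {2 + kmax} repeats for lag {kmax}; got {p.n_repeats}"
        )
    floor = _db_floor(series, cfg)
    linear = series.intensity.astype(np.float64)
    db = to_db(linear, floor)
    x = db if cfg.correlation_domain == "db" else linear
    xc = x - x.mean(axis=1, keepdims=True)
    var = np.mean(xc**2, axis=1)
    scale = np.mean(x**2, axis=1)
    static = var <= cfg.static_var_rel_tol * np.maximum(scale, 1e-300)
    safe_var = np.where(static, 1.0, var)
    rho = np.empty((x.shape[0], kmax, x.shape[2], x.shape[3]), dtype=np.float64)
    for k in range(1, kmax + 1):
        num = np.mean(xc[:, :-k] * xc[:, k:], axis=1)
        rho[:, k - 1] = num / safe_var
    rho[np.broadcast_to(static[:, None], rho.shape)] = 1.0
    return AutocorrelationResult(
        rho=rho,
        delays_ms=np.arange(1, kmax + 1, dtype=np.float64) * p.frame_interval_ms,
        static_mask=static,
        mean_intensity_db=db.mean(axis=1),
        frame_interval_ms=p.frame_interval_ms,
    )


def compute_ocds(
    curves: AutocorrelationResult, cfg: MetricConfig | None = None
) -> DynamicsVolume:
    """Late OCT correlation decay speed per voxel, in 1/ms.

    Ordinary least-squares slope of rho versus delay over the lags falling
    in the configured window; the reported value is the negated slope by
    default, so a faster decay gives a larger (positive) value.  Static
    voxels have rho = 1 at all lags and hence OCDS_l = 0 exactly.
    """
    cfg = cfg or MetricConfig()
    delays = curves.delays_ms
    lo, hi = cfg.ocds_window_ms
    keep = (delays >= lo * (1 - 1e-9)) & (delays <= hi * (1 + 1e-9))
    if keep.sum() < 2:
        raise ValueError("OCDS window must contain at least 2 computed lags")
    tau = delays[keep]
    rho = curves.rho[:, keep].astype(np.float64)
    tc = tau - tau.mean()
    # OLS slope with fixed abscissa: sum_k w_k * rho_k, w = tc / sum(tc^2)
    w = tc / np.sum(tc**2)
    slope = np.tensordot(rho, w, axes=([1], [0]))
    values = -slope if cfg.ocds_sign == "negated_slope" else slope
    values[curves.static_mask] = 0.0
    return DynamicsVolume(
        values=values,
        metric_name="OCDS_l",
        units="1/ms",
        mean_intensity_db=curves.mean_intensity_db,
    )


def compute_dynamics(
    series: FrameTimeSeries, cfg: MetricConfig | None = None
) -> Tuple[DynamicsVolume, DynamicsVolume]:
    """Convenience: (LIV, OCDS_l) volumes of a time series."""
    cfg = cfg or MetricConfig()
    liv = compute_liv(series, cfg)
    ocds = compute_ocds(compute_autocorrelation(series, cfg), cfg)
    return liv, ocds


def pooled_autocorrelation(samples: np.ndarray, lags: Sequence[int]) -> np.ndarray:
    """Ensemble autocorrelation pooled over many voxel realizations.

    ``samples`` is ``[n_voxels, n_repeats]``.  For each lag k the Pearson
    correlation is computed over all pooled pairs ``(x[v, t], x[v, t + k])``
    across voxels and times.  Unlike the per-voxel 32-sample estimator this
    ensemble estimator is essentially unbiased, which makes it the right
    quantity to compare against the analytic correlation curve.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("samples must be [n_voxels, n_repeats]")
    out = np.empty(len(lags), dtype=np.float64)
    for i, k in enumerate(lags):
        k = int(k)
        a = x[:, : x.shape[1] - k].ravel()
        b = x[:, k:].ravel()
        out[i] = np.corrcoef(a, b)[0, 1]
    return out
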