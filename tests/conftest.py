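import numpy as np
import pytest

from doct.phantom import RegionDynamics, RegionLabelVolume, simulate_timeseries
from doct.scan_io import FrameTimeSeries, ScanProtocol


@pytest.fixture
def small_protocol() -> ScanProtocol:
    return ScanProtocol(
        n_blocks=1,
        locations_per_block=2,
        n_repeats=4,
        a_lines_per_frame=8,
        n_depth_pixels=6,
        depth_pixel_size_um=16.0,
    )


@pytest.fixture
def oracle_protocol() -> ScanProtocol:
    """Grid with ~16k voxels for Monte-Carlo region statistics."""
    return ScanProtocol(
        n_blocks=1,
        locations_per_block=16,
        a_lines_per_frame=32,
        n_depth_pixels=32,
        depth_pixel_size_um=16.0,
    )


@pytest.fixture
def uniform_region_series(oracle_protocol):
    """Factory: homogeneous-dynamics speckle series without PSF blur/noise.

    Voxels are statistically independent, so region statistics follow the
    analytic single-voxel model exactly.
    """

    def _make(m: float, tau_c_ms: float, seed: int, protocol=None) -> FrameTimeSeries:
        protocol = protocol or oracle_protocol
        labels = np.ones(protocol.grid_shape, dtype=np.int16)
        regions = RegionLabelVolume(
            labels, {1: RegionDynamics(m=m, tau_c_ms=tau_c_ms, mean_reflectivity=1.0)}
        )
        return simulate_timeseries(
            regions, protocol, seed, psf_lateral_fwhm_um=0.0, psf_axial_fwhm_um=0.0
        )

    return _make


def series_from_array(intensity: np.ndarray, frame_interval_ms: float = 204.8) -> FrameTimeSeries:
    """Wrap a raw [location, repeat, depth, lateral] array as a time series."""
    n_loc, n_rep, n_depth, n_lat = intensity.shape
    protocol = ScanProtocol(
        n_blocks=1,
        locations_per_block=n_loc,
        n_repeats=n_rep,
        n_depth_pixels=n_depth,
        a_lines_per_frame=n_lat,
        frame_interval_ms=frame_interval_ms,
        depth_pixel_size_um=16.0,
    )
    return FrameTimeSeries(
        intensity=intensity,
        timestamps_ms=protocol.timestamps_ms(),
        protocol=protocol,
    )
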