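"""Segmentation, scalar quantification and Welch's t-test."""

import numpy as np
import pytest
from scipy import stats as sps

from doct.metrics import compute_liv
from doct.phantom import PhantomSpec, simulate_phantom
from doct.quantify import (
    SegmentationConfig,
    SegmentationError,
    SegmentationMask,
    SpheroidResult,
    ViabilityCutoffs,
    compute_volume,
    dead_cell_ratio,
    evaluate_direction_expectations,
    mean_metrics,
    segment_spheroid,
    timecourse_report,
    welch_ttest,
)
from doct.scan_io import DynamicsVolume, ScanProtocol


@pytest.fixture(scope="module")
def sphere_phantom():
    """Bright ellipsoid at ~30 dB SNR above the noise floor, with a plate."""
    protocol = ScanProtocol(
        n_blocks=2,
        locations_per_block=16,
        a_lines_per_frame=48,
        n_depth_pixels=48,
        depth_pixel_size_um=16.0,
    )
    spec = PhantomSpec(
        protocol=protocol,
        radii_um=(200.0, 200.0, 180.0),
        noise_floor=1e-3,
        plate_depth=44,
        seed=5,
    )
    regions, series = simulate_phantom(spec)
    liv = compute_liv(series)
    return spec, regions, liv


def _vol(values, mean_db=None) -> DynamicsVolume:
    values = np.asarray(values, np.float32)
    return DynamicsVolume(
        values=values,
        metric_name="LIV",
        units="dB^2",
        mean_intensity_db=np.zeros_like(values) if mean_db is None else mean_db,
    )


class TestSegmentation:
    def test_recovers_known_geometry_volume(self, sphere_phantom):
        spec, regions, liv = sphere_phantom
        mask = segment_spheroid(
            liv.mean_intensity_db, SegmentationConfig(), spec.protocol.voxel_volume_mm3
        )
        true_voxels = int(np.count_nonzero(regions.labels > 0) -
                          np.count_nonzero(regions.labels == regions.plate_label))
        assert mask.mask.sum() == pytest.approx(true_voxels, rel=0.05)

    def test_plate_slab_fully_excluded(self, sphere_phantom):
        spec, _, liv = sphere_phantom
        cfg = SegmentationConfig()
        mask = segment_spheroid(liv.mean_intensity_db, cfg, 1.0)
        assert mask.provenance["plate_depth"] == spec.plate_depth
        lo = spec.plate_depth - cfg.plate_slab_halfwidth
        hi = spec.plate_depth + cfg.plate_slab_halfwidth + 1
        assert mask.mask[:, lo:hi, :].sum() == 0

    def test_threshold_above_maximum_errors(self, sphere_phantom):
        _, _, liv = sphere_phantom
        cfg = SegmentationConfig(
            intensity_threshold_db=float(liv.mean_intensity_db.max()) + 10.0
        )
        with pytest.raises(SegmentationError, match="no spheroid found"):
            segment_spheroid(liv.mean_intensity_db, cfg, 1.0)

    def test_mask_is_single_connected_component(self, sphere_phantom):
        from skimage.measure import label

        _, _, liv = sphere_phantom
        mask = segment_spheroid(liv.mean_intensity_db, SegmentationConfig(), 1.0)
        assert label(mask.mask, connectivity=3).max() == 1


class TestScalars:
    def test_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:1000] = True
        assert compute_volume(SegmentationMask(mask, 1e-6)) == pytest.approx(1e-3)

    def test_empty_mask_volume_is_zero(self):
        assert compute_volume(SegmentationMask(np.zeros((2, 2, 2), bool), 1e-6)) == 0.0

    def test_uniform_mean(self):
        mask = SegmentationMask(np.ones((2, 2, 2), bool), 1.0)
        liv = _vol(np.full((2, 2, 2), 5.0))
        ocds = DynamicsVolume(
            np.full((2, 2, 2), 1e-4, np.float32), "OCDS_l", "1/ms",
            np.zeros((2, 2, 2), np.float32),
        )
        m_liv, m_ocds = mean_metrics(mask, liv, ocds)
        assert m_liv == pytest.approx(5.0)
        assert m_ocds == pytest.approx(1e-4)

    def test_two_level_mean(self):
        mask = SegmentationMask(np.ones((1, 2, 2), bool), 1.0)
        vals = np.array([[[1e-4, 1e-4], [3e-4, 3e-4]]], np.float32)
        ocds = DynamicsVolume(vals, "OCDS_l", "1/ms", np.zeros_like(vals))
        liv = _vol(np.zeros((1, 2, 2)))
        assert mean_metrics(mask, liv, ocds)[1] == pytest.approx(2e-4)

    def test_in_mask_mean_is_count_weighted_region_mean(self):
        rng = np.random.default_rng(0)
        mask_arr = np.zeros((4, 8, 8), bool)
        region_a = np.zeros_like(mask_arr)
        region_a[:2] = True
        region_b = np.zeros_like(mask_arr)
        region_b[2:3] = True
        mask_arr = region_a | region_b
        vals = rng.normal(10, 2, mask_arr.shape).astype(np.float32) ** 2
        liv = _vol(vals)
        mask = SegmentationMask(mask_arr, 1.0)
        m, _ = mean_metrics(mask, liv, _as_ocds(np.zeros_like(vals)))
        na, nb = region_a.sum(), region_b.sum()
        expected = (vals[region_a].mean() * na + vals[region_b].mean() * nb) / (na + nb)
        assert m == pytest.approx(float(expected), rel=1e-6)

    def test_empty_mask_errors(self):
        mask = SegmentationMask(np.zeros((2, 2, 2), bool), 1.0)
        vol = _vol(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            mean_metrics(mask, vol, vol)
        with pytest.raises(ValueError, match="empty"):
            dead_cell_ratio(mask, vol)


def _as_ocds(values) -> DynamicsVolume:
    values = np.asarray(values, np.float32)
    return DynamicsVolume(values, "OCDS_l", "1/ms", np.zeros_like(values))


class TestDeadCellRatio:
    def test_all_viable_gives_zero(self):
        mask = SegmentationMask(np.ones((2, 2, 2), bool), 1.0)
        assert dead_cell_ratio(mask, _vol(np.full((2, 2, 2), 10.0))) == 0.0

    def test_constructed_fraction_recovered_exactly(self):
        rng = np.random.default_rng(42)
        mask_arr = rng.uniform(size=(10, 20, 20)) < 0.5
        n_in = int(mask_arr.sum())
        n_dead = int(round(0.30 * n_in))
        vals = np.full(mask_arr.shape, 10.0, np.float32)
        idx = np.argwhere(mask_arr)
        dead_idx = idx[rng.choice(n_in, size=n_dead, replace=False)]
        vals[tuple(dead_idx.T)] = 1.0  # below the 3 dB^2 cut-off
        ratio = dead_cell_ratio(SegmentationMask(mask_arr, 1.0), _vol(vals))
        assert ratio == n_dead / n_in

    def test_strictly_below_cutoff_and_complement(self):
        cutoffs = ViabilityCutoffs()
        mask = SegmentationMask(np.ones((1, 2, 2), bool), 1.0)
        vals = np.array([[[2.9, 3.0], [3.1, 0.5]]])
        ratio = dead_cell_ratio(mask, _vol(vals), cutoffs)
        assert ratio == 0.5  # exactly-at-cutoff voxel counts as viable
        alive = np.count_nonzero(vals >= cutoffs.liv_cutoff_db2) / vals.size
        assert ratio + alive == 1.0


class TestWelch:
    def test_identical_groups(self):
        res = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_constant_groups_with_distinct_means(self):
        res = welch_ttest([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert res.p == 0.0

    def test_identical_constant_groups(self):
        res = welch_ttest([2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(2, 10))
            b = rng.normal(0.3, 2, rng.integers(2, 10))
            mine = welch_ttest(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.dof == pytest.approx(ref.df, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)


def _fake_results(conditions=("control", "X_1"), days=(1, 3, 6), n_rep=3, jitter=0.0):
    rng = np.random.default_rng(0)
    out = []
    for ci, cond in enumerate(conditions):
        drug, conc = ("control", 0.0) if cond == "control" else tuple(cond.split("_"))
        for day in days:
            for rep in range(n_rep):
                base = 1.0 + 0.1 * day + ci
                out.append(
                    SpheroidResult(
                        drug=str(drug),
                        concentration_uM=float(conc),
                        treatment_day=day,
                        replicate=rep,
                        volume_mm3=base + jitter * rng.normal(),
                        mean_liv=20.0 - day + jitter * rng.normal(),
                        mean_ocds=4e-4 - 1e-5 * day,
                        dead_ratio_liv=0.05 * day,
                        dead_ratio_ocds=0.04 * day,
                    )
                )
    return out


class TestTimecourseReport:
    def test_row_counts(self):
        report = timecourse_report(_fake_results())
        assert len(report.summary) == 2 * 3
        assert len(report.comparisons) == 2 * 3 * 5  # conditions x day pairs x scalars

    def test_identical_replicates_have_zero_sd(self):
        report = timecourse_report(_fake_results(jitter=0.0))
        assert np.allclose(report.summary["volume_mm3_std"], 0.0)

    def test_missing_day_omitted_with_warning(self):
        results = [r for r in _fake_results() if not (r.condition == "X_1" and r.treatment_day == 6)]
        with pytest.warns(UserWarning, match="omitted"):
            report = timecourse_report(results)
        x1 = report.comparisons[report.comparisons.condition == "X_1"]
        assert set(zip(x1.day_a, x1.day_b)) == {(1, 3)}

    def test_direction_evaluation(self):
        report = timecourse_report(_fake_results(jitter=0.0))
        expectations = {
            "control": {"volume": "+", "mean_liv": "-"},
            "X_1": {"volume": "+", "mean_liv": "+"},  # second is wrong on purpose
        }
        checks = evaluate_direction_expectations(report, expectations)
        assert len(checks) == 4
        agree = dict(zip(zip(checks.condition, checks.quantity), checks.agree))
        assert agree[("control", "volume")]
        assert not agree[("X_1", "mean_liv")]
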