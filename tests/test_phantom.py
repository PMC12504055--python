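"""Phantom-benchmark tests: segmentation, session stats, report arithmetic."""

import numpy as np
import pandas as pd
import pytest

import qmapkit as qk
from qmapkit.errors import ConfigurationError, SegmentationError
from qmapkit.phantom import (
    MEASUREMENT_COLUMNS,
    PHYSIOLOGICAL_WINDOWS,
    benchmark,
    segment_vials,
    session_summary,
    sphere_roi_mask,
    vial_measurements,
)
from qmapkit.synthetic import phantom_ground_truth
from qmapkit.utils import round_half_away


def brute_force_sphere_count(shape, voxel_size, center, radius):
    """Oracle: voxel-by-voxel loop applying the center-inside rule."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                p = ((i + 0.5) * voxel_size[0], (j + 0.5) * voxel_size[1],
                     (k + 0.5) * voxel_size[2])
                if sum((a - b) ** 2 for a, b in zip(p, center)) <= radius**2:
                    count += 1
    return count


class TestSphereRoi:
    @pytest.mark.parametrize("radius", [5.0, 7.5])
    def test_matches_rasterization_oracle(self, radius):
        shape, vx = (14, 14, 14), (2.0, 2.0, 2.0)
        center = (13.0, 15.0, 14.5)
        mask = sphere_roi_mask(shape, vx, center, radius)
        assert mask.sum() == brute_force_sphere_count(shape, vx, center, radius)


@pytest.fixture(scope="module")
def noiseless_acquisition(timing, small_layout):
    design = qk.StudyDesign(n_sessions=1, n_repeats_per_session=1,
                            noise_sd=0.0, session_drift_sd=0.0, seed=0)
    return next(iter(qk.generate_phantom_series(small_layout, design, timing)))


class TestSegmentVials:
    def test_centroids_within_one_voxel(self, small_layout, noiseless_acquisition):
        pdw = noiseless_acquisition.contrasts[..., 0]
        seg = segment_vials(pdw, small_layout.t1_centers, small_layout.voxel_size,
                            small_layout.vial_radius)
        assert seg.masks.shape[0] == 14
        err = np.linalg.norm(seg.centroids_mm - small_layout.t1_centers, axis=1)
        assert np.max(err) <= np.max(small_layout.voxel_size)
        assert all(m.sum() > 0 for m in seg.masks)

    def test_polarity_autodetected(self, small_layout):
        truth = phantom_ground_truth(small_layout)
        pdw = np.where(truth.labels > 0, 1.0, 0.2)
        seg_bright = segment_vials(pdw, small_layout.t1_centers,
                                   small_layout.voxel_size,
                                   small_layout.vial_radius)
        seg_dark = segment_vials(1.2 - pdw, small_layout.t1_centers,
                                 small_layout.voxel_size,
                                 small_layout.vial_radius)
        np.testing.assert_allclose(seg_dark.centroids_mm,
                                   seg_bright.centroids_mm, atol=1e-9)

    def test_empty_volume_raises(self, small_layout):
        with pytest.raises(SegmentationError):
            segment_vials(np.zeros((32, 32, 32)), small_layout.t1_centers,
                          (2.0, 2.0, 2.0), 7.0)

    def test_missing_vials_reported(self, small_layout, noiseless_acquisition):
        pdw = noiseless_acquisition.contrasts[..., 0].copy()
        truth = phantom_ground_truth(small_layout)
        # erase two vials entirely
        pdw[truth.labels == 1] = pdw.min()
        pdw[truth.labels == 2] = pdw.min()
        with pytest.raises(SegmentationError):
            segment_vials(pdw, small_layout.t1_centers, small_layout.voxel_size,
                          small_layout.vial_radius)


class TestSessionSummary:
    @staticmethod
    def _table(values, session=0):
        return pd.DataFrame([
            {"parameter": "T1", "vial": 1, "session": session, "acquisition": i,
             "value": v, "roi_voxel_count": 10}
            for i, v in enumerate(values)
        ], columns=list(MEASUREMENT_COLUMNS))

    def test_identical_acquisitions_zero_cv(self):
        out = session_summary(self._table([500.0] * 5))
        assert out.loc[0, "intrasession_cv_pct"] == 0.0
        assert out.loc[0, "session_mean"] == 500.0

    def test_hand_arithmetic(self):
        out = session_summary(self._table([100.0, 102.0]))
        assert out.loc[0, "session_mean"] == 101.0
        assert out.loc[0, "intrasession_cv_pct"] == pytest.approx(
            np.sqrt(2.0) / 101.0 * 100.0
        )
        assert round_half_away(out.loc[0, "intrasession_cv_pct"]) == 1.4

    def test_single_acquisition_cv_undefined(self):
        out = session_summary(self._table([100.0]))
        assert np.isnan(out.loc[0, "intrasession_cv_pct"])


def _measurements_from_session_means(means_by_vial, parameter="T1"):
    """One acquisition per session whose value equals the session mean."""
    rows = []
    for vial, means in means_by_vial.items():
        for s, m in enumerate(means):
            rows.append({"parameter": parameter, "vial": vial, "session": s,
                         "acquisition": 0, "value": m, "roi_voxel_count": 9})
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def _session_means(mean, sd, n=12):
    """n values with exact mean and exact sample SD."""
    z = np.array([1.0, -1.0] * (n // 2))
    z = z / np.std(z, ddof=1)
    return mean + sd * z


class TestBenchmark:
    def test_identity_recovery(self):
        refs = {"T1": {1: 1741.3, 2: 962.0, 3: 487.4}}
        meas = _measurements_from_session_means(
            {v: [r] * 3 for v, r in refs["T1"].items()})
        rep = benchmark(meas, refs)
        assert np.allclose(rep.table["bias_ms"], 0.0)
        assert np.allclose(rep.table["intersession_cv_pct"], 0.0)
        reg = rep.regressions["T1"]
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-9)
        assert reg.r_squared == pytest.approx(1.0)

    def test_reported_bias_and_cv_cells(self):
        # vial 1: grand mean 2175.6 vs reference 1741.3
        meas = _measurements_from_session_means(
            {1: _session_means(2175.6, 12.1), 7: _session_means(382.3, 3.3)})
        refs = {"T1": {1: 1741.3, 7: 245.8}}
        rep = benchmark(meas, refs)
        r1 = rep.table.set_index("vial").loc[1]
        assert round_half_away(r1["bias_ms"]) == 434.3
        assert round_half_away(r1["bias_pct"]) == 24.9
        assert round_half_away(r1["intersession_cv_pct"]) == 0.6
        r7 = rep.table.set_index("vial").loc[7]
        assert round_half_away(r7["intersession_cv_pct"]) == 0.9

    def test_window_and_exclusions(self):
        means = {v: [100.0 * v, 100.0 * v] for v in (1, 2, 3)}
        meas = _measurements_from_session_means(means, parameter="T2")
        refs = {"T2": {1: 493.0, 2: 184.7, 3: 30.0}}  # vial 3 below window
        rep = benchmark(meas, refs, excluded={"T2": (1,)})
        assert set(rep.table["vial"]) == {2}

    def test_missing_reference_raises(self):
        meas = _measurements_from_session_means({1: [500.0, 510.0]})
        with pytest.raises(ConfigurationError):
            benchmark(meas, {"T1": {2: 500.0}})

    def test_single_session_cv_sentinel(self):
        meas = _measurements_from_session_means({1: [1741.3]})
        rep = benchmark(meas, {"T1": {1: 1741.3}})
        assert np.isnan(rep.table.loc[0, "intersession_cv_pct"])

    def test_r_squared_invariant_to_rescaling(self):
        rngl = np.random.default_rng(0)
        means = {v: list(500.0 * v + rngl.normal(0, 5, 4)) for v in (1, 2, 3)}
        refs = {"T1": {1: 487.4, 2: 962.0, 3: 1269.8}}
        rep1 = benchmark(_measurements_from_session_means(means), refs)
        scaled = {v: [2.5 * x for x in m] for v, m in means.items()}
        rep2 = benchmark(_measurements_from_session_means(scaled), refs)
        assert rep1.regressions["T1"].r_squared == pytest.approx(
            rep2.regressions["T1"].r_squared, rel=1e-12
        )

    def test_session_regression_mode(self):
        means = {1: [480.0, 500.0], 2: [950.0, 970.0]}
        refs = {"T1": {1: 487.4, 2: 962.0}}
        rep = benchmark(_measurements_from_session_means(means), refs,
                        regression_mode="session")
        assert rep.regressions["T1"].n_points == 4

    def test_vial_measurement_schema(self, small_layout, timing,
                                     noiseless_acquisition, coarse_dictionary):
        pdw = noiseless_acquisition.contrasts[..., 0]
        seg = segment_vials(pdw, small_layout.t1_centers, small_layout.voxel_size,
                            small_layout.vial_radius)
        maps = qk.fit_volume(noiseless_acquisition.contrasts.astype(float),
                             coarse_dictionary, mask=seg.masks.any(axis=0))
        df = vial_measurements(maps.t1_map, seg, "T1", 0, 0)
        assert list(df.columns) == list(MEASUREMENT_COLUMNS)
        assert (df["roi_voxel_count"] > 0).all()
        assert df["value"].notna().all()


def test_windows_match_reference_ladder():
    lo, hi = PHYSIOLOGICAL_WINDOWS["T1"]
    assert lo <= 245.8 and hi >= 1741.3
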