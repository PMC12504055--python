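"""Phantom benchmarking: vial segmentation, repeatability and accuracy.

The analysis mirrors a standard system-phantom protocol: vials are
segmented automatically on the PD-weighted volume, each vial is measured
as the mean fitted value within a 5-mm-radius spherical ROI at the vial
centroid, and accuracy (bias vs. reference), intra-/intersession
repeatability (coefficient of variation, sample SD) and linearity
(ordinary least-squares regression of derived on reference) are reported
for the vials inside the physiological window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import ConfigurationError, SegmentationError
from .fitting import fit_volume
from .sequence import Dictionary, SequenceTiming
from .synthetic import PhantomLayout, StudyDesign, generate_phantom_series
from .utils import cv_percent, round_half_away

__all__ = [
    "PHYSIOLOGICAL_WINDOWS",
    "MEASUREMENT_COLUMNS",
    "VialSegmentation",
    "RegressionResult",
    "BenchmarkReport",
    "sphere_roi_mask",
    "segment_vials",
    "vial_measurements",
    "session_summary",
    "benchmark",
    "run_phantom_benchmark",
]

#: Physiologically relevant reference windows (ms) assessed in the report;
#: the bounds are the reference values of the outermost vials included in
#: the physical-phantom analysis, hence inclusive.
PHYSIOLOGICAL_WINDOWS = {"T1": (245.8, 1741.3), "T2": (42.0, 493.0)}

#: Schema of the tidy measurement table.
MEASUREMENT_COLUMNS = (
    "parameter", "vial", "session", "acquisition", "value", "roi_voxel_count",
)


def sphere_roi_mask(shape, voxel_size, center_mm, radius_mm) -> np.ndarray:
    """Spherical ROI in mm space: a voxel belongs iff its center is inside."""
    vx = np.asarray(voxel_size, float)
    coords = [(np.arange(shape[i]) + 0.5) * vx[i] for i in range(3)]
    c = np.asarray(center_mm, float)
    d2 = (
        (coords[0][:, None, None] - c[0]) ** 2
        + (coords[1][None, :, None] - c[1]) ** 2
        + (coords[2][None, None, :] - c[2]) ** 2
    )
    return d2 <= radius_mm**2


@dataclass
class VialSegmentation:
    """Matched vial ROIs: masks indexed like the template centers (1-based
    vial order), plus the detected centroids in mm."""

    masks: np.ndarray  # (n_vials, nx, ny, nz) bool
    centroids_mm: np.ndarray  # (n_vials, 3)
    threshold: float
    roi_radius: float


def segment_vials(pd_volume: np.ndarray, template_centers_mm,
                  voxel_size, vial_radius_mm: float,
                  roi_radius_mm: float = 5.0,
                  volume_tolerance: tuple[float, float] = (0.5, 2.0),
                  ) -> VialSegmentation:
    """Automated vial segmentation on a PD-weighted volume.

    Otsu threshold -> 26-connected components -> components kept if their
    volume is within ``volume_tolerance`` of the nominal vial volume ->
    centroids matched to the template by least-total-squared-distance
    assignment -> spherical ROI of ``roi_radius_mm`` at each matched
    centroid. Polarity (bright vials on dark background or the inverse)
    is auto-detected: the vials are assumed to be the minority class.
    """
    pd_volume = np.asarray(pd_volume, float)
    template = np.asarray(template_centers_mm, float)
    vx = np.asarray(voxel_size, float)
    if pd_volume.size == 0 or np.all(pd_volume == pd_volume.flat[0]):
        raise SegmentationError("PD volume is empty or constant; cannot segment")
    thr = float(threshold_otsu(pd_volume, nbins=256))
    above = pd_volume > thr
    fg = above if above.mean() <= 0.5 else ~above

    labels = cc_label(fg, connectivity=3)
    voxvol = float(np.prod(vx))
    nominal = 4.0 / 3.0 * np.pi * vial_radius_mm**3
    cands = []
    for region in regionprops(labels):
        vol = region.num_pixels * voxvol
        if volume_tolerance[0] * nominal <= vol <= volume_tolerance[1] * nominal:
            cands.append((np.asarray(region.centroid) + 0.5) * vx)
    if len(cands) < template.shape[0]:
        raise SegmentationError(
            f"found {len(cands)} candidate vial components for "
            f"{template.shape[0]} template vials"
        )
    cands = np.asarray(cands)
    cost = np.sum((template[:, None, :] - cands[None, :, :]) ** 2, axis=-1)
    rows, cols = linear_sum_assignment(cost)
    centroids = cands[cols[np.argsort(rows)]]
    far = np.linalg.norm(centroids - template, axis=1) > 2.0 * vial_radius_mm
    if np.any(far):
        raise SegmentationError(
            "unmatched template vials (nearest component too far): indices "
            f"{(np.flatnonzero(far) + 1).tolist()}"
        )
    masks = np.stack([
        sphere_roi_mask(pd_volume.shape, vx, c, roi_radius_mm) for c in centroids
    ])
    return VialSegmentation(masks=masks, centroids_mm=centroids,
                            threshold=thr, roi_radius=roi_radius_mm)


def vial_measurements(value_map: np.ndarray, segmentation: VialSegmentation,
                      parameter: str, session: int, acquisition: int
                      ) -> pd.DataFrame:
    """Mean fitted value per vial ROI as one tidy measurement block."""
    rows = []
    for i, mask in enumerate(segmentation.masks, start=1):
        vals = value_map[mask]
        vals = vals[np.isfinite(vals)]
        rows.append({
            "parameter": parameter,
            "vial": i,
            "session": session,
            "acquisition": acquisition,
            "value": float(np.mean(vals)),
            "roi_voxel_count": int(vals.size),
        })
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def session_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-vial session mean and intrasession CV (sample SD / mean * 100).

    Works on a tidy measurement table for one or more sessions; a session
    with a single acquisition gets a NaN CV (undefined sentinel).
    """
    grouped = measurements.groupby(["parameter", "vial", "session"])["value"]
    out = grouped.agg(
        session_mean="mean",
        intrasession_cv_pct=cv_percent,
        n_acquisitions="count",
    ).reset_index()
    return out


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class BenchmarkReport:
    """Accuracy/repeatability/linearity summary of a phantom study."""

    table: pd.DataFrame
    regressions: dict[str, RegressionResult]
    windows: Mapping[str, tuple[float, float]]
    excluded: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    regression_mode: str = "grand"

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        """Table rounded half-away-from-zero, as the study tables print."""
        out = self.table.copy()
        for col in ("grand_mean", "intersession_sd", "intersession_cv_pct",
                    "intrasession_cv_min_pct", "intrasession_cv_max_pct",
                    "reference", "bias_ms", "bias_pct"):
            out[col] = round_half_away(out[col].to_numpy(), decimals)
        return out


def benchmark(measurements: pd.DataFrame,
              references: Mapping[str, Mapping[int, float]],
              windows: Mapping[str, tuple[float, float]] | None = None,
              excluded: Mapping[str, Iterable[int]] | None = None,
              regression_mode: str = "grand") -> BenchmarkReport:
    """Accuracy, repeatability and linearity over a repeat-scan design.

    Parameters
    ----------
    measurements : tidy table with MEASUREMENT_COLUMNS.
    references : {'T1': {vial: ms}, 'T2': {...}} manufacturer references.
    windows : per-parameter (lo, hi) reference window included in the
        report; defaults to PHYSIOLOGICAL_WINDOWS.
    excluded : per-parameter 1-based vial indices excluded from analysis.
    regression_mode : 'grand' regresses per-vial grand means on the
        references; 'session' regresses all per-session means.

    Per vial: grand mean over all acquisitions, bias (ms and % of
    reference), intersession SD/CV over the session means, and the range
    of intrasession CVs. Vials whose reference lies outside the window,
    or that are excluded, do not enter the report or the regression.
    """
    if regression_mode not in ("grand", "session"):
        raise ConfigurationError("regression_mode must be 'grand' or 'session'")
    windows = dict(PHYSIOLOGICAL_WINDOWS if windows is None else windows)
    excluded = {k: tuple(v) for k, v in (excluded or {}).items()}
    sessions = session_summary(measurements)
    if measurements["session"].nunique() < 2:
        # single-session input: intersession statistics are undefined
        pass
    rows = []
    regressions: dict[str, RegressionResult] = {}
    for parameter, meas in measurements.groupby("parameter"):
        refs = references.get(parameter)
        if refs is None:
            raise ConfigurationError(f"no references for parameter {parameter!r}")
        lo, hi = windows.get(parameter, (-np.inf, np.inf))
        skip = set(excluded.get(parameter, ()))
        reg_x, reg_y = [], []
        for vial, vdf in meas.groupby("vial"):
            if vial in skip:
                continue
            if vial not in refs:
                raise ConfigurationError(
                    f"missing reference for {parameter} vial {vial}"
                )
            ref = float(refs[vial])
            if not lo <= ref <= hi:
                continue
            ses = sessions[(sessions["parameter"] == parameter)
                           & (sessions["vial"] == vial)]
            grand = float(vdf["value"].mean())
            icv = ses["intrasession_cv_pct"].to_numpy(float)
            rows.append({
                "parameter": parameter,
                "vial": int(vial),
                "grand_mean": grand,
                "intersession_sd": float(np.std(ses["session_mean"], ddof=1))
                if len(ses) > 1 else np.nan,
                "intersession_cv_pct": cv_percent(ses["session_mean"]),
                "intrasession_cv_min_pct": float(np.nanmin(icv))
                if np.isfinite(icv).any() else np.nan,
                "intrasession_cv_max_pct": float(np.nanmax(icv))
                if np.isfinite(icv).any() else np.nan,
                "reference": ref,
                "bias_ms": grand - ref,
                "bias_pct": (grand - ref) / ref * 100.0,
                "n_sessions": int(len(ses)),
                "n_acquisitions": int(len(vdf)),
            })
            if regression_mode == "grand":
                reg_x.append(ref)
                reg_y.append(grand)
            else:
                reg_x.extend([ref] * len(ses))
                reg_y.extend(ses["session_mean"].tolist())
        if len(reg_x) >= 2:
            fit = linregress(reg_x, reg_y)
            regressions[parameter] = RegressionResult(
                slope=float(fit.slope), intercept=float(fit.intercept),
                r_squared=float(fit.rvalue**2), n_points=len(reg_x),
            )
    table = pd.DataFrame(rows)
    return BenchmarkReport(table=table, regressions=regressions,
                           windows=windows, excluded=excluded,
                           regression_mode=regression_mode)


def run_phantom_benchmark(layout: PhantomLayout, design: StudyDesign,
                          timing: SequenceTiming, dictionary: Dictionary,
                          roi_radius_mm: float = 5.0) -> tuple[BenchmarkReport, pd.DataFrame]:
    """Full phantom pipeline: simulate -> segment -> fit -> benchmark.

    Vials are segmented once on the first acquisition's PD-weighted
    volume (the phantom does not move between sessions); fitting is
    restricted to the vial ROIs for speed. Returns the report and the
    tidy measurement table.
    """
    seg_t1 = seg_t2 = None
    all_meas = []
    for acq in generate_phantom_series(layout, design, timing):
        pdw = acq.contrasts[..., 0]
        if seg_t1 is None:
            seg_t1 = segment_vials(pdw, layout.t1_centers, layout.voxel_size,
                                   layout.vial_radius, roi_radius_mm)
            seg_t2 = segment_vials(pdw, layout.t2_centers, layout.voxel_size,
                                   layout.vial_radius, roi_radius_mm)
            fit_mask = seg_t1.masks.any(axis=0) | seg_t2.masks.any(axis=0)
        maps = fit_volume(acq.contrasts.astype(np.float64), dictionary,
                          mask=fit_mask, voxel_size=layout.voxel_size)
        all_meas.append(vial_measurements(maps.t1_map, seg_t1, "T1",
                                          acq.session_index,
                                          acq.acquisition_index))
        all_meas.append(vial_measurements(maps.t2_map, seg_t2, "T2",
                                          acq.session_index,
                                          acq.acquisition_index))
    measurements = pd.concat(all_meas, ignore_index=True)
    references = {
        "T1": {i + 1: v for i, v in enumerate(layout.t1_references)},
        "T2": {i + 1: v for i, v in enumerate(layout.t2_references)},
    }
    report = benchmark(measurements, references,
                       excluded={"T2": layout.excluded_t2_vials})
    return report, measurements
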