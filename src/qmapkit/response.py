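"""Longitudinal in vivo analysis: masking, ROI statistics and deltas.

The treatment-response chain reproduced here: background removal by Otsu
thresholding of the PD-weighted volume, seed-fill masking of the airway,
per-ROI summary statistics and fixed-edge histograms of the fitted T1/T2
maps, longitudinal delta analysis of ROI means relative to the
pre-treatment baseline, the within-subject coefficient of variation
(wCV, sample SD of the per-timepoint means over their mean), and the
comparison of shrinking residual-disease regions against the initial
disease extent via shared-edge histograms and mean/median deltas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.filters import threshold_otsu
from skimage.segmentation import flood

from .errors import DegenerateInputError, EmptyRoiError, SeedPlacementError
from .utils import cv_percent

__all__ = [
    "T1_BIN_WIDTH",
    "T2_BIN_WIDTH",
    "RoiTimepointStats",
    "DeltaReport",
    "background_mask",
    "airway_mask",
    "histogram_edges",
    "roi_stats",
    "delta_analysis",
    "rd_vs_initial_comparison",
]

#: Study-wide histogram bin widths (ms), fixed across timepoints so that
#: histograms of the same ROI are directly comparable.
T1_BIN_WIDTH = 25.0
T2_BIN_WIDTH = 2.5


def background_mask(pd_volume: np.ndarray) -> np.ndarray:
    """Foreground (tissue) mask by Otsu thresholding of the PDw volume.

    The threshold maximizes the between-class variance over a 256-bin
    histogram; foreground is strictly above the threshold.
    """
    pd_volume = np.asarray(pd_volume, float)
    if pd_volume.size == 0 or np.all(pd_volume == pd_volume.flat[0]):
        raise DegenerateInputError("constant or empty volume cannot be thresholded")
    thr = threshold_otsu(pd_volume, nbins=256)
    return pd_volume > thr


def airway_mask(pd_volume: np.ndarray, seed_point: tuple[int, int, int]
                ) -> np.ndarray:
    """6-connected flood fill of the sub-threshold region holding the seed.

    The threshold is the same Otsu threshold used for the background
    mask; the seed must sit in a below-threshold (air) voxel.
    """
    pd_volume = np.asarray(pd_volume, float)
    if pd_volume.size == 0 or np.all(pd_volume == pd_volume.flat[0]):
        raise DegenerateInputError("constant or empty volume cannot be thresholded")
    thr = threshold_otsu(pd_volume, nbins=256)
    air = pd_volume <= thr
    seed = tuple(int(i) for i in seed_point)
    if not air[seed]:
        raise SeedPlacementError(
            f"seed {seed} lies in a foreground (above-threshold) voxel"
        )
    return flood(air, seed, connectivity=1) & air


def histogram_edges(lo: float, hi: float, bin_width: float) -> np.ndarray:
    """Fixed bin edges from lo (inclusive) covering hi, step bin_width."""
    n = max(1, int(np.ceil((hi - lo) / bin_width)))
    return lo + bin_width * np.arange(n + 1)


@dataclass
class RoiTimepointStats:
    """Summary statistics of one ROI on one map at one timepoint."""

    roi_label: str
    timepoint_label: str
    mean: float
    median: float
    sd: float
    skewness: float
    histogram_edges: np.ndarray
    histogram_density: np.ndarray  # normalized to unit area
    voxel_count: int


def roi_stats(value_map: np.ndarray, roi_mask: np.ndarray,
              exclusion_masks: Mapping[str, np.ndarray] | None = None,
              include_mask: np.ndarray | None = None,
              bin_edges: np.ndarray | None = None,
              bin_width: float = T1_BIN_WIDTH,
              roi_label: str = "roi", timepoint_label: str = "") -> RoiTimepointStats:
    """Statistics over ROI voxels after inclusion/exclusion masking.

    Voxels enter if they are in ``roi_mask``, in ``include_mask`` (e.g.
    the Otsu foreground) when given, in none of the named
    ``exclusion_masks`` (e.g. the airway), and carry a finite value.
    Skewness is the adjusted Fisher-Pearson coefficient; a zero-variance
    ROI has skewness 0 by convention. The histogram uses fixed study-wide
    edges (``bin_edges`` wins over ``bin_width``) and is normalized to
    unit area.
    """
    effective = np.asarray(roi_mask, bool).copy()
    if include_mask is not None:
        effective &= np.asarray(include_mask, bool)
    names = []
    for name, m in (exclusion_masks or {}).items():
        effective &= ~np.asarray(m, bool)
        names.append(name)
    values = np.asarray(value_map, float)[effective]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyRoiError(
            f"ROI {roi_label!r} is empty after applying include mask and "
            f"exclusions {names}"
        )
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    skew = float(sps.skew(values, bias=False)) if sd > 0 and values.size > 2 else 0.0
    if bin_edges is None:
        lo = bin_width * np.floor(values.min() / bin_width)
        bin_edges = histogram_edges(lo, values.max() + bin_width, bin_width)
    density, _ = np.histogram(values, bins=bin_edges, density=True)
    return RoiTimepointStats(
        roi_label=roi_label,
        timepoint_label=timepoint_label,
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        sd=sd,
        skewness=skew,
        histogram_edges=np.asarray(bin_edges, float),
        histogram_density=density,
        voxel_count=int(values.size),
    )


@dataclass
class DeltaReport:
    """Longitudinal deltas versus baseline plus per-ROI wCV.

    ``deltas``: one row per ROI x post-baseline timepoint with
    ``delta_ms``/``delta_pct`` of the mean (and of the median when
    available); ``wcv``: one row per ROI with the within-subject CV over
    all timepoints including baseline (sample SD). Missing timepoints are
    reported absent (NaN row), never raised.
    """

    baseline_label: str
    deltas: pd.DataFrame
    wcv: pd.DataFrame


def _stats_frame(stats: Sequence[RoiTimepointStats] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(stats, pd.DataFrame):
        df = stats.copy()
    else:
        df = pd.DataFrame(
            [{"roi": s.roi_label, "timepoint": s.timepoint_label,
              "mean": s.mean, "median": s.median} for s in stats]
        )
    required = {"roi", "timepoint", "mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stats table lacks columns {sorted(missing)}")
    if "median" not in df.columns:
        df["median"] = np.nan
    return df


def delta_analysis(stats: Sequence[RoiTimepointStats] | pd.DataFrame,
                   baseline_label: str = "PreTx",
                   timepoint_order: Sequence[str] | None = None) -> DeltaReport:
    """Delta analysis of per-ROI means relative to the baseline timepoint.

    For each ROI and post-baseline timepoint: ``delta_ms`` = mean minus
    baseline mean and ``delta_pct`` = delta_ms / baseline mean * 100.
    The wCV spans all timepoints at which the ROI was measured,
    baseline included.
    """
    df = _stats_frame(stats)
    if baseline_label not in set(df["timepoint"]):
        raise ValueError(f"baseline timepoint {baseline_label!r} not present")
    if timepoint_order is None:
        seen = dict.fromkeys(df["timepoint"])
        timepoint_order = list(seen)
    followups = [t for t in timepoint_order if t != baseline_label]

    delta_rows, wcv_rows = [], []
    for roi, rdf in df.groupby("roi", sort=False):
        by_tp = {r["timepoint"]: r for _, r in rdf.iterrows()}
        base = by_tp.get(baseline_label)
        for tp in followups:
            row = {"roi": roi, "timepoint": tp, "baseline_mean": np.nan,
                   "delta_ms": np.nan, "delta_pct": np.nan,
                   "delta_median_ms": np.nan, "delta_median_pct": np.nan,
                   "absent": True}
            if base is not None and tp in by_tp:
                cur = by_tp[tp]
                b, m = float(base["mean"]), float(cur["mean"])
                row.update(baseline_mean=b, delta_ms=m - b,
                           delta_pct=(m - b) / b * 100.0, absent=False)
                bm, mm = float(base["median"]), float(cur["median"])
                if np.isfinite(bm) and np.isfinite(mm):
                    row.update(delta_median_ms=mm - bm,
                               delta_median_pct=(mm - bm) / bm * 100.0)
            delta_rows.append(row)
        means = [float(by_tp[tp]["mean"]) for tp in timepoint_order if tp in by_tp]
        wcv_rows.append({"roi": roi, "wcv_pct": cv_percent(means),
                         "n_timepoints": len(means)})
    return DeltaReport(
        baseline_label=baseline_label,
        deltas=pd.DataFrame(delta_rows),
        wcv=pd.DataFrame(wcv_rows),
    )


def rd_vs_initial_comparison(pre_gtv_stats: RoiTimepointStats,
                             rd_stats: Mapping[str, RoiTimepointStats]
                             ) -> pd.DataFrame:
    """Residual disease vs. initial disease: deltas of mean and median.

    All histograms must share bin edges (fixed study-wide edges) so the
    overlaid densities are comparable; empty timepoints are simply absent
    from ``rd_stats``. Deltas are RD minus PreTx-GTV, in ms and percent
    of the PreTx-GTV value.
    """
    rows = []
    for tp, s in rd_stats.items():
        if not np.array_equal(s.histogram_edges, pre_gtv_stats.histogram_edges):
            raise ValueError(
                f"histogram edges of RD at {tp!r} differ from the PreTx GTV; "
                "compute stats with shared bin_edges"
            )
        rows.append({
            "timepoint": tp,
            "delta_mean_ms": s.mean - pre_gtv_stats.mean,
            "delta_mean_pct": (s.mean - pre_gtv_stats.mean) / pre_gtv_stats.mean * 100.0,
            "delta_median_ms": s.median - pre_gtv_stats.median,
            "delta_median_pct": (s.median - pre_gtv_stats.median)
            / pre_gtv_stats.median * 100.0,
            "rd_voxel_count": s.voxel_count,
            "gtv_voxel_count": pre_gtv_stats.voxel_count,
        })
    return pd.DataFrame(rows)
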