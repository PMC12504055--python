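"""Synthetic study data with known ground truth.

Two generators emulate the inputs of the two study arms:

* a digital system phantom — two 14-vial arrays (one spanning the T1
  reference ladder, one the T2 ladder) in a filler medium, imaged over
  repeated sessions with independent acquisition noise, session-level
  multiplicative drift, and an optional systematic bias; and
* a longitudinal patient-like volume — a body with control tissue,
  lesions with programmable per-timepoint T1/T2 effect sizes and
  shrinking residual-disease extents, glands, and a near-zero-signal
  airway — generated pre-aligned across timepoints.

Everything downstream (segmentation, fitting, benchmarking, delta
analysis) can therefore be tested against exact truth without any
acquired data. All randomness is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

from .errors import InvalidEffectError, InvalidParameterError, LayoutError
from .sequence import SequenceTiming, TissueParams, simulate_contrast_vectors

__all__ = [
    "PhantomLayout",
    "BiasModel",
    "StudyDesign",
    "PhantomTruth",
    "PhantomAcquisition",
    "RoiEffect",
    "RoiSpec",
    "AirwaySpec",
    "SubjectDesign",
    "SubjectData",
    "apply_bias",
    "phantom_ground_truth",
    "generate_phantom_series",
    "generate_longitudinal_subject",
]

# Printed T1 reference ladder of the physical phantom (ms), vials 1-7,
# extended by a geometric sub-physiological tail down to 22 ms to fill the
# 14-vial array.
_T1_REFERENCES_PRINTED = (1741.3, 1269.8, 962.0, 684.7, 487.4, 346.4, 245.8)


def _geometric_tail(start: float, stop: float, n: int) -> tuple[float, ...]:
    ratio = (stop / start) ** (1.0 / n)
    return tuple(start * ratio ** (i + 1) for i in range(n))


DEFAULT_T1_REFERENCES = _T1_REFERENCES_PRINTED + tuple(
    round(v, 1) for v in _geometric_tail(245.8, 22.0, 7)
)
#: T2 ladder: geometric over the manufacturer range 493 down to 7 ms.
DEFAULT_T2_REFERENCES = tuple(
    round(v, 1) for v in (493.0 * (7.0 / 493.0) ** (i / 13.0) for i in range(14))
)


def _default_vial_centers(volume_shape, voxel_size, z_frac: float,
                          ring_radius: float) -> np.ndarray:
    """14 centers (mm) on a ring at a given z fraction of the volume."""
    fov = np.asarray(volume_shape) * np.asarray(voxel_size)
    cx, cy = fov[0] / 2.0, fov[1] / 2.0
    z = fov[2] * z_frac
    ang = 2.0 * np.pi * np.arange(14) / 14.0
    return np.column_stack(
        [cx + ring_radius * np.cos(ang), cy + ring_radius * np.sin(ang),
         np.full(14, z)]
    )


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry and reference values of the digital 2x14-vial phantom.

    ``t1_references`` / ``t2_references`` are strictly decreasing with
    vial index, as on the physical phantom plates. Each vial needs a full
    (t1, t2) pair to be simulated; the companion constant of each array is
    a smooth monotone function of the reference (``t1_vial_t2``,
    ``t2_vial_t1``), kept well inside the default fitting grids.
    """

    volume_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    vial_radius: float = 8.0
    t1_references: tuple[float, ...] = DEFAULT_T1_REFERENCES
    t2_references: tuple[float, ...] = DEFAULT_T2_REFERENCES
    t1_centers: np.ndarray | None = None
    t2_centers: np.ndarray | None = None
    vial_pd: float = 1.0
    background: TissueParams = field(
        default_factory=lambda: TissueParams(t1=2800.0, t2=500.0, pd=0.35)
    )
    #: 1-based T2 vial indices excluded from formal analysis by default
    #: (manufacturer guidance on the physical phantom).
    excluded_t2_vials: tuple[int, ...] = (1, 5)

    def __post_init__(self) -> None:
        for name in ("t1_references", "t2_references"):
            refs = np.asarray(getattr(self, name), float)
            if refs.size != 14:
                raise LayoutError(f"{name} must list 14 vials, got {refs.size}")
            if np.any(np.diff(refs) >= 0):
                raise LayoutError(f"{name} must be strictly decreasing")
        if self.t1_centers is None:
            object.__setattr__(
                self, "t1_centers",
                _default_vial_centers(self.volume_shape, self.voxel_size, 1 / 3,
                                      self._default_ring_radius()),
            )
        if self.t2_centers is None:
            object.__setattr__(
                self, "t2_centers",
                _default_vial_centers(self.volume_shape, self.voxel_size, 2 / 3,
                                      self._default_ring_radius()),
            )
        self._validate_geometry()

    def _default_ring_radius(self) -> float:
        fov_xy = min(
            self.volume_shape[0] * self.voxel_size[0],
            self.volume_shape[1] * self.voxel_size[1],
        )
        return 0.3 * fov_xy

    def _validate_geometry(self) -> None:
        fov = np.asarray(self.volume_shape) * np.asarray(self.voxel_size)
        centers = np.vstack([self.t1_centers, self.t2_centers])
        if centers.shape != (28, 3):
            raise LayoutError("each vial array needs 14 (x, y, z) centers in mm")
        low = centers - self.vial_radius
        high = centers + self.vial_radius
        if np.any(low < 0) or np.any(high > fov):
            bad = np.flatnonzero(np.any((low < 0) | (high > fov), axis=1))
            raise LayoutError(f"vials outside the volume: indices {bad.tolist()}")
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d < 2 * self.vial_radius):
            raise LayoutError("vials overlap; increase spacing or shrink radius")

    def vial_tissues(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t1, t2, pd) arrays for the 28 vials: T1 array first, then T2."""
        t1_refs = np.asarray(self.t1_references, float)
        t2_refs = np.asarray(self.t2_references, float)
        # companion constants are free design values of the digital phantom;
        # round ms values keep the vial tissues simple to reason about
        t1_vial_t2 = np.round(np.clip(0.45 * t1_refs, 8.0, 450.0))
        t2_vial_t1 = np.round(np.clip(3.1 * t2_refs, 120.0, 2500.0), -1)
        t1 = np.concatenate([t1_refs, t2_vial_t1])
        t2 = np.concatenate([t1_vial_t2, t2_refs])
        pd = np.full(28, self.vial_pd)
        return t1, t2, pd


@dataclass(frozen=True)
class BiasModel:
    """Multiplicative per-map systematic bias, as fractional offsets.

    ``t1=0.30`` scales every true T1 by 1.30 before simulation; the model
    is invertible and recorded in provenance.
    """

    t1: float = 0.0
    t2: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= -1.0 or self.t2 <= -1.0:
            raise InvalidParameterError("bias offsets must be > -100%")

    @property
    def is_identity(self) -> bool:
        return self.t1 == 0.0 and self.t2 == 0.0


def apply_bias(truth_maps: Mapping[str, np.ndarray], bias: BiasModel) -> dict:
    """Apply the multiplicative bias to a {'t1': ..., 't2': ...} mapping."""
    out = dict(truth_maps)
    out["t1"] = np.asarray(truth_maps["t1"], float) * (1.0 + bias.t1)
    out["t2"] = np.asarray(truth_maps["t2"], float) * (1.0 + bias.t2)
    return out


@dataclass(frozen=True)
class StudyDesign:
    """Repeat-scan design of the phantom arm.

    Defaults mirror the benchmarking protocol: 12 sessions of 5
    consecutive acquisitions, small acquisition noise (fraction of the
    vial PDw signal) and session-level multiplicative drift.
    """

    n_sessions: int = 12
    n_repeats_per_session: int = 5
    noise_sd: float = 0.005
    session_drift_sd: float = 0.002
    bias: BiasModel = field(default_factory=BiasModel)
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.n_repeats_per_session < 1:
            raise InvalidParameterError("session/repeat counts must be >= 1")
        if self.noise_sd < 0 or self.session_drift_sd < 0:
            raise InvalidParameterError("noise/drift SD must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise InvalidParameterError("noise_model must be gaussian or rician")


@dataclass
class PhantomTruth:
    """Ground truth of the digital phantom.

    ``labels`` is 0 for background, 1..14 for T1-array vials,
    15..28 for T2-array vials.
    """

    labels: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    pd_map: np.ndarray
    layout: PhantomLayout

    def vial_mask(self, array: str, index: int) -> np.ndarray:
        """Boolean mask of one vial; ``array`` is 't1' or 't2', index 1-based."""
        offset = 0 if array == "t1" else 14
        return self.labels == offset + index


@dataclass
class PhantomAcquisition:
    """One simulated 5-contrast acquisition of the phantom."""

    session_index: int
    acquisition_index: int
    contrasts: np.ndarray  # (nx, ny, nz, 5) float32
    drift_t1: float
    drift_t2: float


def _paint_labels(layout: PhantomLayout) -> np.ndarray:
    shape = layout.volume_shape
    vx = np.asarray(layout.voxel_size)
    coords = [(np.arange(shape[i]) + 0.5) * vx[i] for i in range(3)]
    labels = np.zeros(shape, dtype=np.int16)
    centers = np.vstack([layout.t1_centers, layout.t2_centers])
    for k, c in enumerate(centers, start=1):
        # bounding box to avoid full-volume distance fields per vial
        lo = np.maximum(((c - layout.vial_radius) / vx - 1).astype(int), 0)
        hi = np.minimum(((c + layout.vial_radius) / vx + 2).astype(int), shape)
        xs = coords[0][lo[0]:hi[0]][:, None, None]
        ys = coords[1][lo[1]:hi[1]][None, :, None]
        zs = coords[2][lo[2]:hi[2]][None, None, :]
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[d2 <= layout.vial_radius**2] = k
    return labels


def phantom_ground_truth(layout: PhantomLayout,
                         bias: BiasModel | None = None) -> PhantomTruth:
    """Voxelwise (optionally biased) truth maps and vial labels."""
    labels = _paint_labels(layout)
    t1v, t2v, pdv = layout.vial_tissues()
    bg = layout.background
    t1_by_label = np.concatenate([[bg.t1], t1v])
    t2_by_label = np.concatenate([[bg.t2], t2v])
    pd_by_label = np.concatenate([[bg.pd], pdv])
    if bias is not None:
        t1_by_label = t1_by_label * (1.0 + bias.t1)
        t2_by_label = t2_by_label * (1.0 + bias.t2)
    return PhantomTruth(
        labels=labels,
        t1_map=t1_by_label[labels],
        t2_map=t2_by_label[labels],
        pd_map=pd_by_label[labels],
        layout=layout,
    )


def _add_noise(signals: np.ndarray, sigma: float, model: str,
               rng: np.random.Generator) -> np.ndarray:
    if sigma == 0.0:
        return signals
    if model == "gaussian":
        return signals + rng.normal(0.0, sigma, size=signals.shape)
    # rician: magnitude of complex signal with iid gaussian components
    re = signals + rng.normal(0.0, sigma, size=signals.shape)
    im = rng.normal(0.0, sigma, size=signals.shape)
    return np.sqrt(re**2 + im**2)


def generate_phantom_series(layout: PhantomLayout, design: StudyDesign,
                            timing: SequenceTiming) -> Iterator[PhantomAcquisition]:
    """Yield the 5-contrast volumes of every acquisition in the design.

    Per acquisition, each voxel carries the steady-state contrast vector
    of its (biased, session-drifted) true tissue plus independent noise
    scaled to ``noise_sd`` times the mean vial PDw signal. Drift is a
    shared multiplicative factor per session (one for T1, one for T2)
    applied to the true relaxation times, identically for that session's
    repeats. Fully reproducible from ``design.seed``.
    """
    labels = _paint_labels(layout)
    t1v, t2v, pdv = layout.vial_tissues()
    bg = layout.background
    t1_all = np.concatenate([[bg.t1], t1v]) * (1.0 + design.bias.t1)
    t2_all = np.concatenate([[bg.t2], t2v]) * (1.0 + design.bias.t2)
    pd_all = np.concatenate([[bg.pd], pdv])

    # noise amplitude referenced to the unbiased, undrifted vial PDw level
    ref_signals = simulate_contrast_vectors(t1v, t2v, pdv, timing)
    sigma = design.noise_sd * float(np.mean(ref_signals[:, 0]))

    ss = np.random.SeedSequence(design.seed)
    drift_ss, *session_ss = ss.spawn(1 + design.n_sessions)
    drift_rng = np.random.default_rng(drift_ss)
    drift = drift_rng.normal(1.0, design.session_drift_sd,
                             size=(design.n_sessions, 2))
    for s in range(design.n_sessions):
        f1, f2 = drift[s]
        signals = simulate_contrast_vectors(t1_all * f1, t2_all * f2, pd_all,
                                            timing)
        noiseless = signals[labels]  # (nx, ny, nz, 5)
        repeat_ss = session_ss[s].spawn(design.n_repeats_per_session)
        for r in range(design.n_repeats_per_session):
            rng = np.random.default_rng(repeat_ss[r])
            vol = _add_noise(noiseless, sigma, design.noise_model, rng)
            yield PhantomAcquisition(
                session_index=s,
                acquisition_index=r,
                contrasts=vol.astype(np.float32),
                drift_t1=float(f1),
                drift_t2=float(f2),
            )


# --------------------------------------------------------------------------
# Longitudinal subject


@dataclass(frozen=True)
class RoiEffect:
    """Per-timepoint change of one ROI: percent effects and extent."""

    dt1_pct: float = 0.0
    dt2_pct: float = 0.0
    volume_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.dt1_pct <= -100.0 or self.dt2_pct <= -100.0:
            raise InvalidEffectError("effects of -100% or below are invalid")
        if not 0.0 < self.volume_fraction <= 1.0:
            raise InvalidEffectError("volume_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class RoiSpec:
    """An ellipsoidal ROI with baseline tissue and per-timepoint effects.

    ``effects`` maps timepoint labels to :class:`RoiEffect`; timepoints
    not listed keep the baseline tissue (zero effect, full extent).
    Control ROIs simply list no effects.
    """

    name: str
    center: tuple[float, float, float]  # mm
    radii: tuple[float, float, float]  # mm semi-axes
    baseline: TissueParams
    effects: Mapping[str, RoiEffect] = field(default_factory=dict)

    def effect_at(self, timepoint: str) -> RoiEffect:
        return self.effects.get(timepoint, RoiEffect())


@dataclass(frozen=True)
class AirwaySpec:
    """A low-signal tube along z emulating the airway."""

    center_xy: tuple[float, float]  # mm
    radius: float = 6.0  # mm
    pd: float = 0.005
    z_extent: tuple[float, float] | None = None  # mm, None = full body


def _default_rois(volume_shape, voxel_size) -> tuple[RoiSpec, ...]:
    fov = np.asarray(volume_shape) * np.asarray(voxel_size)
    cx, cy, cz = fov / 2.0
    return (
        # uninvolved control tissue (masseter/NAWM stand-in): no effects
        RoiSpec(
            name="control",
            center=(cx - 0.30 * fov[0], cy, cz),
            radii=(9.0, 9.0, 9.0),
            baseline=TissueParams(t1=950.0, t2=40.0, pd=0.9),
        ),
        # lesion showing moderate T1/T2 enhancement at follow-up
        RoiSpec(
            name="gtv_enhancing",
            center=(cx + 0.28 * fov[0], cy + 0.18 * fov[1], cz),
            radii=(11.0, 11.0, 11.0),
            baseline=TissueParams(t1=1130.0, t2=75.0, pd=1.0),
            effects={
                "MidTx": RoiEffect(6.0, 8.0, 0.6),
                "PostTx": RoiEffect(13.7, 17.8, 0.4),
            },
        ),
        # nodal-type lesion resolving with large T1/T2 decreases
        RoiSpec(
            name="gtv_resolving",
            center=(cx + 0.26 * fov[0], cy - 0.22 * fov[1], cz),
            radii=(12.0, 12.0, 12.0),
            baseline=TissueParams(t1=1370.0, t2=73.0, pd=1.0),
            effects={
                "MidTx": RoiEffect(-20.0, -16.0, 0.6),
                "PostTx": RoiEffect(-39.5, -32.7, 0.3),
            },
        ),
        # gland adjacent to disease, enhancing over treatment
        RoiSpec(
            name="gland",
            center=(cx, cy + 0.30 * fov[1], cz),
            radii=(10.0, 8.0, 8.0),
            baseline=TissueParams(t1=700.0, t2=60.0, pd=0.95),
            effects={
                "MidTx": RoiEffect(6.0, 7.0),
                "PostTx": RoiEffect(12.4, 13.4),
            },
        ),
    )


@dataclass(frozen=True)
class SubjectDesign:
    """Longitudinal patient-like study: timepoints, ROIs, airway, noise."""

    timepoint_labels: tuple[str, ...] = ("PreTx", "MidTx", "PostTx")
    volume_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    roi_specs: tuple[RoiSpec, ...] | None = None
    airway_spec: AirwaySpec | None = None
    body_tissue: TissueParams = field(
        default_factory=lambda: TissueParams(t1=1000.0, t2=55.0, pd=0.85)
    )
    noise_sd: float = 0.005
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoint_labels) < 2:
            raise InvalidParameterError("at least two timepoints required")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.roi_specs is None:
            object.__setattr__(
                self, "roi_specs",
                _default_rois(self.volume_shape, self.voxel_size),
            )
        if self.airway_spec is None:
            fov = np.asarray(self.volume_shape) * np.asarray(self.voxel_size)
            object.__setattr__(
                self, "airway_spec",
                AirwaySpec(center_xy=(fov[0] / 2.0, fov[1] / 2.0 - 0.12 * fov[1])),
            )
        for roi in self.roi_specs:
            for label in roi.effects:
                if label not in self.timepoint_labels:
                    raise InvalidParameterError(
                        f"ROI {roi.name!r} lists effect for unknown timepoint "
                        f"{label!r}"
                    )


@dataclass
class SubjectData:
    """Aligned longitudinal volumes plus truth and masks.

    ``roi_masks[name]`` is the full baseline ROI (identical at all
    timepoints, emulating rigidly propagated contours);
    ``rd_masks[timepoint][name]`` is the shrunken residual-disease extent
    at that timepoint for ROIs with ``volume_fraction < 1``.
    """

    timepoints: tuple[str, ...]
    contrasts: dict[str, np.ndarray]
    truth_t1: dict[str, np.ndarray]
    truth_t2: dict[str, np.ndarray]
    truth_pd: dict[str, np.ndarray]
    roi_masks: dict[str, np.ndarray]
    rd_masks: dict[str, dict[str, np.ndarray]]
    airway_mask: np.ndarray
    body_mask: np.ndarray
    voxel_size: tuple[float, float, float]
    design: SubjectDesign


def _ellipsoid_mask(shape, voxel_size, center, radii) -> np.ndarray:
    vx = np.asarray(voxel_size)
    coords = [(np.arange(shape[i]) + 0.5) * vx[i] for i in range(3)]
    xs = coords[0][:, None, None]
    ys = coords[1][None, :, None]
    zs = coords[2][None, None, :]
    c, r = np.asarray(center, float), np.asarray(radii, float)
    return ((xs - c[0]) / r[0]) ** 2 + ((ys - c[1]) / r[1]) ** 2 + (
        (zs - c[2]) / r[2]
    ) ** 2 <= 1.0


def _shrink_mask(mask: np.ndarray, center, voxel_size, fraction: float) -> np.ndarray:
    """Keep the round(fraction * n) voxels closest to the ROI center."""
    if fraction >= 1.0:
        return mask.copy()
    idx = np.argwhere(mask)
    mm = (idx + 0.5) * np.asarray(voxel_size)
    d2 = np.sum((mm - np.asarray(center, float)) ** 2, axis=1)
    keep = int(round(fraction * idx.shape[0]))
    order = np.argsort(d2, kind="stable")[:keep]
    out = np.zeros_like(mask)
    out[tuple(idx[order].T)] = True
    return out


def generate_longitudinal_subject(design: SubjectDesign,
                                  timing: SequenceTiming) -> SubjectData:
    """Simulate aligned 5-contrast volumes at every timepoint.

    At each timepoint, tissue inside an ROI's current (possibly shrunken)
    extent is the baseline scaled by that timepoint's percent effects;
    former lesion voxels outside the shrunken extent revert to body
    tissue (resolved disease). Airway voxels keep near-zero proton
    density throughout.
    """
    shape = design.volume_shape
    vx = design.voxel_size
    fov = np.asarray(shape) * np.asarray(vx)

    body = _ellipsoid_mask(shape, vx, fov / 2.0,
                           (0.46 * fov[0], 0.46 * fov[1], 0.48 * fov[2]))
    aw = design.airway_spec
    coords = [(np.arange(shape[i]) + 0.5) * vx[i] for i in range(3)]
    d2_xy = (coords[0][:, None] - aw.center_xy[0]) ** 2 + (
        coords[1][None, :] - aw.center_xy[1]
    ) ** 2
    airway = np.zeros(shape, dtype=bool)
    airway[d2_xy <= aw.radius**2, :] = True
    if aw.z_extent is not None:
        zmask = (coords[2] >= aw.z_extent[0]) & (coords[2] <= aw.z_extent[1])
        airway &= zmask[None, None, :]
    airway &= body

    roi_masks = {
        roi.name: _ellipsoid_mask(shape, vx, roi.center, roi.radii) & body
        for roi in design.roi_specs
    }
    for roi in design.roi_specs:
        if roi_masks[roi.name].sum() == 0:
            raise LayoutError(f"ROI {roi.name!r} lies outside the body")
        if (roi_masks[roi.name] & airway).any():
            raise LayoutError(f"ROI {roi.name!r} intersects the airway")

    ss = np.random.SeedSequence(design.seed)
    tp_ss = ss.spawn(len(design.timepoint_labels))

    bt = design.body_tissue
    contrasts, truth_t1, truth_t2, truth_pd = {}, {}, {}, {}
    rd_masks: dict[str, dict[str, np.ndarray]] = {}
    # noise amplitude referenced to the body PDw signal
    body_sig = simulate_contrast_vectors(
        np.array(bt.t1), np.array(bt.t2), np.array(bt.pd), timing
    )
    sigma = design.noise_sd * float(body_sig[0])

    for k, label in enumerate(design.timepoint_labels):
        t1_map = np.zeros(shape)
        t2_map = np.zeros(shape)
        pd_map = np.zeros(shape)
        t1_map[body] = bt.t1
        t2_map[body] = bt.t2
        pd_map[body] = bt.pd
        rd_masks[label] = {}
        for roi in design.roi_specs:
            eff = roi.effect_at(label)
            extent = _shrink_mask(roi_masks[roi.name], roi.center, vx,
                                  eff.volume_fraction)
            if eff.volume_fraction < 1.0:
                rd_masks[label][roi.name] = extent
            t1_map[extent] = roi.baseline.t1 * (1.0 + eff.dt1_pct / 100.0)
            t2_map[extent] = roi.baseline.t2 * (1.0 + eff.dt2_pct / 100.0)
            pd_map[extent] = roi.baseline.pd
        pd_map[airway] = aw.pd
        # simulate only over distinct tissues present in the volume
        stack = np.stack([t1_map, t2_map, pd_map], axis=-1)
        flat = stack.reshape(-1, 3)
        uniq, inv = np.unique(flat, axis=0, return_inverse=True)
        sig = np.zeros((uniq.shape[0], 5))
        inside = uniq[:, 0] > 0
        sig[inside] = simulate_contrast_vectors(
            uniq[inside, 0], uniq[inside, 1], uniq[inside, 2], timing
        )
        vol = sig[inv].reshape(shape + (5,))
        rng = np.random.default_rng(tp_ss[k])
        vol = _add_noise(vol, sigma, design.noise_model, rng)
        contrasts[label] = vol.astype(np.float32)
        truth_t1[label] = t1_map.astype(np.float32)
        truth_t2[label] = t2_map.astype(np.float32)
        truth_pd[label] = pd_map.astype(np.float32)

    return SubjectData(
        timepoints=tuple(design.timepoint_labels),
        contrasts=contrasts,
        truth_t1=truth_t1,
        truth_t2=truth_t2,
        truth_pd=truth_pd,
        roi_masks=roi_masks,
        rd_masks=rd_masks,
        airway_mask=airway,
        body_mask=body,
        voxel_size=tuple(float(v) for v in vx),
        design=design,
    )
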