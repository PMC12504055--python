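"""YAML study configuration: timing, grids, phantom and subject designs.

A config file holds optional sections; anything omitted falls back to
the documented defaults so that ``{}`` is a valid configuration. The
resolved (fully expanded) configuration is written beside every CLI
output for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .sequence import SequenceTiming, TissueParams
from .synthetic import (
    AirwaySpec,
    BiasModel,
    PhantomLayout,
    RoiEffect,
    RoiSpec,
    StudyDesign,
    SubjectDesign,
)

_SECTIONS = {"timing", "grids", "phantom", "subject", "report", "seed"}


@dataclass
class StudyConfig:
    """Validated study configuration with builder methods."""

    timing: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    subject: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict | None) -> "StudyConfig":
        raw = raw or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config root must be a mapping")
        unknown = set(raw) - _SECTIONS
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        for section in _SECTIONS - {"seed"}:
            if section in raw and not isinstance(raw[section], dict):
                raise ConfigurationError(f"config section {section!r} must be a mapping")
        return cls(
            timing=dict(raw.get("timing", {})),
            grids=dict(raw.get("grids", {})),
            phantom=dict(raw.get("phantom", {})),
            subject=dict(raw.get("subject", {})),
            report=dict(raw.get("report", {})),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
        try:
            return cls.from_dict(raw)
        except ConfigurationError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc

    # ---- builders -------------------------------------------------------
    def make_timing(self) -> SequenceTiming:
        kwargs = dict(self.timing)
        if "acquisition_delays" in kwargs:
            kwargs["acquisition_delays"] = tuple(kwargs["acquisition_delays"])
        try:
            return SequenceTiming(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"timing: {exc}") from exc

    def _grid(self, name: str, default_start, default_stop, default_step):
        g = self.grids.get(name, {})
        start = float(g.get("start", default_start))
        stop = float(g.get("stop", default_stop))
        step = float(g.get("step", default_step))
        if not (start > 0 and stop > start and step > 0):
            raise ConfigurationError(f"grids.{name}: need 0 < start < stop, step > 0")
        return np.arange(start, stop + 1e-9, step)

    def make_t1_grid(self) -> np.ndarray:
        return self._grid("t1", 100.0, 3000.0, 10.0)

    def make_t2_grid(self) -> np.ndarray:
        return self._grid("t2", 5.0, 600.0, 2.0)

    def make_layout(self) -> PhantomLayout:
        kwargs = dict(self.phantom.get("layout", {}))
        for key in ("volume_shape", "voxel_size", "t1_references",
                    "t2_references", "excluded_t2_vials"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "background" in kwargs:
            kwargs["background"] = TissueParams(**kwargs["background"])
        try:
            return PhantomLayout(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"phantom.layout: {exc}") from exc

    def make_phantom_design(self, seed: int | None = None) -> StudyDesign:
        kwargs = dict(self.phantom.get("design", {}))
        if "bias" in kwargs:
            kwargs["bias"] = BiasModel(**kwargs["bias"])
        kwargs["seed"] = int(self.seed if seed is None else seed)
        try:
            return StudyDesign(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"phantom.design: {exc}") from exc

    def make_subject_design(self, seed: int | None = None) -> SubjectDesign:
        kwargs = dict(self.subject)
        for key in ("timepoint_labels", "volume_shape", "voxel_size"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "roi_specs" in kwargs:
            specs = []
            for spec in kwargs["roi_specs"]:
                spec = dict(spec)
                spec["center"] = tuple(spec["center"])
                spec["radii"] = tuple(spec["radii"])
                spec["baseline"] = TissueParams(**spec["baseline"])
                spec["effects"] = {
                    tp: RoiEffect(**eff) for tp, eff in spec.get("effects", {}).items()
                }
                specs.append(RoiSpec(**spec))
            kwargs["roi_specs"] = tuple(specs)
        if "airway_spec" in kwargs:
            aw = dict(kwargs["airway_spec"])
            aw["center_xy"] = tuple(aw["center_xy"])
            kwargs["airway_spec"] = AirwaySpec(**aw)
        if "body_tissue" in kwargs:
            kwargs["body_tissue"] = TissueParams(**kwargs["body_tissue"])
        kwargs["seed"] = int(self.seed if seed is None else seed)
        try:
            return SubjectDesign(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"subject: {exc}") from exc

    # ---- provenance -----------------------------------------------------
    def resolved(self) -> dict:
        """Fully expanded configuration (defaults made explicit)."""
        timing = self.make_timing()
        layout = self.make_layout()
        design = self.make_phantom_design()
        t1g, t2g = self.make_t1_grid(), self.make_t2_grid()
        return {
            "seed": self.seed,
            "timing": {
                **{k: getattr(timing, k) for k in (
                    "pd_flip_angle", "readout_flip_angle", "readout_tr",
                    "views_per_segment", "te_t2prep", "t1prep_efficiency",
                    "t2prep_delay", "cycle_duration", "steady_state_tol",
                    "flip_scale")},
                "acquisition_delays": list(timing.acquisition_delays),
            },
            "grids": {
                "t1": {"start": float(t1g[0]), "stop": float(t1g[-1]),
                       "step": float(t1g[1] - t1g[0]) if t1g.size > 1 else 0.0},
                "t2": {"start": float(t2g[0]), "stop": float(t2g[-1]),
                       "step": float(t2g[1] - t2g[0]) if t2g.size > 1 else 0.0},
            },
            "phantom": {
                "layout": {
                    "volume_shape": list(layout.volume_shape),
                    "voxel_size": list(layout.voxel_size),
                    "vial_radius": layout.vial_radius,
                    "t1_references": list(layout.t1_references),
                    "t2_references": list(layout.t2_references),
                    "excluded_t2_vials": list(layout.excluded_t2_vials),
                },
                "design": {
                    "n_sessions": design.n_sessions,
                    "n_repeats_per_session": design.n_repeats_per_session,
                    "noise_sd": design.noise_sd,
                    "session_drift_sd": design.session_drift_sd,
                    "bias": {"t1": design.bias.t1, "t2": design.bias.t2},
                    "noise_model": design.noise_model,
                },
            },
            "subject": dict(self.subject),
            "report": {"decimals": int(self.report.get("decimals", 1)),
                       "regression_mode": self.report.get("regression_mode", "grand")},
        }

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.resolved(), sort_keys=True,
                              default_flow_style=None)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write_resolved(self, out_dir) -> Path:
        path = Path(out_dir) / "resolved_config.yaml"
        path.write_text(yaml.safe_dump(self.resolved(), sort_keys=True,
                                       default_flow_style=None))
        return path
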