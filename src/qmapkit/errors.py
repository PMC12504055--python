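"""Exception hierarchy for the relaxometry pipeline."""


class QmapkitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(QmapkitError, ValueError):
    """A tissue or sequence parameter is outside its physical domain."""


class NonConvergentCycleError(QmapkitError, ValueError):
    """The per-cycle magnetization map has |a| >= 1; no periodic steady state.

    This signals a misconfigured preparation cycle (e.g. zero relaxation
    time between repetitions), not a numerical failure.
    """


class DimensionError(QmapkitError, ValueError):
    """Input volumes disagree in shape; the message names the offender."""


class LayoutError(QmapkitError, ValueError):
    """Phantom vials overlap or fall outside the simulated volume."""


class InvalidEffectError(QmapkitError, ValueError):
    """A longitudinal effect size of -100% or below would zero/negate tissue."""


class SegmentationError(QmapkitError, RuntimeError):
    """Vial segmentation matched fewer components than the template expects."""


class SeedPlacementError(QmapkitError, ValueError):
    """A flood-fill seed was placed in a foreground (tissue) voxel."""


class EmptyRoiError(QmapkitError, ValueError):
    """An ROI is empty after intersecting inclusion/exclusion masks."""


class DegenerateInputError(QmapkitError, ValueError):
    """An operation received a constant or empty volume it cannot threshold."""


class ConfigurationError(QmapkitError, ValueError):
    """A study configuration is incomplete or inconsistent."""
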