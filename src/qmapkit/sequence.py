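"""Signal model of the 5-contrast multiparametric acquisition.

The sequence acquires one steady-state proton-density-weighted (PDw) image
with a very low flip angle, then a magnetization-prepared transient train:
one segment after a T2 preparation and three segments at increasing delays
after a T1 (inversion) preparation, all read out with a spoiled
gradient-echo (SPGR) readout at a small flip angle. Per preparation cycle
the longitudinal magnetization evolves through a chain of affine maps
``mz -> a*mz + b`` (relaxation intervals, preparation pulses, readout
segments), so the periodic steady state has the closed form
``mz* = b/(1 - a)`` for the composed cycle map.

All magnetization is tracked as a fraction of equilibrium (pd = 1); the
proton density multiplies the emitted signals only. Transverse relaxation
during the readout itself and B1 inhomogeneity are not modeled; a
flip-angle scale hook (``flip_scale``) is exposed for sensitivity studies.

Units: times in ms, angles in degrees, signals in arbitrary units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, NonConvergentCycleError

__all__ = [
    "SequenceTiming",
    "TissueParams",
    "Dictionary",
    "spgr_segment_signal",
    "spgr_steady_state_signal",
    "simulate_contrast_vector",
    "simulate_contrast_vectors",
    "cycle_steady_state",
    "build_dictionary",
    "CONTRAST_NAMES",
]

#: Order of the five contrasts in every SignalVector.
CONTRAST_NAMES = ("PDw", "T2w", "T1w_1", "T1w_2", "T1w_3")


@dataclass(frozen=True)
class SequenceTiming:
    """Acquisition schedule and flip angles of the 5-contrast sequence.

    Defaults are chosen so that the five contrasts are well conditioned
    over physiological T1/T2 ranges; every field is config-overridable
    and recorded in reports.

    Parameters
    ----------
    pd_flip_angle : float
        Flip angle of the steady-state PDw readout, degrees (~1).
    readout_flip_angle : float
        Flip angle of the prepared readout segments, degrees (3).
    readout_tr : float
        Repetition time between excitations within a segment, ms.
    views_per_segment : int
        Number of excitations per readout segment.
    te_t2prep : float
        Effective echo time of the T2 preparation, ms. The magnetization
        is transverse for this duration and is attenuated by
        ``exp(-te_t2prep / t2)``.
    t1prep_efficiency : float
        Longitudinal inversion efficiency in [0, 1]: the preparation maps
        ``mz -> (1 - 2*efficiency) * mz`` (1 = ideal adiabatic inversion,
        0.5 = saturation, 0 = preparation disabled).
    acquisition_delays : tuple of 3 floats
        Start times of the three T1-recovery segments, ms, measured from
        the end of the T1 preparation; strictly increasing and spaced by
        at least one segment duration.
    t2prep_delay : float
        Offset of the T2 preparation from the cycle start, ms.
    cycle_duration : float
        Full repetition period of the preparation cycle, ms.
    steady_state_tol : float
        Relative tolerance used when verifying the closed-form periodic
        steady state against fixed-point iteration.
    flip_scale : float
        Multiplicative scale applied to both flip angles (B1-like hook);
        default 1 (no scaling).
    """

    pd_flip_angle: float = 1.0
    readout_flip_angle: float = 3.0
    readout_tr: float = 3.0
    views_per_segment: int = 128
    te_t2prep: float = 100.0
    t1prep_efficiency: float = 1.0
    acquisition_delays: tuple[float, float, float] = (100.0, 1000.0, 1900.0)
    t2prep_delay: float = 0.0
    cycle_duration: float = 4000.0
    steady_state_tol: float = 1e-9
    flip_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pd_flip_angle * self.flip_scale < 90.0):
            raise InvalidParameterError(
                f"pd_flip_angle (scaled) must lie in (0, 90) deg, got "
                f"{self.pd_flip_angle * self.flip_scale}"
            )
        if not (0.0 < self.readout_flip_angle * self.flip_scale < 90.0):
            raise InvalidParameterError(
                f"readout_flip_angle (scaled) must lie in (0, 90) deg, got "
                f"{self.readout_flip_angle * self.flip_scale}"
            )
        for name in ("readout_tr", "te_t2prep", "t2prep_delay", "cycle_duration"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.views_per_segment < 1:
            raise InvalidParameterError("views_per_segment must be >= 1")
        if not 0.0 <= self.t1prep_efficiency <= 1.0:
            raise InvalidParameterError("t1prep_efficiency must lie in [0, 1]")
        delays = tuple(float(d) for d in self.acquisition_delays)
        if len(delays) != 3:
            raise InvalidParameterError("exactly three acquisition_delays required")
        if min(delays) < 0:
            raise InvalidParameterError("acquisition_delays must be >= 0")
        if not (delays[0] < delays[1] < delays[2]):
            raise InvalidParameterError("acquisition_delays must be strictly increasing")
        seg = self.segment_duration
        if delays[1] - delays[0] < seg or delays[2] - delays[1] < seg:
            raise InvalidParameterError(
                "acquisition_delays must be spaced by at least one segment "
                f"duration ({seg} ms)"
            )
        if self.cycle_duration < self._busy_duration:
            raise InvalidParameterError(
                "cycle_duration too short for the scheduled preparations and "
                f"readouts (needs >= {self._busy_duration} ms)"
            )
        object.__setattr__(self, "acquisition_delays", delays)

    @property
    def segment_duration(self) -> float:
        """Duration of one readout segment, ms."""
        return self.views_per_segment * self.readout_tr

    @property
    def _busy_duration(self) -> float:
        # T2prep offset + T2prep + T2w segment + last T1w delay + its segment
        return (
            self.t2prep_delay
            + self.te_t2prep
            + self.segment_duration
            + self.acquisition_delays[2]
            + self.segment_duration
        )


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one tissue: t1, t2 in ms, pd >= 0 (a.u.).

    t2 > t1 is permitted: phantom vials decouple the two constants.
    """

    t1: float
    t2: float
    pd: float = 1.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise InvalidParameterError(
                f"t1 and t2 must be > 0 ms (got t1={self.t1}, t2={self.t2})"
            )
        if self.pd < 0:
            raise InvalidParameterError(f"pd must be >= 0 (got {self.pd})")


def _segment_affine(t1, fa_rad: float, tr: float, views: int):
    """Affine coefficients of one readout segment.

    Per excitation the longitudinal magnetization is scaled by cos(fa)
    (instantaneous pulse, transverse part spoiled) and then recovers
    toward equilibrium over one TR: ``mz -> c*e*mz + (1 - e)``.

    Returns ``(a, b, ac, bc)``: the full-segment map and the map from the
    segment start to the instant before the central excitation
    (pulse index ``views // 2``).
    """
    t1 = np.asarray(t1, dtype=float)
    c = np.cos(fa_rad)
    e = np.exp(-tr / t1)
    k = c * e

    def _compose(n: int):
        kn = k**n
        with np.errstate(divide="ignore", invalid="ignore"):
            geo = np.where(np.abs(1.0 - k) > 1e-15, (1.0 - kn) / (1.0 - k), float(n))
        return kn, (1.0 - e) * geo

    a, b = _compose(views)
    ac, bc = _compose(views // 2)
    return a, b, ac, bc


def _relax_affine(t1, dt: float):
    """Free T1 recovery toward equilibrium (mz_eq = 1) over dt ms."""
    e = np.exp(-dt / np.asarray(t1, dtype=float))
    return e, 1.0 - e


def spgr_segment_signal(mz_in: float, tissue: TissueParams, timing: SequenceTiming):
    """Signal of one SPGR readout segment and the exiting magnetization.

    The signal is ``pd * sin(flip) * mz`` evaluated at the segment center;
    ``mz_out`` is the longitudinal state after all ``views_per_segment``
    spoiled excitations with inter-excitation T1 recovery.
    """
    if not -1.0 <= mz_in <= 1.0:
        raise InvalidParameterError(f"mz_in must lie in [-1, 1], got {mz_in}")
    fa = np.deg2rad(timing.readout_flip_angle * timing.flip_scale)
    a, b, ac, bc = _segment_affine(
        tissue.t1, fa, timing.readout_tr, timing.views_per_segment
    )
    signal = tissue.pd * np.sin(fa) * (ac * mz_in + bc)
    mz_out = a * mz_in + b
    return float(signal), float(mz_out)


def spgr_steady_state_signal(tissue: TissueParams, timing: SequenceTiming) -> float:
    """Steady-state SPGR signal of the low-flip PDw readout."""
    fa = np.deg2rad(timing.pd_flip_angle * timing.flip_scale)
    c = np.cos(fa)
    e = np.exp(-timing.readout_tr / tissue.t1)
    mz_ss = (1.0 - e) / (1.0 - c * e)
    return float(tissue.pd * np.sin(fa) * mz_ss)


def _cycle_ops(t1, t2, timing: SequenceTiming):
    """Ordered affine ops of one preparation cycle.

    Each element is ``(a, b, record)`` where ``record`` is None or the
    ``(ac, bc)`` center map of a recorded readout segment. Order of
    recorded segments: T2w, T1w_1, T1w_2, T1w_3.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    fa = np.deg2rad(timing.readout_flip_angle * timing.flip_scale)
    seg = timing.segment_duration
    a_seg, b_seg, ac, bc = _segment_affine(
        t1, fa, timing.readout_tr, timing.views_per_segment
    )
    zeros = np.zeros_like(t1)
    ops = []
    # dead time before the T2 preparation
    ops.append((*_relax_affine(t1, timing.t2prep_delay), None))
    # T2 preparation: transverse for te_t2prep, attenuated by exp(-te/t2)
    ops.append((np.exp(-timing.te_t2prep / t2), zeros, None))
    # T2-weighted readout segment
    ops.append((a_seg, b_seg, (ac, bc)))
    # T1 preparation (partial inversion)
    eff = timing.t1prep_efficiency
    ops.append((np.full_like(t1, 1.0 - 2.0 * eff), zeros, None))
    # three T1-recovery readout segments
    tau = 0.0
    for delay in timing.acquisition_delays:
        ops.append((*_relax_affine(t1, delay - tau), None))
        ops.append((a_seg, b_seg, (ac, bc)))
        tau = delay + seg
    # recovery to the end of the cycle
    remaining = timing.cycle_duration - timing._busy_duration
    ops.append((*_relax_affine(t1, remaining), None))
    return ops, fa


def cycle_steady_state(t1, t2, timing: SequenceTiming, method: str = "closed",
                       n_cycles: int = 50):
    """Longitudinal magnetization at the cycle start in periodic steady state.

    ``method='closed'`` composes the affine cycle map and returns
    ``b / (1 - a)``; ``method='iterate'`` fixed-point iterates ``n_cycles``
    preparation cycles from equilibrium (used to verify the closed form).
    """
    ops, _ = _cycle_ops(t1, t2, timing)
    if method == "closed":
        a_tot = np.ones_like(np.asarray(t1, dtype=float))
        b_tot = np.zeros_like(a_tot)
        for a, b, _rec in ops:
            a_tot = a * a_tot
            b_tot = a * b_tot + b
        if np.any(np.abs(a_tot) >= 1.0):
            raise NonConvergentCycleError(
                "cycle map has |a| >= 1 for at least one tissue; check the "
                "timing configuration (no net relaxation per cycle)"
            )
        return b_tot / (1.0 - a_tot)
    if method == "iterate":
        mz = np.ones_like(np.asarray(t1, dtype=float))
        for _ in range(n_cycles):
            for a, b, _rec in ops:
                mz = a * mz + b
        return mz
    raise ValueError(f"unknown method {method!r}")


def simulate_contrast_vectors(t1, t2, pd, timing: SequenceTiming) -> np.ndarray:
    """Vectorized 5-contrast signals for arrays of tissue parameters.

    Returns an array of shape ``(..., 5)`` ordered as
    ``(PDw, T2w, T1w_1, T1w_2, T1w_3)``, evaluated at the periodic
    steady state of the preparation cycle.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    pd = np.asarray(pd, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise InvalidParameterError("t1 and t2 must be > 0 ms")
    ops, fa = _cycle_ops(t1, t2, timing)
    mz = cycle_steady_state(t1, t2, timing, method="closed")
    sin_fa = np.sin(fa)
    signals = []
    for a, b, rec in ops:
        if rec is not None:
            ac, bc = rec
            signals.append(sin_fa * (ac * mz + bc))
        mz = a * mz + b
    # steady-state PDw readout
    fa_pd = np.deg2rad(timing.pd_flip_angle * timing.flip_scale)
    e = np.exp(-timing.readout_tr / t1)
    pdw = np.sin(fa_pd) * (1.0 - e) / (1.0 - np.cos(fa_pd) * e)
    out = np.stack([pdw] + signals, axis=-1)
    return pd[..., None] * out


def simulate_contrast_vector(tissue: TissueParams, timing: SequenceTiming) -> np.ndarray:
    """5-contrast signal vector of a single tissue (see CONTRAST_NAMES)."""
    return simulate_contrast_vectors(
        np.asarray(tissue.t1), np.asarray(tissue.t2), np.asarray(tissue.pd), timing
    )


@dataclass
class Dictionary:
    """Unit-normalized simulated signal atoms over a (T1, T2) grid.

    Atoms are ordered T1-major then T2, both ascending; ``norms`` holds
    the pre-normalization l2 norms (pd = 1 atoms).
    """

    atoms: np.ndarray
    norms: np.ndarray
    t1_lookup: np.ndarray
    t2_lookup: np.ndarray
    t1_grid: np.ndarray
    t2_grid: np.ndarray
    timing: SequenceTiming = field(repr=False, default_factory=SequenceTiming)

    def __post_init__(self) -> None:
        n = self.atoms.shape[0]
        if not (len(self.t1_lookup) == len(self.t2_lookup) == len(self.norms) == n):
            raise InvalidParameterError("dictionary lookup arrays disagree in length")
        unit = np.abs(np.linalg.norm(self.atoms, axis=1) - 1.0)
        if np.any(unit > 1e-9):
            raise InvalidParameterError("dictionary atoms must be unit-norm (1e-9)")

    def __len__(self) -> int:
        return self.atoms.shape[0]


def build_dictionary(t1_grid, t2_grid, timing: SequenceTiming) -> Dictionary:
    """Simulate one unit-norm atom per (t1, t2) grid pair (pd = 1).

    Grids must be strictly increasing and non-empty. Emits a warning if
    distinct grid points yield numerically identical normalized atoms
    (degenerate dictionary regions).
    """
    t1_grid = np.asarray(t1_grid, dtype=float)
    t2_grid = np.asarray(t2_grid, dtype=float)
    for name, g in (("t1_grid", t1_grid), ("t2_grid", t2_grid)):
        if g.size == 0:
            raise InvalidParameterError(f"{name} must be non-empty")
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise InvalidParameterError(f"{name} must be strictly increasing")
    t1s = np.repeat(t1_grid, t2_grid.size)
    t2s = np.tile(t2_grid, t1_grid.size)
    raw = simulate_contrast_vectors(t1s, t2s, np.ones_like(t1s), timing)
    norms = np.linalg.norm(raw, axis=1)
    if np.any(norms == 0):
        raise InvalidParameterError("zero-signal atom encountered; check timing")
    atoms = raw / norms[:, None]
    n_unique = np.unique(np.round(atoms, 9), axis=0).shape[0]
    if n_unique < atoms.shape[0]:
        warnings.warn(
            f"{atoms.shape[0] - n_unique} duplicate normalized atoms at 1e-9 "
            "resolution; T1/T2 are not separable in those grid regions",
            RuntimeWarning,
            stacklevel=2,
        )
    return Dictionary(
        atoms=atoms,
        norms=norms,
        t1_lookup=t1s,
        t2_lookup=t2s,
        t1_grid=t1_grid,
        t2_grid=t2_grid,
        timing=timing,
    )
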