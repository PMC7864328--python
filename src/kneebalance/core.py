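"""Intraoperative knee state and the quantitative balance / alignment classifiers.

The sensor-assisted balancing workflow measures six quantities at trialing:
medial and lateral tibiofemoral compartment loads (lbf) at 10 and 90 degrees
of flexion, the coronal mechanical alignment of the limb (degrees, negative =
varus, positive = valgus) and the sagittal extension deficit (degrees,
positive = flexion contracture, negative = hyperextension).

A knee is *balanced* when the mediolateral load differential is below 15 lbf
at both flexion angles and every compartment load lies in the 10-40 lbf
window.  Coronal alignment is acceptable within a +/-3 degree window of the
neutral mechanical axis (valgus beyond the window is never accepted; up to
three degrees of varus is tolerated).  The sagittal target is full terminal
extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum

__all__ = [
    "KneeState",
    "Thresholds",
    "BalanceAssessment",
    "LoadStatus",
    "Side",
    "CoronalCategory",
    "SagittalCategory",
    "classify_load",
    "classify_coronal",
    "classify_sagittal",
    "assess_balance",
]

#: Alignment within this many degrees of zero is reported as neutral.
NEUTRAL_TOL = 0.5
#: A contracture this small (degrees) still counts as full terminal extension.
FULL_EXTENSION_TOL = 0.5

# Sanity bounds on navigation readings; values beyond these indicate a data
# error rather than a plausible intraoperative measurement.
MAX_ABS_CORONAL = 30.0
MAX_ABS_EXT_DEFICIT = 40.0


class LoadStatus(str, Enum):
    LOOSE = "loose"
    ACCEPTABLE = "acceptable"
    TIGHT = "tight"


class Side(str, Enum):
    NONE = "none"
    MEDIAL = "medial"
    LATERAL = "lateral"


class CoronalCategory(str, Enum):
    VARUS_OUT = "varus_out"
    VARUS_IN_WINDOW = "varus_in_window"
    NEUTRAL = "neutral"
    VALGUS_IN_WINDOW = "valgus_in_window"
    VALGUS_OUT = "valgus_out"


class SagittalCategory(str, Enum):
    FULL_EXTENSION = "full_extension"
    SMALL_CONTRACTURE = "small_contracture"
    LARGE_CONTRACTURE = "large_contracture"
    HYPEREXTENSION = "hyperextension"


CHANNELS = ("m10", "l10", "m90", "l90", "coronal", "ext_deficit")
LOAD_CHANNELS = ("m10", "l10", "m90", "l90")


@dataclass(frozen=True)
class KneeState:
    """One six-channel intraoperative measurement.

    Parameters
    ----------
    m10, l10 : float
        Medial / lateral compartment load (lbf) at 10 degrees of flexion.
    m90, l90 : float
        Medial / lateral compartment load (lbf) at 90 degrees of flexion.
    coronal : float
        Coronal mechanical alignment (degrees); negative = varus,
        positive = valgus.
    ext_deficit : float
        Sagittal extension deficit (degrees); positive = flexion contracture
        (a decrease in terminal extension), negative = hyperextension.
    """

    m10: float
    l10: float
    m90: float
    l90: float
    coronal: float
    ext_deficit: float

    def __post_init__(self) -> None:
        for name in LOAD_CHANNELS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"load {name}={v!r} must be finite and >= 0")
        if not math.isfinite(self.coronal) or abs(self.coronal) > MAX_ABS_CORONAL:
            raise ValueError(f"coronal={self.coronal!r} outside sanity bounds")
        if not math.isfinite(self.ext_deficit) or abs(self.ext_deficit) > MAX_ABS_EXT_DEFICIT:
            raise ValueError(f"ext_deficit={self.ext_deficit!r} outside sanity bounds")

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.m10, self.l10, self.m90, self.l90, self.coronal, self.ext_deficit)

    @classmethod
    def from_iterable(cls, values) -> "KneeState":
        vals = list(values)
        if len(vals) != 6:
            raise ValueError(f"expected 6 channel values, got {len(vals)}")
        return cls(*map(float, vals))


@dataclass(frozen=True)
class Thresholds:
    """Balance and alignment acceptance thresholds.

    ``diff_max`` is the mediolateral differential cap (lbf), ``load_min`` /
    ``load_max`` the per-compartment load window (lbf), ``coronal_window``
    the valgus-side coronal acceptance bound and ``varus_allow`` the
    varus-side bound (degrees; equal by default, exposed separately because
    the two bounds have different clinical rationales).  ``small_deficit_max``
    separates small from large flexion contractures and ``hyper_min`` is the
    tolerated hyperextension (degrees).
    """

    diff_max: float = 15.0
    load_max: float = 40.0
    load_min: float = 10.0
    coronal_window: float = 3.0
    varus_allow: float = 3.0
    small_deficit_max: float = 5.0
    hyper_min: float = 2.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"threshold {f.name}={v!r} must be finite and > 0")
        if self.load_min >= self.load_max:
            raise ValueError("load_min must be < load_max")

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class BalanceAssessment:
    """Per-compartment load classification and the overall balance verdict."""

    diff10: float
    diff90: float
    status_m10: LoadStatus
    status_l10: LoadStatus
    status_m90: LoadStatus
    status_l90: LoadStatus
    tight_side_10: Side
    tight_side_90: Side
    balanced: bool

    @property
    def any_loose(self) -> bool:
        return LoadStatus.LOOSE in (
            self.status_m10, self.status_l10, self.status_m90, self.status_l90
        )


def classify_load(load: float, thresholds: Thresholds) -> LoadStatus:
    """Classify a single compartment load against the 10-40 lbf window.

    Boundary values are acceptable: a load is loose only strictly below
    ``load_min`` and tight only strictly above ``load_max``.
    """
    if not math.isfinite(load) or load < 0:
        raise ValueError(f"load={load!r} must be finite and >= 0")
    if load < thresholds.load_min:
        return LoadStatus.LOOSE
    if load > thresholds.load_max:
        return LoadStatus.TIGHT
    return LoadStatus.ACCEPTABLE


def _tight_side(medial: float, lateral: float, thresholds: Thresholds) -> Side:
    """Tight compartment at one flexion angle.

    A side is flagged tight when its absolute load exceeds ``load_max`` or
    when the mediolateral differential reaches ``diff_max`` (the higher side
    is then the tight one).  When both compartments exceed the ceiling the
    higher load wins; an exact tie is reported medial, the medial column
    being the primary balance target.
    """
    m_tight = medial > thresholds.load_max
    l_tight = lateral > thresholds.load_max
    if m_tight or l_tight:
        if m_tight and l_tight:
            return Side.LATERAL if lateral > medial else Side.MEDIAL
        return Side.MEDIAL if m_tight else Side.LATERAL
    if abs(medial - lateral) >= thresholds.diff_max:
        return Side.MEDIAL if medial > lateral else Side.LATERAL
    return Side.NONE


def assess_balance(state: KneeState, thresholds: Thresholds) -> BalanceAssessment:
    """Evaluate the quantitative balance definition on a knee state.

    Balanced means: differential < ``diff_max`` at both 10 and 90 degrees and
    every compartment load inside ``[load_min, load_max]``.
    """
    diff10 = abs(state.m10 - state.l10)
    diff90 = abs(state.m90 - state.l90)
    statuses = {ch: classify_load(getattr(state, ch), thresholds) for ch in LOAD_CHANNELS}
    balanced = (
        diff10 < thresholds.diff_max
        and diff90 < thresholds.diff_max
        and all(s is LoadStatus.ACCEPTABLE for s in statuses.values())
    )
    return BalanceAssessment(
        diff10=diff10,
        diff90=diff90,
        status_m10=statuses["m10"],
        status_l10=statuses["l10"],
        status_m90=statuses["m90"],
        status_l90=statuses["l90"],
        tight_side_10=_tight_side(state.m10, state.l10, thresholds),
        tight_side_90=_tight_side(state.m90, state.l90, thresholds),
        balanced=balanced,
    )


def classify_coronal(coronal: float, thresholds: Thresholds) -> CoronalCategory:
    """Classify coronal alignment against the acceptance window.

    Varus beyond ``varus_allow`` or valgus beyond ``coronal_window`` is out of
    window; within the window the sign decides varus vs valgus, with a
    ``NEUTRAL_TOL`` band around zero reported as neutral.
    """
    if not math.isfinite(coronal):
        raise ValueError("coronal must be finite")
    if coronal < -thresholds.varus_allow:
        return CoronalCategory.VARUS_OUT
    if coronal > thresholds.coronal_window:
        return CoronalCategory.VALGUS_OUT
    if abs(coronal) < NEUTRAL_TOL:
        return CoronalCategory.NEUTRAL
    return CoronalCategory.VARUS_IN_WINDOW if coronal < 0 else CoronalCategory.VALGUS_IN_WINDOW


def classify_sagittal(ext_deficit: float, thresholds: Thresholds) -> SagittalCategory:
    """Classify the sagittal extension deficit.

    Hyperextension beyond ``hyper_min`` degrees is flagged; deficits up to
    ``FULL_EXTENSION_TOL`` count as full extension; contractures are split at
    ``small_deficit_max`` into small (soft-tissue range) and large
    (bone-recut range).
    """
    if not math.isfinite(ext_deficit):
        raise ValueError("ext_deficit must be finite")
    if ext_deficit < -thresholds.hyper_min:
        return SagittalCategory.HYPEREXTENSION
    if ext_deficit <= FULL_EXTENSION_TOL:
        return SagittalCategory.FULL_EXTENSION
    if ext_deficit <= thresholds.small_deficit_max:
        return SagittalCategory.SMALL_CONTRACTURE
    return SagittalCategory.LARGE_CONTRACTURE
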