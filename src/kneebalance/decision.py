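"""Rule-based surgical decision engine for intraoperative knee balancing.

Maps a measured knee state to the next recommended surgical correction.
Rules are evaluated in a fixed clinical priority order and the first match
wins:

1. Sagittal block — terminal extension is assured first.  Large flexion
   contractures are addressed with an arcuate release (valgus knee with a
   tight lateral compartment in extension), a femoral recut (flexion loads
   acceptable) or a tibial recut (loads excessive in both flexion and
   extension); small contractures with a posterior capsule release;
   hyperextension with a thicker insert.
2. Loose block — any compartment below the load floor is addressed by
   increasing the polyethylene insert thickness.
3. Lateral-tight block — arcuate release (extension), popliteus release
   (flexion), or their combination across the range of motion; the
   iliotibial band is released when an arcuate release was already done.
4. Medial-tight block — MCL pie-crusting versus recuts, gated on coronal
   alignment (pie-crusting adds valgus, a tibial recut adds varus).
5. Residual malalignment in an otherwise balanced knee is corrected toward
   the window, then the state is accepted.

The engine is deterministic and single-step; closed-loop use (simulation)
re-invokes it after every applied correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .core import (
    BalanceAssessment,
    CoronalCategory,
    KneeState,
    SagittalCategory,
    Side,
    Thresholds,
    assess_balance,
    classify_coronal,
    classify_sagittal,
)

__all__ = [
    "CorrectionType",
    "Recommendation",
    "RuleTraceEntry",
    "recommend",
    "rule_trace",
    "truth_table",
    "ACCEPT",
]


class CorrectionType(str, Enum):
    """The eight documented surgical corrections."""

    MCL_PIECRUST = "MCL_PIECRUST"
    ARCUATE_RELEASE = "ARCUATE_RELEASE"
    POPLITEUS_RELEASE = "POPLITEUS_RELEASE"
    POSTERIOR_CAPSULE_RELEASE = "POSTERIOR_CAPSULE_RELEASE"
    ITB_RELEASE = "ITB_RELEASE"
    TIBIA_RECUT = "TIBIA_RECUT"
    FEMUR_RECUT = "FEMUR_RECUT"
    INSERT_UP_2MM = "INSERT_UP_2MM"


#: Sentinel action meaning the state meets all balance and alignment targets.
ACCEPT = "ACCEPT"


@dataclass(frozen=True)
class Recommendation:
    """Outcome of one engine evaluation.

    ``action`` is a :class:`CorrectionType`, or ``None`` when the knee is
    accepted.  ``rule_id`` identifies the fired rule; ``rationale`` restates
    the classification facts that triggered it.
    """

    action: Optional[CorrectionType]
    rule_id: str
    rationale: str

    @property
    def is_accept(self) -> bool:
        return self.action is None

    @property
    def action_label(self) -> str:
        return ACCEPT if self.action is None else self.action.value


@dataclass(frozen=True)
class RuleTraceEntry:
    rule_id: str
    fired: bool
    winner: bool
    action: str
    facts: str


@dataclass(frozen=True)
class _Facts:
    """Derived classification facts the rules condition on."""

    assessment: BalanceAssessment
    coronal: CoronalCategory
    sagittal: SagittalCategory
    lateral_tight_10: bool
    lateral_tight_90: bool
    medial_tight_10: bool
    medial_tight_90: bool
    flexion_over_ceiling: bool
    extension_over_ceiling: bool

    def summary(self) -> str:
        a = self.assessment
        return (
            f"sagittal={self.sagittal.value}, coronal={self.coronal.value}, "
            f"balanced={a.balanced}, diff10={a.diff10:.1f}, diff90={a.diff90:.1f}, "
            f"tight10={a.tight_side_10.value}, tight90={a.tight_side_90.value}, "
            f"loose={a.any_loose}"
        )


def _derive_facts(state: KneeState, thresholds: Thresholds) -> _Facts:
    a = assess_balance(state, thresholds)
    return _Facts(
        assessment=a,
        coronal=classify_coronal(state.coronal, thresholds),
        sagittal=classify_sagittal(state.ext_deficit, thresholds),
        lateral_tight_10=a.tight_side_10 is Side.LATERAL,
        lateral_tight_90=a.tight_side_90 is Side.LATERAL,
        medial_tight_10=a.tight_side_10 is Side.MEDIAL,
        medial_tight_90=a.tight_side_90 is Side.MEDIAL,
        flexion_over_ceiling=max(state.m90, state.l90) > thresholds.load_max,
        extension_over_ceiling=max(state.m10, state.l10) > thresholds.load_max,
    )


_VALGUS = (CoronalCategory.VALGUS_IN_WINDOW, CoronalCategory.VALGUS_OUT)
_VARUS = (CoronalCategory.VARUS_IN_WINDOW, CoronalCategory.VARUS_OUT)


def _evaluate_rules(
    facts: _Facts,
    state: KneeState,
    thresholds: Thresholds,
    history: frozenset[CorrectionType],
) -> list[tuple[str, bool, Optional[CorrectionType], str]]:
    """All rule predicates in priority order: (rule_id, fired, action, why)."""
    f = facts
    large = f.sagittal is SagittalCategory.LARGE_CONTRACTURE
    rules: list[tuple[str, bool, Optional[CorrectionType], str]] = []

    # --- R1: sagittal block ------------------------------------------------
    r1a = large and f.lateral_tight_10 and f.coronal in _VALGUS
    rules.append((
        "R1a", r1a, CorrectionType.ARCUATE_RELEASE,
        "large flexion contracture with a tight lateral compartment in "
        "extension and valgus alignment: an arcuate release addresses both",
    ))
    r1b = (not r1a) and large and state.m90 <= thresholds.load_max and state.l90 <= thresholds.load_max
    rules.append((
        "R1b", r1b, CorrectionType.FEMUR_RECUT,
        "large flexion contracture with acceptable flexion loads: a femoral "
        "recut opens the extension space without disturbing flexion balance",
    ))
    r1c = (not (r1a or r1b)) and large and f.flexion_over_ceiling and f.extension_over_ceiling
    rules.append((
        "R1c", r1c, CorrectionType.TIBIA_RECUT,
        "large flexion contracture with loads over the ceiling in both "
        "flexion and extension: a tibial recut relieves both gaps",
    ))
    r1d = f.sagittal is SagittalCategory.SMALL_CONTRACTURE
    rules.append((
        "R1d", r1d, CorrectionType.POSTERIOR_CAPSULE_RELEASE,
        "small extension deficit: a posterior capsule release restores "
        "terminal extension without shifting the mediolateral balance",
    ))
    r1e = f.sagittal is SagittalCategory.HYPEREXTENSION
    rules.append((
        "R1e", r1e, CorrectionType.INSERT_UP_2MM,
        "hyperextension: a thicker polyethylene insert tightens the "
        "extension space",
    ))
    sagittal_fired = r1a or r1b or r1c or r1d or r1e

    # --- R2: loose block ---------------------------------------------------
    r2 = (not sagittal_fired) and f.assessment.any_loose
    rules.append((
        "R2", r2, CorrectionType.INSERT_UP_2MM,
        "a compartment load below the floor: loose conditions are addressed "
        "first by increasing the insert thickness",
    ))
    blocked = sagittal_fired or r2

    # --- R3: lateral-tight block -------------------------------------------
    r3a = (not blocked) and f.lateral_tight_10 and not f.lateral_tight_90
    r3a_action = (
        CorrectionType.ITB_RELEASE
        if CorrectionType.ARCUATE_RELEASE in history
        else CorrectionType.ARCUATE_RELEASE
    )
    rules.append((
        "R3a", r3a, r3a_action,
        "isolated lateral tightness in extension: arcuate release, or an "
        "iliotibial band release once the arcuate has been released",
    ))
    r3b = (not blocked) and f.lateral_tight_90 and not f.lateral_tight_10
    rules.append((
        "R3b", r3b, CorrectionType.POPLITEUS_RELEASE,
        "isolated lateral tightness in flexion: popliteus release",
    ))
    r3c = (not blocked) and f.lateral_tight_10 and f.lateral_tight_90
    r3c_action = (
        CorrectionType.POPLITEUS_RELEASE
        if CorrectionType.ARCUATE_RELEASE in history
        else CorrectionType.ARCUATE_RELEASE
    )
    rules.append((
        "R3c", r3c, r3c_action,
        "lateral tightness through the range of motion: arcuate release "
        "first, popliteus release on a subsequent pass",
    ))
    blocked = blocked or r3a or r3b or r3c

    # --- R4: medial-tight block --------------------------------------------
    r4a = (not blocked) and f.medial_tight_10 and not f.medial_tight_90
    r4a_action = (
        CorrectionType.MCL_PIECRUST
        if f.coronal is CoronalCategory.VARUS_OUT
        else CorrectionType.FEMUR_RECUT
    )
    rules.append((
        "R4a", r4a, r4a_action,
        "isolated medial tightness in extension: MCL pie-crust when the limb "
        "is varus outside the window (the release also corrects alignment), "
        "otherwise a varus femoral recut",
    ))
    r4b = (not blocked) and f.medial_tight_90 and not f.medial_tight_10
    rules.append((
        "R4b", r4b, CorrectionType.MCL_PIECRUST,
        "isolated medial tightness in flexion: MCL pie-crust",
    ))
    r4cd = (not blocked) and f.medial_tight_10 and f.medial_tight_90
    r4c = r4cd and f.coronal in _VARUS
    rules.append((
        "R4c", r4c, CorrectionType.MCL_PIECRUST,
        "medial tightness through the range of motion in a varus limb: MCL "
        "pie-crust lowers medial loads while correcting the varus",
    ))
    r4d = r4cd and f.coronal not in _VARUS
    rules.append((
        "R4d", r4d, CorrectionType.TIBIA_RECUT,
        "medial tightness through the range of motion with neutral or valgus "
        "alignment: a varus tibial recut (pie-crusting would push the limb "
        "into valgus)",
    ))
    blocked = blocked or r4a or r4b or r4cd

    # --- R4e/R4f: residual malalignment in a balanced knee ------------------
    r4e = (not blocked) and f.coronal is CoronalCategory.VARUS_OUT
    rules.append((
        "R4e", r4e, CorrectionType.MCL_PIECRUST,
        "balanced loads but varus beyond the allowed window: MCL pie-crust "
        "shifts the limb toward neutral",
    ))
    r4f = (not blocked) and (not r4e) and f.coronal is CoronalCategory.VALGUS_OUT
    rules.append((
        "R4f", r4f, CorrectionType.ARCUATE_RELEASE,
        "balanced loads but valgus beyond the window: an arcuate release "
        "reduces valgus alignment",
    ))
    blocked = blocked or r4e or r4f

    # --- R5: accept ---------------------------------------------------------
    rules.append((
        "R5", not blocked, None,
        "balanced, aligned within the coronal window and at full terminal "
        "extension: accept",
    ))
    return rules


def recommend(
    state: KneeState,
    thresholds: Thresholds,
    history: Iterable[CorrectionType] = (),
) -> Recommendation:
    """Return the next recommended correction for ``state``.

    ``history`` is the set of corrections already performed on this case;
    it gates the and/or choices within the lateral release block.
    """
    facts = _derive_facts(state, thresholds)
    rules = _evaluate_rules(facts, state, thresholds, frozenset(history))
    for rule_id, fired, action, why in rules:
        if fired:
            return Recommendation(
                action=action,
                rule_id=rule_id,
                rationale=f"{why} [{facts.summary()}]",
            )
    raise AssertionError("rule set is not exhaustive")  # pragma: no cover


def rule_trace(
    state: KneeState,
    thresholds: Thresholds,
    history: Iterable[CorrectionType] = (),
) -> list[RuleTraceEntry]:
    """Evaluate every rule in order and mark the winning one.

    Exactly one entry is the winner and it matches :func:`recommend` on the
    same inputs.
    """
    facts = _derive_facts(state, thresholds)
    rules = _evaluate_rules(facts, state, thresholds, frozenset(history))
    entries: list[RuleTraceEntry] = []
    winner_seen = False
    for rule_id, fired, action, why in rules:
        is_winner = fired and not winner_seen
        winner_seen = winner_seen or fired
        entries.append(RuleTraceEntry(
            rule_id=rule_id,
            fired=fired,
            winner=is_winner,
            action=ACCEPT if action is None else action.value,
            facts=why,
        ))
    return entries


def trace_to_frame(entries: list[RuleTraceEntry]) -> pd.DataFrame:
    """Rule trace as a DataFrame (exportable to CSV)."""
    return pd.DataFrame(
        [(e.rule_id, e.fired, e.winner, e.action) for e in entries],
        columns=["rule_id", "fired", "winner", "action"],
    )


def truth_table(grid: Iterable[KneeState], thresholds: Thresholds) -> pd.DataFrame:
    """Evaluate the engine over a grid of states.

    Returns one row per state with the six channel values, the recommended
    action and the fired rule.  Deterministic: repeated calls on the same
    grid yield identical tables.
    """
    states = list(grid)
    if not states:
        raise ValueError("grid must be non-empty")
    rows = []
    for s in states:
        rec = recommend(s, thresholds)
        rows.append(s.as_tuple() + (rec.action_label, rec.rule_id))
    return pd.DataFrame(
        rows,
        columns=["m10", "l10", "m90", "l90", "coronal", "ext_deficit", "action", "rule_id"],
    )
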