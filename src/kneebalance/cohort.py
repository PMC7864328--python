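"""Synthetic intraoperative cohorts: virtual patients, initial knee states
and closed-loop virtual surgery.

Each virtual case starts from a post-initial-cut knee state drawn from a
phenotype mixture (medial-tight varus, lateral-tight valgus, flexion
contracture, hyperextension with loose compartments, already balanced).  The
decision engine then recommends corrections one at a time; each is applied
through the calibrated effect model (mean delta + patient offset + residual
noise) until the knee is accepted or the correction cap is reached.  A fixed
number of randomly chosen patients is flagged as missing (insufficient
documentation, missing completely at random) and excluded from analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .config import CohortConfig, ConfigError, Demographics
from .core import CHANNELS, KneeState, Thresholds
from .decision import CorrectionType, recommend
from .effects import CalibrationTable, apply_corrections, default_calibration

__all__ = [
    "Patient",
    "CorrectionEvent",
    "CohortTable",
    "generate_patients",
    "generate_initial_state",
    "simulate_case",
    "simulate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "CohortParseError",
]

N_CHANNELS = len(CHANNELS)


class CohortParseError(ValueError):
    """Raised when a cohort CSV is malformed; carries the offending row number."""


@dataclass(frozen=True)
class Patient:
    id: int
    age: float
    sex: str  # "M" or "F"
    random_offset: np.ndarray  # shape (6,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "random_offset", np.asarray(self.random_offset, dtype=float))
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.random_offset.shape != (N_CHANNELS,):
            raise ValueError("random_offset must have 6 entries")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Patient)
            and self.id == other.id
            and self.age == other.age
            and self.sex == other.sex
            and np.array_equal(self.random_offset, other.random_offset)
        )


@dataclass(frozen=True)
class CorrectionEvent:
    """One applied correction (or batched set) with its pre/post measurements."""

    patient_id: int
    sequence_index: int  # 1-based within the case
    corrections: tuple[CorrectionType, ...]
    pre: KneeState
    post: KneeState

    def __post_init__(self) -> None:
        if not self.corrections:
            raise ValueError("an event needs at least one correction")
        if self.sequence_index < 1:
            raise ValueError("sequence_index is 1-based")


@dataclass(frozen=True)
class CohortTable:
    patients: tuple[Patient, ...]
    events: tuple[CorrectionEvent, ...]
    missing_patient_ids: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "missing_patient_ids", frozenset(self.missing_patient_ids))
        ids = [p.id for p in self.patients]
        id_set = set(ids)
        if len(ids) != len(id_set):
            raise ValueError("patient ids must be unique")
        if not self.missing_patient_ids <= id_set:
            raise ValueError("missing ids must be a subset of patient ids")
        for e in self.events:
            if e.patient_id not in id_set:
                raise ValueError(f"event references unknown patient {e.patient_id}")

    @property
    def analyzable_patient_ids(self) -> set[int]:
        return {p.id for p in self.patients} - set(self.missing_patient_ids)

    def events_for(self, patient_id: int) -> list[CorrectionEvent]:
        return [e for e in self.events if e.patient_id == patient_id]


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_patients(
    n: int,
    demographics: Optional[Demographics] = None,
    seed=None,
    sigma_patient: Optional[np.ndarray] = None,
) -> list[Patient]:
    """Draw ``n`` virtual patients.

    Ages come from a normal distribution truncated to the configured range,
    sex from a Bernoulli split, and the per-patient six-channel random offset
    from independent zero-mean Gaussians with SD ``sigma_patient`` (defaults
    to the packaged calibration's values).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    demographics = demographics or Demographics()
    if sigma_patient is None:
        sigma_patient = default_calibration().sigma_patient
    sigma_patient = np.asarray(sigma_patient, dtype=float)
    rng = _as_rng(seed)
    d = demographics
    a = (d.age_min - d.age_mean) / d.age_sd
    b = (d.age_max - d.age_mean) / d.age_sd
    ages = stats.truncnorm.rvs(a, b, loc=d.age_mean, scale=d.age_sd, size=n, random_state=rng)
    sexes = np.where(rng.random(n) < d.male_fraction, "M", "F")
    offsets = rng.normal(0.0, 1.0, size=(n, N_CHANNELS)) * sigma_patient
    return [
        Patient(id=i + 1, age=float(ages[i]), sex=str(sexes[i]), random_offset=offsets[i])
        for i in range(n)
    ]


def generate_initial_state(phenotypes: dict[str, dict], rng) -> KneeState:
    """Draw a post-initial-cut knee state from the phenotype mixture.

    Each phenotype specifies a mixture weight and an inclusive uniform range
    per channel; weights must sum to one.
    """
    names = list(phenotypes)
    weights = np.array([float(phenotypes[k]["weight"]) for k in names])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigError(f"phenotype weights must sum to 1 (got {weights.sum()!r})")
    rng = _as_rng(rng)
    name = names[rng.choice(len(names), p=weights)]
    spec = phenotypes[name]
    values = []
    for ch in CHANNELS:
        lo, hi = spec[ch]
        values.append(rng.uniform(float(lo), float(hi)))
    return KneeState.from_iterable(values)


def simulate_case(
    patient: Patient,
    initial_state: KneeState,
    thresholds: Thresholds,
    calibration: CalibrationTable,
    rng,
    max_corrections: int = 7,
    batch_prob: float = 0.0,
) -> list[CorrectionEvent]:
    """Run the closed balancing loop for one case.

    The decision engine is consulted after every event; the loop stops on
    acceptance or after ``max_corrections`` events.  With probability
    ``batch_prob`` a second, compatible correction (the engine's next call on
    the noiseless preview state) is folded into the same event.
    """
    rng = _as_rng(rng)
    state = initial_state
    history: set[CorrectionType] = set()
    events: list[CorrectionEvent] = []
    zeros = np.zeros(N_CHANNELS)
    for k in range(1, max_corrections + 1):
        rec = recommend(state, thresholds, history)
        if rec.is_accept:
            break
        corrections = [rec.action]
        if batch_prob > 0 and rng.random() < batch_prob:
            preview = apply_corrections(state, corrections, calibration, zeros, zeros)
            rec2 = recommend(preview, thresholds, history | {rec.action})
            if not rec2.is_accept and rec2.action != rec.action:
                corrections.append(rec2.action)
        noise = rng.normal(0.0, 1.0, size=N_CHANNELS) * calibration.sigma_resid
        post = apply_corrections(state, corrections, calibration, patient.random_offset, noise)
        events.append(CorrectionEvent(
            patient_id=patient.id,
            sequence_index=k,
            corrections=tuple(corrections),
            pre=state,
            post=post,
        ))
        history.update(corrections)
        state = post
    return events


def simulate_cohort(
    config: Optional[CohortConfig] = None,
    seed=None,
    thresholds: Optional[Thresholds] = None,
    calibration: Optional[CalibrationTable] = None,
) -> CohortTable:
    """Simulate a full cohort under the configured study conditions.

    Reproducible: the same seed yields an identical table.  Exactly
    ``config.n_missing`` randomly chosen patients are flagged missing.
    """
    config = config or CohortConfig()
    thresholds = thresholds or Thresholds()
    calibration = calibration or default_calibration()
    rng = _as_rng(seed)
    patients = generate_patients(
        config.n, config.demographics, seed=rng, sigma_patient=calibration.sigma_patient
    )
    events: list[CorrectionEvent] = []
    for p in patients:
        initial = generate_initial_state(config.phenotypes, rng)
        events.extend(simulate_case(
            p, initial, thresholds, calibration, rng,
            max_corrections=config.max_corrections,
            batch_prob=config.batch_prob,
        ))
    ids = np.array([p.id for p in patients])
    missing = rng.choice(ids, size=config.n_missing, replace=False) if config.n_missing else []
    return CohortTable(
        patients=tuple(patients),
        events=tuple(events),
        missing_patient_ids=frozenset(int(i) for i in missing),
    )


# ---------------------------------------------------------------------------
# CSV round trip.  One file with two sections: a patient table and a wide
# per-event table (12 pre/post channel columns, semicolon-joined corrections).
# Floats are written with repr so the round trip is exact.

_PATIENT_HEADER = ["patient_id", "age", "sex", "missing"] + [f"off_{ch}" for ch in CHANNELS]
_EVENT_HEADER = (
    ["patient_id", "sequence_index", "corrections"]
    + [f"pre_{ch}" for ch in CHANNELS]
    + [f"post_{ch}" for ch in CHANNELS]
)


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["[patients]"])
        w.writerow(_PATIENT_HEADER)
        for p in table.patients:
            w.writerow(
                [p.id, repr(p.age), p.sex, int(p.id in table.missing_patient_ids)]
                + [repr(float(v)) for v in p.random_offset]
            )
        w.writerow(["[events]"])
        w.writerow(_EVENT_HEADER)
        for e in table.events:
            w.writerow(
                [e.patient_id, e.sequence_index, ";".join(c.value for c in e.corrections)]
                + [repr(v) for v in e.pre.as_tuple()]
                + [repr(v) for v in e.post.as_tuple()]
            )


def read_cohort_csv(path: str | Path) -> CohortTable:
    patients: list[Patient] = []
    events: list[CorrectionEvent] = []
    missing: set[int] = set()
    section = None
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if row[0] in ("[patients]", "[events]"):
                section = row[0]
                expect_header = True
                continue
            if section is None:
                raise CohortParseError(f"row {lineno}: content before any section marker")
            if expect_header:
                want = _PATIENT_HEADER if section == "[patients]" else _EVENT_HEADER
                if row != want:
                    raise CohortParseError(f"row {lineno}: unexpected header {row!r}")
                expect_header = False
                continue
            try:
                if section == "[patients]":
                    pid = int(row[0])
                    patients.append(Patient(
                        id=pid,
                        age=float(row[1]),
                        sex=row[2],
                        random_offset=[float(v) for v in row[4:10]],
                    ))
                    if int(row[3]):
                        missing.add(pid)
                else:
                    labels = row[2].split(";")
                    try:
                        corrections = tuple(CorrectionType(lbl) for lbl in labels)
                    except ValueError as err:
                        raise CohortParseError(
                            f"row {lineno}: unknown correction label in {row[2]!r}"
                        ) from err
                    events.append(CorrectionEvent(
                        patient_id=int(row[0]),
                        sequence_index=int(row[1]),
                        corrections=corrections,
                        pre=KneeState.from_iterable(float(v) for v in row[3:9]),
                        post=KneeState.from_iterable(float(v) for v in row[9:15]),
                    ))
            except CohortParseError:
                raise
            except (ValueError, IndexError) as err:
                raise CohortParseError(f"row {lineno}: {err}") from err
    return CohortTable(
        patients=tuple(patients), events=tuple(events), missing_patient_ids=frozenset(missing)
    )
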