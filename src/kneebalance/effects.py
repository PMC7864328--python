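"""Correction-effect model: calibrated per-correction state deltas.

Each surgical correction shifts the six measured channels (four compartment
loads, coronal alignment, extension deficit) by a correction-specific mean
delta, plus a per-patient random offset (constant within a case — the
random-intercept analogue of patient-to-patient variability) and independent
Gaussian residual noise per channel.

The *sign ledger* below encodes the direction of every statistically
significant effect:

* MCL pie-crusting lowers medial loads at both flexion angles, raises
  lateral loads, adds valgus and improves terminal extension.
* An arcuate release lowers lateral extension loads, adds varus and improves
  extension; a popliteus release lowers lateral loads (chiefly in flexion)
  and adds varus; an ITB release lowers lateral extension loads.
* A posterior capsule release lowers medial extension loads and improves
  extension.
* A varus tibial recut lowers medial loads at both angles and lateral
  flexion loads, adds varus, and improves extension; a femoral recut only
  improves extension (load changes were not significant once recut subtypes
  are pooled).
* A 2 mm insert-thickness increase raises extension loads on both sides and
  decreases terminal extension by 2.5 degrees on average.

Only the signs and the 2.5-degree insert effect are anchored findings; the
remaining magnitudes are model defaults stored in the packaged calibration
file, tuned so that closed-loop simulation reproduces the observed ~3
corrections per case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import CHANNELS, MAX_ABS_CORONAL, MAX_ABS_EXT_DEFICIT, KneeState
from .decision import CorrectionType

__all__ = [
    "EffectProfile",
    "CalibrationTable",
    "SIGN_LEDGER",
    "default_calibration",
    "load_calibration",
    "save_calibration",
    "apply_correction",
    "apply_corrections",
    "CalibrationError",
]

N_CHANNELS = len(CHANNELS)

#: Direction of each significant effect per correction, in channel order
#: (m10, l10, m90, l90, coronal, ext_deficit); 0 = no significant effect.
SIGN_LEDGER: dict[CorrectionType, tuple[int, ...]] = {
    CorrectionType.MCL_PIECRUST: (-1, +1, -1, +1, +1, -1),
    CorrectionType.ARCUATE_RELEASE: (0, -1, 0, 0, -1, -1),
    CorrectionType.POPLITEUS_RELEASE: (0, -1, 0, -1, -1, 0),
    CorrectionType.ITB_RELEASE: (0, -1, 0, 0, 0, 0),
    CorrectionType.POSTERIOR_CAPSULE_RELEASE: (-1, 0, 0, 0, 0, -1),
    CorrectionType.TIBIA_RECUT: (-1, 0, -1, -1, -1, -1),
    CorrectionType.FEMUR_RECUT: (0, 0, 0, 0, 0, -1),
    CorrectionType.INSERT_UP_2MM: (+1, +1, 0, 0, 0, +1),
}


class CalibrationError(ValueError):
    """Raised for malformed or sign-ledger-violating calibration documents."""


@dataclass(frozen=True)
class EffectProfile:
    """Mean six-channel delta of one correction plus significance flags."""

    correction: CorrectionType
    mean_delta: np.ndarray  # shape (6,), lbf / degrees
    significant: np.ndarray  # shape (6,), bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_delta", np.asarray(self.mean_delta, dtype=float))
        object.__setattr__(self, "significant", np.asarray(self.significant, dtype=bool))
        if self.mean_delta.shape != (N_CHANNELS,):
            raise CalibrationError(
                f"{self.correction.value}: mean_delta must have {N_CHANNELS} entries"
            )
        if self.significant.shape != (N_CHANNELS,):
            raise CalibrationError(
                f"{self.correction.value}: significant must have {N_CHANNELS} entries"
            )
        if not np.all(np.isfinite(self.mean_delta)):
            raise CalibrationError(f"{self.correction.value}: non-finite mean_delta")

    def check_signs(self) -> list[str]:
        """Return the channels whose significant component contradicts the ledger."""
        ledger = SIGN_LEDGER[self.correction]
        bad = []
        for i, ch in enumerate(CHANNELS):
            if self.significant[i] and ledger[i] != 0:
                if np.sign(self.mean_delta[i]) != ledger[i]:
                    bad.append(ch)
        return bad

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EffectProfile)
            and self.correction is other.correction
            and np.array_equal(self.mean_delta, other.mean_delta)
            and np.array_equal(self.significant, other.significant)
        )


@dataclass(frozen=True)
class CalibrationTable:
    """One :class:`EffectProfile` per correction plus variance components.

    ``sigma_patient`` is the per-channel SD of the patient random offset
    (shared by every correction within a case); ``sigma_resid`` the
    per-channel residual SD of a single correction's observed delta.
    """

    profiles: Mapping[CorrectionType, EffectProfile]
    sigma_patient: np.ndarray
    sigma_resid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", dict(self.profiles))
        object.__setattr__(self, "sigma_patient", np.asarray(self.sigma_patient, dtype=float))
        object.__setattr__(self, "sigma_resid", np.asarray(self.sigma_resid, dtype=float))
        missing = set(CorrectionType) - set(self.profiles)
        if missing:
            raise CalibrationError(
                f"calibration missing corrections: {sorted(c.value for c in missing)}"
            )
        extra = set(self.profiles) - set(CorrectionType)
        if extra:
            raise CalibrationError(f"unknown corrections in calibration: {sorted(extra)}")
        for sd_name in ("sigma_patient", "sigma_resid"):
            sd = getattr(self, sd_name)
            if sd.shape != (N_CHANNELS,) or not np.all(np.isfinite(sd)) or np.any(sd < 0):
                raise CalibrationError(f"{sd_name} must be {N_CHANNELS} finite values >= 0")

    def check_signs(self) -> dict[str, list[str]]:
        """Ledger violations as {correction: [channels]} (empty when conformant)."""
        out = {}
        for c, p in self.profiles.items():
            bad = p.check_signs()
            if bad:
                out[c.value] = bad
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CalibrationTable)
            and dict(self.profiles) == dict(other.profiles)
            and np.array_equal(self.sigma_patient, other.sigma_patient)
            and np.array_equal(self.sigma_resid, other.sigma_resid)
        )


_DEFAULT_PATH = Path(__file__).parent / "data" / "default_calibration.json"


def _table_from_doc(doc: dict, strict: bool) -> CalibrationTable:
    if "profiles" not in doc or "sigma_patient" not in doc or "sigma_resid" not in doc:
        raise CalibrationError(
            "calibration document needs 'profiles', 'sigma_patient' and 'sigma_resid'"
        )
    profiles = {}
    for name, entry in doc["profiles"].items():
        try:
            correction = CorrectionType(name)
        except ValueError as err:
            raise CalibrationError(f"unknown correction {name!r}") from err
        profiles[correction] = EffectProfile(
            correction=correction,
            mean_delta=entry["mean_delta"],
            significant=entry["significant"],
        )
    table = CalibrationTable(
        profiles=profiles,
        sigma_patient=doc["sigma_patient"],
        sigma_resid=doc["sigma_resid"],
    )
    if strict:
        bad = table.check_signs()
        if bad:
            raise CalibrationError(f"sign-ledger violations: {bad}")
    return table


def load_calibration(path: str | Path, strict: bool = False) -> CalibrationTable:
    """Load a calibration table from JSON; with ``strict`` the sign ledger is enforced."""
    with open(path) as fh:
        doc = json.load(fh)
    return _table_from_doc(doc, strict=strict)


def save_calibration(table: CalibrationTable, path: str | Path) -> None:
    doc = {
        "sigma_patient": table.sigma_patient.tolist(),
        "sigma_resid": table.sigma_resid.tolist(),
        "profiles": {
            c.value: {
                "mean_delta": p.mean_delta.tolist(),
                "significant": [bool(b) for b in p.significant],
            }
            for c, p in table.profiles.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def default_calibration() -> CalibrationTable:
    """The packaged default calibration (sign-ledger checked on load)."""
    return load_calibration(_DEFAULT_PATH, strict=True)


def _clip_state_vector(vec: np.ndarray) -> KneeState:
    vec = vec.copy()
    vec[:4] = np.maximum(vec[:4], 0.0)  # a load sensor cannot read negative
    vec[4] = np.clip(vec[4], -MAX_ABS_CORONAL, MAX_ABS_CORONAL)
    vec[5] = np.clip(vec[5], -MAX_ABS_EXT_DEFICIT, MAX_ABS_EXT_DEFICIT)
    return KneeState.from_iterable(vec)


def apply_corrections(
    state: KneeState,
    corrections,
    calibration: CalibrationTable,
    patient_offset: np.ndarray,
    noise_draw: np.ndarray,
) -> KneeState:
    """Apply one event (one or several batched corrections) to a knee state.

    The new state is ``old + sum(mean_delta) + patient_offset + noise_draw``
    with loads clamped at zero.  Pure function of its arguments: the noise
    draw comes from the caller's random stream.
    """
    corrections = list(corrections)
    if not corrections:
        raise ValueError("at least one correction required")
    offset = np.asarray(patient_offset, dtype=float)
    noise = np.asarray(noise_draw, dtype=float)
    if offset.shape != (N_CHANNELS,) or noise.shape != (N_CHANNELS,):
        raise ValueError(f"patient_offset and noise_draw must have {N_CHANNELS} entries")
    delta = np.zeros(N_CHANNELS)
    for c in corrections:
        if not isinstance(c, CorrectionType):
            raise ValueError(f"unknown correction {c!r}")
        delta += calibration.profiles[c].mean_delta
    new = np.array(state.as_tuple()) + delta + offset + noise
    return _clip_state_vector(new)


def apply_correction(
    state: KneeState,
    correction: CorrectionType,
    calibration: CalibrationTable,
    patient_offset: np.ndarray,
    noise_draw: np.ndarray,
) -> KneeState:
    """Single-correction convenience wrapper around :func:`apply_corrections`."""
    return apply_corrections(state, [correction], calibration, patient_offset, noise_draw)
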