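"""Random-intercept linear mixed model for per-correction channel effects.

For one outcome channel, every correction event contributes one row with the
observed pre-to-post delta and binary indicators for the correction type(s)
applied (multi-hot for batched events).  The model is

    delta_ij = sum_c beta_c x_cij + u_i + eps_ij,
    u_i ~ N(0, sigma_u^2),   eps_ij ~ N(0, sigma_e^2),

with patient i as random intercept and cell-means coding (no global
intercept): each beta_c is the mean effect of correction c itself, not a
contrast against a reference.  Estimation is REML (ML optional) via
statsmodels MixedLM; significance uses two-sided Wald z tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core import CHANNELS
from .cohort import CohortTable
from .decision import CorrectionType
from .effects import SIGN_LEDGER

__all__ = [
    "ModelFrame",
    "EffectEstimate",
    "VarianceComponents",
    "EstimationError",
    "build_model_frame",
    "fit_random_intercept_lmm",
    "effect_table",
    "summarize_cohort",
    "CohortSummary",
]

logger = logging.getLogger(__name__)

_CORRECTIONS = list(CorrectionType)


class EstimationError(RuntimeError):
    """Raised when the mixed-model fit is impossible on the given frame."""


@dataclass(frozen=True)
class ModelFrame:
    """Long-format design for one outcome channel.

    ``data`` columns: patient_id, delta, plus one 0/1 indicator column per
    correction type (named by the enum value).
    """

    channel: str
    data: pd.DataFrame

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()


@dataclass(frozen=True)
class EffectEstimate:
    correction: CorrectionType
    channel: str
    beta: float
    se: float
    z: float
    p: float
    significant: bool
    n_events: int
    estimable: bool = True

    @classmethod
    def not_estimable(cls, correction: CorrectionType, channel: str) -> "EffectEstimate":
        return cls(
            correction=correction, channel=channel,
            beta=float("nan"), se=float("nan"), z=float("nan"), p=float("nan"),
            significant=False, n_events=0, estimable=False,
        )


@dataclass(frozen=True)
class VarianceComponents:
    sigma_u2: float  # patient random-intercept variance
    sigma_e2: float  # residual variance
    loglik: float


def build_model_frame(table: CohortTable, channel: str) -> ModelFrame:
    """One row per event of each analyzable patient: delta plus indicators.

    Patients flagged as missing are dropped, as are rows with a non-finite
    outcome (per-channel casewise deletion).
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    idx = CHANNELS.index(channel)
    analyzable = table.analyzable_patient_ids
    rows = []
    for e in table.events:
        if e.patient_id not in analyzable:
            continue
        delta = e.post.as_tuple()[idx] - e.pre.as_tuple()[idx]
        if not np.isfinite(delta):
            continue
        row = {"patient_id": e.patient_id, "delta": delta}
        for c in _CORRECTIONS:
            row[c.value] = int(c in e.corrections)
        rows.append(row)
    data = pd.DataFrame(rows, columns=["patient_id", "delta"] + [c.value for c in _CORRECTIONS])
    return ModelFrame(channel=channel, data=data)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        offending = sorted(names[j] for j in piv[rank:])
        raise EstimationError(
            f"fixed-effect design is rank-deficient; collinear columns: {offending}"
        )


def fit_random_intercept_lmm(
    frame: ModelFrame,
    reml: bool = True,
    random_intercept: bool = True,
    alpha: float = 0.05,
) -> tuple[list[EffectEstimate], VarianceComponents]:
    """Fit the per-correction effect model on one channel.

    With ``random_intercept=False`` the patient variance is fixed at zero and
    the model reduces to ordinary least squares on the same design (the
    sigma_u^2 = 0 limit).  Corrections without any event in the frame are
    returned as not-estimable rather than fitted.
    """
    data = frame.data
    if data.empty:
        raise EstimationError("empty model frame: nothing to fit")
    used = [c for c in _CORRECTIONS if data[c.value].sum() > 0]
    if not used:
        raise EstimationError("no correction indicator has any event")
    if random_intercept and data["patient_id"].nunique() < 2:
        raise EstimationError(
            "at least 2 patients are required to estimate a patient random intercept"
        )
    X = data[[c.value for c in used]].to_numpy(dtype=float)
    y = data["delta"].to_numpy(dtype=float)
    _check_design(X, [c.value for c in used])

    if random_intercept:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=data["patient_id"].to_numpy())
            result = model.fit(reml=reml)
        beta = np.asarray(result.fe_params)
        se = np.asarray(result.bse_fe)
        sigma_u2 = float(np.asarray(result.cov_re).ravel()[0])
        sigma_e2 = float(result.scale)
        loglik = float(result.llf)
    else:
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - X.shape[1], 1)
        sigma_e2 = float(resid @ resid) / dof
        cov = sigma_e2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        sigma_u2 = 0.0
        n = len(y)
        loglik = float(-0.5 * n * (np.log(2 * np.pi * max(sigma_e2, 1e-300)) + 1))

    estimates: list[EffectEstimate] = []
    by_used = {c: i for i, c in enumerate(used)}
    for c in _CORRECTIONS:
        if c not in by_used:
            estimates.append(EffectEstimate.not_estimable(c, frame.channel))
            continue
        i = by_used[c]
        b, s = float(beta[i]), float(se[i])
        z = b / s if s > 0 else float("nan")
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
        estimates.append(EffectEstimate(
            correction=c, channel=frame.channel,
            beta=b, se=s, z=z, p=p,
            significant=bool(np.isfinite(p) and p < alpha),
            n_events=int(data[c.value].sum()),
        ))
    components = VarianceComponents(sigma_u2=sigma_u2, sigma_e2=sigma_e2, loglik=loglik)
    logger.info(
        "fit %s: %d events, %d patients, sigma_u2=%.3f, sigma_e2=%.3f",
        frame.channel, frame.n_events, frame.n_patients, sigma_u2, sigma_e2,
    )
    return estimates, components


def effect_table(
    estimates_by_channel: dict[str, list[EffectEstimate]],
) -> pd.DataFrame:
    """Corrections x channels grid of fitted effects with ledger agreement.

    ``ledger_sign_ok`` is True when a cell the sign ledger marks as a
    significant finding was fitted with the matching sign (cells the ledger
    leaves unconstrained are vacuously True); not-estimable cells are False.
    """
    rows = []
    for channel, estimates in estimates_by_channel.items():
        ch_idx = CHANNELS.index(channel)
        for est in estimates:
            ledger_sign = SIGN_LEDGER[est.correction][ch_idx]
            if not est.estimable:
                ok = ledger_sign == 0
            elif ledger_sign == 0:
                ok = True
            else:
                ok = bool(np.sign(est.beta) == ledger_sign)
            rows.append({
                "correction": est.correction.value,
                "channel": channel,
                "beta": est.beta,
                "se": est.se,
                "z": est.z,
                "p": est.p,
                "significant": est.significant,
                "n_events": est.n_events,
                "estimable": est.estimable,
                "ledger_sign": ledger_sign,
                "ledger_sign_ok": ok,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSummary:
    n_cases: int
    n_missing: int
    n_events_total: int
    n_corrections_total: int
    n_corrections_analyzable: int
    mean_corrections_per_analyzable: float
    frequency_ranking: tuple[tuple[str, int], ...]  # most frequent first

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_missing": self.n_missing,
            "n_events_total": self.n_events_total,
            "n_corrections_total": self.n_corrections_total,
            "n_corrections_analyzable": self.n_corrections_analyzable,
            "mean_corrections_per_analyzable": self.mean_corrections_per_analyzable,
            "frequency_ranking": [list(t) for t in self.frequency_ranking],
        }


def summarize_cohort(table: CohortTable) -> CohortSummary:
    """Cohort descriptives: counts, corrections per analyzable patient,
    per-type frequency ranking (over analyzable patients)."""
    analyzable = table.analyzable_patient_ids
    counts: dict[str, int] = {c.value: 0 for c in _CORRECTIONS}
    total = 0
    total_analyzable = 0
    for e in table.events:
        k = len(e.corrections)
        total += k
        if e.patient_id in analyzable:
            total_analyzable += k
            for c in e.corrections:
                counts[c.value] += 1
    n_analyzable = len(analyzable)
    mean = total_analyzable / n_analyzable if n_analyzable else 0.0
    ranking = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return CohortSummary(
        n_cases=len(table.patients),
        n_missing=len(table.missing_patient_ids),
        n_events_total=len(table.events),
        n_corrections_total=total,
        n_corrections_analyzable=total_analyzable,
        mean_corrections_per_analyzable=mean,
        frequency_ranking=ranking,
    )
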