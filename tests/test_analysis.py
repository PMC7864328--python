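import numpy as np
import pandas as pd
import pytest

from kneebalance import (
    CohortConfig,
    CorrectionType,
    EstimationError,
    ModelFrame,
    build_model_frame,
    effect_table,
    fit_random_intercept_lmm,
    simulate_cohort,
    summarize_cohort,
)
from kneebalance.cohort import CohortTable, CorrectionEvent, Patient
from kneebalance.core import CHANNELS, KneeState
from kneebalance.effects import SIGN_LEDGER

CVALS = [c.value for c in CorrectionType]


def make_frame(patient_ids, corr_idx, deltas, channel="m10"):
    rows = []
    for pid, ci, d in zip(patient_ids, corr_idx, deltas):
        row = {"patient_id": pid, "delta": d}
        for j, cv in enumerate(CVALS):
            row[cv] = int(j == ci)
        rows.append(row)
    return ModelFrame(channel, pd.DataFrame(rows, columns=["patient_id", "delta"] + CVALS))


def tiny_cohort():
    patients = [Patient(i, 70.0, "M", np.zeros(6)) for i in (1, 2, 3)]
    ev = [
        CorrectionEvent(1, 1, (CorrectionType.MCL_PIECRUST,),
                        KneeState(45, 22, 45, 22, -4, 0), KneeState(38, 24, 36, 25, -2.5, 0)),
        CorrectionEvent(2, 1, (CorrectionType.ARCUATE_RELEASE, CorrectionType.POPLITEUS_RELEASE),
                        KneeState(22, 45, 22, 45, 4, 0), KneeState(22, 33, 22, 36, 1.5, -1)),
        CorrectionEvent(3, 1, (CorrectionType.MCL_PIECRUST,),
                        KneeState(46, 24, 44, 22, -5, 0), KneeState(39, 26, 35, 24, -3.5, 0)),
    ]
    return CohortTable(patients, ev, frozenset())


def test_build_model_frame_deltas_and_indicators():
    table = tiny_cohort()
    frame = build_model_frame(table, "m10")
    assert frame.n_events == 3
    assert frame.data.loc[0, "delta"] == pytest.approx(38 - 45)
    assert frame.data.loc[0, "MCL_PIECRUST"] == 1
    # batched event: two indicators on one row
    row = frame.data.loc[1]
    assert row["ARCUATE_RELEASE"] == 1 and row["POPLITEUS_RELEASE"] == 1
    assert row[CVALS].sum() == 2


def test_build_model_frame_drops_missing_patients():
    table = tiny_cohort()
    flagged = CohortTable(table.patients, table.events, frozenset({1}))
    frame = build_model_frame(flagged, "m10")
    assert frame.n_events == 2
    assert 1 not in set(frame.data["patient_id"])


def test_build_model_frame_unknown_channel():
    with pytest.raises(ValueError):
        build_model_frame(tiny_cohort(), "torsion")


def test_empty_frame_refused():
    cfg = CohortConfig(n=3, n_missing=0)
    empty = CohortTable([Patient(1, 70.0, "F", np.zeros(6))], [], frozenset())
    frame = build_model_frame(empty, "m10")
    with pytest.raises(EstimationError):
        fit_random_intercept_lmm(frame)


def test_single_patient_refused_for_random_intercept():
    frame = make_frame([1, 1, 1, 1], [0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0])
    with pytest.raises(EstimationError):
        fit_random_intercept_lmm(frame)


def test_collinear_design_reports_offending_columns():
    # duplicate a correction column by giving every event both corrections
    rows = []
    rng = np.random.default_rng(0)
    for pid in range(1, 30):
        row = {"patient_id": pid, "delta": float(rng.normal())}
        for cv in CVALS:
            row[cv] = int(cv in ("ARCUATE_RELEASE", "POPLITEUS_RELEASE"))
        rows.append(row)
    frame = ModelFrame("m10", pd.DataFrame(rows, columns=["patient_id", "delta"] + CVALS))
    with pytest.raises(EstimationError, match="collinear"):
        fit_random_intercept_lmm(frame)


def test_constant_zero_outcome_gives_zero_insignificant_beta():
    frame = make_frame(list(range(1, 41)), [2] * 40, [0.0] * 40)
    ests, vc = fit_random_intercept_lmm(frame)
    e = next(x for x in ests if x.correction is CorrectionType.POPLITEUS_RELEASE)
    assert e.beta == pytest.approx(0.0, abs=1e-10)
    assert not e.significant
    assert vc.sigma_u2 >= 0 and vc.sigma_e2 >= 0


def test_reml_betas_equal_group_means_with_one_event_per_patient():
    """With one event per patient the GLS weighting is a scalar, so the fitted
    coefficients equal the per-correction sample means exactly."""
    rng = np.random.default_rng(42)
    n = 160
    ci = rng.integers(0, 8, n)
    y = np.array([(-3.0 + j) for j in ci]) + rng.normal(0, 2, n)
    frame = make_frame(np.arange(1, n + 1), ci, y)
    ests, _ = fit_random_intercept_lmm(frame)
    for j, c in enumerate(CorrectionType):
        est = next(x for x in ests if x.correction is c)
        if est.estimable:
            assert est.beta == pytest.approx(y[ci == j].mean(), abs=1e-6)


def test_zero_variance_limit_reproduces_ols_cell_means():
    """Disabling the random intercept (the sigma_u^2 = 0 limit) reproduces
    ordinary least-squares cell means to 1e-6."""
    rng = np.random.default_rng(7)
    n = 300
    pids = rng.integers(1, 60, n)
    ci = rng.integers(0, 8, n)
    y = np.array([float(2 * j - 5) for j in ci]) + rng.normal(0, 3, n)
    frame = make_frame(pids, ci, y)
    ests, vc = fit_random_intercept_lmm(frame, random_intercept=False)
    assert vc.sigma_u2 == 0.0
    for j, c in enumerate(CorrectionType):
        est = next(x for x in ests if x.correction is c)
        if est.estimable:
            assert est.beta == pytest.approx(y[ci == j].mean(), abs=1e-6)


def test_estimates_invariant_to_relabeling_and_order():
    rng = np.random.default_rng(11)
    n = 240
    pids = rng.integers(1, 50, n)
    ci = rng.integers(0, 8, n)
    y = rng.normal(0, 2, n) + pids * 0.01
    frame = make_frame(pids, ci, y)
    base, _ = fit_random_intercept_lmm(frame)

    perm = rng.permutation(n)
    relabel = {pid: 1000 - pid for pid in np.unique(pids)}
    shuffled = make_frame([relabel[p] for p in pids[perm]], ci[perm], y[perm])
    other, _ = fit_random_intercept_lmm(shuffled)
    for a, b in zip(base, other):
        if a.estimable:
            assert a.beta == pytest.approx(b.beta, abs=1e-6)
            assert a.se == pytest.approx(b.se, rel=1e-4)


def test_absent_correction_marked_not_estimable():
    rng = np.random.default_rng(5)
    n = 60
    frame = make_frame(
        np.arange(1, n + 1), rng.integers(0, 2, n), rng.normal(0, 1, n)
    )
    ests, _ = fit_random_intercept_lmm(frame)
    absent = next(x for x in ests if x.correction is CorrectionType.TIBIA_RECUT)
    assert not absent.estimable and not absent.significant


def test_effect_table_grid_and_ledger_marks(default_cohort):
    fits = {}
    for ch in CHANNELS:
        ests, _ = fit_random_intercept_lmm(build_model_frame(default_cohort, ch))
        fits[ch] = ests
    grid = effect_table(fits)
    assert len(grid) == 48
    sig = grid[grid["significant"] & (grid["ledger_sign"] != 0)]
    assert sig["ledger_sign_ok"].all(), sig[~sig["ledger_sign_ok"]]
    # the insert-thickness effect on extension deficit is near +2.5 degrees
    cell = grid[(grid["correction"] == "INSERT_UP_2MM") & (grid["channel"] == "ext_deficit")]
    assert cell["beta"].iloc[0] == pytest.approx(2.5, abs=0.3)
    assert cell["significant"].iloc[0]


def test_summarize_cohort_arithmetic():
    table = tiny_cohort()
    s = summarize_cohort(table)
    assert s.n_cases == 3 and s.n_missing == 0
    assert s.n_events_total == 3
    assert s.n_corrections_total == 4  # one batched event counts twice
    assert s.mean_corrections_per_analyzable == pytest.approx(4 / 3)
    assert s.frequency_ranking[0] == ("MCL_PIECRUST", 2)


def test_summarize_empty_cohort_no_division_error():
    empty = CohortTable([], [], frozenset())
    s = summarize_cohort(empty)
    assert s.n_cases == 0 and s.mean_corrections_per_analyzable == 0.0


def test_default_cohort_most_common_corrections(default_cohort):
    """Pie-crusting the MCL and increasing the insert thickness are the two
    most frequent corrections under the default study conditions."""
    ranking = summarize_cohort(default_cohort).frequency_ranking
    top_two = {ranking[0][0], ranking[1][0]}
    assert top_two == {"MCL_PIECRUST", "INSERT_UP_2MM"}
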