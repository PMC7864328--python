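import copy

import numpy as np
import pytest

from kneebalance import (
    CohortConfig,
    ConfigError,
    CorrectionType,
    Demographics,
    KneeState,
    Thresholds,
    assess_balance,
    generate_initial_state,
    generate_patients,
    read_cohort_csv,
    recommend,
    simulate_case,
    simulate_cohort,
    write_cohort_csv,
)
from kneebalance.cohort import CohortParseError
from kneebalance.config import default_config_dict
from kneebalance.effects import CalibrationTable


def default_phenotypes():
    return copy.deepcopy(default_config_dict()["cohort"]["phenotypes"])


def single_phenotype(name):
    ph = default_phenotypes()
    for k in ph:
        ph[k]["weight"] = 1.0 if k == name else 0.0
    return ph


# --- patients ---------------------------------------------------------------

def test_generate_patients_demographics():
    patients = generate_patients(479, seed=11)
    ages = np.array([p.age for p in patients])
    assert len(patients) == 479
    assert ages.min() >= 39 and ages.max() <= 96
    d = Demographics()
    se = d.age_sd / np.sqrt(479)
    assert abs(ages.mean() - d.age_mean) < 3 * se
    male = np.mean([p.sex == "M" for p in patients])
    assert abs(male - d.male_fraction) < 3 * np.sqrt(0.25 / 479)


def test_generate_patients_reproducible_and_validated():
    a = generate_patients(25, seed=3)
    b = generate_patients(25, seed=3)
    assert a == b
    with pytest.raises(ValueError):
        generate_patients(0, seed=3)
    solo = generate_patients(1, seed=5, sigma_patient=np.zeros(6))
    assert np.all(solo[0].random_offset == 0)


# --- initial states ---------------------------------------------------------

def test_balanced_phenotype_is_accepted_at_the_outset(thresholds, rng):
    ph = single_phenotype("balanced")
    for _ in range(50):
        state = generate_initial_state(ph, rng)
        assert assess_balance(state, thresholds).balanced
        assert recommend(state, thresholds).is_accept


def test_medial_tight_phenotype_distribution(thresholds, rng):
    ph = single_phenotype("medial_tight_varus")
    states = [generate_initial_state(ph, rng) for _ in range(1000)]
    assert np.mean([s.m10 > 40 for s in states]) > 0.99
    assert np.mean([s.coronal < -3 for s in states]) > 0.99


def test_invalid_mixture_weights_rejected(rng):
    ph = default_phenotypes()
    next(iter(ph.values()))["weight"] += 0.2
    with pytest.raises(ConfigError):
        generate_initial_state(ph, rng)


# --- closed-loop cases ------------------------------------------------------

def test_already_acceptable_state_yields_no_events(thresholds, calibration, rng):
    patient = generate_patients(1, seed=1)[0]
    state = KneeState(25, 24, 25, 24, -1, 0)
    assert simulate_case(patient, state, thresholds, calibration, rng) == []


def test_hyperextension_resolved_by_one_insert_at_zero_noise(
    thresholds, noiseless_calibration, rng
):
    patient = generate_patients(1, seed=1, sigma_patient=np.zeros(6))[0]
    state = KneeState(25, 24, 25, 24, -1, -4)
    events = simulate_case(patient, state, thresholds, noiseless_calibration, rng)
    assert len(events) == 1
    assert events[0].corrections == (CorrectionType.INSERT_UP_2MM,)
    assert events[0].post.ext_deficit == pytest.approx(-4 + 2.5)


def test_correction_cap_enforced_under_zero_progress(thresholds, calibration, rng):
    """A pathological all-zero calibration makes no progress; the loop must
    stop at the cap rather than spin."""
    zero = CalibrationTable(
        profiles={
            c: type(p)(correction=c, mean_delta=np.zeros(6), significant=np.zeros(6, bool))
            for c, p in calibration.profiles.items()
        },
        sigma_patient=np.zeros(6),
        sigma_resid=np.zeros(6),
    )
    patient = generate_patients(1, seed=1, sigma_patient=np.zeros(6))[0]
    state = KneeState(48, 22, 46, 20, -5, 0)
    events = simulate_case(patient, state, thresholds, zero, rng, max_corrections=7)
    assert len(events) == 7
    assert [e.sequence_index for e in events] == list(range(1, 8))


def test_batched_events_contain_distinct_compatible_corrections(
    thresholds, calibration
):
    cfg = CohortConfig(n=60, n_missing=0, batch_prob=1.0)
    table = simulate_cohort(cfg, seed=9)
    multi = [e for e in table.events if len(e.corrections) > 1]
    assert multi, "forced batching should produce multi-correction events"
    for e in multi:
        assert len(set(e.corrections)) == len(e.corrections)


def test_every_zero_noise_case_terminates_within_cap(thresholds, noiseless_calibration):
    """Progress property: with sign-correct mean effects and no noise, the
    closed loop reaches acceptance within the correction cap for every case."""
    cfg = CohortConfig(n=400, n_missing=0)
    table = simulate_cohort(cfg, seed=321, calibration=noiseless_calibration)
    for p in table.patients:
        events = table.events_for(p.id)
        assert len(events) <= 7
        if events:
            final = events[-1].post
            history = {c for e in events for c in e.corrections}
            assert recommend(final, thresholds, history).is_accept, (
                p.id, events[0].pre, final,
            )


# --- cohort-level -----------------------------------------------------------

def test_simulated_cohort_counts_and_missingness(default_cohort):
    assert len(default_cohort.patients) == 479
    assert len(default_cohort.missing_patient_ids) == 21
    per_patient = [len(default_cohort.events_for(p.id)) for p in default_cohort.patients]
    assert min(per_patient) >= 0 and max(per_patient) <= 7


def test_zero_event_configuration(thresholds):
    cfg = CohortConfig(n=10, n_missing=0, phenotypes=single_phenotype("balanced"))
    table = simulate_cohort(cfg, seed=4)
    assert table.events == ()


def test_n_missing_must_be_below_n():
    with pytest.raises(ConfigError):
        CohortConfig(n=10, n_missing=10)


def test_cohort_csv_round_trip_and_determinism(tmp_path):
    cfg = CohortConfig(n=40, n_missing=3)
    table = simulate_cohort(cfg, seed=8)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort_csv(table, p1)
    back = read_cohort_csv(p1)
    assert back == table
    # identical seed, byte-identical file
    write_cohort_csv(simulate_cohort(cfg, seed=8), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_cohort_csv_unknown_label_reports_row(tmp_path):
    cfg = CohortConfig(n=5, n_missing=0)
    table = simulate_cohort(cfg, seed=8)
    path = tmp_path / "c.csv"
    write_cohort_csv(table, path)
    text = path.read_text().replace("MCL_PIECRUST", "LCL_RELEASE", 1)
    path.write_text(text)
    with pytest.raises(CohortParseError, match=r"row \d+"):
        read_cohort_csv(path)


def test_cohort_csv_patients_only(tmp_path):
    cfg = CohortConfig(n=5, n_missing=0, phenotypes=single_phenotype("balanced"))
    table = simulate_cohort(cfg, seed=4)
    path = tmp_path / "empty_events.csv"
    write_cohort_csv(table, path)
    back = read_cohort_csv(path)
    assert back == table and back.events == ()
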