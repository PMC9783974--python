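"""Cohort construction: symptom mapping, filters, covariates, outcomes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emscausal import generate_analysis_table
from emscausal.cohort import (
    CONTRAINDICATION_KEYWORDS,
    DataIntegrityError,
    ExclusionLog,
    apply_eligibility,
    build_cohort,
    categorize_symptom,
    derive_covariates,
    derive_outcomes,
    detect_asa_contraindication,
    select_asa_population,
)
from emscausal.synthetic import RegistryBundle


# ---------------------------------------------------------------------------
# hand-written fixture bundle: 12 calls, 5 violating distinct filters
# ---------------------------------------------------------------------------

T0 = pd.Timestamp("2016-05-01 10:00:00")


def hand_bundle() -> RegistryBundle:
    def call(cid, pid, ts, criterion, service, dispatch, age, sex="male",
             ethnicity="danish", education="intermediate", **flags):
        base = {"nursing_home": 0, "terminal": 0, "dead_at_call": 0, "unconscious": 0}
        base.update(flags)
        return {
            "call_id": cid, "person_id": pid, "timestamp": ts,
            "criterion": criterion, "service": service, "dispatch_type": dispatch,
            **base, "age": age, "sex": sex, "ethnicity": ethnicity,
            "education": education,
        }

    hours = pd.Timedelta(hours=1)
    days = pd.Timedelta(days=1)
    calls = pd.DataFrame([
        # seven eligible calls
        call("C01", "P01", T0, "chest pain", "112", "emergency_ambulance", 70.0),
        call("C02", "P02", T0 + 2 * hours, "breathing problems", "1813", "home_visit", 55.0),
        call("C03", "P03", T0 + 3 * hours, "chest discomfort", "112", "emergency_ambulance", 64.0),
        call("C04", "P04", T0 + 4 * hours, "abdominal pain", "112", "emergency_ambulance", 81.0),
        call("C05", "P05", T0 + 5 * hours, "dizziness", "1813", "self_transport", 47.0,
             education=""),
        call("C06", "P06", T0 + 6 * hours, "chest pain", "112", "emergency_ambulance", 59.0),
        call("C07", "P07", T0 + 7 * hours, "trauma", "1813", "emergency_ambulance", 73.0),
        # five violations, one filter each
        call("C08", "P08", T0 + 8 * hours, "chest pain", "112", "emergency_ambulance", 25.0),
        call("C09", "P09", T0 + 9 * hours, "chest pain", "112", "emergency_ambulance", 66.0),  # 25 h
        call("C10", "P10", T0 + 10 * hours, "chest pain", "112", "emergency_ambulance", 77.0,
             nursing_home=1),
        call("C11", "P11", T0 + 11 * hours, "chest pain", "112", "emergency_ambulance", 58.0,
             unconscious=1),
        call("C12", "P12", T0 + 12 * hours, "", "1813", "home_visit", 69.0),
    ])

    def adm(pid, offset_hours, code="I21.4", stay_days=4):
        a = T0 + pd.Timedelta(hours=offset_hours)
        return {"person_id": pid, "icd10": code, "admission_datetime": a,
                "discharge_date": (a + stay_days * days).normalize(), "primary": 1}

    diagnoses = [
        adm("P01", 2, code="I21.0"),
        adm("P02", 5),
        adm("P03", 6, code="I21.9"),
        adm("P04", 7),
        adm("P05", 8),
        adm("P06", 9, code="I21.1"),
        adm("P07", 10),
        adm("P08", 11),
        adm("P09", 9 + 25),  # 25 h after the call at T0+9h
        adm("P10", 13),
        adm("P11", 14),
        adm("P12", 15),
        # heart failure coded during P03's index admission: must not count
        {"person_id": "P03", "icd10": "I50.9", "admission_datetime": T0 + 6 * hours,
         "discharge_date": (T0 + 6 * hours + 4 * days).normalize(), "primary": 0},
        # P06 re-infarction 100 days after diagnosis
        {"person_id": "P06", "icd10": "I21.9",
         "admission_datetime": T0 + 9 * hours + 100 * days,
         "discharge_date": (T0 + 9 * hours + 103 * days).normalize(), "primary": 1},
        # P07 prior MI two years back
        {"person_id": "P07", "icd10": "I21.9",
         "admission_datetime": T0 - 730 * days,
         "discharge_date": (T0 - 729 * days).normalize(), "primary": 1},
    ]
    diagnoses = pd.DataFrame(diagnoses)

    prescriptions = pd.DataFrame([
        # P04: two distinct antihypertensive classes -> hypertension
        {"person_id": "P04", "atc": "C03CA01", "claim_date": (T0 - 30 * days).normalize()},
        {"person_id": "P04", "atc": "C07AB02", "claim_date": (T0 - 100 * days).normalize()},
        # P05: two claims of the same class (C09) -> no hypertension
        {"person_id": "P05", "atc": "C09AA05", "claim_date": (T0 - 20 * days).normalize()},
        {"person_id": "P05", "atc": "C09CA01", "claim_date": (T0 - 90 * days).normalize()},
        # P07: opioid claim outside the 180-day window
        {"person_id": "P07", "atc": "N02AA01", "claim_date": (T0 - 200 * days).normalize()},
    ])

    prehospital = pd.DataFrame([
        {"call_id": "C01", "medicine": "acetylsalicylic acid 300 mg", "note": "given oxygen",
         "allergy_flag": 0},
        {"call_id": "C03", "medicine": "", "note": "suspected GI bleeding", "allergy_flag": 0},
        {"call_id": "C04", "medicine": "morphine 5 mg iv", "note": "Ulcer hx", "allergy_flag": 0},
        {"call_id": "C06", "medicine": "acetylsalicylic acid 300 mg", "note": "bp 140/90",
         "allergy_flag": 0},
        {"call_id": "C07", "medicine": "", "note": "pt pale", "allergy_flag": 0},
    ])

    vitals = pd.DataFrame(
        {
            "person_id": [f"P{i:02d}" for i in range(1, 13)],
            "death_date": [
                (T0 + 2 * hours + 10 * days).normalize(),  # P01: day 10
                (T0 + 5 * hours + 31 * days).normalize(),  # P02: day 31
                pd.NaT, pd.NaT, pd.NaT, pd.NaT, pd.NaT, pd.NaT, pd.NaT,
                pd.NaT, pd.NaT, pd.NaT,
            ],
        }
    )
    return RegistryBundle(calls, prehospital, diagnoses, prescriptions, vitals)


@pytest.fixture()
def bundle12() -> RegistryBundle:
    return hand_bundle()


# ---------------------------------------------------------------------------
# symptom dichotomization and the contraindication screen
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "criterion, expected",
    [
        ("chest pain", "chest"),
        ("Chest Pain", "chest"),
        ("breathing problems", "nonchest"),
        ("abdominal pain", "nonchest"),
        ("unclear problem", "nonchest"),
        ("", "exclude"),
        ("unclear notification", "exclude"),
        ("some novel label", "exclude"),
        (None, "exclude"),
    ],
)
def test_categorize_symptom(criterion, expected):
    assert categorize_symptom(criterion) == expected


@pytest.mark.parametrize(
    "text, allergy, expected",
    [
        ("suspected GI bleeding", 0, 1),
        ("", 0, 0),
        ("Ulcer hx", 0, 1),
        ("BLOOD in vomit", 0, 1),
        ("aortic ANEURYSM", 0, 1),
        ("pt stable, no complaints", 0, 0),
        ("", 1, 1),
        (None, 0, 0),
    ],
)
def test_detect_asa_contraindication(text, allergy, expected):
    assert detect_asa_contraindication(text, allergy) == expected


@settings(max_examples=60, derandomize=True)
@given(st.text(max_size=40), st.integers(min_value=0, max_value=1))
def test_contraindication_keyword_property(text, allergy):
    """The screen fires exactly on allergy or a case-insensitive keyword hit."""
    expected = int(
        allergy == 1 or any(k in text.lower() for k in CONTRAINDICATION_KEYWORDS)
    )
    assert detect_asa_contraindication(text, allergy) == expected


# ---------------------------------------------------------------------------
# eligibility and the exclusion log
# ---------------------------------------------------------------------------

def test_hand_fixture_exclusions(bundle12):
    eligible, log = apply_eligibility(bundle12)
    assert len(eligible) == 7
    removed = dict((name, r) for name, r, _ in log.steps)
    assert removed["age under 30"] == 1
    assert removed["no confirmed MI within 24 h"] == 1
    assert removed["nursing home"] == 1
    assert removed["unconscious"] == 1
    assert removed["missing/non-informative criterion"] == 1
    assert removed["terminal/palliative"] == 0
    assert removed["suspected dead at call"] == 0
    assert log.final_remaining == 7
    assert log.total_removed == len(bundle12.calls) - 7


def test_exclusion_log_counts_reconcile(small_registry):
    _, bundle = small_registry
    cohort, log = build_cohort(bundle)
    assert log.final_remaining == len(cohort)
    assert log.total_removed == len(bundle.calls) - len(cohort)
    remaining = [rem for _, _, rem in log.steps]
    assert remaining == sorted(remaining, reverse=True)


def test_exclusion_log_rejects_inconsistent_counts():
    log = ExclusionLog()
    log.add("start", 0, 100)
    with pytest.raises(ValueError):
        log.add("bad", -1, 99)
    with pytest.raises(ValueError):
        log.add("bad", 1, 120)


def test_missing_vitals_row_is_integrity_error(bundle12):
    bundle12.vitals.drop(index=0, inplace=True)
    with pytest.raises(DataIntegrityError):
        apply_eligibility(bundle12)


def test_row_shuffle_leaves_cohort_invariant(bundle12):
    cohort_a, log_a = build_cohort(bundle12)
    shuffled = RegistryBundle(
        **{
            name: getattr(bundle12, name)
            .sample(frac=1.0, random_state=5)
            .reset_index(drop=True)
            for name in RegistryBundle.TABLES
        }
    )
    cohort_b, log_b = build_cohort(shuffled)
    key = cohort_a.columns.tolist()
    a = cohort_a.sort_values("call_id").reset_index(drop=True)
    b = cohort_b.sort_values("call_id").reset_index(drop=True)[key]
    pd.testing.assert_frame_equal(a, b)
    assert log_a.total_removed == log_b.total_removed


# ---------------------------------------------------------------------------
# covariates, exposures, outcomes on the hand fixture
# ---------------------------------------------------------------------------

def test_hand_fixture_records(bundle12):
    cohort, _ = build_cohort(bundle12)
    rec = cohort.set_index("call_id")

    assert rec.loc["C01", "symptom_group"] == "chest"
    assert rec.loc["C01", "amb"] == 1 and rec.loc["C01", "asa"] == 1
    assert (rec.loc["C01", ["y30", "y1yr"]] == [1, 1]).all()

    # death at day 31: outside the 30-day window, inside the 1-year window
    assert rec.loc["C02", "amb"] == 0 and np.isnan(rec.loc["C02", "asa"])
    assert (rec.loc["C02", ["y30", "y1yr"]] == [0, 1]).all()

    # heart failure coded only during the index admission does not count
    assert rec.loc["C03", "asa_contraindicated"] == 1
    assert (rec.loc["C03", ["y30", "y1yr"]] == [0, 0]).all()
    assert rec.loc["C03", "infarct_type"] == "other"

    assert rec.loc["C04", "hypertension"] == 1
    assert rec.loc["C04", "asa_contraindicated"] == 1  # "Ulcer hx"
    assert rec.loc["C05", "hypertension"] == 0  # same class twice
    assert rec.loc["C05", "education"] == "basic"  # missing recoded

    # re-infarction at day 100 drives the combined outcome
    assert (rec.loc["C06", ["y30", "y1yr"]] == [0, 1]).all()
    assert rec.loc["C06", "infarct_type"] == "STEMI"

    assert rec.loc["C07", "prev_mi"] == 1
    assert rec.loc["C07", "opioid"] == 0  # claim outside the 180-day window
    assert rec.loc["C07", "symptom_group"] == "nonchest"


def test_death_before_diagnosis_raises(bundle12):
    bundle12.vitals.loc[
        bundle12.vitals["person_id"] == "P01", "death_date"
    ] = (T0 - pd.Timedelta(days=3)).normalize()
    eligible, _ = apply_eligibility(bundle12)
    with pytest.raises(DataIntegrityError):
        derive_outcomes(bundle12, eligible)


def test_all_flagged_calls_yield_empty_cohort(bundle12):
    bundle12.calls["unconscious"] = 1
    cohort, log = build_cohort(bundle12)
    assert cohort.empty
    assert log.total_removed == len(bundle12.calls)


def test_select_asa_population(bundle12):
    cohort, _ = build_cohort(bundle12)
    asa_pop = select_asa_population(cohort)
    # C01, C06, C07 dispatched without contraindication; C03/C04 contraindicated
    assert set(asa_pop["call_id"]) == {"C01", "C06", "C07"}
    all_in = cohort[(cohort["amb"] == 1) & (cohort["asa_contraindicated"] == 0)]
    pd.testing.assert_frame_equal(
        asa_pop, all_in.reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# consistency with the generator's latent records
# ---------------------------------------------------------------------------

def test_cohort_reconstructs_latent_records(small_registry):
    """Building the cohort from raw tables recovers the latent analysis table."""
    cfg, bundle = small_registry
    cohort, _ = build_cohort(bundle)
    latent = generate_analysis_table(cfg, seed=20240)
    assert len(cohort) == len(latent) == cfg.n_calls

    cols = [
        "symptom_group", "amb", "asa_contraindicated", "y30", "y1yr", "male",
        "service_112", "t2d", "hypertension", "opioid", "nsaid", "ihd",
        "prev_mi", "heart_failure", "cancer", "renal", "copd", "afib",
        "education", "infarct_type", "immigrant",
    ]
    a = cohort[cols].assign(asa=cohort["asa"].fillna(-1.0), age=cohort["age"].round(1))
    b = latent[cols].assign(asa=latent["asa"].fillna(-1.0), age=latent["age"].round(1))
    key = cols + ["asa", "age"]
    a = a.sort_values(key).reset_index(drop=True).astype(str)
    b = b.sort_values(key).reset_index(drop=True).astype(str)
    pd.testing.assert_frame_equal(a, b)


def test_outcome_ordering_invariant(small_registry):
    _, bundle = small_registry
    cohort, _ = build_cohort(bundle)
    assert (cohort["y30"] <= cohort["y1yr"]).all()
    assert (cohort["age"] >= 30).all()
    assert cohort.loc[cohort["amb"] == 0, "asa"].isna().all()
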