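"""Cohort construction from raw registry tables.

Transforms the five registry tables into one analysis record per eligible
call: symptom dichotomization from the dispatch criterion, eligibility
filtering with a logged exclusion flow, covariate derivation from diagnosis
and prescription look-backs, ASA contraindication screening of the
prehospital record, and outcome construction (30-day mortality and the
1-year combined outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CHEST_CRITERIA, NONCHEST_CRITERIA, RegistryBundle

#: ASA contraindication keywords screened in the prehospital free text
CONTRAINDICATION_KEYWORDS = ("blood", "bleeding", "aneurysm", "ulcer")

#: ICD-10 prefixes defining diagnosis-based comorbidities (5-year look-back)
ICD_PREFIXES = {
    "ihd": ("I20", "I24", "I25"),
    "prev_mi": ("I21", "I22"),
    "heart_failure": ("I50",),
    "cancer": ("C",),
    "renal": ("N18", "N19"),
    "copd": ("J44",),
    "afib": ("I48",),
}

#: ATC prefixes defining prescription-based indicators (180-day look-back)
ATC_PREFIXES = {"t2d": ("A10",), "opioid": ("N02A",), "nsaid": ("M01A",)}
ANTIHYPERTENSIVE_ATC_CLASSES = ("C03", "C07", "C08", "C09")

DIAGNOSIS_LOOKBACK_DAYS = 5 * 365
PRESCRIPTION_LOOKBACK_DAYS = 180
MI_ADMISSION_WINDOW_HOURS = 24.0
MIN_AGE = 30.0

_FLAG_FILTERS = (
    ("nursing_home", "nursing home"),
    ("terminal", "terminal/palliative"),
    ("dead_at_call", "suspected dead at call"),
    ("unconscious", "unconscious"),
)


class DataIntegrityError(ValueError):
    """Raised when the registry tables violate their contract."""


@dataclass
class ExclusionLog:
    """Ordered record of the eligibility filters, Fig.-1 style."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, removed: int, remaining: int) -> None:
        if removed < 0 or remaining < 0:
            raise ValueError("exclusion counts must be non-negative")
        if self.steps and remaining > self.steps[-1][2]:
            raise ValueError("remaining counts must be non-increasing")
        self.steps.append((name, int(removed), int(remaining)))

    @property
    def total_removed(self) -> int:
        return sum(r for _, r, _ in self.steps)

    @property
    def final_remaining(self) -> int:
        return self.steps[-1][2] if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["filter", "calls_removed", "calls_remaining"]
        )


def categorize_symptom(criterion: str) -> str:
    """Map a dispatch criterion to ``chest``/``nonchest``/``exclude``.

    Empty, non-informative and unknown criteria are excluded (unknown
    strings carry no information about the patient's presentation).
    """
    if criterion is None:
        return "exclude"
    c = str(criterion).strip().lower()
    if not c:
        return "exclude"
    if c in CHEST_CRITERIA:
        return "chest"
    if c in NONCHEST_CRITERIA:
        return "nonchest"
    return "exclude"


def detect_asa_contraindication(free_text: str, allergy_flag: int) -> int:
    """Keyword/allergy screen of the electronic prehospital record.

    Returns 1 iff the allergy flag is set or the free text contains any of
    the contraindication keywords as a case-insensitive substring.
    """
    if int(allergy_flag) == 1:
        return 1
    text = ("" if free_text is None else str(free_text)).lower()
    return int(any(k in text for k in CONTRAINDICATION_KEYWORDS))


def _index_admissions(calls: pd.DataFrame, diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Earliest primary I21 admission within (call, call + 24 h] per call."""
    mi = diagnoses[
        (diagnoses["primary"] == 1)
        & diagnoses["icd10"].astype(str).str.startswith("I21")
    ][["person_id", "icd10", "admission_datetime", "discharge_date"]]
    merged = calls[["call_id", "person_id", "timestamp"]].merge(
        mi, on="person_id", how="left"
    )
    delta = merged["admission_datetime"] - merged["timestamp"]
    ok = (delta > pd.Timedelta(0)) & (
        delta <= pd.Timedelta(hours=MI_ADMISSION_WINDOW_HOURS)
    )
    merged = merged[ok.fillna(False)]
    merged = merged.sort_values(["call_id", "admission_datetime"], kind="mergesort")
    return merged.drop_duplicates("call_id").set_index("call_id")


def apply_eligibility(bundle: RegistryBundle) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the eligibility filters in flowchart order.

    Returns the eligible calls (joined with their index MI admission) and
    the exclusion log.  Filter order: age, confirmed MI within 24 h, the
    situational flags, then non-informative criteria.
    """
    calls = bundle.calls
    log = ExclusionLog()
    known = set(bundle.vitals["person_id"])
    missing = set(calls["person_id"]) - known
    if missing:
        raise DataIntegrityError(
            f"{len(missing)} persons in calls have no vital-status row"
        )

    current = calls
    log.add("calls considered", 0, len(current))

    keep = current["age"].astype(float) >= MIN_AGE
    log.add("age under 30", int((~keep).sum()), int(keep.sum()))
    current = current[keep]

    admissions = _index_admissions(current, bundle.diagnoses)
    keep = current["call_id"].isin(admissions.index)
    log.add("no confirmed MI within 24 h", int((~keep).sum()), int(keep.sum()))
    current = current[keep]

    for col, label in _FLAG_FILTERS:
        keep = current[col].astype(int) == 0
        log.add(label, int((~keep).sum()), int(keep.sum()))
        current = current[keep]

    group = current["criterion"].map(categorize_symptom)
    keep = group != "exclude"
    log.add("missing/non-informative criterion", int((~keep).sum()), int(keep.sum()))
    current = current[keep].copy()
    current["symptom_group"] = group[keep]

    adm = admissions.loc[current["call_id"]]
    current = current.assign(
        mi_code=adm["icd10"].to_numpy(),
        admission_datetime=adm["admission_datetime"].to_numpy(),
        discharge_date=adm["discharge_date"].to_numpy(),
    )
    return current.reset_index(drop=True), log


def _lookback_indicators(
    eligible: pd.DataFrame, events: pd.DataFrame, date_col: str, window_days: int
) -> pd.DataFrame:
    """Join events to calls restricted to [call - window, call)."""
    merged = eligible[["call_id", "person_id", "timestamp"]].merge(
        events, on="person_id", how="inner"
    )
    delta = merged["timestamp"] - merged[date_col]
    ok = (delta > pd.Timedelta(0)) & (delta <= pd.Timedelta(days=window_days))
    return merged[ok]


def derive_covariates(bundle: RegistryBundle, eligible: pd.DataFrame) -> pd.DataFrame:
    """Derive the adjustment covariates for eligible calls.

    Diagnosis-based comorbidities use primary or secondary ICD-10 codes in
    the 5 years before the call; prescription indicators use claims within
    180 days; hypertension requires claims from at least two distinct
    antihypertensive drug classes in that window.  Missing education is
    recoded to basic, missing ethnicity to immigrant/descendant.
    """
    out = eligible[["call_id"]].copy()
    out["age"] = eligible["age"].astype(float).to_numpy()
    out["male"] = (eligible["sex"].astype(str) == "male").astype(np.int8).to_numpy()
    out["service_112"] = (
        (eligible["service"].astype(str) == "112").astype(np.int8).to_numpy()
    )
    education = eligible["education"].astype(str).replace("", "basic")
    out["education"] = education.fillna("basic").to_numpy()
    ethnicity = eligible["ethnicity"].astype(str).replace("", "immigrant")
    out["immigrant"] = (ethnicity != "danish").astype(np.int8).to_numpy()

    diag = bundle.diagnoses[["person_id", "icd10", "admission_datetime"]]
    hist = _lookback_indicators(
        eligible, diag, "admission_datetime", DIAGNOSIS_LOOKBACK_DAYS
    )
    codes = hist["icd10"].astype(str)
    for name, prefixes in ICD_PREFIXES.items():
        hits = hist.loc[codes.str.startswith(prefixes), "call_id"].unique()
        out[name] = out["call_id"].isin(hits).astype(np.int8)

    rx = bundle.prescriptions[["person_id", "atc", "claim_date"]]
    claims = _lookback_indicators(eligible, rx, "claim_date", PRESCRIPTION_LOOKBACK_DAYS)
    atc = claims["atc"].astype(str)
    for name, prefixes in ATC_PREFIXES.items():
        hits = claims.loc[atc.str.startswith(prefixes), "call_id"].unique()
        out[name] = out["call_id"].isin(hits).astype(np.int8)
    anti = claims[atc.str.startswith(ANTIHYPERTENSIVE_ATC_CLASSES)].copy()
    anti["atc_class"] = anti["atc"].astype(str).str[:3]
    n_classes = anti.groupby("call_id")["atc_class"].nunique()
    out["hypertension"] = (
        out["call_id"].map(n_classes).fillna(0).ge(2).astype(np.int8)
    )
    return out


def derive_outcomes(bundle: RegistryBundle, eligible: pd.DataFrame) -> pd.DataFrame:
    """30-day mortality and the 1-year combined outcome per eligible call.

    Y30 is death within 30 days of the MI diagnosis (date-level, inclusive
    endpoint).  Y1yr is death, re-infarction, or heart-failure admission
    within 365 days, not counting MI or heart failure coded during the index
    hospital admission.
    """
    vit = bundle.vitals.set_index("person_id")["death_date"]
    death = eligible["person_id"].map(vit)
    dx_date = pd.to_datetime(eligible["admission_datetime"]).dt.normalize()
    death_days = (pd.to_datetime(death).dt.normalize() - dx_date).dt.days
    if (death_days.dropna() < 0).any():
        raise DataIntegrityError("death date precedes MI diagnosis")
    y30 = death_days.le(30).fillna(False)
    death_1yr = death_days.le(365).fillna(False)

    events = bundle.diagnoses[
        bundle.diagnoses["icd10"].astype(str).str.startswith(("I21", "I22", "I50"))
    ][["person_id", "admission_datetime"]].rename(
        columns={"admission_datetime": "event_datetime"}
    )
    merged = eligible[
        ["call_id", "person_id", "admission_datetime", "discharge_date"]
    ].merge(events, on="person_id", how="inner")
    after_index = merged["event_datetime"] > pd.to_datetime(merged["discharge_date"])
    within_1yr = (
        merged["event_datetime"].dt.normalize()
        - pd.to_datetime(merged["admission_datetime"]).dt.normalize()
    ).dt.days.le(365)
    hits = merged.loc[after_index & within_1yr, "call_id"].unique()
    y1yr = death_1yr | eligible["call_id"].isin(hits)
    return pd.DataFrame(
        {
            "call_id": eligible["call_id"].to_numpy(),
            "y30": y30.astype(np.int8).to_numpy(),
            "y1yr": y1yr.astype(np.int8).to_numpy(),
        }
    )


def build_cohort(bundle: RegistryBundle) -> tuple[pd.DataFrame, ExclusionLog]:
    """Compose eligibility, covariates, exposures and outcomes.

    Emergency-ambulance dispatch (lights and sirens) defines A_amb; all
    other dispatch types count as no emergency ambulance.  Prehospital ASA
    and the contraindication screen are defined only for dispatched calls.
    """
    eligible, log = apply_eligibility(bundle)
    if eligible.empty:
        return _empty_cohort(), log
    covariates = derive_covariates(bundle, eligible)
    outcomes = derive_outcomes(bundle, eligible)

    records = eligible[
        ["call_id", "person_id", "symptom_group", "mi_code", "dispatch_type"]
    ].copy()
    records["amb"] = (
        (records.pop("dispatch_type").astype(str) == "emergency_ambulance")
        .astype(np.int8)
    )
    code = records.pop("mi_code").astype(str)
    records["infarct_type"] = np.select(
        [
            code.str.startswith(("I21.0", "I21.1", "I21.2", "I21.3")),
            code.str.startswith("I21.4"),
        ],
        ["STEMI", "NSTEMI"],
        default="other",
    )

    pre = bundle.prehospital.set_index("call_id")
    pre = pre[~pre.index.duplicated()]
    note = records["call_id"].map(pre["note"]) if len(pre) else pd.Series(
        np.nan, index=records.index
    )
    allergy = (
        records["call_id"].map(pre["allergy_flag"]) if len(pre) else pd.Series(
            np.nan, index=records.index
        )
    )
    medicine = records["call_id"].map(pre["medicine"]) if len(pre) else pd.Series(
        np.nan, index=records.index
    )
    amb = records["amb"].to_numpy().astype(bool)
    contra = np.zeros(len(records), dtype=np.int8)
    asa = np.full(len(records), np.nan)
    contra[amb] = [
        detect_asa_contraindication(t, 0 if pd.isna(a) else int(a))
        for t, a in zip(note[amb], allergy[amb])
    ]
    asa[amb] = (
        medicine[amb].astype(str).str.lower().str.contains("acetylsalicylic")
    ).astype(float)
    records["asa_contraindicated"] = contra
    records["asa"] = asa

    cohort = records.merge(covariates, on="call_id").merge(outcomes, on="call_id")
    return cohort.reset_index(drop=True), log


def _empty_cohort() -> pd.DataFrame:
    cols = [
        "call_id",
        "person_id",
        "symptom_group",
        "amb",
        "infarct_type",
        "asa_contraindicated",
        "asa",
        "age",
        "male",
        "service_112",
        "education",
        "immigrant",
        "ihd",
        "prev_mi",
        "heart_failure",
        "cancer",
        "renal",
        "copd",
        "afib",
        "t2d",
        "opioid",
        "nsaid",
        "hypertension",
        "y30",
        "y1yr",
    ]
    return pd.DataFrame({c: [] for c in cols})


def select_asa_population(cohort: pd.DataFrame) -> pd.DataFrame:
    """ASA analysis population: dispatched calls without contraindication."""
    mask = (cohort["amb"] == 1) & (cohort["asa_contraindicated"] == 0)
    return cohort[mask].reset_index(drop=True)
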