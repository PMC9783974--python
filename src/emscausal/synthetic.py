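"""Synthetic electronic-registry generator with known ground truth.

Two levels of output are provided:

* :func:`generate_analysis_table` draws the latent analysis-level records
  (covariates, symptom group, exposures, outcomes) directly from the
  configured law — the fast path used by simulation studies;
* :func:`generate_registry` materializes those records into the five raw
  registry tables (calls, prehospital records, hospital diagnoses,
  prescriptions, vital status) together with decoy calls destined for each
  eligibility filter, so the cohort builder can be exercised end to end.

:func:`true_risk` evaluates the target parameters of the causal analysis
exactly (grid enumeration, discrete covariates only) or by Monte Carlo
integration under the configured law.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    BINARY_COVARIATES,
    ConfigurationError,
    EDUCATION_LEVELS,
    GROUPS,
    INFARCT_LEVELS,
    GeneratorConfig,
)

EXPOSURES = ("ambulance", "asa")
INTERVENTIONS = ("none", "all", "as_reference")
OUTCOMES = ("y30", "y1yr")

# fixed synthetic criterion vocabulary; the real national catalogues
# (Danish Index, 1813 decision support) are not publicly available
CHEST_CRITERIA = ("chest pain", "chest discomfort")
NONCHEST_CRITERIA = (
    "breathing problems",
    "abdominal pain",
    "back pain",
    "urinary symptoms",
    "infection/fever",
    "trauma",
    "unclear problem",
    "impaired consciousness",
    "dizziness",
    "weakness/fatigue",
)
EXCLUDED_CRITERIA = ("", "unclear notification", "administrative task")

STEMI_CODES = ("I21.0", "I21.1", "I21.2", "I21.3")
NSTEMI_CODE = "I21.4"
OTHER_MI_CODE = "I21.9"

# representative code pools standing in for the national registers' full lists
ICD_POOLS = {
    "ihd": ("I20.0", "I20.9", "I25.1", "I25.9"),
    "prev_mi": ("I21.4", "I21.9", "I22.0"),
    "heart_failure": ("I50.0", "I50.9"),
    "cancer": ("C18.9", "C34.9", "C50.9", "C61"),
    "renal": ("N18.3", "N18.9"),
    "copd": ("J44.0", "J44.9"),
    "afib": ("I48.0", "I48.9"),
}
ATC_POOLS = {
    "t2d": ("A10BA02", "A10BB09", "A10AE04"),
    "opioid": ("N02AA01", "N02AX02"),
    "nsaid": ("M01AB05", "M01AE01"),
}
ANTIHYPERTENSIVE_CLASSES = {
    "C03": ("C03CA01",),
    "C07": ("C07AB02",),
    "C08": ("C08CA01",),
    "C09": ("C09AA05", "C09CA01"),
}

CONTRA_PHRASES = (
    "known gi bleeding",
    "suspected aortic aneurysm",
    "peptic ulcer noted",
    "blood in vomit",
)
BENIGN_NOTES = (
    "pt pale and clammy",
    "given oxygen 10 l",
    "ecg transmitted to cardiology",
    "pain on exertion",
    "nausea during transport",
    "bp 135/85 pulse 92",
)
OTHER_MEDICINES = ("", "morphine 5 mg iv", "nitroglycerin spray")
ASA_MEDICINE = "acetylsalicylic acid 300 mg"


@dataclass
class RegistryBundle:
    """The five raw synthetic registry tables."""

    calls: pd.DataFrame
    prehospital: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    vitals: pd.DataFrame

    TABLES = ("calls", "prehospital", "diagnoses", "prescriptions", "vitals")

    def to_csv_dir(self, directory) -> None:
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.TABLES:
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def from_csv_dir(cls, directory) -> "RegistryBundle":
        import pathlib

        directory = pathlib.Path(directory)
        tables = {}
        for name in cls.TABLES:
            df = pd.read_csv(directory / f"{name}.csv", keep_default_na=False)
            for col in df.columns:
                if col.endswith(("timestamp", "_datetime")) or col in (
                    "admission_datetime",
                    "discharge_date",
                    "claim_date",
                    "death_date",
                    "diagnosis_date",
                ):
                    df[col] = pd.to_datetime(df[col].replace("", pd.NaT))
            tables[name] = df
        return cls(**tables)


@dataclass
class TrueRisk:
    value: float
    method: str
    mc_error: float | None = None


@dataclass
class TruthReport:
    """Ground-truth risks and reductions for every target parameter."""

    risks: dict[tuple, TrueRisk] = field(default_factory=dict)

    def risk(self, exposure, intervention, outcome, group="nonchest") -> float:
        return self.risks[(exposure, intervention, outcome, group)].value

    def reduction(self, exposure, intervention, outcome, group="nonchest") -> float:
        return self.risk(exposure, "none", outcome, group) - self.risk(
            exposure, intervention, outcome, group
        )


# ---------------------------------------------------------------------------
# linear predictors under the configured law
# ---------------------------------------------------------------------------

def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def linear_predictor(df: pd.DataFrame, coefs: dict[str, float], law: dict) -> np.ndarray:
    """Evaluate a coefficient dictionary on latent records."""
    n = len(df)
    lp = np.zeros(n)
    center = law.get("age_center", 0.0)
    scale = law.get("age_scale", 1.0)
    for term, value in coefs.items():
        if value == 0.0:
            continue
        if term == "intercept":
            lp += value
        elif term == "z_age":
            lp += value * (df["age"].to_numpy(float) - center) / scale
        elif term.startswith("education:"):
            level = term.split(":", 1)[1]
            lp += value * (df["education"].to_numpy() == level)
        elif term.startswith("infarct:"):
            level = term.split(":", 1)[1]
            lp += value * (df["infarct_type"].to_numpy() == level)
        elif term in ("amb", "asa"):
            lp += value * df[term].to_numpy(float)
        else:
            lp += value * df[term].to_numpy(float)
    return lp


def _sample_covariates(rng: np.random.Generator, n: int, law: dict) -> pd.DataFrame:
    age_law = law["age"]
    if age_law["kind"] == "reflected_lognormal":
        age = np.empty(n)
        remaining = np.arange(n)
        lo, hi = age_law.get("min", -np.inf), age_law.get("max", np.inf)
        while remaining.size:
            draw = age_law["offset"] - rng.lognormal(
                age_law["mu"], age_law["sigma"], size=remaining.size
            )
            ok = (draw >= lo) & (draw <= hi)
            age[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
    else:
        age = rng.choice(
            np.asarray(age_law["values"], dtype=float), size=n, p=age_law["probs"]
        )
    df = pd.DataFrame({"age": age})
    z = (age - law.get("age_center", 0.0)) / law.get("age_scale", 1.0)
    for name, spec in law.get("binary", {}).items():
        p = _expit(spec["intercept"] + spec.get("z_age", 0.0) * z)
        df[name] = (rng.random(n) < p).astype(np.int8)
    education = law.get("education")
    if education is not None:
        df["education"] = rng.choice(
            education["levels"], size=n, p=education["probs"]
        )
    else:
        df["education"] = EDUCATION_LEVELS[0]
    return df


def _sample_infarct(rng, df, config, group_col="symptom_group"):
    infarct = np.empty(len(df), dtype=object)
    for g in GROUPS:
        mask = (df[group_col] == g).to_numpy()
        if not mask.any():
            continue
        sub = df.loc[mask]
        l_stemi = linear_predictor(sub, config.infarct_coefs[g]["STEMI"], config.covariate_law)
        l_other = linear_predictor(sub, config.infarct_coefs[g]["other"], config.covariate_law)
        denom = 1.0 + np.exp(l_stemi) + np.exp(l_other)
        p = np.column_stack(
            [np.exp(l_stemi) / denom, 1.0 / denom, np.exp(l_other) / denom]
        )
        u = rng.random(mask.sum())
        idx = (u[:, None] >= np.cumsum(p, axis=1)).sum(axis=1)
        infarct[mask] = np.asarray(INFARCT_LEVELS, dtype=object)[idx]
    return infarct


def _per_group_bernoulli(rng, df, coef_table, law, group_col="symptom_group"):
    out = np.zeros(len(df), dtype=np.int8)
    for g in GROUPS:
        mask = (df[group_col] == g).to_numpy()
        if not mask.any():
            continue
        p = _expit(linear_predictor(df.loc[mask], coef_table[g], law))
        out[mask] = rng.random(mask.sum()) < p
    return out


def generate_analysis_table(
    config: GeneratorConfig, seed: int | None = None, n_calls: int | None = None
) -> pd.DataFrame:
    """Draw analysis-level records directly from the configured law.

    Returns one row per eligible call with columns ``call_id``, ``person_id``,
    the covariates, ``symptom_group``, ``infarct_type``, ``amb``,
    ``asa_contraindicated``, ``asa`` (missing when no ambulance was
    dispatched), ``y30`` and ``y1yr``.  Repeat calls (duplicate registrations
    of the same episode) share ``person_id`` and all record content.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_calls if n_calls is None else n_calls
    if n == 0:
        return _empty_analysis_table()
    n_persons = int(round(n / (1.0 + config.repeat_call_rate)))
    n_persons = max(1, min(n, n_persons))
    law = config.covariate_law

    df = _sample_covariates(rng, n_persons, law)
    p_nonchest = _expit(linear_predictor(df, config.symptom_coefs, law))
    df["symptom_group"] = np.where(
        rng.random(n_persons) < p_nonchest, "nonchest", "chest"
    )
    df["infarct_type"] = _sample_infarct(rng, df, config)
    df["amb"] = _per_group_bernoulli(rng, df, config.amb_coefs, law)

    contra = np.zeros(n_persons, dtype=np.int8)
    asa = np.zeros(n_persons, dtype=np.int8)
    amb_mask = df["amb"].to_numpy().astype(bool)
    for g in GROUPS:
        m = amb_mask & (df["symptom_group"] == g).to_numpy()
        contra[m] = rng.random(m.sum()) < config.contraindication_rate[g]
        p_asa = _expit(linear_predictor(df.loc[m], config.asa_coefs[g], law))
        asa[m] = rng.random(m.sum()) < p_asa
    df["asa_contraindicated"] = contra
    df["asa"] = asa

    p30 = np.zeros(n_persons)
    q1 = np.zeros(n_persons)
    for g in GROUPS:
        m = (df["symptom_group"] == g).to_numpy()
        p30[m] = _expit(linear_predictor(df.loc[m], config.y30_coefs[g], law))
        q1[m] = _expit(linear_predictor(df.loc[m], config.y1yr_coefs[g], law))
    df["y30"] = (rng.random(n_persons) < p30).astype(np.int8)
    extra = (rng.random(n_persons) < q1).astype(np.int8)
    df["y1yr"] = np.maximum(df["y30"].to_numpy(), extra)

    # duplicate registrations of the same episode
    n_dup = n - n_persons
    dup_idx = rng.choice(n_persons, size=n_dup, replace=False) if n_dup else []
    df["person_id"] = [f"P{i + 1:06d}" for i in range(n_persons)]
    df["is_repeat_call"] = 0
    if n_dup:
        dups = df.iloc[dup_idx].copy()
        dups["is_repeat_call"] = 1
        df = pd.concat([df, dups], ignore_index=True)
        order = rng.permutation(len(df))
        df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "call_id", [f"C{i + 1:06d}" for i in range(len(df))])
    cols = df.columns.tolist()
    cols.insert(1, cols.pop(cols.index("person_id")))
    df = df[cols]
    df["asa"] = df["asa"].astype(float)
    df.loc[df["amb"] == 0, "asa"] = np.nan
    return df


def _empty_analysis_table() -> pd.DataFrame:
    cols = (
        ["call_id", "person_id", "age"]
        + list(BINARY_COVARIATES)
        + [
            "education",
            "symptom_group",
            "infarct_type",
            "amb",
            "asa_contraindicated",
            "asa",
            "y30",
            "y1yr",
            "is_repeat_call",
        ]
    )
    return pd.DataFrame({c: [] for c in cols})


# ---------------------------------------------------------------------------
# registry materialization
# ---------------------------------------------------------------------------

_CALLS_COLUMNS = [
    "call_id",
    "person_id",
    "timestamp",
    "criterion",
    "service",
    "dispatch_type",
    "nursing_home",
    "terminal",
    "dead_at_call",
    "unconscious",
    "age",
    "sex",
    "ethnicity",
    "education",
]
_PREHOSPITAL_COLUMNS = ["call_id", "medicine", "note", "allergy_flag"]
_DIAGNOSES_COLUMNS = [
    "person_id",
    "icd10",
    "admission_datetime",
    "discharge_date",
    "primary",
]
_PRESCRIPTIONS_COLUMNS = ["person_id", "atc", "claim_date"]
_VITALS_COLUMNS = ["person_id", "death_date"]


def generate_registry(config: GeneratorConfig, seed: int | None = None) -> RegistryBundle:
    """Generate the five raw registry tables.

    The bundle contains ``config.n_calls`` eligible calls plus decoy calls
    (per ``config.exclusion_counts``) that each violate exactly one
    eligibility filter, emulating the study's exclusion flow.  Identical
    ``(config, seed)`` yield identical bundles.
    """
    config.validate()
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, 827_153])
    latent = generate_analysis_table(config, seed=base_seed)

    n_decoys = int(sum(config.exclusion_counts.values()))
    decoys = _make_decoys(config, rng, n_decoys) if n_decoys else None

    frames = [latent]
    if decoys is not None:
        frames.append(decoys)
    allrec = pd.concat(frames, ignore_index=True) if len(frames) > 1 else latent.copy()
    if allrec.empty:
        return _empty_registry()

    allrec = _assign_timestamps(allrec, config, rng)
    # re-issue identifiers in timestamp order
    allrec = allrec.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    old_person = allrec["person_id"].to_numpy()
    uniq, first_pos = np.unique(old_person, return_index=True)
    order = np.argsort(first_pos)
    mapping = {uniq[i]: f"P{j + 1:06d}" for j, i in enumerate(order)}
    allrec["person_id"] = [mapping[p] for p in old_person]
    allrec["call_id"] = [f"C{i + 1:06d}" for i in range(len(allrec))]

    allrec = _assign_followup_events(allrec, rng)
    calls = _build_calls_table(allrec, config, rng)
    prehospital = _build_prehospital_table(allrec, rng)
    diagnoses = _build_diagnoses_table(allrec, config, rng)
    prescriptions = _build_prescriptions_table(allrec, config, rng)
    vitals = _build_vitals_table(allrec, rng)
    return RegistryBundle(calls, prehospital, diagnoses, prescriptions, vitals)


def _assign_followup_events(allrec, rng):
    """Pick, per person, how a 1-year combined outcome materializes."""
    persons = allrec.drop_duplicates("person_id")
    kind = {}
    for _, rec in persons.iterrows():
        if rec["y30"] == 1:
            kind[rec["person_id"]] = "early_death"
        elif rec["y1yr"] == 1:
            kind[rec["person_id"]] = ("re_mi", "hf", "late_death")[
                int(rng.integers(0, 3))
            ]
        else:
            kind[rec["person_id"]] = ""
    allrec = allrec.copy()
    allrec["y1yr_event"] = allrec["person_id"].map(kind)
    return allrec


def _empty_registry() -> RegistryBundle:
    return RegistryBundle(
        calls=pd.DataFrame({c: [] for c in _CALLS_COLUMNS}),
        prehospital=pd.DataFrame({c: [] for c in _PREHOSPITAL_COLUMNS}),
        diagnoses=pd.DataFrame({c: [] for c in _DIAGNOSES_COLUMNS}),
        prescriptions=pd.DataFrame({c: [] for c in _PRESCRIPTIONS_COLUMNS}),
        vitals=pd.DataFrame({c: [] for c in _VITALS_COLUMNS}),
    )


def _make_decoys(config, rng, n_decoys) -> pd.DataFrame:
    cfg = config.copy()
    cfg.repeat_call_rate = 0.0
    seed = int(rng.integers(0, 2**31 - 1))
    decoys = generate_analysis_table(cfg, seed=seed, n_calls=n_decoys)
    decoys["person_id"] = [f"X{i + 1:06d}" for i in range(len(decoys))]
    reasons = []
    for reason, count in sorted(config.exclusion_counts.items()):
        reasons.extend([reason] * int(count))
    rng.shuffle(reasons)
    decoys["exclusion_reason"] = reasons[: len(decoys)]
    decoys["age"] = decoys["age"].astype(float)
    under = decoys["exclusion_reason"] == "age_under_30"
    decoys.loc[under, "age"] = rng.uniform(18.0, 29.9, under.sum())
    for reason, col in (
        ("nursing_home", "nursing_home"),
        ("palliative", "terminal"),
        ("dead_at_call", "dead_at_call"),
        ("unconscious", "unconscious"),
    ):
        decoys[col] = 0
        decoys.loc[decoys["exclusion_reason"] == reason, col] = 1
    noninf = decoys["exclusion_reason"] == "noninformative_criterion"
    decoys["force_exclude_criterion"] = noninf.astype(int)
    decoys["force_criterion"] = ""
    decoys.loc[noninf, "force_criterion"] = rng.choice(
        np.asarray(EXCLUDED_CRITERIA, dtype=object), size=int(noninf.sum())
    )
    return decoys


def _assign_timestamps(allrec, config, rng):
    law = config.timestamp_law
    start = pd.Timestamp(law["start"])
    end = pd.Timestamp(law["end"])
    span = (end - start).total_seconds()
    n = len(allrec)
    call_sec = rng.uniform(0.0, span, n)
    delay_min = np.exp(
        rng.normal(law["delay_log_mu_minutes"], law["delay_log_sigma"], n)
    )
    delay_min = np.clip(delay_min, law["delay_min_minutes"], law["delay_max_minutes"])

    reason = allrec.get("exclusion_reason")
    if reason is not None:
        late = (reason == "no_mi_within_24h").to_numpy()
        # half of these decoys are admitted too late, half never admitted
        split = rng.random(n) < 0.5
        delay_min[late & split] = rng.uniform(25 * 60, 72 * 60, int((late & split).sum()))
        allrec = allrec.assign(no_admission=(late & ~split).astype(int))
    else:
        allrec = allrec.assign(no_admission=0)

    allrec["timestamp"] = start + pd.to_timedelta(call_sec, unit="s")
    allrec["admission_datetime"] = allrec["timestamp"] + pd.to_timedelta(
        delay_min, unit="m"
    )
    # duplicate registrations: same admission, second call between the two
    if "is_repeat_call" in allrec and allrec["is_repeat_call"].any():
        rep = allrec["is_repeat_call"] == 1
        firsts = (
            allrec.loc[~rep, ["person_id", "timestamp", "admission_datetime"]]
            .drop_duplicates("person_id")
            .set_index("person_id")
        )
        pid = allrec.loc[rep, "person_id"]
        t0 = firsts.loc[pid, "timestamp"].to_numpy()
        adm = firsts.loc[pid, "admission_datetime"].to_numpy()
        frac = rng.uniform(0.1, 0.8, int(rep.sum()))
        gap = (adm - t0) * frac
        allrec.loc[rep, "timestamp"] = t0 + gap
        allrec.loc[rep, "admission_datetime"] = adm
    allrec["timestamp"] = allrec["timestamp"].dt.floor("s")
    allrec["admission_datetime"] = allrec["admission_datetime"].dt.floor("s")
    return allrec


def _build_calls_table(allrec, config, rng):
    n = len(allrec)
    crit = np.empty(n, dtype=object)
    chest = (allrec["symptom_group"] == "chest").to_numpy()
    crit[chest] = rng.choice(np.asarray(CHEST_CRITERIA, dtype=object), chest.sum())
    crit[~chest] = rng.choice(np.asarray(NONCHEST_CRITERIA, dtype=object), (~chest).sum())
    if "force_exclude_criterion" in allrec:
        forced = allrec["force_exclude_criterion"].fillna(0).astype(int).to_numpy() == 1
        crit[forced] = allrec.loc[forced, "force_criterion"].fillna("").to_numpy()

    dispatch = np.where(
        allrec["amb"].to_numpy() == 1,
        "emergency_ambulance",
        rng.choice(
            np.asarray(
                ["non_emergency_ambulance", "home_visit", "self_transport", "referral"],
                dtype=object,
            ),
            n,
        ),
    )
    education = allrec["education"].to_numpy(dtype=object).copy()
    basic = education == "basic"
    miss_edu = basic & (rng.random(n) < config.missing_education_rate)
    education[miss_edu] = ""
    ethnicity = np.where(allrec["immigrant"].to_numpy() == 1, "immigrant", "danish")
    ethnicity = ethnicity.astype(object)
    miss_eth = (allrec["immigrant"].to_numpy() == 1) & (
        rng.random(n) < config.missing_ethnicity_rate
    )
    ethnicity[miss_eth] = ""

    flags = {}
    for col in ("nursing_home", "terminal", "dead_at_call", "unconscious"):
        flags[col] = (
            allrec[col].fillna(0).astype(int).to_numpy() if col in allrec else np.zeros(n, int)
        )
    return pd.DataFrame(
        {
            "call_id": allrec["call_id"],
            "person_id": allrec["person_id"],
            "timestamp": allrec["timestamp"],
            "criterion": crit,
            "service": np.where(allrec["service_112"] == 1, "112", "1813"),
            "dispatch_type": dispatch,
            **flags,
            "age": allrec["age"].round(1),
            "sex": np.where(allrec["male"] == 1, "male", "female"),
            "ethnicity": ethnicity,
            "education": education,
        }
    )[_CALLS_COLUMNS]


def _build_prehospital_table(allrec, rng):
    amb = allrec[allrec["amb"] == 1]
    n = len(amb)
    if n == 0:
        return pd.DataFrame({c: [] for c in _PREHOSPITAL_COLUMNS})
    asa = amb["asa"].fillna(0).to_numpy() == 1
    medicine = np.where(
        asa,
        np.where(
            rng.random(n) < 0.4,
            ASA_MEDICINE + "; morphine 5 mg iv",
            ASA_MEDICINE,
        ),
        rng.choice(np.asarray(OTHER_MEDICINES, dtype=object), n),
    )
    contra = amb["asa_contraindicated"].to_numpy() == 1
    note = rng.choice(np.asarray(BENIGN_NOTES, dtype=object), n)
    allergy = np.zeros(n, dtype=int)
    via_text = contra & (rng.random(n) < 0.7)
    note[via_text] = rng.choice(np.asarray(CONTRA_PHRASES, dtype=object), via_text.sum())
    allergy[contra & ~via_text] = 1
    return pd.DataFrame(
        {
            "call_id": amb["call_id"].to_numpy(),
            "medicine": medicine,
            "note": note,
            "allergy_flag": allergy,
        }
    )


def _draw_days(rng, lo, hi, size):
    return rng.integers(lo, hi + 1, size)


def _build_diagnoses_table(allrec, config, rng):
    rows = {k: [] for k in _DIAGNOSES_COLUMNS}

    def add(person, code, admission, discharge, primary):
        rows["person_id"].append(person)
        rows["icd10"].append(code)
        rows["admission_datetime"].append(admission)
        rows["discharge_date"].append(discharge)
        rows["primary"].append(primary)

    persons = allrec.drop_duplicates("person_id")
    for _, rec in persons.iterrows():
        pid = rec["person_id"]
        if rec.get("no_admission", 0) == 1:
            continue
        adm = rec["admission_datetime"]
        stay = int(rng.integers(2, 9))
        discharge = (adm + pd.Timedelta(days=stay)).normalize()
        infarct = rec["infarct_type"]
        if infarct == "STEMI":
            code = STEMI_CODES[int(rng.integers(0, len(STEMI_CODES)))]
        elif infarct == "NSTEMI":
            code = NSTEMI_CODE
        else:
            code = OTHER_MI_CODE
        add(pid, code, adm, discharge, 1)

        # in-hospital heart failure coded during the index admission must not
        # count toward the 1-year combined outcome
        p_hf_index = 0.215 if rec["symptom_group"] == "nonchest" else 0.103
        if rng.random() < p_hf_index:
            add(pid, "I50.9", adm, discharge, 0)

        call = rec["timestamp"]
        for name, pool in ICD_POOLS.items():
            if rec[name] == 1:
                back = int(rng.integers(2, 5 * 365))
                d = (call - pd.Timedelta(days=back)).floor("s")
                add(pid, pool[int(rng.integers(0, len(pool)))], d, d.normalize(), int(rng.random() < 0.6))
            elif rng.random() < 0.03:
                back = int(rng.integers(5 * 365 + 1, 8 * 365))
                d = (call - pd.Timedelta(days=back)).floor("s")
                add(pid, pool[int(rng.integers(0, len(pool)))], d, d.normalize(), 1)

        # follow-up events materializing the 1-year combined outcome
        event = rec.get("y1yr_event", "")
        if event in ("re_mi", "hf"):
            code = "I21.9" if event == "re_mi" else "I50.9"
            day = int(rng.integers(stay + 1, 366))
            d = adm + pd.Timedelta(days=day)
            add(pid, code, d, (d + pd.Timedelta(days=3)).normalize(), 1)
        # late deaths are handled in the vitals table
    df = pd.DataFrame(rows)
    df["admission_datetime"] = pd.to_datetime(df["admission_datetime"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    return df


def _build_prescriptions_table(allrec, config, rng):
    rows = {k: [] for k in _PRESCRIPTIONS_COLUMNS}
    persons = allrec.drop_duplicates("person_id")
    class_names = list(ANTIHYPERTENSIVE_CLASSES)
    for _, rec in persons.iterrows():
        pid = rec["person_id"]
        call = rec["timestamp"]

        def claim(atc, lo=1, hi=179):
            rows["person_id"].append(pid)
            rows["atc"].append(atc)
            rows["claim_date"].append(
                (call - pd.Timedelta(days=int(rng.integers(lo, hi + 1)))).normalize()
            )

        for name, pool in ATC_POOLS.items():
            if rec[name] == 1:
                claim(pool[int(rng.integers(0, len(pool)))])
            elif rng.random() < 0.05:
                claim(pool[int(rng.integers(0, len(pool)))], lo=181, hi=300)
        if rec["hypertension"] == 1:
            k = 2 + int(rng.random() < 0.35)
            chosen = rng.choice(len(class_names), size=k, replace=False)
            for ci in chosen:
                pool = ANTIHYPERTENSIVE_CLASSES[class_names[ci]]
                claim(pool[int(rng.integers(0, len(pool)))])
        elif rng.random() < 0.15:
            pool = ANTIHYPERTENSIVE_CLASSES[
                class_names[int(rng.integers(0, len(class_names)))]
            ]
            claim(pool[int(rng.integers(0, len(pool)))])
    df = pd.DataFrame(rows)
    df["claim_date"] = pd.to_datetime(df["claim_date"])
    return df


def _build_vitals_table(allrec, rng):
    persons = allrec.drop_duplicates("person_id")
    rows = {"person_id": [], "death_date": []}
    for _, rec in persons.iterrows():
        rows["person_id"].append(rec["person_id"])
        death = pd.NaT
        event = rec.get("y1yr_event", "")
        if rec.get("no_admission", 0) != 1:
            adm = rec["admission_datetime"].normalize()
            if event == "early_death":
                death = adm + pd.Timedelta(days=int(rng.integers(0, 31)))
            elif event == "late_death":
                death = adm + pd.Timedelta(days=int(rng.integers(31, 366)))
        rows["death_date"].append(death)
    df = pd.DataFrame(rows)
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


class UnsupportedMethodError(ValueError):
    """Enumeration requested for a law it cannot integrate exactly."""


def _conditional_outcome_prob(df, config, group, amb, asa, outcome):
    """P(outcome | A, W, S=group), marginal over infarct type."""
    law = config.covariate_law
    work = df.copy()
    work["amb"] = float(amb)
    work["asa"] = float(asa)
    l_stemi = linear_predictor(work, config.infarct_coefs[group]["STEMI"], law)
    l_other = linear_predictor(work, config.infarct_coefs[group]["other"], law)
    denom = 1.0 + np.exp(l_stemi) + np.exp(l_other)
    probs = {
        "STEMI": np.exp(l_stemi) / denom,
        "NSTEMI": 1.0 / denom,
        "other": np.exp(l_other) / denom,
    }
    total = np.zeros(len(work))
    for level, w in probs.items():
        work["infarct_type"] = level
        p30 = _expit(linear_predictor(work, config.y30_coefs[group], law))
        if outcome == "y30":
            total += w * p30
        else:
            q = _expit(linear_predictor(work, config.y1yr_coefs[group], law))
            total += w * (p30 + (1.0 - p30) * q)
    return total


def _risk_given_amb(df, config, group, amb, outcome):
    """P(outcome | A_amb=amb, W, S), ASA marginalized out."""
    if amb == 0:
        return _conditional_outcome_prob(df, config, group, 0, 0, outcome)
    p_asa = _expit(linear_predictor(df, config.asa_coefs[group], config.covariate_law))
    p1 = _conditional_outcome_prob(df, config, group, 1, 1, outcome)
    p0 = _conditional_outcome_prob(df, config, group, 1, 0, outcome)
    return p_asa * p1 + (1.0 - p_asa) * p0


def _per_row_target_risk(df, config, exposure, intervention, group, outcome):
    law = config.covariate_law
    if exposure == "ambulance":
        if intervention == "none":
            p_amb = _expit(linear_predictor(df, config.amb_coefs[group], law))
            return p_amb * _risk_given_amb(df, config, group, 1, outcome) + (
                1.0 - p_amb
            ) * _risk_given_amb(df, config, group, 0, outcome)
        if intervention == "all":
            return _risk_given_amb(df, config, group, 1, outcome)
        if intervention == "as_reference":
            pi_ref = _expit(linear_predictor(df, config.amb_coefs["chest"], law))
            return pi_ref * _risk_given_amb(df, config, group, 1, outcome) + (
                1.0 - pi_ref
            ) * _risk_given_amb(df, config, group, 0, outcome)
    else:  # asa, population already conditioned on dispatch without contraindication
        if intervention == "none":
            p_asa = _expit(linear_predictor(df, config.asa_coefs[group], law))
            return p_asa * _conditional_outcome_prob(df, config, group, 1, 1, outcome) + (
                1.0 - p_asa
            ) * _conditional_outcome_prob(df, config, group, 1, 0, outcome)
        if intervention == "all":
            return _conditional_outcome_prob(df, config, group, 1, 1, outcome)
        if intervention == "as_reference":
            pi_ref = _expit(linear_predictor(df, config.asa_coefs["chest"], law))
            return pi_ref * _conditional_outcome_prob(df, config, group, 1, 1, outcome) + (
                1.0 - pi_ref
            ) * _conditional_outcome_prob(df, config, group, 1, 0, outcome)
    raise ValueError(f"unknown intervention {intervention!r}")


def true_risk(
    config: GeneratorConfig,
    exposure: str,
    intervention: str,
    outcome: str,
    group: str = "nonchest",
    method: str = "monte_carlo",
    n_draws: int = 2_000_000,
    seed: int = 0,
) -> TrueRisk:
    """True value of a target parameter under the configured law.

    ``enumeration`` integrates exactly over the covariate grid and requires a
    discrete age law; ``monte_carlo`` reports its standard error.  For the
    ASA exposure the target population is conditioned on emergency dispatch
    without contraindication, which reweights the covariate distribution.
    """
    if exposure not in EXPOSURES:
        raise ValueError(f"unknown exposure {exposure!r}")
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if intervention not in INTERVENTIONS:
        raise ValueError(f"unknown intervention {intervention!r}")
    config.validate()
    law = config.covariate_law
    if method == "enumeration":
        if law["age"]["kind"] != "discrete":
            raise UnsupportedMethodError(
                "enumeration requires a discrete age law; use monte_carlo"
            )
        grid, weights = _covariate_grid(law)
        p_nonchest = _expit(linear_predictor(grid, config.symptom_coefs, law))
        w_group = weights * (p_nonchest if group == "nonchest" else 1.0 - p_nonchest)
        if exposure == "asa":
            p_amb = _expit(linear_predictor(grid, config.amb_coefs[group], law))
            w_group = w_group * p_amb  # contraindication rate cancels (independent of W)
        total = w_group.sum()
        if total <= 0:
            raise ConfigurationError(f"group {group!r} has zero probability")
        risk = _per_row_target_risk(grid, config, exposure, intervention, group, outcome)
        return TrueRisk(float(np.dot(w_group, risk) / total), "enumeration")

    if method != "monte_carlo":
        raise UnsupportedMethodError(f"unknown method {method!r}")
    rng = np.random.default_rng([seed, 40_417])
    df = _sample_covariates(rng, int(n_draws), law)
    p_nonchest = _expit(linear_predictor(df, config.symptom_coefs, law))
    in_group = (
        rng.random(len(df)) < p_nonchest
        if group == "nonchest"
        else rng.random(len(df)) >= p_nonchest
    )
    df = df.loc[in_group].reset_index(drop=True)
    if exposure == "asa":
        p_amb = _expit(linear_predictor(df, config.amb_coefs[group], law))
        dispatched = rng.random(len(df)) < p_amb
        df = df.loc[dispatched].reset_index(drop=True)
        # contraindication is drawn independently of W: selection leaves the
        # covariate distribution unchanged, no further filtering required
    if df.empty:
        raise ConfigurationError(f"no Monte Carlo draws fell in group {group!r}")
    risk = _per_row_target_risk(df, config, exposure, intervention, group, outcome)
    return TrueRisk(
        float(risk.mean()),
        "monte_carlo",
        mc_error=float(risk.std(ddof=1) / np.sqrt(len(risk))),
    )


def _covariate_grid(law):
    age_values = list(law["age"]["values"])
    age_probs = list(law["age"]["probs"])
    binary = law.get("binary", {})
    education = law.get("education")
    levels = [list(zip(age_values, age_probs))]
    levels += [[(0, None), (1, None)] for _ in binary]
    if education is not None:
        levels.append(list(zip(education["levels"], education["probs"])))
    names = ["age"] + list(binary) + (["education"] if education is not None else [])
    rows, weights = [], []
    center = law.get("age_center", 0.0)
    scale = law.get("age_scale", 1.0)
    for combo in itertools.product(*levels):
        row = {name: val for name, (val, _) in zip(names, combo)}
        w = combo[0][1]
        z = (row["age"] - center) / scale
        for i, (name, spec) in enumerate(binary.items()):
            p = float(_expit(spec["intercept"] + spec.get("z_age", 0.0) * z))
            w *= p if combo[1 + i][0] == 1 else 1.0 - p
        if education is not None:
            w *= dict(zip(education["levels"], education["probs"]))[row["education"]]
        rows.append(row)
        weights.append(w)
    grid = pd.DataFrame(rows)
    if education is None:
        grid["education"] = EDUCATION_LEVELS[0]
    return grid, np.asarray(weights)


def truth_report(
    config: GeneratorConfig,
    method: str = "monte_carlo",
    n_draws: int = 2_000_000,
    seed: int = 0,
    groups=GROUPS,
) -> TruthReport:
    """Evaluate every (exposure, intervention, outcome, group) target."""
    report = TruthReport()
    for exposure in EXPOSURES:
        for intervention in INTERVENTIONS:
            for outcome in OUTCOMES:
                for group in groups:
                    if intervention == "as_reference" and group == "chest":
                        continue
                    report.risks[(exposure, intervention, outcome, group)] = true_risk(
                        config,
                        exposure,
                        intervention,
                        outcome,
                        group,
                        method=method,
                        n_draws=n_draws,
                        seed=seed,
                    )
    return report
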