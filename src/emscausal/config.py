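"""Configuration objects for the synthetic registry generator and the analysis.

The generator configuration encodes a complete data-generating law for calls
to the emergency (1-1-2) and non-emergency (1813) medical services regarding
patients later hospitalized with myocardial infarction (MI):

* covariates W (age, sex, medical service, education, ethnicity and the
  comorbidity/medication indicators used for adjustment),
* symptom presentation S (chest pain vs non-chest pain) given W,
* emergency-ambulance dispatch A_amb given (W, S),
* prehospital acetylsalicylic-acid administration A_asa given (W, S, A_amb=1),
* ASA contraindication given dispatch,
* infarct type (STEMI/NSTEMI/other) given (W, S),
* 30-day mortality and the 1-year combined outcome given everything upstream.

All conditional probabilities are logistic in a small set of named design
terms, so the law is fully known and every target parameter of the causal
analysis has a computable ground truth (see :mod:`emscausal.synthetic`).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Any

GROUPS = ("chest", "nonchest")
INFARCT_LEVELS = ("STEMI", "NSTEMI", "other")
EDUCATION_LEVELS = ("basic", "intermediate", "advanced")

#: binary covariates of the canonical (study-like) configuration
BINARY_COVARIATES = (
    "male",
    "service_112",
    "immigrant",
    "t2d",
    "hypertension",
    "opioid",
    "nsaid",
    "ihd",
    "prev_mi",
    "heart_failure",
    "cancer",
    "renal",
    "copd",
    "afib",
)


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Full data-generating law with known ground truth.

    Coefficient dictionaries map design-term names to values.  Recognised
    terms are ``intercept``, ``z_age`` (standardized age), any binary
    covariate name, ``education:<level>``, ``infarct:<level>`` (reference
    NSTEMI) and the exposure terms ``amb`` / ``asa``.
    """

    n_calls: int
    seed: int
    covariate_law: dict[str, Any]
    symptom_coefs: dict[str, float]
    amb_coefs: dict[str, dict[str, float]]
    asa_coefs: dict[str, dict[str, float]]
    contraindication_rate: dict[str, float]
    infarct_coefs: dict[str, dict[str, dict[str, float]]]
    y30_coefs: dict[str, dict[str, float]]
    y1yr_coefs: dict[str, dict[str, float]]
    timestamp_law: dict[str, Any]
    repeat_call_rate: float
    exclusion_counts: dict[str, int] = field(default_factory=dict)
    missing_education_rate: float = 0.0
    missing_ethnicity_rate: float = 0.0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_calls < 0:
            raise ConfigurationError("n_calls must be non-negative")
        if not 0.0 <= self.repeat_call_rate < 1.0:
            raise ConfigurationError("repeat_call_rate must be in [0, 1)")
        for rate in (self.missing_education_rate, self.missing_ethnicity_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("missing-data rates must be in [0, 1]")
        for g in GROUPS:
            for name, table in (
                ("amb_coefs", self.amb_coefs),
                ("asa_coefs", self.asa_coefs),
                ("y30_coefs", self.y30_coefs),
                ("y1yr_coefs", self.y1yr_coefs),
            ):
                if g not in table:
                    raise ConfigurationError(f"{name} missing group {g!r}")
            if not 0.0 <= self.contraindication_rate.get(g, -1.0) <= 1.0:
                raise ConfigurationError(
                    f"contraindication_rate[{g!r}] must be a probability"
                )
        for coefs in self._all_coef_dicts():
            for term, value in coefs.items():
                if not math.isfinite(value):
                    raise ConfigurationError(f"non-finite coefficient for {term!r}")
        law = self.covariate_law
        age = law.get("age")
        if not isinstance(age, dict) or age.get("kind") not in (
            "reflected_lognormal",
            "discrete",
        ):
            raise ConfigurationError("covariate_law['age'] must define a valid law")
        if age["kind"] == "discrete":
            probs = age["probs"]
            if abs(sum(probs) - 1.0) > 1e-8 or any(p < 0 for p in probs):
                raise ConfigurationError("discrete age probabilities must sum to 1")
        for name, spec in law.get("binary", {}).items():
            if "intercept" not in spec:
                raise ConfigurationError(f"binary covariate {name!r} needs an intercept")
        education = law.get("education")
        if education is not None:
            probs = education["probs"]
            if abs(sum(probs) - 1.0) > 1e-8 or any(p < 0 for p in probs):
                raise ConfigurationError("education probabilities must sum to 1")
        for count in self.exclusion_counts.values():
            if count < 0:
                raise ConfigurationError("exclusion counts must be non-negative")

    def _all_coef_dicts(self):
        yield self.symptom_coefs
        for g in GROUPS:
            yield self.amb_coefs[g]
            yield self.asa_coefs[g]
            yield self.y30_coefs[g]
            yield self.y1yr_coefs[g]
            for level_coefs in self.infarct_coefs[g].values():
                yield level_coefs

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "GeneratorConfig":
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                data = json.load(fh)
        config = cls(**data)
        config.validate()
        return config

    def copy(self) -> "GeneratorConfig":
        return copy.deepcopy(self)


@dataclass
class AnalysisConfig:
    """Settings for nuisance-model fitting and estimation.

    ``g_covariates`` is the adjustment set of the exposure (and reference
    exposure) models; ``q_covariates`` the adjustment set of the outcome
    model, which additionally receives the infarct type.  Both follow the
    candidate logistic regressions with and without second-order interaction
    terms, selected by a discrete super learner.
    """

    sl_folds: int = 10
    sl_seed: int = 2023
    g_trunc: tuple[float, float] = (0.01, 0.99)
    g_covariates: tuple[str, ...] = (
        "age",
        "male",
        "service_112",
        "t2d",
        "heart_failure",
        "copd",
        "opioid",
        "prev_mi",
        "education",
    )
    q_covariates: tuple[str, ...] = (
        "age",
        "male",
        "service_112",
        "t2d",
        "heart_failure",
        "copd",
        "opioid",
        "prev_mi",
        "education",
        "cancer",
        "immigrant",
        "ihd",
        "infarct_type",
    )
    max_fluctuation_iter: int = 100
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Packaged default calibration.
#
# Intercepts marked "calibrated" are solved numerically (Monte Carlo root
# finding, 1.5M draws; see emscausal.calibration) so that the implied
# marginal frequencies reproduce the study-scale descriptive statistics:
# 24.2% non-chest presentation, 89.8%/40.1% dispatch, 73.5%/37.1% ASA,
# 2.8%/10.9% crude 30-day mortality, 18.5%/31.6% 1-year combined outcome,
# and the ASA-population risks 3.0%/12.8% (30-day) and 18.7%/33.9% (1-year)
# with an all-ASA 30-day risk of 7.4% and 1-year risk of 31.3% among
# non-chest-pain patients.  Slopes are fixed design choices (docs/methods.md).
# ---------------------------------------------------------------------------

_DEFAULT_COVARIATE_LAW = {
    "age": {
        "kind": "reflected_lognormal",
        "offset": 112.34,
        "mu": 3.769,
        "sigma": 0.3407,
        "min": 30.0,
        "max": 100.0,
    },
    "age_center": 69.0,
    "age_scale": 12.0,
    "binary": {
        # intercepts below are placeholders; default_config() overrides them
        # with the calibrated values in _CALIBRATED["binary_intercepts"].
        "male": {"intercept": 0.650, "z_age": 0.0},
        "service_112": {"intercept": 0.624, "z_age": 0.0},
        "immigrant": {"intercept": -1.68, "z_age": -0.30},
        "t2d": {"intercept": -1.65, "z_age": 0.35},
        "hypertension": {"intercept": -0.64, "z_age": 0.80},
        "opioid": {"intercept": -1.57, "z_age": 0.25},
        "nsaid": {"intercept": -1.89, "z_age": 0.0},
        "ihd": {"intercept": -1.08, "z_age": 0.60},
        "prev_mi": {"intercept": -1.61, "z_age": 0.50},
        "heart_failure": {"intercept": -2.14, "z_age": 0.70},
        "cancer": {"intercept": -2.27, "z_age": 0.50},
        "renal": {"intercept": -2.86, "z_age": 0.50},
        "copd": {"intercept": -2.43, "z_age": 0.45},
        "afib": {"intercept": -2.19, "z_age": 0.70},
    },
    "education": {
        # analysis-scale shares with missing recoded to basic:
        # (1683+284)/5418, 2259/5418, 1192/5418
        "levels": list(EDUCATION_LEVELS),
        "probs": [0.3631, 0.4169, 0.2200],
    },
}

_SYMPTOM_SLOPES = {
    "z_age": 0.45,
    "male": -0.45,
    "service_112": -0.55,
    "copd": 0.85,
    "opioid": 0.45,
    "ihd": -0.35,
    "prev_mi": -0.35,
    "cancer": 0.15,
    "renal": 0.15,
    "afib": 0.05,
    "education:intermediate": -0.10,
    "education:advanced": -0.20,
}

_AMB_SLOPES = {
    "chest": {
        "z_age": 0.15,
        "service_112": 1.60,
        "heart_failure": 0.10,
        "copd": 0.10,
        "prev_mi": 0.10,
    },
    "nonchest": {
        "z_age": 0.30,
        "service_112": 1.30,
        "heart_failure": 0.25,
        "copd": 0.25,
        "opioid": 0.10,
        "t2d": 0.10,
    },
}

_ASA_SLOPES = {
    "chest": {"z_age": -0.15, "service_112": 0.35, "prev_mi": 0.25},
    "nonchest": {"z_age": -0.25, "service_112": 0.40, "prev_mi": 0.30, "copd": -0.30},
}

_Y30_W_SLOPES = {
    "z_age": 0.95,
    "male": 0.10,
    "heart_failure": 0.55,
    "copd": 0.40,
    "t2d": 0.20,
    "cancer": 0.45,
    "renal": 0.35,
    "prev_mi": 0.20,
    "opioid": 0.25,
    "service_112": 0.15,
    "afib": 0.20,
    "education:intermediate": -0.10,
    "education:advanced": -0.25,
    "infarct:STEMI": 0.55,
    "infarct:other": 0.25,
}

_Y1YR_W_SLOPES = {
    "z_age": 0.70,
    "heart_failure": 0.60,
    "t2d": 0.30,
    "copd": 0.45,
    "prev_mi": 0.35,
    "cancer": 0.50,
    "renal": 0.35,
    "afib": 0.35,
    "opioid": 0.20,
    "service_112": 0.05,
    "education:intermediate": -0.05,
    "education:advanced": -0.15,
    "infarct:STEMI": -0.15,
    "infarct:other": 0.10,
}

# Infarct-type multinomial logits relative to NSTEMI, chosen so that the
# implied shares reproduce the subgroup sizes (STEMI 31%, NSTEMI 44%).
_INFARCT_COEFS = {
    "chest": {
        "STEMI": {"intercept": math.log(0.33 / 0.44)},
        "other": {"intercept": math.log(0.23 / 0.44)},
    },
    "nonchest": {
        "STEMI": {"intercept": math.log(0.25 / 0.42)},
        "other": {"intercept": math.log(0.33 / 0.42)},
    },
}

_DEFAULT_TIMESTAMP_LAW = {
    "start": "2015-04-01",
    "end": "2018-12-31",
    "delay_log_mu_minutes": math.log(50.0),
    "delay_log_sigma": 0.35,
    "delay_min_minutes": 10.0,
    "delay_max_minutes": 1380.0,
}

# Invented split of the Fig.-1-scale exclusions (1255 of 6673 calls) across
# the filter categories; only the total is reported in the source material.
_DEFAULT_EXCLUSION_COUNTS = {
    "age_under_30": 40,
    "no_mi_within_24h": 120,
    "nursing_home": 300,
    "palliative": 150,
    "dead_at_call": 100,
    "unconscious": 200,
    "noninformative_criterion": 345,
}

# Calibrated intercepts (frozen output of scripts in emscausal.calibration).
_CALIBRATED: dict[str, Any] = {
    "binary_intercepts": {
        "male": 0.6494,
        "service_112": 0.6225,
        "immigrant": -1.7489,
        "t2d": -1.6681,
        "hypertension": -0.6996,
        "opioid": -1.5639,
        "nsaid": -1.8901,
        "ihd": -1.131,
        "prev_mi": -1.671,
        "heart_failure": -2.2984,
        "cancer": -2.3423,
        "renal": -2.9411,
        "copd": -2.4871,
        "afib": -2.3464,
    },
    "symptom_intercept": -0.5099,
    "amb_intercepts": {"chest": 1.3375, "nonchest": -1.3878},
    "asa_intercepts": {"chest": 0.708, "nonchest": -0.7159},
    "y30": {
        "intercept_chest": -5.1693,
        "intercept_nonchest": -3.4527,
        "amb_chest": 1.2231,
        "amb_nonchest": 0.2423,
        "asa": -0.927,
    },
    "y1yr": {
        "intercept_chest": -1.9072,
        "intercept_nonchest": -1.8388,
        "amb_chest": -0.2116,
        "amb_nonchest": -0.2184,
        "asa": 0.0861,
    },
}


def default_config(n_calls: int = 5418, seed: int = 0) -> GeneratorConfig:
    """Packaged default calibration of the synthetic registry.

    The defaults reproduce, in expectation, the descriptive marginals of the
    study population: 24.2% of calls recorded without chest pain, emergency
    ambulances for 90% of chest-pain and 40% of non-chest-pain calls,
    prehospital ASA for 73% and 37% of dispatched, non-contraindicated
    chest/non-chest calls, and the group-wise crude 30-day and 1-year
    outcome frequencies.
    """
    law = copy.deepcopy(_DEFAULT_COVARIATE_LAW)
    for name, intercept in _CALIBRATED["binary_intercepts"].items():
        law["binary"][name]["intercept"] = intercept

    symptom = {"intercept": _CALIBRATED["symptom_intercept"], **_SYMPTOM_SLOPES}
    amb = {
        g: {"intercept": _CALIBRATED["amb_intercepts"][g], **_AMB_SLOPES[g]}
        for g in GROUPS
    }
    asa = {
        g: {"intercept": _CALIBRATED["asa_intercepts"][g], **_ASA_SLOPES[g]}
        for g in GROUPS
    }
    y30 = {
        "chest": {
            "intercept": _CALIBRATED["y30"]["intercept_chest"],
            "amb": _CALIBRATED["y30"]["amb_chest"],
            "asa": _CALIBRATED["y30"]["asa"],
            **_Y30_W_SLOPES,
        },
        "nonchest": {
            "intercept": _CALIBRATED["y30"]["intercept_nonchest"],
            "amb": _CALIBRATED["y30"]["amb_nonchest"],
            "asa": _CALIBRATED["y30"]["asa"],
            **_Y30_W_SLOPES,
        },
    }
    y1yr = {
        "chest": {
            "intercept": _CALIBRATED["y1yr"]["intercept_chest"],
            "amb": _CALIBRATED["y1yr"]["amb_chest"],
            "asa": _CALIBRATED["y1yr"]["asa"],
            **_Y1YR_W_SLOPES,
        },
        "nonchest": {
            "intercept": _CALIBRATED["y1yr"]["intercept_nonchest"],
            "amb": _CALIBRATED["y1yr"]["amb_nonchest"],
            "asa": _CALIBRATED["y1yr"]["asa"],
            **_Y1YR_W_SLOPES,
        },
    }

    config = GeneratorConfig(
        n_calls=n_calls,
        seed=seed,
        covariate_law=law,
        symptom_coefs=symptom,
        amb_coefs=amb,
        asa_coefs=asa,
        contraindication_rate={"chest": 57 / 3689, "nonchest": 7 / 525},
        infarct_coefs=copy.deepcopy(_INFARCT_COEFS),
        y30_coefs=y30,
        y1yr_coefs=y1yr,
        timestamp_law=dict(_DEFAULT_TIMESTAMP_LAW),
        repeat_call_rate=0.07,
        exclusion_counts=dict(_DEFAULT_EXCLUSION_COUNTS),
        missing_education_rate=284 / 1967,  # missing raw records among latent basic
        missing_ethnicity_rate=0.01,
    )
    config.validate()
    return config


def null_exposure_config(config: GeneratorConfig, exposure: str) -> GeneratorConfig:
    """Return a copy of ``config`` with no outcome effect of ``exposure``.

    For the ambulance exposure both the dispatch and the ASA coefficients are
    zeroed, because ASA administration is a downstream consequence of
    dispatch; leaving an ASA effect in place would let a dispatch
    intervention act through the mediator.
    """
    if exposure not in ("ambulance", "asa"):
        raise ValueError(f"unknown exposure {exposure!r}")
    out = config.copy()
    terms = ("amb", "asa") if exposure == "ambulance" else ("asa",)
    for table in (out.y30_coefs, out.y1yr_coefs):
        for g in GROUPS:
            for term in terms:
                if term in table[g]:
                    table[g][term] = 0.0
    return out
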