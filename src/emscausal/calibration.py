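"""Numerical calibration of the default generator to the study marginals.

The packaged default configuration must reproduce, in expectation, the
descriptive frequencies of the study population (symptom shares, dispatch
and ASA rates, crude outcome risks).  Slopes of every conditional logistic
model are fixed design choices; this module solves the free intercepts so
the implied marginals hit their targets, by Monte Carlo root finding on a
large common set of covariate draws.

The solved values are frozen into :mod:`emscausal.config`; re-running
:func:`calibrate_default` reproduces them up to Monte Carlo error.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from . import synthetic
from .config import GROUPS, default_config
from .synthetic import _expit, _per_row_target_risk, _sample_covariates, linear_predictor

#: marginal frequencies of the study population the default law is tuned to
CALIBRATION_TARGETS = {
    "binary": {
        "male": 3559 / 5418,
        "service_112": 3526 / 5418,
        "immigrant": 0.157,
        "t2d": 874 / 5418,
        "hypertension": 1867 / 5418,
        "opioid": 940 / 5418,
        "nsaid": 711 / 5418,
        "ihd": 1378 / 5418,
        "prev_mi": 899 / 5418,
        "heart_failure": 571 / 5418,
        "cancer": 509 / 5418,
        "renal": 295 / 5418,
        "copd": 440 / 5418,
        "afib": 548 / 5418,
    },
    "nonchest_share": 1309 / 5418,
    "amb": {"chest": 3689 / 4109, "nonchest": 525 / 1309},
    "asa": {"chest": 2668 / 3632, "nonchest": 192 / 518},
    "y30": {
        "marginal": {"chest": 116 / 4109, "nonchest": 143 / 1309},
        "asa_pop": {"chest": 0.030, "nonchest": 0.128},
        "all_asa_nonchest": 0.074,
    },
    "y1yr": {
        "marginal": {"chest": 0.185, "nonchest": 0.316},
        "asa_pop": {"chest": 0.187, "nonchest": 0.339},
        "all_asa_nonchest": 0.313,
    },
}


def _wmean(weights, values):
    return float(np.dot(weights, values) / weights.sum())


def calibrate_default(m: int = 1_500_000, seed: int = 12345) -> dict:
    """Solve all free intercepts of the default law; returns the frozen dict."""
    rng = np.random.default_rng(seed)
    config = default_config()
    law = config.covariate_law
    z_center, z_scale = law["age_center"], law["age_scale"]

    # ---- stage A: covariate intercepts ------------------------------------
    age_law = law["age"]
    age = age_law["offset"] - rng.lognormal(age_law["mu"], age_law["sigma"], m)
    keep = (age >= age_law["min"]) & (age <= age_law["max"])
    while not keep.all():
        redraw = age_law["offset"] - rng.lognormal(
            age_law["mu"], age_law["sigma"], int((~keep).sum())
        )
        age[~keep] = redraw
        keep = (age >= age_law["min"]) & (age <= age_law["max"])
    z = (age - z_center) / z_scale

    binary_intercepts = {}
    for name, target in CALIBRATION_TARGETS["binary"].items():
        slope = law["binary"][name].get("z_age", 0.0)
        sol = optimize.brentq(
            lambda b: float(_expit(b + slope * z).mean()) - target, -10.0, 10.0
        )
        binary_intercepts[name] = round(float(sol), 4)
        law["binary"][name]["intercept"] = binary_intercepts[name]

    # ---- common covariate draws under the solved law ----------------------
    df = _sample_covariates(np.random.default_rng(seed + 1), m, law)

    # ---- stage B: symptom intercept ---------------------------------------
    coefs = dict(config.symptom_coefs)

    def nonchest_mean(b0):
        coefs["intercept"] = b0
        return float(_expit(linear_predictor(df, coefs, law)).mean())

    b_sym = optimize.brentq(
        lambda b: nonchest_mean(b) - CALIBRATION_TARGETS["nonchest_share"], -8, 8
    )
    config.symptom_coefs["intercept"] = round(float(b_sym), 4)
    p_nonchest = _expit(linear_predictor(df, config.symptom_coefs, law))
    w_group = {"nonchest": p_nonchest, "chest": 1.0 - p_nonchest}

    # ---- stage C/D: dispatch and ASA intercepts ---------------------------
    amb_intercepts, asa_intercepts = {}, {}
    p_amb = {}
    for g in GROUPS:
        coefs = dict(config.amb_coefs[g])

        def amb_rate(b0, coefs=coefs, g=g):
            coefs["intercept"] = b0
            return _wmean(w_group[g], _expit(linear_predictor(df, coefs, law)))

        sol = optimize.brentq(
            lambda b: amb_rate(b) - CALIBRATION_TARGETS["amb"][g], -8, 8
        )
        amb_intercepts[g] = round(float(sol), 4)
        config.amb_coefs[g]["intercept"] = amb_intercepts[g]
        p_amb[g] = _expit(linear_predictor(df, config.amb_coefs[g], law))

        coefs_asa = dict(config.asa_coefs[g])
        w_asa_pop = w_group[g] * p_amb[g]  # contraindication is independent of W

        def asa_rate(b0, coefs=coefs_asa, w=w_asa_pop):
            coefs["intercept"] = b0
            return _wmean(w, _expit(linear_predictor(df, coefs, law)))

        sol = optimize.brentq(
            lambda b: asa_rate(b) - CALIBRATION_TARGETS["asa"][g], -8, 8
        )
        asa_intercepts[g] = round(float(sol), 4)
        config.asa_coefs[g]["intercept"] = asa_intercepts[g]

    # ---- stage E/F: outcome intercepts and exposure effects ---------------
    result = {
        "binary_intercepts": binary_intercepts,
        "symptom_intercept": config.symptom_coefs["intercept"],
        "amb_intercepts": amb_intercepts,
        "asa_intercepts": asa_intercepts,
    }
    for outcome in ("y30", "y1yr"):
        targets = CALIBRATION_TARGETS[outcome]
        table = config.y30_coefs if outcome == "y30" else config.y1yr_coefs

        def residuals(x, table=table, targets=targets, outcome=outcome):
            table["chest"]["intercept"] = x[0]
            table["nonchest"]["intercept"] = x[1]
            table["chest"]["amb"] = x[2]
            table["nonchest"]["amb"] = x[3]
            table["chest"]["asa"] = x[4]
            table["nonchest"]["asa"] = x[4]
            res = []
            for g in GROUPS:
                r = _per_row_target_risk(df, config, "ambulance", "none", g, outcome)
                res.append(_wmean(w_group[g], r) - targets["marginal"][g])
            for g in GROUPS:
                r = _per_row_target_risk(df, config, "asa", "none", g, outcome)
                res.append(_wmean(w_group[g] * p_amb[g], r) - targets["asa_pop"][g])
            r = _per_row_target_risk(df, config, "asa", "all", "nonchest", outcome)
            res.append(
                _wmean(w_group["nonchest"] * p_amb["nonchest"], r)
                - targets["all_asa_nonchest"]
            )
            return res

        x0 = np.array(
            [
                table["chest"]["intercept"],
                table["nonchest"]["intercept"],
                table["chest"].get("amb", 0.0),
                table["nonchest"].get("amb", 0.0),
                table["chest"].get("asa", 0.0),
            ]
        )
        sol = optimize.root(residuals, x0, method="hybr", tol=1e-10)
        if not sol.success:
            raise RuntimeError(f"{outcome} calibration failed: {sol.message}")
        x = np.round(sol.x, 4)
        residuals(x)  # leave the rounded solution in the config
        result[outcome] = {
            "intercept_chest": float(x[0]),
            "intercept_nonchest": float(x[1]),
            "amb_chest": float(x[2]),
            "amb_nonchest": float(x[3]),
            "asa": float(x[4]),
        }
    return result
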