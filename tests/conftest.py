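"""Shared fixtures: configurations, small synthetic registries, toy cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emscausal import default_config, generate_registry
from emscausal.config import GeneratorConfig


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return default_config()


@pytest.fixture(scope="session")
def small_registry():
    """A small but complete registry (600 eligible calls plus decoys)."""
    cfg = default_config(n_calls=600)
    cfg.exclusion_counts = {
        "age_under_30": 5,
        "no_mi_within_24h": 14,
        "nursing_home": 33,
        "palliative": 17,
        "dead_at_call": 11,
        "unconscious": 22,
        "noninformative_criterion": 38,
    }
    return cfg, generate_registry(cfg, seed=20240)


def toy_discrete_config(
    beta_a: float = 0.8,
    beta_asa: float = -0.5,
    w_prob_logit: float = 0.0,
) -> GeneratorConfig:
    """Single-binary-covariate law with a degenerate age; enumeration-friendly."""
    law = {
        "age": {"kind": "discrete", "values": [60.0], "probs": [1.0]},
        "age_center": 60.0,
        "age_scale": 10.0,
        "binary": {"w": {"intercept": w_prob_logit, "z_age": 0.0}},
        "education": None,
    }
    cfg = GeneratorConfig(
        n_calls=0,
        seed=0,
        covariate_law=law,
        symptom_coefs={"intercept": -0.5, "w": 0.4},
        amb_coefs={
            "chest": {"intercept": 1.2, "w": 0.5},
            "nonchest": {"intercept": -0.6, "w": 0.5},
        },
        asa_coefs={
            "chest": {"intercept": 0.8, "w": -0.3},
            "nonchest": {"intercept": -0.4, "w": -0.3},
        },
        contraindication_rate={"chest": 0.01, "nonchest": 0.01},
        infarct_coefs={
            "chest": {"STEMI": {"intercept": 0.0}, "other": {"intercept": -0.5}},
            "nonchest": {"STEMI": {"intercept": -0.3}, "other": {"intercept": 0.1}},
        },
        y30_coefs={
            "chest": {"intercept": -2.5, "w": 0.6, "amb": beta_a, "asa": beta_asa},
            "nonchest": {"intercept": -1.8, "w": 0.6, "amb": beta_a, "asa": beta_asa},
        },
        y1yr_coefs={
            "chest": {"intercept": -1.5, "w": 0.5, "amb": 0.2, "asa": -0.1},
            "nonchest": {"intercept": -1.0, "w": 0.5, "amb": 0.2, "asa": -0.1},
        },
        timestamp_law={
            "start": "2015-04-01",
            "end": "2018-12-31",
            "delay_log_mu_minutes": np.log(50.0),
            "delay_log_sigma": 0.35,
            "delay_min_minutes": 10.0,
            "delay_max_minutes": 1380.0,
        },
        repeat_call_rate=0.0,
    )
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def toy_cfg() -> GeneratorConfig:
    return toy_discrete_config()


def saturated_toy_cohort() -> pd.DataFrame:
    """Deterministic two-group cohort over one binary covariate.

    Cell layout (group, w, a) -> (records, events); event rates stay inside
    (0.05, 0.95) so the default propensity truncation is inactive.
    """
    cells = {
        ("nonchest", 0, 0): (10, 3),
        ("nonchest", 0, 1): (8, 2),
        ("nonchest", 1, 0): (12, 5),
        ("nonchest", 1, 1): (10, 4),
        ("chest", 0, 0): (6, 1),
        ("chest", 0, 1): (14, 3),
        ("chest", 1, 0): (5, 2),
        ("chest", 1, 1): (15, 6),
    }
    rows = []
    for (group, w, a), (n, events) in cells.items():
        for i in range(n):
            rows.append(
                {
                    "symptom_group": group,
                    "w": w,
                    "amb": a,
                    "y30": int(i < events),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_cohort() -> pd.DataFrame:
    return saturated_toy_cohort()
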