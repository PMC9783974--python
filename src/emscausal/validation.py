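"""Simulation studies validating the estimator against the generator truth.

The recovery study repeatedly draws analysis cohorts from a configured law,
runs the four main analyses for both outcomes, and summarizes bias against
the exact/Monte-Carlo ground truth, influence-curve CI coverage of the
intervention-specific risk, and the rejection rate of the expected-change
test (the latter is the type-I error rate under a null configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import select_asa_population
from .config import AnalysisConfig, GeneratorConfig
from .estimator import (
    ANALYSES,
    FluctuationError,
    InterventionSpec,
    expected_change,
    observed_risk,
    tmle,
)
from .nuisance import DegenerateOutcomeError, NonEstimableError, fit_nuisances
from .synthetic import generate_analysis_table, true_risk

OUTCOMES = ("y30", "y1yr")


@dataclass
class RecoveryResult:
    """Replicate-level draws and their summary for one simulation study."""

    estimates: pd.DataFrame  # one row per (replicate, analysis, outcome)
    summary: pd.DataFrame  # one row per (analysis, outcome)
    truth: dict
    n_calls: int
    replicates: int


def _truth_table(config: GeneratorConfig, n_draws: int, seed: int) -> dict:
    truth = {}
    for exposure, kind in ANALYSES:
        for outcome in OUTCOMES:
            for intervention in ("none", kind):
                key = (exposure, intervention, outcome)
                if key not in truth:
                    truth[key] = true_risk(
                        config,
                        exposure,
                        intervention,
                        outcome,
                        group="nonchest",
                        method="monte_carlo",
                        n_draws=n_draws,
                        seed=seed,
                    )
    return truth


def run_recovery_study(
    config: GeneratorConfig,
    n_calls: int = 5000,
    replicates: int = 500,
    seed: int = 0,
    analysis_config: AnalysisConfig | None = None,
    truth_draws: int = 4_000_000,
) -> RecoveryResult:
    """Parameter-recovery / coverage study for the four main analyses.

    Per replicate a fresh cohort of ``n_calls`` is drawn and each analysis
    (ambulance and ASA exposure, ``as_reference`` and ``all`` intervention)
    is run for both outcomes.  The summary reports, per analysis cell, the
    mean estimate, the Monte Carlo standard error of that mean (combined
    with the truth's own Monte Carlo error), bias, 95% CI coverage of the
    intervention risk, and the rejection rate of the Δ = 0 test.
    """
    if analysis_config is None:
        analysis_config = AnalysisConfig()
    truth = _truth_table(config, truth_draws, seed=seed + 90_001)
    rng = np.random.default_rng([seed, 55_801])
    rep_seeds = rng.integers(0, 2**31 - 1, size=replicates)

    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        cohort = generate_analysis_table(config, seed=int(rep_seed), n_calls=n_calls)
        asapop = select_asa_population(cohort)
        for exposure in ("ambulance", "asa"):
            population = cohort if exposure == "ambulance" else asapop
            for outcome in OUTCOMES:
                try:
                    nuis = fit_nuisances(
                        population, exposure, outcome, config=analysis_config
                    )
                except (NonEstimableError, DegenerateOutcomeError):
                    continue
                obs = observed_risk(population, "nonchest", outcome)
                for kind in ("as_reference", "all"):
                    if (exposure, kind) not in ANALYSES:
                        continue
                    spec = InterventionSpec(kind=kind, exposure=exposure)
                    try:
                        est = tmle(population, nuis, spec, outcome)
                    except (FluctuationError, NonEstimableError):
                        continue
                    contrast = expected_change(obs, est)
                    rows.append(
                        {
                            "replicate": rep,
                            "exposure": exposure,
                            "intervention": kind,
                            "outcome": outcome,
                            "psi": est.psi,
                            "ci_lower": est.ci_lower,
                            "ci_upper": est.ci_upper,
                            "psi_observed": obs.psi,
                            "delta": contrast.delta,
                            "delta_lower": contrast.ci_lower,
                            "delta_upper": contrast.ci_upper,
                        }
                    )
    estimates = pd.DataFrame(rows)
    summary = _summarize(estimates, truth)
    return RecoveryResult(
        estimates=estimates,
        summary=summary,
        truth=truth,
        n_calls=n_calls,
        replicates=replicates,
    )


def _summarize(estimates: pd.DataFrame, truth: dict) -> pd.DataFrame:
    rows = []
    for (exposure, kind, outcome), sub in estimates.groupby(
        ["exposure", "intervention", "outcome"]
    ):
        t_int = truth[(exposure, kind, outcome)]
        t_obs = truth[(exposure, "none", outcome)]
        true_psi = t_int.value
        true_delta = t_obs.value - t_int.value
        n = len(sub)
        mean_psi = float(sub["psi"].mean())
        se_mean = float(sub["psi"].std(ddof=1) / np.sqrt(n))
        mc_se = float(np.hypot(se_mean, t_int.mc_error or 0.0))
        covered = (sub["ci_lower"] <= true_psi) & (true_psi <= sub["ci_upper"])
        rejected = (sub["delta_lower"] > 0.0) | (sub["delta_upper"] < 0.0)
        delta_se_mean = float(sub["delta"].std(ddof=1) / np.sqrt(n))
        delta_mc_se = float(
            np.hypot(delta_se_mean, np.hypot(t_int.mc_error or 0.0, t_obs.mc_error or 0.0))
        )
        rows.append(
            {
                "exposure": exposure,
                "intervention": kind,
                "outcome": outcome,
                "replicates_used": n,
                "true_psi": true_psi,
                "mean_psi": mean_psi,
                "bias": mean_psi - true_psi,
                "mc_se": mc_se,
                "coverage": float(covered.mean()),
                "true_delta": true_delta,
                "mean_delta": float(sub["delta"].mean()),
                "delta_bias": float(sub["delta"].mean()) - true_delta,
                "delta_mc_se": delta_mc_se,
                "rejection_rate": float(rejected.mean()),
            }
        )
    return pd.DataFrame(rows)
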