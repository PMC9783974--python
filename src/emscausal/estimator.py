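"""TMLE of intervention-specific risks and expected risk reductions.

The target parameter is an interventional disparity effect: the expected
outcome risk in the non-chest-pain group had its exposure (emergency
ambulance dispatch, or prehospital ASA among dispatched patients) been
assigned either to everyone (``all``) or with the chest-pain group's fitted
conditional probability (``as_reference``), standardized to the target
group's covariate distribution, contrasted with the group's observed risk.

Estimation follows canonical logistic-fluctuation TMLE for a stochastic
intervention on a binary exposure: the initial outcome regression Q̄ is
fluctuated along the least-favorable submodel using the clever covariate

    H = [A π*(1|W) + (1-A)(1-π*(1|W))] / [A ĝ(1|W) + (1-A)(1-ĝ(1|W))]

until the efficient-score equation Σ H (Y - Q*) = 0 is solved, and ψ is the
plug-in under the fluctuated Q*.  Standard errors come from the empirical
influence curve; π̂_ref and p̂0 are treated as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .config import AnalysisConfig
from .cohort import select_asa_population
from .nuisance import (
    DegenerateOutcomeError,
    NonEstimableError,
    NuisanceSet,
    REFERENCE_GROUP,
    fit_nuisances,
)

_QBOUND = 1e-10
SCORE_TOL = 1e-9


@dataclass
class InterventionSpec:
    """A hypothetical exposure assignment for one target group."""

    kind: str  # "all" | "as_reference"
    exposure: str  # "ambulance" | "asa"
    target_group: str = "nonchest"

    def __post_init__(self):
        if self.kind not in ("all", "as_reference"):
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.exposure not in ("ambulance", "asa"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.kind == "as_reference" and self.target_group == REFERENCE_GROUP:
            raise ValueError(
                "as_reference requires a reference group distinct from the target"
            )


@dataclass
class EstimateResult:
    """One estimated risk with influence-curve inference."""

    psi: float
    se: float
    ci_lower: float
    ci_upper: float
    n_target: int
    epsilon: float = 0.0
    mean_ic: float = 0.0
    score: float = 0.0
    ic: np.ndarray = field(repr=False, default=None)
    index: np.ndarray = field(repr=False, default=None)


@dataclass
class ContrastResult:
    """Expected change under the intervention: observed minus intervened.

    Positive values mean the intervention lowers risk.
    """

    delta: float
    se: float
    ci_lower: float
    ci_upper: float
    psi_observed: float
    psi_intervention: float
    n_target: int


class FluctuationError(RuntimeError):
    """The targeting step failed to solve the score equation."""


def _wald_ci(est, se, alpha):
    z = norm.ppf(1.0 - alpha / 2.0)
    return est - z * se, est + z * se


def intervention_distribution(
    spec: InterventionSpec, nuisances: NuisanceSet, records: pd.DataFrame
) -> np.ndarray:
    """π*(1|W) per record: 1 under ``all``, π̂_ref(W) under ``as_reference``."""
    if spec.kind == "all":
        return np.ones(len(records))
    if nuisances.pi_ref_model is None:
        raise ValueError("as_reference intervention requires a reference model")
    return nuisances.predict_pi_ref(records)


def observed_risk(
    cohort: pd.DataFrame, group: str, outcome: str, alpha: float = 0.05
) -> EstimateResult:
    """Empirical outcome risk in a symptom group with IC-based inference."""
    target = cohort[cohort["symptom_group"] == group]
    if target.empty:
        raise ValueError(f"group {group!r} is empty")
    y = target[outcome].to_numpy(float)
    psi = float(y.mean())
    ic = y - psi
    se = float(ic.std(ddof=0) / np.sqrt(len(y)))
    lo, hi = _wald_ci(psi, se, alpha)
    return EstimateResult(
        psi=psi,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        n_target=len(y),
        mean_ic=float(ic.mean()),
        ic=ic,
        index=target.index.to_numpy(),
    )


def plug_in(
    nuisances: NuisanceSet, spec: InterventionSpec, target: pd.DataFrame
) -> float:
    """Untargeted g-computation: average of π* Q̄(1,·) + (1-π*) Q̄(0,·)."""
    pi = intervention_distribution(spec, nuisances, target)
    q1 = nuisances.predict_q(target, a=1)
    q0 = nuisances.predict_q(target, a=0)
    return float(np.mean(pi * q1 + (1.0 - pi) * q0))


def tmle(
    cohort: pd.DataFrame,
    nuisances: NuisanceSet,
    spec: InterventionSpec,
    outcome: str | None = None,
    alpha: float = 0.05,
    max_iter: int = 100,
) -> EstimateResult:
    """Targeted estimate of the intervention-specific risk.

    Fluctuates Q̄ by maximum-likelihood logistic regression of Y on the
    clever covariate H with offset logit Q̄(A, W) and no intercept, fit on
    the target-group records; ψ is the plug-in under the fluctuated Q*, and
    the Wald CI uses the empirical influence curve
    ``H (Y - Q*) + m*(W) - ψ`` with m*(W) = π* Q*(1,W) + (1-π*) Q*(0,W).
    """
    outcome = nuisances.outcome if outcome is None else outcome
    target = cohort[cohort["symptom_group"] == spec.target_group]
    if target.empty:
        raise NonEstimableError(f"target group {spec.target_group!r} is empty")
    y = target[outcome].to_numpy(float)
    a = target[nuisances.exposure_col].to_numpy(float)
    if np.isnan(a).any():
        raise ValueError("exposure undefined for part of the target records")

    pi = intervention_distribution(spec, nuisances, target)
    g1 = nuisances.predict_g(target)
    q1 = np.clip(nuisances.predict_q(target, a=1), _QBOUND, 1.0 - _QBOUND)
    q0 = np.clip(nuisances.predict_q(target, a=0), _QBOUND, 1.0 - _QBOUND)

    h1 = pi / g1
    h0 = (1.0 - pi) / (1.0 - g1)
    h_obs = np.where(a == 1.0, h1, h0)
    logit_q_obs = np.where(a == 1.0, logit(q1), logit(q0))

    # one-dimensional ML logistic fluctuation, Newton with step halving
    eps = 0.0
    converged = False
    for _ in range(max_iter):
        q_obs = expit(logit_q_obs + eps * h_obs)
        score = float(h_obs @ (y - q_obs))
        if abs(score) <= SCORE_TOL:
            converged = True
            break
        info = float((h_obs**2) @ (q_obs * (1.0 - q_obs)))
        if info <= 0.0:
            break
        step = score / info
        step = float(np.clip(step, -4.0, 4.0))
        eps += step
        if not np.isfinite(eps):
            break
    if not converged:
        q_obs = expit(logit_q_obs + eps * h_obs)
        score = float(h_obs @ (y - q_obs))
        if abs(score) > SCORE_TOL:
            raise FluctuationError(
                f"targeting did not converge: |score|={abs(score):.3e}, eps={eps:.3f}"
            )

    q1_star = expit(logit(q1) + eps * h1)
    q0_star = expit(logit(q0) + eps * h0)
    m_star = pi * q1_star + (1.0 - pi) * q0_star
    psi = float(m_star.mean())
    q_obs_star = np.where(a == 1.0, q1_star, q0_star)
    ic = h_obs * (y - q_obs_star) + m_star - psi
    se = float(ic.std(ddof=0) / np.sqrt(len(y)))
    lo, hi = _wald_ci(psi, se, alpha)
    return EstimateResult(
        psi=psi,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        n_target=len(y),
        epsilon=float(eps),
        mean_ic=float(ic.mean()),
        score=float(h_obs @ (y - q_obs_star)),
        ic=ic,
        index=target.index.to_numpy(),
    )


def expected_change(
    observed: EstimateResult, intervention: EstimateResult, alpha: float = 0.05
) -> ContrastResult:
    """Expected reduction Δ = ψ_observed − ψ_intervention with IC inference.

    Both estimates must be computed on the same target records; the
    influence curve of the contrast is the per-record difference of the two
    influence curves.
    """
    if observed.ic is None or intervention.ic is None:
        raise ValueError("both estimates must carry per-record influence curves")
    if observed.n_target != intervention.n_target or not np.array_equal(
        observed.index, intervention.index
    ):
        raise ValueError("estimates were computed on different record sets")
    delta = observed.psi - intervention.psi
    ic = observed.ic - intervention.ic
    se = float(ic.std(ddof=0) / np.sqrt(len(ic)))
    lo, hi = _wald_ci(delta, se, alpha)
    return ContrastResult(
        delta=float(delta),
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        psi_observed=observed.psi,
        psi_intervention=intervention.psi,
        n_target=observed.n_target,
    )


def brute_force_psi(
    cohort: pd.DataFrame,
    spec: InterventionSpec,
    covariates: tuple[str, ...],
    outcome: str = "y30",
    max_cells: int = 12,
    reference_group: str = REFERENCE_GROUP,
) -> float:
    """Nonparametric plug-in on a discrete cohort (oracle for validation).

    Cell means of the outcome by (A, covariate cell) in the target group,
    empirical reference exposure probabilities per cell (or 1 under
    ``all``), averaged over the target group's empirical cell distribution.
    Passing ``reference_group=spec.target_group`` uses the target group's
    own empirical exposure distribution, which reproduces the observed risk.
    """
    a_col = {"ambulance": "amb", "asa": "asa"}[spec.exposure]
    work = cohort.copy()
    work["_cell"] = list(zip(*(work[c] for c in covariates)))
    cells = sorted(set(work["_cell"]))
    if len(cells) > max_cells:
        raise ValueError(f"{len(cells)} cells exceed the limit of {max_cells}")
    target = work[work["symptom_group"] == spec.target_group]
    reference = work[work["symptom_group"] == reference_group]
    total = 0.0
    for cell, sub in target.groupby("_cell", sort=False):
        w = len(sub) / len(target)
        if spec.kind == "all":
            pi = 1.0
        else:
            ref_cell = reference[reference["_cell"] == cell]
            if ref_cell.empty:
                raise ValueError(f"empty reference stratum for cell {cell!r}")
            pi = float((ref_cell[a_col] == 1).mean())
        means = {}
        for aval in (0, 1):
            stratum = sub[sub[a_col] == aval]
            if stratum.empty:
                if (aval == 1 and pi > 0.0) or (aval == 0 and pi < 1.0):
                    raise ValueError(
                        f"empty (A={aval}) stratum in target cell {cell!r}"
                    )
                means[aval] = 0.0
            else:
                means[aval] = float(stratum[outcome].mean())
        total += w * (pi * means[1] + (1.0 - pi) * means[0])
    return total


# ---------------------------------------------------------------------------
# the full analysis grid
# ---------------------------------------------------------------------------

ANALYSES = (
    ("ambulance", "as_reference"),
    ("ambulance", "all"),
    ("asa", "as_reference"),
    ("asa", "all"),
)
STRATA = ("full", "STEMI", "NSTEMI", "calls_112")
TARGET_GROUPS = ("nonchest", "chest")
OUTCOMES = ("y30", "y1yr")


def _stratum_mask(cohort: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "full":
        return pd.Series(True, index=cohort.index)
    if stratum in ("STEMI", "NSTEMI"):
        return cohort["infarct_type"] == stratum
    if stratum == "calls_112":
        return cohort["service_112"] == 1
    raise ValueError(f"unknown stratum {stratum!r}")


def run_analysis(
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
    strata=STRATA,
    target_groups=TARGET_GROUPS,
    outcomes=OUTCOMES,
    analyses=ANALYSES,
) -> pd.DataFrame:
    """Execute the analysis grid and return one row per cell.

    Four main analyses (ambulance and ASA exposures, ``as_reference`` and
    ``all`` interventions) for both outcomes, across the population strata
    (full, STEMI, NSTEMI, 1-1-2 calls), for the non-chest-pain target group
    and the chest-pain counterparts (observed and ``all`` only; chest pain
    is its own reference distribution).  Non-estimable cells are flagged and
    retained.
    """
    if config is None:
        config = AnalysisConfig()
    rows = []
    for stratum in strata:
        sub = cohort[_stratum_mask(cohort, stratum)]
        for exposure, kind in analyses:
            population = sub if exposure == "ambulance" else select_asa_population(sub)
            for group in target_groups:
                if kind == "as_reference" and group == REFERENCE_GROUP:
                    for outcome in outcomes:
                        rows.append(
                            _grid_row(
                                stratum, exposure, kind, group, outcome,
                                flag="not_applicable",
                            )
                        )
                    continue
                for outcome in outcomes:
                    rows.append(
                        _run_cell(
                            population, stratum, exposure, kind, group, outcome, config
                        )
                    )
    return pd.DataFrame(rows)


def _grid_row(stratum, exposure, kind, group, outcome, flag="ok", **values):
    row = {
        "stratum": stratum,
        "exposure": exposure,
        "intervention": kind,
        "target_group": group,
        "outcome": outcome,
        "psi_observed": np.nan,
        "psi_intervention": np.nan,
        "delta": np.nan,
        "se": np.nan,
        "ci_lower": np.nan,
        "ci_upper": np.nan,
        "n_target": 0,
        "epsilon": np.nan,
        "flag": flag,
    }
    row.update(values)
    return row


def _run_cell(population, stratum, exposure, kind, group, outcome, config):
    try:
        nuis = fit_nuisances(
            population, exposure, outcome, config=config, target_group=group
        )
        spec = InterventionSpec(kind=kind, exposure=exposure, target_group=group)
        obs = observed_risk(population, group, outcome, alpha=config.alpha)
        est = tmle(
            population,
            nuis,
            spec,
            outcome,
            alpha=config.alpha,
            max_iter=config.max_fluctuation_iter,
        )
        contrast = expected_change(obs, est, alpha=config.alpha)
    except (NonEstimableError, DegenerateOutcomeError, FluctuationError, ValueError) as err:
        return _grid_row(
            stratum, exposure, kind, group, outcome, flag=f"non_estimable: {err}"
        )
    return _grid_row(
        stratum,
        exposure,
        kind,
        group,
        outcome,
        psi_observed=obs.psi,
        psi_intervention=est.psi,
        delta=contrast.delta,
        se=contrast.se,
        ci_lower=contrast.ci_lower,
        ci_upper=contrast.ci_upper,
        n_target=est.n_target,
        epsilon=est.epsilon,
    )
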