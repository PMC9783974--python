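"""TMLE, plug-in, brute-force oracle, contrasts, and the analysis grid."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from emscausal import default_config, generate_analysis_table
from emscausal.cohort import select_asa_population
from emscausal.config import AnalysisConfig
from emscausal.estimator import (
    ContrastResult,
    EstimateResult,
    InterventionSpec,
    brute_force_psi,
    expected_change,
    intervention_distribution,
    observed_risk,
    plug_in,
    run_analysis,
    tmle,
)
from emscausal.nuisance import CandidateSpec, NuisanceSet, fit_discrete_superlearner


def toy_nuisances(cohort: pd.DataFrame, trunc=(0.001, 0.999)) -> NuisanceSet:
    """Saturated nuisance models on the single-binary-covariate toy cohort."""
    target = cohort[cohort["symptom_group"] == "nonchest"]
    reference = cohort[cohort["symptom_group"] == "chest"]
    q = fit_discrete_superlearner(
        target,
        target["y30"].to_numpy(float),
        [CandidateSpec(("w", "amb"), interaction_order=2)],
        V=5,
        seed=0,
    )
    g = fit_discrete_superlearner(
        target, target["amb"].to_numpy(float), [CandidateSpec(("w",))], V=5, seed=0
    )
    pi = fit_discrete_superlearner(
        reference, reference["amb"].to_numpy(float), [CandidateSpec(("w",))], V=5, seed=0
    )
    return NuisanceSet(
        exposure="ambulance",
        outcome="y30",
        target_group="nonchest",
        q_model=q,
        g_model=g,
        pi_ref_model=pi,
        p0=len(target) / len(cohort),
        trunc=trunc,
    )


# ---------------------------------------------------------------------------
# intervention distributions and observed risk
# ---------------------------------------------------------------------------

def test_intervention_distribution(toy_cohort):
    nuis = toy_nuisances(toy_cohort)
    target = toy_cohort[toy_cohort["symptom_group"] == "nonchest"]
    spec_all = InterventionSpec(kind="all", exposure="ambulance")
    assert (intervention_distribution(spec_all, nuis, target) == 1.0).all()

    spec_ref = InterventionSpec(kind="as_reference", exposure="ambulance")
    pi = intervention_distribution(spec_ref, nuis, target)
    assert ((pi > 0) & (pi < 1)).all()
    np.testing.assert_allclose(pi, nuis.predict_pi_ref(target))

    nuis.pi_ref_model = None
    with pytest.raises(ValueError):
        intervention_distribution(spec_ref, nuis, target)

    with pytest.raises(ValueError):
        InterventionSpec(kind="as_reference", exposure="ambulance", target_group="chest")


def test_observed_risk_closed_form():
    cohort = pd.DataFrame(
        {"symptom_group": ["nonchest"] * 1309, "y30": [1] * 143 + [0] * (1309 - 143)}
    )
    est = observed_risk(cohort, "nonchest", "y30")
    assert est.psi == pytest.approx(0.1092, abs=5e-5)
    p = 143 / 1309
    assert est.se == pytest.approx(np.sqrt(p * (1 - p) / 1309), rel=1e-12)
    assert est.ci_lower <= est.psi <= est.ci_upper
    assert est.mean_ic == pytest.approx(0.0, abs=1e-12)

    zeros = pd.DataFrame({"symptom_group": ["chest"] * 40, "y30": 0})
    est0 = observed_risk(zeros, "chest", "y30")
    assert est0.psi == 0.0 and est0.se == 0.0
    with pytest.raises(ValueError):
        observed_risk(zeros, "nonchest", "y30")


def test_plug_in_degenerate_outcome_models(toy_cohort):
    nuis = toy_nuisances(toy_cohort)
    target = toy_cohort[toy_cohort["symptom_group"] == "nonchest"]

    class ConstantQ:
        def __init__(self, c):
            self.c = c

        def predict_proba(self, records):
            return np.full(len(records), self.c)

    nuis.q_model = ConstantQ(0.37)
    for kind in ("all", "as_reference"):
        spec = InterventionSpec(kind=kind, exposure="ambulance")
        assert plug_in(nuis, spec, target) == pytest.approx(0.37, rel=1e-12)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def test_brute_force_worked_instance():
    """Two cells at P(w=1)=0.5 with mean outcomes 0.1/0.2 under exposure."""
    rows = []
    for w, ybar in ((0, 0.1), (1, 0.2)):
        for i in range(10):
            rows.append({"symptom_group": "nonchest", "w": w, "amb": 1,
                         "y30": int(i < round(10 * ybar))})
        rows.append({"symptom_group": "nonchest", "w": w, "amb": 0, "y30": 0})
        rows.append({"symptom_group": "chest", "w": w, "amb": 1, "y30": 0})
    cohort = pd.DataFrame(rows)
    # equal cell sizes (11 each) -> weights 0.5; pi* = 1
    spec = InterventionSpec(kind="all", exposure="ambulance")
    got = brute_force_psi(cohort, spec, covariates=("w",))
    assert got == pytest.approx(0.5 * 0.1 + 0.5 * 0.2, rel=1e-12)


def test_brute_force_exhaustive_enumeration():
    """Agreement with a direct double sum over all 2^6 outcome assignments."""
    base = pd.DataFrame(
        {
            "symptom_group": ["nonchest"] * 4 + ["chest"] * 2,
            "w": [0, 0, 1, 1, 0, 1],
            "amb": [0, 1, 0, 1, 1, 0],
        }
    )
    spec = InterventionSpec(kind="all", exposure="ambulance")
    for bits in itertools.product((0, 1), repeat=6):
        cohort = base.assign(y30=list(bits))
        got = brute_force_psi(cohort, spec, covariates=("w",))
        # independent oracle: explicit sum over the target's cells
        target = cohort[cohort["symptom_group"] == "nonchest"]
        expected = 0.0
        for w in (0, 1):
            cell = target[target["w"] == w]
            expected += (len(cell) / len(target)) * cell.loc[
                cell["amb"] == 1, "y30"
            ].mean()
        assert got == pytest.approx(expected, rel=1e-12)


def test_brute_force_self_intervention_identity(toy_cohort):
    """π* taken from the target group itself returns the observed risk."""
    spec = InterventionSpec(kind="as_reference", exposure="ambulance")
    got = brute_force_psi(
        toy_cohort, spec, covariates=("w",), reference_group="nonchest"
    )
    observed = toy_cohort.loc[toy_cohort["symptom_group"] == "nonchest", "y30"].mean()
    assert got == pytest.approx(observed, rel=1e-12)


def test_brute_force_guards():
    cohort = pd.DataFrame(
        {
            "symptom_group": ["nonchest"] * 3 + ["chest"],
            "w": [0, 1, 2, 0],
            "amb": [1, 1, 1, 1],
            "y30": [0, 1, 0, 0],
        }
    )
    spec = InterventionSpec(kind="all", exposure="ambulance")
    with pytest.raises(ValueError):  # cells exceed the cap
        brute_force_psi(cohort, spec, covariates=("w",), max_cells=2)
    with pytest.raises(ValueError):  # empty exposed stratum needed under pi*>0
        brute_force_psi(
            cohort.assign(amb=[0, 1, 1, 1]), spec, covariates=("w",)
        )


# ---------------------------------------------------------------------------
# TMLE on saturated toy instances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind", ["all", "as_reference"])
def test_tmle_equals_oracle_on_saturated_instance(toy_cohort, kind):
    nuis = toy_nuisances(toy_cohort)
    spec = InterventionSpec(kind=kind, exposure="ambulance")
    target = toy_cohort[toy_cohort["symptom_group"] == "nonchest"]
    est = tmle(toy_cohort, nuis, spec, "y30")
    oracle = brute_force_psi(toy_cohort, spec, covariates=("w",))
    untargeted = plug_in(nuis, spec, target)
    assert est.psi == pytest.approx(oracle, rel=1e-11)
    assert untargeted == pytest.approx(oracle, rel=1e-11)
    assert abs(est.epsilon) < 1e-7
    assert abs(est.score) <= 1e-8
    assert est.ci_lower <= est.psi <= est.ci_upper


def test_tmle_fixed_point(toy_cohort):
    """Re-targeting an already-targeted outcome model leaves ψ unchanged."""
    nuis = toy_nuisances(toy_cohort)
    spec = InterventionSpec(kind="as_reference", exposure="ambulance")
    first = tmle(toy_cohort, nuis, spec, "y30")

    class TargetedQ:
        """Q* frozen from the first pass, exposed as an outcome model."""

        def __init__(self, nuis, eps, spec, cohort):
            self.nuis, self.eps, self.spec, self.cohort = nuis, eps, spec, cohort

        def predict_proba(self, records):
            from scipy.special import expit, logit

            pi = intervention_distribution(self.spec, self.nuis, records)
            g = self.nuis.predict_g(records)
            a = records["amb"].to_numpy(float)
            h = np.where(a == 1, pi / g, (1 - pi) / (1 - g))
            q = np.clip(self.nuis.q_model.predict_proba(records), 1e-10, 1 - 1e-10)
            return expit(logit(q) + self.eps * h)

    second_nuis = toy_nuisances(toy_cohort)
    second_nuis.q_model = TargetedQ(nuis, first.epsilon, spec, toy_cohort)
    second = tmle(toy_cohort, second_nuis, spec, "y30")
    assert second.psi == pytest.approx(first.psi, rel=1e-9)
    assert abs(second.epsilon) < 1e-7


def test_tmle_monotone_response(toy_cohort):
    """If exposure is never harmful in Q*, ψ(all) is the extreme risk."""
    nuis = toy_nuisances(toy_cohort)
    target = toy_cohort[toy_cohort["symptom_group"] == "nonchest"]
    q1 = nuis.predict_q(target, a=1)
    q0 = nuis.predict_q(target, a=0)
    psi_all = tmle(
        toy_cohort, nuis, InterventionSpec(kind="all", exposure="ambulance"), "y30"
    ).psi
    psi_ref = tmle(
        toy_cohort, nuis, InterventionSpec(kind="as_reference", exposure="ambulance"),
        "y30",
    ).psi
    if (q1 <= q0).all():
        assert psi_all <= psi_ref + 1e-12
    else:  # in the fixture exposure raises risk in every cell
        assert (q1 >= q0).all()
        assert psi_all >= psi_ref - 1e-12


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def test_expected_change_identity_and_arithmetic(toy_cohort):
    obs = observed_risk(toy_cohort, "nonchest", "y30")
    same = expected_change(obs, obs)
    assert same.delta == 0.0 and same.se == 0.0

    # the headline arithmetic: 12.8% observed minus 7.4% intervened
    a = EstimateResult(psi=0.128, se=0.01, ci_lower=0, ci_upper=1, n_target=4,
                       ic=np.array([0.1, -0.1, 0.05, -0.05]), index=np.arange(4))
    b = EstimateResult(psi=0.074, se=0.01, ci_lower=0, ci_upper=1, n_target=4,
                       ic=np.array([0.02, -0.02, 0.01, -0.01]), index=np.arange(4))
    contrast = expected_change(a, b)
    assert contrast.delta == pytest.approx(0.054, abs=1e-12)
    assert contrast.ci_lower <= contrast.delta <= contrast.ci_upper

    # variance triangle bound
    sd_sum = a.ic.std() + b.ic.std()
    assert (a.ic - b.ic).std() <= sd_sum + 1e-12

    with pytest.raises(ValueError):
        expected_change(a, EstimateResult(psi=0.1, se=0.01, ci_lower=0, ci_upper=1,
                                          n_target=3, ic=np.zeros(3), index=np.arange(3)))


def test_tmle_self_intervention_matches_observed(toy_cohort):
    """π* = target group's own ĝ reproduces the observed risk (saturated)."""
    nuis = toy_nuisances(toy_cohort)
    nuis.pi_ref_model = nuis.g_model  # reference distribution := own exposure law
    spec = InterventionSpec(kind="as_reference", exposure="ambulance")
    est = tmle(toy_cohort, nuis, spec, "y30")
    observed = toy_cohort.loc[toy_cohort["symptom_group"] == "nonchest", "y30"].mean()
    assert est.psi == pytest.approx(observed, rel=1e-11)


# ---------------------------------------------------------------------------
# analysis grid
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def grid_cohort():
    return generate_analysis_table(default_config(), seed=31, n_calls=2600)


def test_run_analysis_grid_shape_and_determinism(grid_cohort):
    config = AnalysisConfig(sl_seed=11)
    grid = run_analysis(grid_cohort, config=config, strata=("full", "STEMI"))
    # 2 strata x 4 analyses x 2 outcomes x 2 target groups
    assert len(grid) == 32
    chest_ref = grid[(grid.target_group == "chest") & (grid.intervention == "as_reference")]
    assert (chest_ref["flag"] == "not_applicable").all()
    ok = grid[grid["flag"] == "ok"]
    assert len(ok) > 0
    assert ok["psi_intervention"].between(0, 1).all()
    assert (ok["ci_lower"] <= ok["delta"] + 1e-12).all()
    assert (ok["delta"] <= ok["ci_upper"] + 1e-12).all()

    again = run_analysis(grid_cohort, config=config, strata=("full", "STEMI"))
    pd.testing.assert_frame_equal(grid, again)


def test_run_analysis_flags_positivity_failure(grid_cohort):
    broken = grid_cohort.copy()
    asa_pop = (broken["amb"] == 1) & (broken["asa_contraindicated"] == 0)
    broken.loc[asa_pop & (broken["symptom_group"] == "nonchest"), "asa"] = 0.0
    grid = run_analysis(
        broken, config=AnalysisConfig(), strata=("full",), analyses=(("asa", "all"),),
        target_groups=("nonchest",),
    )
    assert (grid["flag"].str.startswith("non_estimable")).all()


def test_targeting_score_solved_across_grid(grid_cohort):
    """The efficient-score equation is solved in every estimable cell."""
    config = AnalysisConfig(sl_seed=17)
    from emscausal.nuisance import fit_nuisances

    asa_pop = select_asa_population(grid_cohort)
    for exposure, population in (("ambulance", grid_cohort), ("asa", asa_pop)):
        for outcome in ("y30", "y1yr"):
            nuis = fit_nuisances(population, exposure, outcome, config=config)
            for kind in ("all", "as_reference"):
                est = tmle(
                    population, nuis,
                    InterventionSpec(kind=kind, exposure=exposure), outcome,
                )
                assert abs(est.score) <= 1e-8
                assert 0.0 <= est.psi <= 1.0
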