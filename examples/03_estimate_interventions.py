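"""Estimate risks under hypothetical prehospital interventions with TMLE.

For non-chest-pain MI patients we ask what their 30-day mortality would be
(i) had they received prehospital ASA as often as chest-pain patients do
given covariates ("as chest pain"), and (ii) had they all received it
("all").  Nuisance models are discrete-super-learner logistic regressions;
inference is influence-curve based.  Δ > 0 means the intervention lowers
risk.
"""

from emscausal import default_config, generate_analysis_table
from emscausal.cohort import select_asa_population
from emscausal.estimator import InterventionSpec, expected_change, observed_risk, tmle
from emscausal.nuisance import fit_nuisances

cohort = generate_analysis_table(default_config(), seed=11, n_calls=5418)
asa_pop = select_asa_population(cohort)

nuisances = fit_nuisances(asa_pop, exposure="asa", outcome="y30")
observed = observed_risk(asa_pop, "nonchest", "y30")
print(f"observed 30-day mortality, non-chest (ASA population): "
      f"{100 * observed.psi:.1f}% (n={observed.n_target})")

for kind, label in (("as_reference", "as chest pain"), ("all", "all receive ASA")):
    spec = InterventionSpec(kind=kind, exposure="asa", target_group="nonchest")
    est = tmle(asa_pop, nuisances, spec)
    contrast = expected_change(observed, est)
    print(f"{label:>16}: risk {100 * est.psi:.1f}% "
          f"[{100 * est.ci_lower:.1f}; {100 * est.ci_upper:.1f}], "
          f"reduction {100 * contrast.delta:.1f}% "
          f"[{100 * contrast.ci_lower:.1f}; {100 * contrast.ci_upper:.1f}]")
# Under the packaged calibration the all-ASA reduction is ~5% of absolute
# risk (true value 5.4%), mirroring the configured gap between observed
# (12.8%) and fully-treated (7.4%) mortality.
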