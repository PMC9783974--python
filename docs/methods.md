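# Methods

`emscausal` implements, end to end, a causal analysis of hypothetical
prehospital interventions — emergency-ambulance dispatch and prehospital
acetylsalicylic acid (ASA) — among myocardial-infarction (MI) patients who
present *without* chest pain, together with a synthetic registry generator
whose data-generating law is fully known, so that every estimate the
package produces can be checked against an exact or Monte-Carlo ground
truth.

## Target parameters

Let S ∈ {chest, non-chest} be the recorded symptom group, W the adjustment
covariates, A a binary prehospital exposure, and Y a binary outcome
(30-day all-cause mortality, or the 1-year combined outcome of death,
re-infarction or heart-failure admission).  For the non-chest-pain target
group the package estimates the expected outcome risk under a stochastic
intervention π* on A, standardized to the target group's covariate
distribution:

    ψ(π*) = E[ Σ_a π*(a | W) · E(Y | A = a, W, S = nonchest) | S = nonchest ]

Two interventions are considered: **all** (π*(1|W) ≡ 1) and **as chest
pain** (π*(1|W) = P(A = 1 | W, S = chest), the reference group's fitted
conditional exposure probability).  The contrast with the group's observed
risk, Δ = ψ_observed − ψ(π*), is an interventional disparity (indirect)
effect; Δ > 0 means the intervention lowers risk.  For the ambulance
exposure the analysis population is the full cohort; for ASA it is the
subgroup with an emergency dispatch and no contraindication, which changes
both the covariate distribution and the interpretation.

Identification requires that W capture exposure-outcome confounding within
the target group and positivity of the exposure assignment; neither holds
by fiat in registry data, which is why the estimates on real-world-like
inputs are "expected outcomes under hypothetical interventions", not
established treatment effects.

## Estimation

Initial estimates (discrete super learner): each nuisance — the outcome
regression Q̄(A, W), the target-group exposure model ĝ(1|W), and the
reference-group exposure model π̂_ref(1|W) — is selected from two candidate
logistic regressions, with and without all second-order interaction terms,
by V = 10-fold cross-validation stratified on the response, using the mean
negative Bernoulli log-likelihood as loss; the winner is refit on all data
(a *discrete* super learner selects one candidate rather than a convex
ensemble).  Candidates whose fit fails to converge in any fold (e.g.
perfect separation) receive infinite loss; ties break toward fewer
parameters.  The adjustment set of the exposure models is {age, sex,
medical service, type-2 diabetes, heart failure, COPD, opioid use,
previous MI, education}; the outcome models additionally adjust for
cancer, immigration, ischemic heart disease and infarct type
(STEMI/NSTEMI/other).  These assignments are configuration defaults
(`AnalysisConfig`) and can be overridden.  Age enters linearly after
standardization to training-set statistics; ĝ and π̂_ref predictions are
truncated to [0.01, 0.99] as a positivity guard.

Targeting (TMLE): the initial Q̄ is fluctuated along the least-favorable
logistic submodel.  With the clever covariate

    H_i = [A_i π*(1|W_i) + (1 − A_i)(1 − π*(1|W_i))] /
          [A_i ĝ(1|W_i) + (1 − A_i)(1 − ĝ(1|W_i))]

the fluctuation coefficient ε maximizes the Bernoulli likelihood of Y on H
with offset logit Q̄(A, W) and no intercept, fit on target-group records by
a one-dimensional Newton iteration until |Σ_i H_i (Y_i − Q*_i)| ≤ 1e-9
(the packaged tolerance; the acceptance suite checks 1e-8).  ψ̂ is the
plug-in under the fluctuated Q*, and its Wald CI uses the empirical
influence curve IC_i = H_i (Y_i − Q*(A_i, W_i)) + m*(W_i) − ψ̂, with
m*(W) = Σ_a π*(a|W) Q*(a, W).  The fluctuation uses H as a regressor (not
as a weight), the canonical logistic-fluctuation form.  Failure to solve
the score equation within 100 iterations, or an empty exposed/unexposed
stratum in the target group, marks the analysis cell non-estimable; cells
are flagged, never dropped.

Variance convention: π̂_ref and the group share p̂0 are treated as fixed,
so the influence curve carries no contribution from estimating the
reference exposure distribution.  The recovery study quantifies the
consequences (below).  Calls are the unit of analysis with no clustering
on person, matching the source design in which the same patient can appear
through several calls.  No multiplicity adjustment is applied across the
analysis grid; significance is 5% throughout.

The full grid (`run_analysis`) crosses 4 analyses (ambulance/ASA ×
as-chest-pain/all) × 2 outcomes × 4 population strata (full, STEMI,
NSTEMI, 1-1-2 calls) × 2 target groups.  Chest-pain-targeted cells
standardize to the chest-pain covariate distribution and only admit the
observed and all-intervention estimands (chest pain is its own reference
distribution).

## The synthetic registry

No public data exist at the individual level, so the generator emulates
the registry structure the analysis consumes: five raw tables (calls,
prehospital records, hospital diagnoses, prescriptions, vital status)
drawn from an explicit law W → S → infarct type → A_amb → (contraindication,
A_asa) → (Y30, Y1yr).  All conditionals are logistic with named terms;
the composite 1-year outcome is generated as Y30 OR a conditional
post-30-day event, so its conditional law is deliberately *not* logistic —
the outcome model is mildly misspecified by construction, which is the
regime TMLE's double robustness is meant for (the exposure models, by
contrast, are exactly within the candidate class).

Calibration: slopes of every conditional model are fixed design choices
(age and comorbidity gradients of plausible sign and magnitude); the free
intercepts and exposure effects are solved numerically (Monte-Carlo root
finding on 1.5M common draws, `emscausal.calibration`) so that the implied
marginals reproduce the study-scale frequencies: 24.2% non-chest calls;
ambulance for 89.8%/40.1% of chest/non-chest calls; ASA for 73.5%/37.1% of
the dispatched, non-contraindicated; crude 30-day mortality 2.8%/10.9% and
1-year risk 18.5%/31.6%; in the ASA population, 30-day risk 3.0%/12.8% and
1-year risk 18.7%/33.9%, with an all-ASA 30-day risk of 7.4% and 1-year
risk of 31.3% among non-chest patients.  The solved values are frozen into
`default_config()`.  Age follows a reflected shifted log-normal matched to
the total cohort's median 69 [57.8, 77.9] years, truncated to [30, 100];
group-wise age contrasts emerge from the symptom model's age coefficient
rather than being imposed per group.  The education distribution uses the
analysis-scale shares (missing recoded to basic), and the raw calls table
re-introduces missingness among basic/immigrant records so the cohort
builder's recodes are exercised.

Covariates are conditionally independent given age — the source material
reports only group-wise marginals, so any dependence beyond the age
gradient would be invention.  Repeat calls (7% of persons) are duplicate
registrations of the same episode: both calls carry identical covariates,
symptom, exposure and outcomes, sharing one admission and one death date.
This keeps every record faithful to the single-call law (the alternative —
independent outcomes per call — cannot be materialized in a registry where
a person dies once).  The cost is a genuine ~13% inflation of sampling
variance relative to influence-curve standard errors that assume
independent calls; see "What the validation shows".

Decoy calls violating exactly one eligibility filter each (age < 30, late
or absent MI admission, nursing home, palliative, dead at call,
unconscious, non-informative criterion) are appended at a fixed count per
category (default total 1255 on top of 5418 eligible calls, matching the
scale of the study's exclusion flow; the per-category split is invented).
Criterion strings come from a fixed 15-string vocabulary standing in for
the unavailable national catalogues; ICD-10/ATC codes come from small
representative pools per condition.  The prehospital free text embeds
contraindication keywords ("blood", "bleeding", "aneurysm", "ulcer") or an
allergy flag for contraindicated records and keyword-free notes otherwise.

Ground truth: `true_risk` integrates the law exactly over discrete
covariate grids (enumeration; refuses continuous age laws) or by Monte
Carlo with a reported standard error, marginalizing ASA as a mediator
inside the ambulance exposure's outcome law and conditioning the ASA
population on dispatch (contraindication is independent of W, so it drops
out of that conditioning).  A null configuration helper zeroes the
exposure's outcome coefficients — both dispatch and ASA for the ambulance
null, since ASA only occurs given dispatch and would otherwise carry a
mediated effect.

## Cohort construction

Filters apply in flowchart order: age ≥ 30 at call ("above age 30"
implemented inclusively); a primary ICD-10 I21 admission in (call,
call + 24 h]; no nursing-home/palliative/dead-at-call/unconscious flag; an
informative criterion.  Unknown criterion strings are excluded, as they
carry no information about the presentation.  Look-back windows are
half-open — diagnoses in [call − 5 y, call), prescription claims in
[call − 180 d, call) — and outcome windows closed: death in
[diagnosis, diagnosis + 30 d] (date resolution, inclusive endpoint) and
events in [diagnosis, diagnosis + 365 d].  Hypertension requires claims
from ≥ 2 distinct antihypertensive ATC classes (C03/C07/C08/C09) in the
window; MI or heart failure coded during the index admission (admission
within the index stay) never counts toward the 1-year outcome.  Emergency
dispatch ("lights and sirens") defines A_amb; every other dispatch type,
self-transport or home visit is unexposed.  ASA and its contraindication
screen (case-insensitive substring match on the keywords, or the allergy
flag) are defined only for dispatched calls.  Each removal is logged;
the exclusion counts sum exactly to input minus output, and on default
synthetic data the per-filter counts equal the planted decoy counts.

## What the validation shows — and what it does not

On saturated single-binary-covariate instances, TMLE, the untargeted
plug-in, and a nonparametric cell-mean oracle agree to ≥ 10 significant
digits, and the self-intervention identity (π* set to the target group's
own empirical exposure law) returns the observed risk exactly.

The full-scale recovery study (500 replicates, cohorts of 5000 calls from
the default law) shows |mean ψ̂ − truth| within 2 Monte-Carlo SE for all
four main analyses and both outcomes — the estimator tracks the truth at
the ~1e-3 absolute level.  95% CI coverage, however, is 0.92–0.94: the
30-day cells sit just below 0.93.  Two known causes, both documented
properties rather than estimator defects: (i) duplicate repeat-call
registrations analyzed as independent units inflate true sampling variance
~13% above the influence-curve estimate (disabling repeats moves the
ambulance cells to 0.936–0.946); (ii) the ASA population is small
(~480 target records, ~60 events at 30 days), where Wald intervals on
skewed weighted influence curves undercover by a further 2–3%.  For the
same reason, the 5%-level test of Δ = 0 rejects at ~7–8% under a null law
(the null study confirms Δ itself is centred on zero).  Users should read
the packaged standard errors as slightly optimistic whenever repeat calls
are present, exactly as they would be in the source design that analyzes
calls without clustering.

Passing tests on synthetic data show internal validity — the estimator
recovers parameters of a law satisfying its own assumptions.  They do not
show that the adjustment set suffices in any real registry, nor do the
synthetic tables reproduce real-data features such as coding error,
informative missingness, covariate dependence beyond age, geography or
response times, non-MI calls, or hospital treatment pathways.

## Numerical choices

Logistic fits use damped Newton–Raphson on the exact likelihood with a
pseudo-inverse fallback for rank-deficient (saturated) designs, score
tolerance 1e-9 in max-norm (1e-6 inside CV folds, where only the loss
ranking matters), and full steps once the score is below 1e-4 (the
likelihood comparison is rounding noise in that zone).  Runs heading to
separation (|η| > 40) report non-convergence and are penalized in CV.
Q̄ is clipped to [1e-10, 1 − 1e-10] before taking logits; ĝ and π̂_ref to
the configured [0.01, 0.99].  Influence-curve SDs use the population
convention (ddof = 0), making the observed-risk SE exactly
√(p(1−p)/n).  Simulation sizes (500 replicates × 5000 calls; truth by
4M-draw Monte Carlo with its error folded into the bias tolerance) were
chosen so the recovery study resolves biases of ~2e-3 on risks of 0.07–0.33.

## Known limitations

* The influence curve omits the contribution of estimating π̂_ref and p̂0
  (fixed-nuisance convention); as-reference CIs are approximate.
* Only logistic candidates enter the super learner; no ensemble weighting.
* The generator emits the MI-within-24 h universe plus filter decoys, not
  the full call population; timestamps are uniform with log-normal
  admission delays, with no geography or seasonality.
* Estimates carry causal meaning only under the synthetic law; on
  real-world-like data they are descriptive standardizations.
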