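# Methods

## Synthetic cohort model

Each subject is a draw from a declarative 38-variable schema
(`riskcascade.cohort.default_schema`) of binary, categorical, ordinal and
continuous questionnaire features. Non-continuous features are sampled
independently from their marginal probability vectors and stored as integer
level codes; age is uniform on [18, 69] years and stored continuously. The
ground truth is a latent body-mass index

    latent_bmi = b0 + Σ_f effect_f(x_f) + Σ_t interaction_t(x) + ε,
    ε ~ N(0, noise_sd²),  outcome = 1{latent_bmi ≥ 25 kg/m²},

so the binary outcome and a continuous ground truth are mutually consistent
with the standard BMI ≥ 25 overweight cut-off. Effects are signed weights on
the BMI scale (kg/m² per level, or per year for age, centred at 43.5). The
defaults encode the qualitative risk structure reported for this kind of
urban adult cohort: a dominant adverse age slope (0.105 kg/m² per year),
adverse ex-smoker status, apnea, metabolic syndrome, sedentarism and short
sleep; protective Mediterranean-diet adherence, medium/vigorous physical
activity and moderate wine/beer consumption; a 14-level recruitment-centre
nuisance variable with zero effect. The bimodal sex pattern is one
interaction pair: +1.0 kg/m² for women above 50 and for men aged 35–50.
These are qualitative emulations, not estimates of the study population.

`noise_sd` defaults to 2.6 kg/m². Together with the default effect scale
this places ten-fold CV accuracy of the nine single learners at ≈ 0.61–0.70
— the regime the cascade is meant to operate in, where single models are
informative but far from certain — and the cascade's classified-subset
accuracy near 0.78–0.80 at 55–65 % coverage. Larger noise collapses all
models toward the majority baseline; smaller noise makes every learner
confident and the reject option pointless.

When `target_prevalence` is set (default 0.45, inside the 0.42–0.48 band a
cohort of this kind reports), the intercept is calibrated by bisection
against a fixed internal Monte Carlo sample of 10 000 subjects, making the
calibrated intercept a deterministic function of (schema, effects); the
tolerance is 2 percentage points, and a target falling in a gap of the
attainable prevalence set (possible with large discrete effects) raises a
calibration error rather than silently drifting. All sampling flows through
one `numpy` generator per call, so identical (schema, effects, n, seed)
reproduce byte-identical tables.

What the generator does *not* emulate: missing data, recruitment-centre
selection bias, correlated features (beyond the declared interactions),
measurement error in the questionnaire instruments, and any real effect
*magnitudes*. Tests passing on this generator therefore demonstrate that the
machinery — deferral flow, selective metrics, ranking, attribution — behaves
correctly and that the qualitative effect structure is recoverable; they say
nothing quantitative about a real population.

## Cascade classifier

Stages are any of nine classical learners (AdaBoost, bagging, Bernoulli NB,
decision tree, extra trees, gradient boosting, Gaussian NB, logistic
regression, random forest), instantiated from scikit-learn with default
hyperparameters unless overridden per stage. Logistic regression and
Bernoulli NB are wrapped with standardisation — the latter so its
binarisation splits each feature at its mean rather than at code zero,
without which it degenerates on multi-level codes.

Acceptance thresholds default to 0.70 for the positive (overweight/obesity)
class and 0.80 for the negative (normal weight) class, in that order of
convention; since 0.70 + 0.80 > 1 the two conditions are mutually exclusive.
A probability exactly equal to its threshold is accepted. Design choices
where the procedure was genuinely open:

- **Training regime.** All stages are fitted on the full training set;
  deferral operates only at prediction time. The alternative — refitting
  each downstream stage on the rows its predecessors would defer — is
  implemented behind `refit_on_deferred` but is not the default, because the
  deferral flow is described for evaluation, and sequential refitting
  shrinks downstream training sets sharply (and can empty them).
- **Stage order.** `ordering_mode="manual"` uses the configured order
  (default gradient boosting → random forest → logistic regression);
  `"by_training_accuracy"` re-orders by descending 5-fold cross-validated
  training accuracy, stable under ties, covering the reading in which "the
  best classifier in training" leads.
- **Probabilities** are used as emitted by each learner; no post-hoc
  calibration, which would alter deferral behaviour invisibly.
- **Leftovers** after the final stage stay unclassified by default
  (`force_final` assigns the final stage's argmax label, flagged as forced,
  for deployments needing total coverage).

Flow bookkeeping is invariant-checked: received₁ = N,
receivedᵢ = deferredᵢ₋₁, classifiedᵢ + deferredᵢ = receivedᵢ, and a naive
per-sample reference loop (`reference_predict`) is kept as an oracle for the
vectorised implementation.

## Selective metrics

All metrics are computed over classified subjects only, with the
unclassified count carried alongside: the headline "correct classification
rate" is accuracy on the classified subset and is only meaningful next to
coverage. Macro averages are unweighted means over the two classes; weighted
averages weight by true-class support among classified subjects. Ratios with
zero denominators are reported as NaN with an `undefined` flag. Rounding to
printed precision (half away from zero) happens only in the presentation
helper; internal values are full precision.

## Ranking and the Friedman test

The harness re-splits each instance (75/25, stratified), refits every model,
and records the full metric panel; within a run all models see the same
split. Cascade entries are scored by classified-subset accuracy with
coverage recorded beside it. Ranking defaults to one rank vector per
instance over the models' mean accuracies (a per-run mode is available);
ties receive average ranks, so fractional ranks are legal. Rank dispersion
uses the sample convention (divisor n − 1). The statistic

    F_f = [12n/(k(k+1))] [Σ_j R_j² − k(k+1)²/4]

is referred to χ²(k−1) via scipy's quantile (regularised
incomplete-gamma inverse); no table lookup. With only n = 3 instances the
chi-square approximation is conservative: simulated null rejection at
α = 0.05 runs near 2 %, which the test suite asserts within [0.01, 0.12].

"Probability of winning" is the empirical fraction of (run, instance) cells
in which a model's accuracy is strictly maximal, exact ties splitting the
win equally; its uncertainty is the standard deviation over bootstrap
resamples of runs. This is an empirical-frequency reading of a
winner-summary plot whose original construction is not fully specified, and
is documented as such. Accuracy densities use a Gaussian KDE on a fixed
grid; zero-spread samples are flagged degenerate with the constant as mode.

## Shapley attribution

The attribution engine is implemented in-package. For a shared, seeded
collection of (permutation, background-row) pairs, the features of the
explained subject are inserted into the background row in permutation order
and the model-output increments are attributed to the inserted feature;
averaging over pairs gives the sampling estimator of the interventional
Shapley value. Reusing the same pairs for every feature makes the increments
telescope, so additivity — base value + Σ attributions = model output —
holds to float rounding (observed ≤ 1e-15; the contract requires 1e-4) by
construction, not asymptotically. An exact mode enumerates all p!
permutations over all background rows for p ≤ 6 and is used as the oracle
(together with an independent subset-enumeration implementation in the
tests). Defaults: 20 sampled permutations, a 100-row seeded subsample of the
training set as background, the positive-class probability as the explained
output (recorded in the attribution metadata).

For the multi-stage cascade the default policy explains stage 1, the model
every subject passes through; `per_stage_classified` explains each stage on
exactly the subjects it classified, and global importance then aggregates
stages weighted by classified counts. Both are interpretations — how to
attribute a deferral architecture is not canonically defined — and both are
exposed. Global importance is the mean absolute attribution per feature
normalised to sum to 1, ties broken alphabetically; waterfalls sort signed
contributions by magnitude with risk-increasing/-decreasing labels.

## Problem sizes and numerical notes

The shipped defaults (cohort n = 1179; 20-replicate recovery checks;
20-run CLI harness default with a flag for the study-scale 100; 2000-table
null simulation; 150-subject, 12-permutation attribution runs) were chosen
so the complete pipeline — generation, fitting, ranking, attribution — runs
end to end in well under an hour on a single CPU while keeping every
stochastic assertion's Monte Carlo error small relative to its margin.
Degenerate inputs are handled explicitly: single-class training sets,
single-class split parts, empty classified sets, single-run std, single
instance rank tables and zero-spread densities all raise or flag rather than
return silent zeros.

## Known limitations

- Feature independence (outside declared interactions) is unrealistic;
  real questionnaire variables are strongly collinear (e.g. profession and
  activity), which SHAP-style attributions are known to split across
  correlated features.
- The cascade's coverage is threshold- and calibration-sensitive; learners
  with poorly calibrated probabilities (unpruned trees emit 0/1) can starve
  or flood downstream stages.
- The Friedman test at n = 3 instances is conservative; failing to reject
  there is weak evidence of equivalence.
- Attribution of the cascade as a whole is policy-dependent; no policy is
  "the" Shapley value of the composite decision rule, which is
  discontinuous in the inputs.
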