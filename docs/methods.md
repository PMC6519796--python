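# Methods

This note documents the models and procedures implemented in `prognopipe`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not establish
about real data.

## The synthetic cohort generator

Real biobank cohorts of the kind this package targets are
access-restricted, so the generator (`prognopipe.synth`) produces cohorts
with the structural features that make such data hard, under a fully known
generative model.

**Covariates.** Seven core risk factors (age, gender, systolic blood
pressure, antihypertensive treatment, smoking, diabetes history, BMI) are
drawn with realistic marginals: age ~ N(56.4, 8.1) truncated to 40–73
years, 44.5% male, 4.22% diabetes prevalence, 10.5% current smokers, SBP
linearly age-dependent. The remaining variables are organised in the nine
standard biobank categories (health/medical history, lifestyle and
environment, blood assays, physical activity, family history, physical
measures, psychosocial, diet/nutrition, sociodemographics) as
block-equicorrelated Gaussians (pairwise ρ = 0.3 within a category by
default), with a mix of continuous, ordinal and small-cardinality
categorical codings. ~22% of variables carry a laboratory flag (all blood
assays plus a top-up of physical measures). Defaults give 60 variables —
a desk-scale stand-in for a several-hundred-variable table.

**Risk model.** The outcome is Bernoulli with logistic risk. The linear
predictor plants: a dominant age effect (0.9 per SD); smoking (0.5); SBP,
BMI, treatment, diabetes main effects; a strong ordinal non-laboratory
`walking_pace` effect (−0.45 per level); a laboratory `microalbumin`
effect whose coefficient is amplified by +0.6 in the diabetic subgroup; a
gender main effect; six extra linear effects (0.3 per SD) on non-core
variables; nonlinearities from a fixed transform library (quadratic BMI,
SBP threshold at 160 mmHg, saturating tanh on one assay; 0.35 each by
default); and interactions (age×smoking, gender-specific health-rating
effect; 0.25 each). The intercept is solved numerically (Brent) so mean
risk equals the configured prevalence (1.13% five-year default).
`signal_scale=0` yields a pure-noise cohort at the same prevalence.
Event times within the horizon are uniform for events, censored at the
horizon otherwise — enough for proportional-hazards fits, with no attempt
at a realistic hazard shape.

**Missingness.** Each non-core variable receives a Beta-distributed base
missingness rate with mean `missingness_overall` (0.25 default); the
per-cell missingness probability is logistic in that base rate shifted by
`informative_missingness_strength × outcome` (default 1.0 log-odds), so a
value is more likely to be missing for a participant with an event. Core
analogs stay near-complete (SBP 6.8%, BMI 0.62%, the rest and the outcome
fully observed). Note a consequence used by the tests: a cohort with all
effect sizes zeroed still carries *real* signal through the mask unless
the informativeness is also zeroed.

**What passing tests do not show.** The generator has Gaussian blocks,
exact logistic risk and a modest variable count; real cohorts have
heavy-tailed assays, structured non-response, measurement error and
hundreds of variables. Recovery results here demonstrate that the
machinery works when its assumptions hold; they are not estimates of
performance on any real cohort, and the headline AUCs of real studies are
not reproducible from synthetic data.

## Cohort filtering

Participants below the age floor (40) or with prior CVD are excluded
first; the variable screen is applied second (the ordering is a package
choice). A variable is retained iff it is missing for strictly less than
50% of participants *with events* — missingness is assessed among cases
because it may itself be informative; a variable at exactly the boundary
is excluded. Raising the threshold never removes a retained variable.

## Imputation

`impute_simple` fills with per-column mean/median/mode of observed values.
`impute_missforest` iterates variables in increasing-missingness order,
re-predicting each variable's missing cells with a random forest on all
others, stopping at the first increase of the normalized difference
between successive imputations (continuous and categorical tracked
separately), max 10 iterations. Multiple draws (default m = 5) differ only
in forest seeds. Pooling is prediction-level: the per-participant risk is
the arithmetic mean over draws. Coefficient-level variance combination is
deliberately out of scope. No imputer ever changes an observed cell.

Inside searched pipelines, the MissForest entry is inductive: the
per-column forests fitted on the training completion are stored and
re-applied to unseen rows, so no test-fold statistics enter the fit.

## Comparator models

**Framingham (office-based/BMI).** The published per-gender equation on
log(age), log(BMI), log(SBP) (treated/untreated), smoking and diabetes,
with risk `1 − S0(t)^exp(LP − mean LP)`. Coefficients live in a versioned
JSON constants file; they are data, not code, and are never refit. The
published baseline survival is at 10 years; other horizons use
constant-hazard scaling `S0(t) = S0(10)^(t/10)` — a monotone
transformation, so discrimination is unaffected; absolute 5-year risks
inherit the constant-hazard approximation.

**Cox PH.** Fitted on standardized covariates via partial likelihood, risk
at horizon from the Breslow baseline. The all-variables model first runs
LASSO preselection *on the binary outcome* (faithful to the comparator
design: a squared-error L1 model of the 0/1 outcome, not a survival
penalty), keeping non-zero-coefficient variables. λ is chosen by
cross-validation with the one-standard-error rule (the largest penalty
within one SE of the CV minimum) — the plain CV minimum keeps ~17% of
pure-noise variables, defeating the purpose of the screen. At very low
event rates the 1-SE rule can select nothing; the study battery then falls
back to the CV-minimum choice.

**Grid-searched classifiers.** Linear SVM, random forest, neural network,
AdaBoost and gradient boosting, each grid-searched by mean stratified-CV
AUC and refit on the full training data. Margin classifiers pass through
a monotone logistic (Platt) map fitted on training margins: AUC identical,
output range calibrated. The default grids are small, documented in
`models.py`; no grids are inherited from any external study.

## The pipeline search

**Design space.** Four stages with default catalogs of 8 imputation
entries (MissForest, mean, MICE, median, EM, none, most-frequent, matrix
completion), 9 feature processors (feature agglomeration, random kitchen
sinks, univariate rate selection, kernel PCA, fast ICA, Nystroem,
polynomial-on-top-k, PCA, L1-SVM selection), 20 classifiers (naive Bayes
variants, linear SVM, LightGBM, survival forest, Cox, AdaBoost, gradient
boosting, XGBoost, random forest, logistic, bagging, ridge, decision
tree, LDA, extra trees, neural network, Gaussian process, k-NN) and 3
calibration methods (sigmoid, isotonic, none). Each entry carries a small
fixed hyper-parameter domain. Quadratic-cost fitters (kernel PCA,
Gaussian process, survival forest) are fitted on capped stratified row
subsamples and transform/score everything. Survival-style entries receive
pseudo-times (events before censoring) because the pipeline data contract
is (X, binary y); their risk scores pass through a monotone logistic link.
Rate-based selectors fall back to passthrough when nothing survives, so
null-signal pipelines remain fittable.

The corresponding published catalog prints a cardinality of 5,460 with
per-stage counts 7 × 9 × 20 × 3 (= 3,780) while its table lists 8
imputation entries; this package follows the table (8 × 9 × 20 × 3) and
records the discrepancy rather than resolving it.

**Search.** `bo_search` runs an initial random design (default 10), then
repeats: fit a random-forest surrogate mapping pipeline descriptors
(one-hot stage entries + normalized hyper-parameters) to CV score; draw
500 random candidates; propose the expected-improvement maximiser
(mean/spread from per-tree predictions); evaluate by stratified k-fold
with the whole pipeline refit per fold. A forest surrogate is used instead
of a Gaussian process deliberately: the space is mixed
discrete/continuous, and forests are robust there. Failed pipeline
evaluations score 0 and stay in the history with their error. An
exhaustive mode enumerates the default-hyper-parameter grid for small
spaces; with budget = cardinality it provably returns the brute-force
optimum. Everything is deterministic given the seed.

**Ensemble.** The top-k pipelines by CV score (default 5 at desk scale)
are refit on the full training data and weighted by
`softmax(CV-AUC / temperature)` (temperature 0.1): the published design
says "weighted ensemble" without a rule, so the rule is a package choice
exposing sharpness as one parameter. Calibration inside a pipeline is
fitted on an internal stratified 20% split so the calibrator never sees
the classifier's own training scores. Model bundles serialize as text
(specs + weights + seed); reloading refits members on the supplied
training data and reproduces predictions exactly on the same platform.

## Evaluation

AUC-ROC is the rank (Mann–Whitney) statistic with ties counted one-half.
Confidence intervals are Wilson score intervals; applying them to an AUC
requires an effective sample size, which the source studies do not state —
this package uses the number of cases by default and exposes the choice.
Brier is the mean squared error of probabilities. Threshold
classification calls positive at risk ≥ threshold (a participant exactly
at the 7.5% treatment threshold is treated). NRI is the two-category
variant at that single threshold. Subgroup validation fits on the full
training split and stratifies only the held-out metrics; a single-class
stratum is flagged, never dropped. The outer protocol re-derives every
model — including the pipeline search — inside each outer training fold,
with one shared fold assignment across all models so fold scores are
paired.

## Interpretation

**Permutation importance.** A random-forest surrogate regresses the
model's predictions on the covariates within a stratum; each variable's
raw score is the mean increase in held-out squared error over permutations
of that variable (a 25% held-out split rather than out-of-bag trees,
which would require private estimator internals). With rare outcomes the
predicted-risk distribution is extremely right-skewed and raw-risk squared
error is dominated by a handful of tail participants; the surrogate
therefore targets the log-odds of the predictions by default (monotone and
variance-stabilizing), with raw-risk and binarize-at-threshold variants
available. Negative raw scores are floored at zero and scores are
normalized to sum to one per stratum, so they behave as shares. Known
limitation: permutation importance splits — and partially masks — the
importance of strongly correlated or duplicated variables; the combined
share of an identical pair is close to, and typically slightly below, the
singleton's share.

**Per-variable screen.** Per gender: a baseline on age alone, then one
model per variable on {age, variable}, all scored by out-of-fold AUC from
stratified CV with training-fold mean imputation; the AUC improvement is
tested by a paired bootstrap (default 1,000 resamples) over the held-out
predictions, one-sided. The per-variable model is a regularized logistic
fit: a miniature pipeline search per (gender, variable) cell is
configuration-prohibitive at 60+ variables and adds nothing for
two-predictor models.

## Study orchestration and problem sizes

Desk-scale defaults: 20,000 participants, ~60 variables, a reduced
catalog, search budget 30, top-k 5, 10 outer folds. The test suite and
the acceptance script run the battery at outer_k = 3 and budget 12, which
preserves every structural property being checked (shared folds, ordering
of model families, subgroup behaviour) at a few minutes of single-CPU
time; the full-scale configuration (hundreds of thousands of rows, budget
200, 200-member ensembles) is a config preset, not a test requirement.
The comparator battery imputes with training-fold means by default;
MissForest multiple imputation is available and tested but not the
battery default at desk scale.

The gain decomposition uses the Cox model as the linear reference at each
view: information gain = AUC(Cox, all) − AUC(Cox, core7); modeling
gain(view) = AUC(ensemble, view) − AUC(Cox, view). With these definitions
the cross term in total = information + modeling(all) + cross is
identically zero; it is reported anyway so the recombination is explicit.

## Known limitations

* Synthetic cohorts cannot certify real-data performance (above).
* The search surrogate is a forest with random-candidate acquisition, not
  a structured-kernel Bayesian optimiser; the search contract (iterative
  surrogate + acquisition over a staged space, CV-scored) is what is
  preserved.
* Cox entries inside pipelines use pseudo-times; only the dedicated
  `fit_cox_ph` comparator consumes real follow-up times.
* The Wilson interval's effective n for AUC, and the NRI variant, are
  choices exposed as parameters; other choices change the printed
  intervals but not the point estimates.
* Ethnicity, ICD-coded outcome ascertainment and multi-centre sampling
  are out of scope.
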