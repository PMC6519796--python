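# prognopipe

Automated-ML cardiovascular risk prediction at biobank scale, as a reusable,
tested Python library.

## The problem

Clinical guidelines identify people for preventive cardiovascular therapy
with risk scores built from a handful of conventional predictors (age,
gender, systolic blood pressure, antihypertensive treatment, smoking,
diabetes history, BMI) under linear modeling assumptions. Large prospective
cohorts record hundreds of additional variables — lifestyle questionnaires,
blood assays, physical measures — with high and outcome-dependent
missingness. Two distinct questions arise for anyone building a risk model
on such data:

* **information gain** — how much does prediction improve just from using
  more variables, holding the model class fixed?
* **modeling gain** — how much does it improve from a richer model class on
  the same variables?

`prognopipe` implements the full study apparatus for answering both: a
synthetic biobank-like cohort generator with known ground truth (the real
cohorts are access-restricted), cohort filtering rules, MissForest-style
multiple imputation with prediction pooling, comparator models (the
published office-based Framingham equation, Cox proportional hazards with
LASSO preselection, grid-searched classifiers), an automated
pipeline-ensemble search, and a complete evaluation and interpretation
suite.

## The method at its core

A *pipeline* is one choice per stage — data imputation, feature
processing, classification, calibration — plus hyper-parameters. The
default design space mirrors the four-stage catalogs of automated
prognostic-modeling frameworks (8 × 9 × 20 × 3 stage entries). The search
is sequential model-based optimization: after a random initial design, a
random-forest surrogate over pipeline descriptors proposes each next
pipeline by expected improvement; every pipeline is scored by stratified
k-fold AUC-ROC with all preprocessing fitted inside training folds. The
final model is a weighted ensemble of the top pipelines, refit on the full
training data, with weights `softmax(CV-AUC / temperature)`.

Evaluation follows the standard epidemiological toolkit: AUC-ROC
(Mann–Whitney formulation, ties one-half) with Wilson score intervals, the
Brier score for calibration, sensitivity/PPV at the 7.5% treatment
threshold, and the two-category net reclassification index (NRI) against a
reference model. Interpretation uses surrogate-forest permutation
importance and a per-variable, age-adjusted predictive screen per gender.

## Worked example

```python
from prognopipe.study import StudyConfig, make_cohort, \
    run_comparator_battery, run_gain_decomposition
from prognopipe.synth import SyntheticConfig

config = StudyConfig(
    synthetic=SyntheticConfig(n_participants=20_000, seed=1),
    outer_k=3, inner_k=3, budget=12, top_k=3, seed=1)
table, meta, truth = make_cohort(config)
battery = run_comparator_battery(table, meta, config)
for name, report in battery.reports.items():
    print(f"{name:14s} AUC {report.auc:.3f} "
          f"({report.auc_ci[0]:.3f}-{report.auc_ci[1]:.3f})")
print(run_gain_decomposition(battery, config))
```

On the default synthetic cohort (20,000 participants, 1.13% five-year
event rate, planted nonlinear/interaction/subgroup effects, informative
missingness) this prints:

```
framingham     AUC 0.738 (0.675-0.792)
cox_core7      AUC 0.777 (0.717-0.828)
cox_all        AUC 0.801 (0.743-0.849)
automl_core7   AUC 0.766 (0.705-0.817)
automl_all     AUC 0.879 (0.828-0.916)
{'auc': {...}, 'information_gain': 0.0242,
 'modeling_gain': {'core7': -0.0113, 'all': 0.0774},
 'total_gain': 0.1016, 'cross_term': 0.0}
```

Reading: every model is evaluated on pooled held-out predictions under one
shared outer fold assignment. Moving the linear Cox model from the 7 core
factors to all variables buys +0.024 AUC (information gain); moving from
Cox to the searched pipeline ensemble on all variables buys a further
+0.077 (modeling gain), because the generator plants nonlinearities and
interactions a linear model cannot express. The ensemble's advantage
concentrates where the planted structure is subgroup-specific — see
`examples/04_subgroup_and_ranking.py`.

The `examples/` directory contains one short narrative script per
capability (cohort simulation, filtering, imputation, model search,
evaluation metrics, interpretation). A thin CLI wraps the same functions:
`prognopipe simulate|filter|train|evaluate|rank|screen|report`.

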