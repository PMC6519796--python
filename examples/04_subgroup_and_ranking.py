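"""Run the comparator battery, validate in the diabetic subgroup, and rank
variables by their contribution to the generative risk.

The generator plants a microalbumin effect amplified in diabetics: the
all-variable ensemble keeps its accuracy in that subgroup while the
core-factor linear model degrades, and the permutation ranking recovers
the age analog as the dominant predictor in both gender strata.
"""

import warnings

warnings.filterwarnings("ignore")

from prognopipe.interpret import posthoc_importance
from prognopipe.study import StudyConfig, make_cohort, run_comparator_battery, run_subgroup_study
from prognopipe.synth import SyntheticConfig

config = StudyConfig(synthetic=SyntheticConfig(n_participants=20_000, seed=1),
                     outer_k=3, inner_k=3, budget=12, top_k=3, seed=1)
table, meta, truth = make_cohort(config)
battery = run_comparator_battery(table, meta, config)

print("overall held-out AUC:")
for name, rep in battery.reports.items():
    print(f"  {name:14s} {rep.auc:.3f}")

diabetic = table.diabetes_flag.values == 1
sub = run_subgroup_study(battery, diabetic, models=("automl_all", "cox_core7"))
print(f"\ndiabetic subgroup (n={int(diabetic.sum())}):")
for name in ("automl_all", "cox_core7"):
    print(f"  {name:14s} {sub[name]['subgroup']['auc']:.3f}")
print("(the all-variable ensemble holds up; the core-factor linear model "
      "cannot see the diabetes-specific signal)")

print("\ntop-5 variables by importance share (surrogate permutation):")
for gender, value in (("men", 1.0), ("women", 0.0)):
    ranking = posthoc_importance(truth.true_risk, table.covariates,
                                 stratum_mask=table.gender.values == value,
                                 stratum=gender, n_repeats=2, seed=0, n_trees=100)
    top = ", ".join(f"{v} ({s:.2f})" for v, s in ranking.entries[:5])
    print(f"  {gender:6s}: {top}")
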