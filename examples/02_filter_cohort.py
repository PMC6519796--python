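"""Apply the inclusion criteria and the case-missingness variable filter.

Participants under 40 or with prior CVD are excluded; then each variable
is kept only if it is missing for strictly less than half of the
participants with events — missingness is screened among cases because it
can itself carry outcome information.
"""

from prognopipe.cohort import apply_inclusion_criteria, filter_variables_by_case_missingness
from prognopipe.synth import SyntheticConfig, generate_cohort, inject_missingness

config = SyntheticConfig(n_participants=20_000, seed=1, missingness_overall=0.45)
table, _ = generate_cohort(config)
table = inject_missingness(table, config)

included = apply_inclusion_criteria(table, min_age=40)
print(f"participants: {table.n} -> {included.n} after exclusions "
      f"(prior CVD flagged for {int(table.prior_cvd_flag.sum())})")

retained, report = filter_variables_by_case_missingness(included, table.meta,
                                                        max_case_missing=0.5)
print(f"variables: {len(table.meta)} -> {len(retained)} retained")
dropped = report[~report["retained"]]
print("\ndropped (case-missingness >= 50%):")
print(dropped[["name", "case_missingness", "overall_missingness"]]
      .round(3).to_string(index=False))
print("\nNote how variables can survive with high *overall* missingness as "
      "long as they are observed for most cases.")
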