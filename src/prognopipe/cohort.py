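"""Cohort data model, readers/writers, inclusion criteria and variable filters.

A cohort is a participants x variables table with an explicit missingness
mask, a binary 5-year event outcome, and a handful of bookkeeping columns
(gender, age, diabetes history, optional prior-CVD flag and follow-up time).
Missing covariate cells are represented as NaN in memory; the mask is derived
from, and always congruent with, the covariate table.

Variable metadata lives in a sidecar table: one row per covariate column with
its category (one of the nine biobank variable categories), a laboratory
flag, a variable type, and core-7 membership (the seven conventional
non-laboratory risk factors: age, gender, systolic blood pressure,
antihypertensive treatment, smoking, diabetes history and BMI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The nine variable categories used to organise biobank covariates.
CATEGORIES = (
    "health_medical_history",
    "lifestyle_environment",
    "blood_assays",
    "physical_activity",
    "family_history",
    "physical_measures",
    "psychosocial",
    "diet_nutrition",
    "sociodemographics",
)

#: Canonical names of the seven conventional risk factors in synthetic cohorts.
CORE7 = ("age", "gender", "sbp", "htn_treatment", "smoking", "diabetes", "bmi")

VARIABLE_VIEWS = ("core7", "nonlab", "lab", "all")


class CohortError(ValueError):
    """Raised when a cohort violates a structural precondition."""


@dataclass
class VariableMeta:
    """Per-variable metadata sidecar.

    Wraps a DataFrame with columns ``name``, ``category``, ``laboratory``
    (bool), ``var_type`` ({continuous, ordinal, categorical}) and ``core7``
    (bool). Exactly one row per covariate column.
    """

    table: pd.DataFrame

    REQUIRED = ("name", "category", "laboratory", "var_type", "core7")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise CohortError(f"metadata missing columns: {missing}")
        if self.table["name"].duplicated().any():
            dupes = self.table.loc[self.table["name"].duplicated(), "name"].tolist()
            raise CohortError(f"duplicate metadata rows for variables: {dupes}")
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise CohortError(f"unknown variable categories: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def subset(self, names) -> "VariableMeta":
        names = list(names)
        sub = self.table[self.table["name"].isin(names)]
        return VariableMeta(sub.copy())

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "VariableMeta":
        df = pd.read_csv(path)
        df["laboratory"] = df["laboratory"].astype(bool)
        df["core7"] = df["core7"].astype(bool)
        return cls(df)


@dataclass
class CohortTable:
    """Participant-level cohort: covariates, outcome and bookkeeping columns.

    ``covariates`` holds one row per participant and one (float) column per
    variable, with NaN marking missing cells. ``outcome_5y`` is the binary
    5-year event indicator and is never missing. ``gender`` is coded
    0 = female, 1 = male. ``follow_up_years`` (optional) gives event or
    censoring time within the horizon for survival fits.
    """

    covariates: pd.DataFrame
    outcome_5y: pd.Series
    prior_cvd_flag: pd.Series | None = None
    follow_up_years: pd.Series | None = None
    horizon_years: float = 5.0
    participant_id: pd.Index = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.participant_id is None:
            self.participant_id = pd.RangeIndex(len(self.covariates))
        self.participant_id = pd.Index(self.participant_id)
        if not self.participant_id.is_unique:
            raise CohortError("participant ids must be unique")
        if len(self.outcome_5y) != len(self.covariates):
            raise CohortError("outcome length does not match covariate rows")
        if self.outcome_5y.isna().any():
            raise CohortError("outcome must be non-missing for every participant")
        for s in (self.covariates, self.outcome_5y, self.prior_cvd_flag, self.follow_up_years):
            if s is not None:
                s.index = self.participant_id

    # -- accessors for the special columns ---------------------------------
    @property
    def n(self) -> int:
        return len(self.covariates)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask congruent with ``covariates``; True = missing."""
        return self.covariates.isna()

    @property
    def gender(self) -> pd.Series:
        return self.covariates["gender"]

    @property
    def age(self) -> pd.Series:
        return self.covariates["age"]

    @property
    def diabetes_flag(self) -> pd.Series:
        return self.covariates["diabetes"]

    def subset_rows(self, mask) -> "CohortTable":
        mask = np.asarray(mask, dtype=bool)
        return CohortTable(
            covariates=self.covariates.loc[mask].copy(),
            outcome_5y=self.outcome_5y.loc[mask].copy(),
            prior_cvd_flag=None if self.prior_cvd_flag is None else self.prior_cvd_flag.loc[mask].copy(),
            follow_up_years=None if self.follow_up_years is None else self.follow_up_years.loc[mask].copy(),
            horizon_years=self.horizon_years,
            participant_id=self.participant_id[mask],
        )

    def subset_columns(self, names) -> "CohortTable":
        names = list(names)
        return CohortTable(
            covariates=self.covariates[names].copy(),
            outcome_5y=self.outcome_5y.copy(),
            prior_cvd_flag=None if self.prior_cvd_flag is None else self.prior_cvd_flag.copy(),
            follow_up_years=None if self.follow_up_years is None else self.follow_up_years.copy(),
            horizon_years=self.horizon_years,
            participant_id=self.participant_id,
        )

    # -- persistence --------------------------------------------------------
    def write(self, path) -> None:
        """Write the cohort as delimited text; missing cells become empty fields."""
        df = self.covariates.copy()
        df.insert(0, "participant_id", self.participant_id)
        df["outcome_5y"] = self.outcome_5y.values
        if self.prior_cvd_flag is not None:
            df["prior_cvd_flag"] = self.prior_cvd_flag.values
        if self.follow_up_years is not None:
            df["follow_up_years"] = self.follow_up_years.values
        df.to_csv(path, index=False, na_rep="")

    @classmethod
    def read(cls, path, horizon_years: float = 5.0) -> "CohortTable":
        df = pd.read_csv(path)
        pid = pd.Index(df.pop("participant_id").values)
        outcome = df.pop("outcome_5y").astype(int)
        prior = df.pop("prior_cvd_flag").astype(int) if "prior_cvd_flag" in df else None
        fu = df.pop("follow_up_years") if "follow_up_years" in df else None
        table = cls(
            covariates=df.astype(float),
            outcome_5y=outcome,
            prior_cvd_flag=prior,
            follow_up_years=fu,
            horizon_years=horizon_years,
            participant_id=pid,
        )
        return table


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apply_inclusion_criteria(table: CohortTable, min_age: float = 40.0) -> CohortTable:
    """Drop participants younger than ``min_age`` or with prior CVD at baseline.

    Mirrors the analysis-cohort extraction of a prospective biobank study:
    only participants aged ``min_age`` or older with no known CVD history
    enter the analysis. Row order is preserved.
    """
    if "age" not in table.covariates.columns:
        raise CohortError("inclusion criteria require an age column")
    keep = table.age.values >= min_age
    if table.prior_cvd_flag is not None:
        keep = keep & (table.prior_cvd_flag.values == 0)
    return table.subset_rows(keep)


def filter_variables_by_case_missingness(
    table: CohortTable,
    meta: VariableMeta,
    max_case_missing: float = 0.5,
):
    """Retain variables missing for strictly less than ``max_case_missing``
    of participants with events.

    The rationale: missingness may itself be informative (the chance a
    variable is missing can depend on the outcome), so the completeness
    screen is applied among cases rather than the whole cohort. A variable
    missing for exactly the threshold fraction of cases is excluded
    (strict ``<``).

    Returns ``(retained_meta, report)`` where ``report`` is a per-variable
    DataFrame with case-missingness and overall-missingness proportions.
    """
    cases = table.outcome_5y.values == 1
    n_cases = int(cases.sum())
    if n_cases == 0:
        raise CohortError("variable filter undefined with zero cases")
    rows = []
    for name in meta.names:
        col = table.covariates[name]
        case_missing = float(col[cases].isna().mean())
        overall_missing = float(col.isna().mean())
        rows.append((name, case_missing, overall_missing, case_missing < max_case_missing))
    report = pd.DataFrame(rows, columns=["name", "case_missingness", "overall_missingness", "retained"])
    retained = meta.subset(report.loc[report["retained"], "name"])
    return retained, report


def select_variable_view(meta: VariableMeta, view: str) -> VariableMeta:
    """Select a variable view: the core-7 set, non-laboratory, laboratory, or all.

    ``lab`` and ``nonlab`` partition the variables by the laboratory flag;
    ``core7`` returns exactly the seven conventional risk factors.
    """
    if view not in VARIABLE_VIEWS:
        raise CohortError(f"unknown view {view!r}; expected one of {VARIABLE_VIEWS}")
    if view == "all":
        return VariableMeta(meta.table.copy())
    if view == "core7":
        sub = meta.table[meta.table["core7"]]
        if len(sub) != 7:
            raise CohortError(f"core7 view requires exactly 7 flagged variables, found {len(sub)}")
        return VariableMeta(sub.copy())
    if view == "lab":
        return VariableMeta(meta.table[meta.table["laboratory"]].copy())
    return VariableMeta(meta.table[~meta.table["laboratory"]].copy())
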