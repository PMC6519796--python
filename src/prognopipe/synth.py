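"""Synthetic biobank-like cohort generator with known ground truth.

Real biobank cohorts of the kind this package targets are access-restricted,
so every downstream stage (filtering, imputation, model search, evaluation,
interpretation) is exercised against cohorts generated here. The generator
emulates the structural features that make such data hard:

* rare binary 5-year outcome (default prevalence 1.13%),
* a few hundred mixed-type covariates organised in nine categories with
  within-category correlation,
* high, variable-specific missingness whose probability may depend on the
  outcome (informative missingness),
* nonlinear, interaction, gender-specific and subgroup-specific effects,
* a near-complete core of seven conventional risk factors (age, gender,
  systolic blood pressure, antihypertensive treatment, smoking, diabetes
  history, BMI).

Two designated analog variables mirror findings that motivate the study
design: a ``walking_pace`` ordinal non-laboratory variable with a strong
protective main effect, and a ``microalbumin`` laboratory variable whose
coefficient is amplified in the diabetic subgroup.

The outcome is generated from a logistic risk model whose intercept is
solved numerically so the population mean risk equals the configured
prevalence. All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from prognopipe.cohort import CATEGORIES, CORE7, CohortTable, VariableMeta

# Category of each core-7 variable in the metadata sidecar.
_CORE7_CATEGORY = {
    "age": "sociodemographics",
    "gender": "sociodemographics",
    "sbp": "physical_measures",
    "bmi": "physical_measures",
    "smoking": "lifestyle_environment",
    "diabetes": "health_medical_history",
    "htn_treatment": "health_medical_history",
}

# Default variable counts per category (core-7 members included in their
# category's count). Totals ~60 variables: a desk-scale stand-in for a
# several-hundred-variable biobank table.
_DEFAULT_CATEGORY_COUNTS = {
    "health_medical_history": 8,
    "lifestyle_environment": 8,
    "blood_assays": 10,
    "physical_activity": 6,
    "family_history": 4,
    "physical_measures": 10,
    "psychosocial": 4,
    "diet_nutrition": 6,
    "sociodemographics": 4,
}


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort generator.

    The defaults encode the study conditions the generator emulates:
    1.13% 5-year event prevalence, 4.22% diabetes prevalence, ~22% of
    variables laboratory-based, and moderate within-category correlation.
    ``informative_missingness_strength`` is the log-odds shift of a cell
    being missing given that the participant has an event.
    """

    n_participants: int = 20_000
    event_prevalence: float = 0.0113
    n_variables_per_category: dict = field(default_factory=lambda: dict(_DEFAULT_CATEGORY_COUNTS))
    frac_laboratory: float = 0.22
    missingness_overall: float = 0.25
    informative_missingness_strength: float = 1.0
    nonlinear_effect_size: float = 0.35
    interaction_effect_size: float = 0.25
    gender_effect_size: float = 0.35
    subgroup_effect_size: float = 0.6
    diabetes_prevalence: float = 0.0422
    n_informative_extra: int = 6
    extra_effect_size: float = 0.3
    signal_scale: float = 1.0
    block_correlation: float = 0.3
    horizon_years: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("event_prevalence", "missingness_overall", "frac_laboratory",
                     "diabetes_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if 0.0 < self.event_prevalence < 1.0:
            pass
        elif self.event_prevalence != 0.0:
            raise ValueError("event_prevalence must be 0 or inside (0, 1)")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")


@dataclass
class GroundTruth:
    """The generative risk model behind a synthetic cohort.

    ``true_risk`` is the per-participant event probability, a deterministic
    function of the covariates and the stored coefficients; everything else
    records which effects were planted so recovery tests can check them.
    """

    linear_coefficients: dict
    nonlinear_terms: list
    interaction_terms: list
    subgroup_terms: dict
    intercept: float
    true_risk: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "linear_coefficients": self.linear_coefficients,
            "nonlinear_terms": [list(t) for t in self.nonlinear_terms],
            "interaction_terms": [list(t) for t in self.interaction_terms],
            "subgroup_terms": self.subgroup_terms,
            "intercept": self.intercept,
            "true_risk": np.asarray(self.true_risk, dtype=float).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["nonlinear_terms"] = [tuple(t) for t in payload["nonlinear_terms"]]
        payload["interaction_terms"] = [tuple(t) for t in payload["interaction_terms"]]
        payload["true_risk"] = np.asarray(payload["true_risk"], dtype=float)
        return cls(**payload)


def _block_gaussians(rng, n, k, rho):
    """k equicorrelated standard normals (pairwise correlation rho)."""
    shared = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, k))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, GroundTruth]:
    """Generate a complete (pre-missingness) cohort and its ground truth.

    Returns a :class:`CohortTable` whose covariates include the seven core
    risk factors plus category blocks of correlated continuous/ordinal/
    categorical variables, and a :class:`GroundTruth` recording every
    planted effect and the per-participant true risk.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    # --- core-7 risk factors ------------------------------------------------
    age = np.clip(rng.normal(56.4, 8.1, n), 40.0, 73.0)
    gender = (rng.random(n) < 0.445).astype(float)  # 1 = male
    diabetes = (rng.random(n) < cfg.diabetes_prevalence).astype(float)
    smoking = (rng.random(n) < 0.105).astype(float)
    htn_treatment = (rng.random(n) < 0.20).astype(float)
    sbp = 82.0 + 1.0 * age + rng.normal(0.0, 16.0, n)
    bmi = np.clip(rng.normal(27.4, 4.8, n), 15.0, 55.0)

    z_age = (age - 56.4) / 8.1
    z_sbp = (sbp - 138.4) / 19.0
    z_bmi = (bmi - 27.4) / 4.8

    cols: dict[str, np.ndarray] = {
        "age": age, "gender": gender, "sbp": sbp, "htn_treatment": htn_treatment,
        "smoking": smoking, "diabetes": diabetes, "bmi": bmi,
    }
    meta_rows = [
        {"name": name, "category": _CORE7_CATEGORY[name], "laboratory": False,
         "var_type": ("continuous" if name in ("age", "sbp", "bmi") else "categorical"),
         "core7": True}
        for name in CORE7
    ]

    # --- designated analog variables ---------------------------------------
    # walking_pace: ordinal 0=slow, 1=steady, 2=brisk; slower with age.
    pace_latent = -0.3 * z_age + rng.standard_normal(n)
    walking_pace = np.digitize(pace_latent, [-0.8, 0.8]).astype(float)
    cols["walking_pace"] = walking_pace
    meta_rows.append({"name": "walking_pace", "category": "physical_activity",
                      "laboratory": False, "var_type": "ordinal", "core7": False})

    # microalbumin: skewed lab assay, elevated in diabetics; the latent z
    # drives risk, with the coefficient amplified in the diabetic subgroup.
    z_micro = rng.standard_normal(n)
    microalbumin = 27.8 * np.exp(0.9 * z_micro + 0.8 * diabetes)
    cols["microalbumin"] = microalbumin
    meta_rows.append({"name": "microalbumin", "category": "blood_assays",
                      "laboratory": True, "var_type": "continuous", "core7": False})

    # self_health: subjective health rating, gender-specific predictiveness.
    z_health = rng.standard_normal(n)
    self_health = np.digitize(z_health, [-1.0, 0.0, 1.0]).astype(float)
    cols["self_health"] = self_health
    meta_rows.append({"name": "self_health", "category": "psychosocial",
                      "laboratory": False, "var_type": "ordinal", "core7": False})

    # --- category blocks of correlated filler variables ---------------------
    latents: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        n_existing = sum(1 for r in meta_rows if r["category"] == cat)
        k = max(0, int(cfg.n_variables_per_category.get(cat, 0)) - n_existing)
        if k == 0:
            continue
        block = _block_gaussians(rng, n, k, cfg.block_correlation)
        for j in range(k):
            name = f"{cat}_{j:02d}"
            z = block[:, j]
            latents[name] = z
            if j % 5 == 4:  # small-cardinality categorical codes
                values = np.digitize(z, [-0.5, 0.5]).astype(float)
                var_type = "categorical"
            elif j % 5 == 3:
                values = np.digitize(z, [-1.0, 0.0, 1.0]).astype(float)
                var_type = "ordinal"
            else:
                values = z * rng.uniform(0.5, 3.0) + rng.uniform(-1.0, 10.0)
                var_type = "continuous"
            cols[name] = values
            meta_rows.append({"name": name, "category": cat, "laboratory": False,
                              "var_type": var_type, "core7": False})

    # laboratory flags: blood assays always lab; top up other measured
    # variables at random until the configured fraction is reached.
    meta = pd.DataFrame(meta_rows)
    meta["laboratory"] = meta["laboratory"] | (meta["category"] == "blood_assays")
    target_lab = int(round(cfg.frac_laboratory * len(meta)))
    eligible = meta.index[(~meta["laboratory"]) & (~meta["core7"])
                          & meta["category"].isin(["physical_measures"])].to_numpy()
    need = target_lab - int(meta["laboratory"].sum())
    if need > 0 and len(eligible) > 0:
        extra = rng.choice(eligible, size=min(need, len(eligible)), replace=False)
        meta.loc[extra, "laboratory"] = True

    # --- linear predictor ----------------------------------------------------
    lin = {
        "age": 0.9, "smoking": 0.5, "sbp": 0.35, "bmi": 0.2,
        "htn_treatment": 0.25, "diabetes": 0.4, "gender": cfg.gender_effect_size,
        "walking_pace": -0.45, "microalbumin": 0.3, "self_health": -0.25,
    }
    lp = (lin["age"] * z_age + lin["smoking"] * smoking + lin["sbp"] * z_sbp
          + lin["bmi"] * z_bmi + lin["htn_treatment"] * htn_treatment
          + lin["diabetes"] * diabetes + lin["gender"] * gender
          + lin["walking_pace"] * (walking_pace - 1.0)
          + lin["self_health"] * (self_health - 1.5))

    # subgroup amplification: microalbumin matters far more for diabetics.
    lp += z_micro * (lin["microalbumin"] + cfg.subgroup_effect_size * diabetes)
    subgroup_terms = {"diabetes": {"microalbumin": cfg.subgroup_effect_size}}

    # extra planted linear signal outside the core-7 (filler continuous vars).
    filler = [r["name"] for r in meta_rows
              if not r["core7"] and r["name"] in latents and r["var_type"] == "continuous"]
    extra_names = filler[: cfg.n_informative_extra]
    for name in extra_names:
        lin[name] = cfg.extra_effect_size
        lp += cfg.extra_effect_size * latents[name]

    # nonlinear terms: quadratic BMI, SBP threshold, saturating assay effect.
    nonlinear_terms = [("bmi", "quadratic"), ("sbp", "threshold")]
    lp += cfg.nonlinear_effect_size * (z_bmi ** 2 - 1.0)
    lp += cfg.nonlinear_effect_size * (sbp > 160.0)
    if extra_names:
        nonlinear_terms.append((extra_names[0], "saturating"))
        lp += cfg.nonlinear_effect_size * np.tanh(2.0 * latents[extra_names[0]])

    # interaction: smoking is worse at older ages; health rating matters
    # more for women (gender-specific effect).
    interaction_terms = [
        ("age", "smoking", cfg.interaction_effect_size),
        ("gender", "self_health", cfg.interaction_effect_size),
    ]
    lp += cfg.interaction_effect_size * z_age * smoking
    lp += cfg.interaction_effect_size * (1.0 - gender) * (1.5 - self_health)

    # signal_scale = 0 yields a pure-noise cohort at the configured prevalence
    lp = cfg.signal_scale * lp

    # --- outcome --------------------------------------------------------------
    if cfg.event_prevalence == 0.0:
        intercept = -np.inf
        true_risk = np.zeros(n)
    else:
        lo, hi = -30.0, 30.0
        intercept = brentq(lambda c: expit(c + lp).mean() - cfg.event_prevalence, lo, hi)
        true_risk = expit(intercept + lp)
    outcome = (rng.random(n) < true_risk).astype(int)

    follow_up = np.full(n, cfg.horizon_years)
    follow_up[outcome == 1] = rng.uniform(0.0, cfg.horizon_years, int(outcome.sum()))

    prior_cvd = (rng.random(n) < 0.05).astype(int)

    covariates = pd.DataFrame(cols, columns=[r["name"] for r in meta_rows])
    table = CohortTable(
        covariates=covariates,
        outcome_5y=pd.Series(outcome),
        prior_cvd_flag=pd.Series(prior_cvd),
        follow_up_years=pd.Series(follow_up),
        horizon_years=cfg.horizon_years,
    )
    truth = GroundTruth(
        linear_coefficients=lin,
        nonlinear_terms=nonlinear_terms,
        interaction_terms=interaction_terms,
        subgroup_terms=subgroup_terms,
        intercept=float(intercept) if np.isfinite(intercept) else -1e9,
        true_risk=true_risk,
    )
    table.meta = VariableMeta(meta)  # attach sidecar for convenience
    return table, truth


# Per-variable missingness base rates for the near-complete core analogs.
_CORE_MISSINGNESS = {
    "age": 0.0, "gender": 0.0, "smoking": 0.0, "diabetes": 0.0,
    "htn_treatment": 0.0, "sbp": 0.068, "bmi": 0.0062,
}


def inject_missingness(table: CohortTable, config: SyntheticConfig) -> CohortTable:
    """Apply per-cell missingness, optionally informative about the outcome.

    Each non-core variable gets a base missingness rate drawn around
    ``missingness_overall``; the per-cell missingness probability is then
    logistic in that base rate shifted by
    ``informative_missingness_strength`` x outcome, so cases can be more
    likely to have a value missing than non-cases. Core-analog variables
    stay near-complete (systolic blood pressure 6.8%, BMI 0.62%, the rest
    of the core and the outcome fully observed).
    """
    cfg = config
    if cfg.missingness_overall == 0.0:
        return table
    if cfg.informative_missingness_strength != 0.0 and table.outcome_5y is None:
        raise ValueError("informative missingness requires an outcome column")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    out = table.covariates.copy()
    y = table.outcome_5y.values
    m = cfg.missingness_overall
    for name in out.columns:
        if name in _CORE_MISSINGNESS:
            base = _CORE_MISSINGNESS[name]
        else:
            # Beta-distributed per-variable rate with mean missingness_overall.
            base = float(rng.beta(2.0, 2.0 * (1.0 - m) / max(m, 1e-9)))
        if base <= 0.0:
            continue
        p = expit(logit(np.clip(base, 1e-9, 1 - 1e-9))
                  + cfg.informative_missingness_strength * y)
        miss = rng.random(len(out)) < p
        out.loc[miss, name] = np.nan
    result = CohortTable(
        covariates=out,
        outcome_5y=table.outcome_5y.copy(),
        prior_cvd_flag=None if table.prior_cvd_flag is None else table.prior_cvd_flag.copy(),
        follow_up_years=None if table.follow_up_years is None else table.follow_up_years.copy(),
        horizon_years=table.horizon_years,
        participant_id=table.participant_id,
    )
    if hasattr(table, "meta"):
        result.meta = table.meta
    return result
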