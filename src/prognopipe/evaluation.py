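"""Performance statistics for binary risk models.

Discrimination is summarised by the AUC-ROC in its rank (Mann-Whitney)
formulation — the probability that a randomly chosen case outscores a
randomly chosen non-case, with ties counted one-half — with Wilson score
confidence intervals. Calibration is summarised by the Brier score.
Clinical utility at a decision threshold is summarised by a confusion
summary (sensitivity, PPV) and by the two-category net reclassification
index against a reference model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold


@dataclass
class ConfusionSummary:
    """Binary classification counts at a single risk threshold.

    A participant is called positive iff predicted risk >= threshold, so a
    participant exactly at the treatment threshold is treated.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["sensitivity"] = self.sensitivity
        d["ppv"] = self.ppv
        return d


@dataclass
class EvalReport:
    """Evaluation summary for one model on one (sub)population."""

    auc: float
    auc_ci: tuple
    brier: float
    threshold_summary: ConfusionSummary | None = None
    nri_vs_reference: float | None = None
    fold_scores: list = field(default_factory=list)
    n: int = 0
    n_cases: int = 0

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "brier": self.brier,
            "threshold_summary": None if self.threshold_summary is None
            else self.threshold_summary.as_dict(),
            "nri_vs_reference": self.nri_vs_reference,
            "fold_scores": list(self.fold_scores),
            "n": self.n,
            "n_cases": self.n_cases,
        }


def stratified_folds(outcome, k: int, seed: int = 0) -> np.ndarray:
    """Assign each participant to one of ``k`` outcome-stratified folds.

    Returns an integer array of fold labels; per-fold case counts differ by
    at most one.
    """
    y = np.asarray(outcome).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if y.sum() < k or (len(y) - y.sum()) < k:
        raise ValueError(f"need at least {k} cases and {k} controls for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def auc_roc(scores, labels) -> float:
    """Rank-based AUC-ROC: P(case score > control score) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def wilson_interval(estimate: float, n_effective: int, level: float = 0.95) -> tuple:
    """Wilson score interval for a proportion-like estimate.

    Used here for AUC values, with the number of cases as the default
    effective sample size (the choice is a parameter of the callers).
    """
    if not 0.0 <= estimate <= 1.0:
        raise ValueError("estimate must be in [0, 1]")
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    denom = 1.0 + z * z / n_effective
    centre = (estimate + z * z / (2.0 * n_effective)) / denom
    half = (z / denom) * np.sqrt(estimate * (1.0 - estimate) / n_effective
                                 + z * z / (4.0 * n_effective ** 2))
    # algebraically the bounds hit 0/1 exactly at degenerate estimates;
    # enforce that over floating-point residue
    lower = 0.0 if estimate == 0.0 else max(0.0, centre - half)
    upper = 1.0 if estimate == 1.0 else min(1.0, centre + half)
    # the interval contains the estimate by construction; enforce it over
    # floating-point cancellation at extreme estimates
    return (min(lower, estimate), max(upper, estimate))


def brier_score(probs, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(p) != len(y):
        raise ValueError("probs and labels must have the same length")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probs must be in [0, 1]")
    return float(np.mean((p - y) ** 2))


def confusion_at_threshold(probs, labels, threshold: float) -> ConfusionSummary:
    """Classification counts when calling positive at risk >= threshold."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probs must be in [0, 1]")
    pos = p >= threshold
    return ConfusionSummary(
        threshold=threshold,
        tp=int(np.sum(pos & (y == 1))),
        fp=int(np.sum(pos & (y == 0))),
        tn=int(np.sum(~pos & (y == 0))),
        fn=int(np.sum(~pos & (y == 1))),
    )


def net_reclassification_index(probs_new, probs_old, labels, threshold: float) -> float:
    """Two-category NRI at a single risk threshold.

    NRI = [P(up | event) - P(down | event)] + [P(down | non-event) -
    P(up | non-event)], where up/down means crossing the threshold when
    switching from the reference model to the new model. Range [-2, 2].
    """
    pn = np.asarray(probs_new, dtype=float)
    po = np.asarray(probs_old, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(pn) != len(po) or len(pn) != len(y):
        raise ValueError("prediction vectors and labels must be aligned")
    events = y == 1
    if events.sum() == 0 or (~events).sum() == 0:
        raise ValueError("NRI requires both events and non-events")
    new_pos = pn >= threshold
    old_pos = po >= threshold
    up = new_pos & ~old_pos
    down = ~new_pos & old_pos
    ev = events.sum()
    ne = (~events).sum()
    return float((up[events].sum() - down[events].sum()) / ev
                 + (down[~events].sum() - up[~events].sum()) / ne)


def evaluate_predictions(
    probs,
    labels,
    threshold: float | None = 0.075,
    reference_probs=None,
    level: float = 0.95,
    n_effective: int | None = None,
    fold_scores=(),
) -> EvalReport:
    """Bundle the full metric suite for one prediction vector."""
    y = np.asarray(labels).astype(int)
    auc = auc_roc(probs, y)
    n_cases = int(y.sum())
    ci = wilson_interval(auc, n_effective if n_effective is not None else n_cases, level)
    report = EvalReport(
        auc=auc,
        auc_ci=ci,
        brier=brier_score(probs, y),
        fold_scores=list(fold_scores),
        n=len(y),
        n_cases=n_cases,
    )
    if threshold is not None:
        report.threshold_summary = confusion_at_threshold(probs, y, threshold)
    if reference_probs is not None:
        report.nri_vs_reference = net_reclassification_index(probs, reference_probs, y, threshold)
    return report


def subgroup_evaluate(probs, labels, subgroup_mask, threshold: float | None = 0.075) -> dict:
    """Evaluate held-out predictions separately inside and outside a subgroup.

    The model is fitted once on the full training data; only the held-out
    metrics are stratified. A stratum with a single outcome class is flagged
    rather than silently dropped.
    """
    mask = np.asarray(subgroup_mask, dtype=bool)
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    if mask.sum() == 0:
        raise ValueError("empty subgroup")
    out = {}
    for name, m in (("subgroup", mask), ("complement", ~mask)):
        if m.sum() == 0:
            out[name] = {"flag": "empty stratum"}
            continue
        if len(np.unique(y[m])) < 2:
            out[name] = {"flag": "single-class stratum"}
            continue
        out[name] = evaluate_predictions(p[m], y[m], threshold=threshold)
    return out
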