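"""Per-feature ROC analysis: Youden-optimal cutoffs, AUC, split aggregation.

The Youden index YI = Se + Sp - 1 is maximized over candidate cutoffs
(midpoints between consecutive distinct values, plus the two infinities)
and, by default, over both orientations of the feature, so the training
YI is always >= 0. The cutoff learned on TRS+VS is then frozen and
applied to TES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .cohorts import Cohort
from .setups import SetUp, draw_split

__all__ = [
    "auc",
    "youden_optimal_cutoff",
    "youden_index_matrix",
    "CutoffRule",
    "AggregatePerformance",
    "run_univariate_setup",
    "screen_features",
    "count_predictive_features",
]

GREATER = "greater_is_positive"
LESS = "less_is_positive"


def auc(values, labels) -> float:
    """Area under the ROC curve of a score vector.

    Equals the Mann-Whitney U statistic normalized by n_pos * n_neg, with
    ties counted 1/2 (probability that a random positive outscores a
    random negative).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, values))


@dataclass(frozen=True)
class CutoffRule:
    """A frozen decision rule: cutoff plus orientation.

    Under ``greater_is_positive`` a value equal to the cutoff counts as
    positive; under ``less_is_positive`` the lower side (inclusive) is
    positive.
    """

    cutoff: float
    direction: str

    def predict(self, values) -> np.ndarray:
        v = np.asarray(values, float)
        if self.direction == GREATER:
            return (v >= self.cutoff).astype(int)
        return (v <= self.cutoff).astype(int)

    def youden(self, values, labels) -> tuple[float, float, float]:
        """(yi, se, sp) of the frozen rule on new data."""
        labels = np.asarray(labels, int)
        pred = self.predict(values)
        se = float(pred[labels == 1].mean())
        sp = float(1 - pred[labels == 0].mean())
        return se + sp - 1.0, se, sp


def _candidates(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _scan_direction(pos_sorted, neg_sorted, cand, direction):
    """Vectorized Se/Sp over candidate cutoffs for one orientation."""
    n_pos, n_neg = len(pos_sorted), len(neg_sorted)
    if direction == GREATER:
        se = (n_pos - np.searchsorted(pos_sorted, cand, side="left")) / n_pos
        sp = np.searchsorted(neg_sorted, cand, side="left") / n_neg
    else:
        se = np.searchsorted(pos_sorted, cand, side="right") / n_pos
        sp = (n_neg - np.searchsorted(neg_sorted, cand, side="right")) / n_neg
    return se, sp


def youden_optimal_cutoff(values, labels, directions: str = "both"):
    """Maximize YI = Se + Sp - 1 over all candidate cutoffs.

    ``directions='both'`` also scans the reversed orientation (a feature
    lower in positives); ``'fixed'`` scans greater-is-positive only. Ties
    are broken by the smallest cutoff, then greater-is-positive.

    Returns ``(rule, yi, se, sp)`` with ``rule`` a :class:`CutoffRule`.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("Youden cutoff undefined: only one class present")
    pos_sorted = np.sort(values[labels == 1])
    neg_sorted = np.sort(values[labels == 0])
    cand = _candidates(values)
    dirs = (GREATER, LESS) if directions == "both" else (GREATER,)
    best = None  # (yi, cutoff, dir_rank, se, sp)
    for rank, d in enumerate(dirs):
        se, sp = _scan_direction(pos_sorted, neg_sorted, cand, d)
        yi = se + sp - 1.0
        j = int(np.argmax(yi))  # argmax returns the first (smallest cutoff)
        key = (-yi[j], cand[j], rank)
        if best is None or key < best[0]:
            best = (key, cand[j], d, yi[j], se[j], sp[j])
    _, cutoff, d, yi, se, sp = best
    return CutoffRule(float(cutoff), d), float(yi), float(se), float(sp)


def youden_index_matrix(features: np.ndarray, labels: np.ndarray,
                        directions: str = "both") -> np.ndarray:
    """Best YI per column of a feature matrix (no rule object; fast path
    for screening and downsampling sweeps)."""
    labels = np.asarray(labels, int)
    pos = features[labels == 1]
    neg = features[labels == 0]
    out = np.empty(features.shape[1])
    for j in range(features.shape[1]):
        ps, ns = np.sort(pos[:, j]), np.sort(neg[:, j])
        cand = _candidates(features[:, j])
        best = -np.inf
        dirs = (GREATER, LESS) if directions == "both" else (GREATER,)
        for d in dirs:
            se, sp = _scan_direction(ps, ns, cand, d)
            best = max(best, float(np.max(se + sp) - 1.0))
        out[j] = best
    return out


@dataclass
class AggregatePerformance:
    """Mean/SD of split-wise performance over repeated random splits.

    SDs use the sample (n-1) estimator; with a single run they are set to
    0 and ``low_precision`` is flagged.
    """

    mean_vs: float
    sd_vs: float
    mean_tes: float
    sd_tes: float
    mean_auc: float
    sd_auc: float
    n_runs: int
    low_precision: bool = False


def _aggregate(vs, tes, aucs) -> AggregatePerformance:
    n = len(vs)
    sd = (lambda a: float(np.std(a, ddof=1))) if n > 1 else (lambda a: 0.0)
    return AggregatePerformance(
        float(np.mean(vs)), sd(vs), float(np.mean(tes)), sd(tes),
        float(np.mean(aucs)), sd(aucs), n, low_precision=n < 2,
    )


def run_univariate_setup(cohort: Cohort, setup: SetUp, feature: str,
                         n_runs: int = 50, base_seed: int = 0,
                         directions: str = "both") -> AggregatePerformance:
    """Repeated-split ROC analysis of one feature under one set-up.

    Per run: the Youden-optimal cutoff is learned on TRS+VS
    (resubstitution YI), then frozen and applied to TES. Aggregates are
    means and sample SDs over the runs; ``mean_auc`` is the TRS+VS AUC.
    """
    values = cohort.feature(feature)
    yi_vs, yi_tes, aucs = [], [], []
    for i in range(1, n_runs + 1):
        plan = draw_split(cohort, setup, i, base_seed)
        v_tr, y_tr = values[plan.trvs_indices], cohort.labels[plan.trvs_indices]
        rule, yi, _, _ = youden_optimal_cutoff(v_tr, y_tr, directions)
        yi_vs.append(yi)
        a = auc(v_tr, y_tr)
        aucs.append(max(a, 1 - a) if directions == "both" else a)
        if setup.n_tes > 0:
            v_te, y_te = values[plan.tes_indices], cohort.labels[plan.tes_indices]
            yi_t, _, _ = rule.youden(v_te, y_te)
            yi_tes.append(yi_t)
        else:
            yi_tes.append(np.nan)
    return _aggregate(yi_vs, yi_tes, aucs)


def screen_features(cohort: Cohort, directions: str = "both"):
    """Single full-data ROC per feature: YI, cutoff, orientation, Se, Sp,
    AUC (raw and orientation-corrected). Returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for name in cohort.feature_names:
        v = cohort.feature(name)
        rule, yi, se, sp = youden_optimal_cutoff(v, cohort.labels, directions)
        a = auc(v, cohort.labels)
        rows.append({
            "feature": name, "yi": yi, "se": se, "sp": sp,
            "cutoff": rule.cutoff, "direction": rule.direction,
            "auc": a, "auc_oriented": max(a, 1 - a),
        })
    return pd.DataFrame(rows)


def count_predictive_features(aggregates: dict[str, AggregatePerformance],
                              threshold: float):
    """Count features whose mean TRS+VS (resp. TES) YI exceeds a threshold.

    Returns ``(n_trvs_selected, n_tes_selected, ratio, flagged)`` where
    ``ratio = n_tes/n_trvs`` (0 and flagged when no feature passes on
    TRS+VS).
    """
    n_vs = sum(a.mean_vs > threshold for a in aggregates.values())
    n_tes = sum(a.mean_tes > threshold for a in aggregates.values())
    flagged = n_vs == 0
    ratio = 0.0 if flagged else n_tes / n_vs
    return n_vs, n_tes, ratio, flagged
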