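"""Quality of the extrapolated prediction vs the full-data reference.

Two absolute errors are compared against the performance measured with
the whole reference cohort (N_tot cases):

    QF1 = |Yec(N)     - Y(N_tot)|   (the downsampling prediction)
    QF2 = |Y(N)       - Y(N_tot)|   (the naive estimate from N cases)

QF1 <= QF2 means the downsampling prediction is the better estimate of
the large-cohort performance. For AUC, a prediction is also graded as
"within 5%" when |Yec - AUC_ref| <= 0.05 * AUC_ref.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import Cohort
from .extrapolation import (
    build_univariate_curves,
    extrapolate_from_curve,
    predict_performance,
)
from .pipelines import ClassifierSpec, run_ml_setup
from .setups import SetUp, default_k
from .univariate import auc as roc_auc
from .univariate import youden_index_matrix

__all__ = ["QualityReport", "quality_factors", "sweep_quality",
           "univariate_quality_sweep"]


@dataclass
class QualityReport:
    """QF1/QF2 comparison for one (analysis, available-N) condition."""

    analysis: str
    metric: str
    n_available: int
    n_reference: int
    yec: float
    perf_n: float
    perf_ref: float
    qf1: float
    qf2: float
    win: bool
    within_5pct: bool | None = None


def quality_factors(yec_n: float, perf_n: float, perf_ntot: float,
                    metric: str, analysis: str = "",
                    n_available: int = 0, n_reference: int = 0) -> QualityReport:
    """Compute QF1 and QF2 (absolute errors against the reference).

    ``within_5pct`` is relative to the reference and reported for AUC
    only."""
    qf1 = abs(yec_n - perf_ntot)
    qf2 = abs(perf_n - perf_ntot)
    within = (qf1 <= 0.05 * perf_ntot) if metric == "auc" else None
    return QualityReport(
        analysis, metric, n_available, n_reference,
        yec_n, perf_n, perf_ntot, float(qf1), float(qf2),
        bool(qf1 <= qf2), within,
    )


def _ml_reference(cohort: Cohort, spec: ClassifierSpec, n_runs: int,
                  base_seed: int, metric: str) -> float:
    """Reference performance for an ML protocol: mean cross-validated
    value over repeated runs on the full cohort (no test split)."""
    k = default_k(min(cohort.n_pos, cohort.n_neg))
    setup = SetUp(f"ref-{spec.id}", cohort.n_pos, cohort.n_neg, 0, 0, k)
    res = run_ml_setup(cohort, setup, spec, n_runs=n_runs, base_seed=base_seed)
    return res.mean_vs if metric == "youden" else res.mean_auc_vs


def _univariate_reference(cohort: Cohort, feature: str, metric: str) -> float:
    """Reference for a feature: single full-data resubstitution value."""
    v = cohort.feature(feature)
    if metric == "youden":
        j = cohort.feature_names.index(feature)
        return float(youden_index_matrix(cohort.features[:, [j]], cohort.labels)[0])
    a = roc_auc(v, cohort.labels)
    return max(a, 1 - a)


def univariate_quality_sweep(cohort: Cohort, n_grid, step: int,
                             n_runs: int = 50, base_seed: int = 0,
                             min_size: int = 13, metric: str = "youden",
                             features: list[str] | None = None,
                             ) -> tuple[pd.DataFrame, dict]:
    """QF1/QF2 sweep over available-N conditions for every feature.

    For each N in ``n_grid`` a downsampling curve with top size N is
    built from the whole cohort (all features share the same subsample
    draws), extrapolated, and compared against each feature's full-data
    reference. Returns (per-cell table, summary dict with the percentage
    of QF1 <= QF2 cells).
    """
    names = list(features) if features is not None else list(cohort.feature_names)
    refs = {f: _univariate_reference(cohort, f, metric) for f in names}
    rows = []
    for n_avail in n_grid:
        curves = build_univariate_curves(
            cohort, names, metric, step, n_runs,
            base_seed, min_size, top_size=int(n_avail),
        )
        for f in names:
            rep = extrapolate_from_curve(curves[f], "univariate")
            q = quality_factors(rep.yec, float(curves[f].means[0]), refs[f],
                                metric, analysis=f"roc:{f}",
                                n_available=int(n_avail),
                                n_reference=cohort.n_samples)
            rows.append({
                "n_available": q.n_available, "feature": f, "yec": q.yec,
                "perf_n": q.perf_n, "perf_ref": q.perf_ref,
                "qf1": q.qf1, "qf2": q.qf2, "win": q.win,
            })
    table = pd.DataFrame(rows)
    summary = {
        "n_cells": len(table),
        "pct_win": 100.0 * table["win"].mean(),
        "pct_win_at_smallest_n": 100.0 * table.loc[
            table.n_available == table.n_available.min(), "win"].mean(),
    }
    return table, summary


def sweep_quality(cohort: Cohort, analyses, n_grid, step: int,
                  n_runs: int = 50, base_seed: int = 0,
                  metric: str = "youden", min_size: int = 13,
                  ref_runs: int | None = None,
                  ) -> tuple[pd.DataFrame, dict]:
    """General QF1/QF2 sweep over analyses x available-N conditions.

    ``analyses`` items are ``"roc:<feature>"`` strings or
    :class:`ClassifierSpec` instances. The reference performance is
    computed once per analysis on the full cohort (single resubstitution
    ROC for features; mean cross-validated value over ``ref_runs`` for ML
    protocols).
    """
    rows = []
    for analysis in analyses:
        if isinstance(analysis, ClassifierSpec):
            ref = _ml_reference(cohort, analysis, ref_runs or n_runs,
                                base_seed, metric)
            label = analysis.id
        else:
            ref = _univariate_reference(cohort, analysis.split(":", 1)[1], metric)
            label = analysis
        for n_avail in n_grid:
            rep = predict_performance(cohort, analysis, metric, step,
                                      n_runs=n_runs, base_seed=base_seed,
                                      min_size=min_size, top_size=int(n_avail))
            q = quality_factors(rep.yec, float(rep.curve.means[0]), ref,
                                metric, analysis=label,
                                n_available=int(n_avail),
                                n_reference=cohort.n_samples)
            rows.append({
                "analysis": label, "n_available": q.n_available,
                "yec": q.yec, "perf_n": q.perf_n, "perf_ref": q.perf_ref,
                "qf1": q.qf1, "qf2": q.qf2, "win": q.win,
                "within_5pct": q.within_5pct,
            })
    table = pd.DataFrame(rows)
    summary = {"n_cells": len(table), "pct_win": 100.0 * table["win"].mean()}
    if metric == "auc":
        summary["pct_within_5pct"] = 100.0 * table["within_5pct"].mean()
    return table, summary
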