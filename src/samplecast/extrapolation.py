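"""Downsampling curves and performance extrapolation.

The core method: from a pool of available cases, draw stratified
subsamples of decreasing sizes N_p = N - (p-1)S, measure a figure of
merit (Youden index or AUC) on each subsample many times, then

* fit the SD of the metric against N_p (linear for the univariate ROC
  path, logarithmic for the cross-validated ML path), and solve for the
  size N_c at which the fitted SD reaches zero;
* fit the mean metric against log N_p by weighted least squares (weights
  = 1 / SD), and evaluate that fit at N_c.

The evaluated value Yec is the performance expected once enough cases
are available. Natural logarithms are used throughout; N_c and Yec are
invariant to the base choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohorts import Cohort
from .pipelines import ClassifierSpec, skfcv_evaluate
from .setups import default_k, split_rng
from .univariate import auc as roc_auc
from .univariate import youden_index_matrix

__all__ = [
    "PerformanceCurve",
    "SdFit",
    "PerfFit",
    "ExtrapolationReport",
    "downsample_sizes",
    "stratified_subsample",
    "build_downsampling_curve",
    "build_univariate_curves",
    "build_ml_curve_pair",
    "fit_sd_linear",
    "fit_sd_log",
    "fit_perf_weighted_log",
    "extrapolate_yec",
    "stability_reached",
    "predict_performance",
]

SD_FLOOR = 1e-3        # weight floor for WLS when a point's SD is ~0
NC_CAP_FACTOR = 10.0   # N_c cap (x top size) when the SD fit never reaches 0


@dataclass
class PerformanceCurve:
    """Mean +/- SD of a figure of merit at descending subsample sizes."""

    metric: str                 # 'youden' | 'auc'
    analysis: str               # e.g. 'roc:worst perimeter' or 'C9'
    step: int
    sizes: np.ndarray           # strictly decreasing, constant step
    means: np.ndarray
    sds: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, int)
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        d = np.diff(self.sizes)
        if len(self.sizes) < 3:
            raise ValueError("a downsampling curve needs at least 3 sizes")
        if not (d == -self.step).all():
            raise ValueError("sizes must decrease with a constant step")
        if (self.sds < 0).any():
            raise ValueError("SDs must be non-negative")


@dataclass
class SdFit:
    """Fitted SD-decay model and its zero crossing N_c."""

    model: str                  # 'linear' | 'logarithmic'
    a: float                    # intercept
    b: float                    # decay coefficient (SD = a - b*x)
    n_c: float
    flags: tuple = ()


@dataclass
class PerfFit:
    """Fitted mean-performance model Y = c + d * ln(N_p)."""

    c: float
    d: float
    flags: tuple = ()


def downsample_sizes(top_size: int, step: int, min_size: int) -> np.ndarray:
    """Sizes N_p = N - (p-1)S down to ``min_size``; errors below 3 points."""
    if step <= 0:
        raise ValueError("step must be positive")
    sizes = np.arange(top_size, min_size - 1, -step)
    if len(sizes) < 3:
        raise ValueError(
            f"insufficient patients for extrapolation: only {len(sizes)} "
            f"size(s) between {top_size} and {min_size} with step {step}"
        )
    return sizes


def stratified_subsample(labels: np.ndarray, size: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Indices of a stratified draw without replacement.

    Class counts follow the pool's class ratio with nearest-integer
    rounding, forced to keep at least one sample of each class.
    """
    labels = np.asarray(labels, int)
    n = len(labels)
    n_pos_pool = int(labels.sum())
    if not 2 <= size <= n:
        raise ValueError(f"subsample size {size} out of range [2, {n}]")
    n_pos = int(round(size * n_pos_pool / n))
    n_pos = min(max(n_pos, 1), size - 1)
    pos = rng.choice(np.flatnonzero(labels == 1), n_pos, replace=False)
    neg = rng.choice(np.flatnonzero(labels == 0), size - n_pos, replace=False)
    return np.sort(np.concatenate([pos, neg]))


def _curve_tag(analysis: str, metric: str) -> str:
    return f"curve/{analysis}/{metric}"


def _target_counts(labels_pool: np.ndarray, size: int) -> tuple[int, int]:
    n = len(labels_pool)
    n_pos_pool = int(labels_pool.sum())
    n_pos = int(round(size * n_pos_pool / n))
    n_pos = min(max(n_pos, 1), size - 1)
    return n_pos, size - n_pos


def _chain_indices(labels_pool: np.ndarray, sizes: np.ndarray,
                   rng: np.random.Generator, nested: bool) -> list[np.ndarray]:
    """Index sets for one run, one per descending size.

    ``nested=True`` (default protocol): the run draws the top subsample
    once and then repeatedly removes cases, so sS_p is a subset of
    sS_{p-1}; the shared sampling noise makes the SD-vs-size slope far
    less noisy than with independent draws. ``nested=False``: independent
    stratified draws at every size.
    """
    labels_pool = np.asarray(labels_pool, int)
    if not nested:
        return [stratified_subsample(labels_pool, int(s), rng) for s in sizes]
    out = []
    current = stratified_subsample(labels_pool, int(sizes[0]), rng)
    out.append(current)
    for s in sizes[1:]:
        n_pos, n_neg = _target_counts(labels_pool, int(s))
        cur_pos = current[labels_pool[current] == 1]
        cur_neg = current[labels_pool[current] == 0]
        keep_pos = rng.choice(cur_pos, n_pos, replace=False)
        keep_neg = rng.choice(cur_neg, n_neg, replace=False)
        current = np.sort(np.concatenate([keep_pos, keep_neg]))
        out.append(current)
    return out


def build_univariate_curves(cohort: Cohort, features: list[str] | None,
                            metric: str, step: int, n_runs: int,
                            base_seed: int, min_size: int,
                            top_size: int | None = None,
                            nested: bool = True,
                            ) -> dict[str, PerformanceCurve]:
    """Downsampling curves for many features at once, sharing the draws.

    Each run draws one stratified subsample chain from the whole cohort
    (see :func:`_chain_indices`) and computes every feature's
    resubstitution Youden index (or orientation-corrected AUC) at each
    size.
    """
    if metric not in ("youden", "auc"):
        raise ValueError(f"unknown metric {metric!r}")
    names = list(features) if features is not None else list(cohort.feature_names)
    cols = [cohort.feature_names.index(f) for f in names]
    top = int(top_size or cohort.n_samples)
    sizes = downsample_sizes(top, step, min_size)
    vals = np.empty((len(sizes), n_runs, len(cols)))
    x, y = cohort.features[:, cols], cohort.labels
    for run in range(n_runs):
        rng = split_rng(base_seed, _curve_tag("roc", metric), run)
        for si, idx in enumerate(_chain_indices(y, sizes, rng, nested)):
            if metric == "youden":
                vals[si, run] = youden_index_matrix(x[idx], y[idx])
            else:
                for j in range(len(cols)):
                    a = roc_auc(x[idx, j], y[idx])
                    vals[si, run, j] = max(a, 1 - a)
    means = vals.mean(axis=1)
    sds = vals.std(axis=1, ddof=1) if n_runs > 1 else np.zeros_like(means)
    return {
        name: PerformanceCurve(metric, f"roc:{name}", step, sizes,
                               means[:, j], sds[:, j], n_runs)
        for j, name in enumerate(names)
    }


def build_ml_curve_pair(cohort: Cohort, spec: ClassifierSpec, step: int,
                        n_runs: int, base_seed: int, min_size: int,
                        top_size: int | None = None,
                        k_folds: int | None = None,
                        nested: bool = True,
                        ) -> tuple[PerformanceCurve, PerformanceCurve]:
    """Youden and AUC downsampling curves for one ML protocol, sharing
    the SKFCV runs (each run yields both figures of merit).

    Each run draws a stratified subsample chain from the whole cohort
    (see :func:`_chain_indices`) and evaluates the protocol with SKFCV on
    every chain member (no TES); the per-run value is the mean over the K
    validation folds. K follows the minority-count rule per size unless
    overridden.
    """
    top = int(top_size or cohort.n_samples)
    sizes = downsample_sizes(top, step, min_size)
    yi = np.empty((len(sizes), n_runs))
    au = np.empty((len(sizes), n_runs))
    for run in range(n_runs):
        rng = split_rng(base_seed, _curve_tag(spec.id, "ml"), run)
        for si, idx in enumerate(_chain_indices(cohort.labels, sizes, rng, nested)):
            ysub = cohort.labels[idx]
            minority = int(np.bincount(ysub, minlength=2).min())
            k = k_folds or default_k(minority)
            res = skfcv_evaluate(cohort.features[idx], ysub, spec,
                                 max(2, min(k, minority)),
                                 int(rng.integers(2**31)), run_index=run)
            yi[si, run] = res.yi_vs
            au[si, run] = res.auc_vs
    def curve(vals, metric):
        m = vals.mean(axis=1)
        s = vals.std(axis=1, ddof=1) if n_runs > 1 else np.zeros_like(m)
        return PerformanceCurve(metric, spec.id, step, sizes, m, s, n_runs)
    return curve(yi, "youden"), curve(au, "auc")


def build_downsampling_curve(cohort: Cohort, analysis, metric: str,
                             step: int, n_runs: int, base_seed: int,
                             min_size: int, top_size: int | None = None,
                             k_folds: int | None = None,
                             nested: bool = True) -> PerformanceCurve:
    """Single-analysis downsampling curve.

    ``analysis`` is either ``"roc:<feature>"`` (univariate resubstitution
    path) or a :class:`ClassifierSpec` (SKFCV path). Subsamples of every
    size are drawn without replacement from the whole cohort passed in;
    pass ``top_size`` below the cohort size so the top point also varies
    across runs (as when predicting from N available out of N+ cases).
    """
    if isinstance(analysis, ClassifierSpec):
        pair = build_ml_curve_pair(cohort, analysis, step, n_runs, base_seed,
                                   min_size, top_size, k_folds, nested)
        return pair[0] if metric == "youden" else pair[1]
    if isinstance(analysis, str) and analysis.startswith("roc:"):
        feature = analysis.split(":", 1)[1]
        curves = build_univariate_curves(cohort, [feature], metric, step,
                                         n_runs, base_seed, min_size, top_size,
                                         nested)
        return curves[feature]
    raise ValueError(
        f"analysis must be 'roc:<feature>' or a ClassifierSpec, got {analysis!r}"
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares intercept and slope of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def _sd_fit(curve: PerformanceCurve, x: np.ndarray, model: str,
            solve_nc, n_c_cap: float) -> SdFit:
    intercept, slope = _ols(x, curve.sds)
    a, b = intercept, -slope   # SD = a - b*x
    flags = []
    if b <= 0:
        flags.append("no_zero_crossing")
        n_c = n_c_cap
    else:
        n_c = solve_nc(a, b)
        if not np.isfinite(n_c) or n_c > n_c_cap:
            flags.append("clamped")
            n_c = n_c_cap
    if n_c <= curve.sizes.max():
        flags.append("n_c_within_observed_range")
    return SdFit(model, a, b, float(n_c), tuple(flags))


def fit_sd_linear(curve: PerformanceCurve,
                  n_c_cap: float | None = None) -> SdFit:
    """OLS fit SD(N_p) = a - b * N_p; N_c is the zero crossing a/b.

    When the slope does not decay (b <= 0) the fit is flagged
    ``no_zero_crossing`` and N_c is capped at ``NC_CAP_FACTOR`` x the top
    size (configurable)."""
    cap = n_c_cap or NC_CAP_FACTOR * curve.sizes.max()
    return _sd_fit(curve, curve.sizes.astype(float), "linear",
                   lambda a, b: a / b, cap)


def fit_sd_log(curve: PerformanceCurve,
               n_c_cap: float | None = None) -> SdFit:
    """OLS fit SD(N_p) = a' - b' * ln(N_p); N_c = exp(a'/b').

    The zero crossing is invariant to the logarithm base (a'/b' rescales
    with the base while exp/log compose back)."""
    cap = n_c_cap or NC_CAP_FACTOR * curve.sizes.max()
    def solve(a, b):
        ratio = a / b
        return np.exp(ratio) if ratio < 700 else np.inf
    return _sd_fit(curve, np.log(curve.sizes.astype(float)), "logarithmic",
                   solve, cap)


def fit_perf_weighted_log(curve: PerformanceCurve, expected_sign: str,
                          sd_floor: float = SD_FLOOR) -> PerfFit:
    """Weighted least squares of the means on ln(N_p), weights 1/SD.

    Each squared residual is weighted by 1 / max(SD, sd_floor). The
    univariate path expects a negative slope (small-sample optimism
    decaying), the ML path a positive one (learning curve); a
    contradicting sign is flagged ``wrong_sign_slope`` but the fit is
    still returned.
    """
    if expected_sign not in ("negative", "positive"):
        raise ValueError("expected_sign must be 'negative' or 'positive'")
    x = np.log(curve.sizes.astype(float))
    y = curve.means
    w = 1.0 / np.maximum(curve.sds, sd_floor)
    sw, swx = w.sum(), (w * x).sum()
    swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
    denom = sw * swxx - swx**2
    if denom <= 0:
        raise ValueError("degenerate design for weighted fit")
    d = (sw * swxy - swx * swy) / denom
    c = (swy - d * swx) / sw
    flags = []
    if (expected_sign == "negative") != (d < 0):
        flags.append("wrong_sign_slope")
    return PerfFit(float(c), float(d), tuple(flags))


def extrapolate_yec(perf_fit: PerfFit, n_c: float, metric: str):
    """Evaluate the performance fit at N_c, clamped to the metric range.

    Returns ``(yec, flags)``; ``flags`` contains ``'clamped'`` when the
    raw value left [-1, 1] (Youden) or [0, 1] (AUC)."""
    raw = perf_fit.c + perf_fit.d * np.log(n_c)
    lo, hi = (-1.0, 1.0) if metric == "youden" else (0.0, 1.0)
    if raw < lo or raw > hi:
        return float(np.clip(raw, lo, hi)), ("clamped",)
    return float(raw), ()


def stability_reached(sizes: np.ndarray, means: np.ndarray, step: int,
                      tol: float = 0.01, mode: str = "all") -> int | None:
    """Smallest size from which the mean curve has stabilized.

    Sizes must be ascending with a constant step. ``mode='all'``: the
    smallest N_p such that every subsequent consecutive absolute change
    is <= tol; ``mode='single'``: the first N_p whose next change is
    <= tol. Returns None when never stable.
    """
    sizes = np.asarray(sizes, int)
    means = np.asarray(means, float)
    if len(sizes) < 2:
        raise ValueError("stability needs at least 2 points")
    if not (np.diff(sizes) == step).all():
        raise ValueError("sizes must ascend with the stated constant step")
    diffs = np.abs(np.diff(means))
    ok = diffs <= tol
    if mode == "single":
        idx = np.flatnonzero(ok)
        return int(sizes[idx[0]]) if idx.size else None
    if not ok[-1]:
        return None
    # last index after which all diffs are <= tol
    bad = np.flatnonzero(~ok)
    start = int(bad[-1]) + 1 if bad.size else 0
    return int(sizes[start])


@dataclass
class ExtrapolationReport:
    """Curve + fits + N_c + Yec for one analysis and metric."""

    analysis: str
    metric: str
    curve: PerformanceCurve
    sd_fit: SdFit
    perf_fit: PerfFit
    n_c: float
    yec: float
    stable_from: int | None
    flags: tuple

    def to_dict(self) -> dict:
        return {
            "analysis": self.analysis,
            "metric": self.metric,
            "sizes": self.curve.sizes.tolist(),
            "means": self.curve.means.tolist(),
            "sds": self.curve.sds.tolist(),
            "n_runs": self.curve.n_runs,
            "sd_model": self.sd_fit.model,
            "sd_a": self.sd_fit.a,
            "sd_b": self.sd_fit.b,
            "perf_c": self.perf_fit.c,
            "perf_d": self.perf_fit.d,
            "n_c": self.n_c,
            "yec": self.yec,
            "stable_from": self.stable_from,
            "flags": list(self.flags),
        }


def extrapolate_from_curve(curve: PerformanceCurve,
                           path: str) -> ExtrapolationReport:
    """Fit + extrapolate a prebuilt curve. ``path`` is 'univariate'
    (linear SD fit, decaying performance) or 'ml' (log SD fit, growing
    performance)."""
    if path == "univariate":
        sd_fit = fit_sd_linear(curve)
        perf_fit = fit_perf_weighted_log(curve, "negative")
    elif path == "ml":
        sd_fit = fit_sd_log(curve)
        perf_fit = fit_perf_weighted_log(curve, "positive")
    else:
        raise ValueError("path must be 'univariate' or 'ml'")
    yec, clamp_flags = extrapolate_yec(perf_fit, sd_fit.n_c, curve.metric)
    stable = stability_reached(curve.sizes[::-1], curve.means[::-1], curve.step)
    return ExtrapolationReport(
        curve.analysis, curve.metric, curve, sd_fit, perf_fit,
        sd_fit.n_c, yec, stable,
        tuple(sd_fit.flags) + tuple(perf_fit.flags) + clamp_flags,
    )


def predict_performance(cohort: Cohort, analysis, metric: str, step: int,
                        n_runs: int = 50, base_seed: int = 0,
                        min_size: int = 20, top_size: int | None = None,
                        k_folds: int | None = None,
                        nested: bool = True) -> ExtrapolationReport:
    """End-to-end prediction: build the downsampling curve, fit the SD
    decay and the performance growth/decay, solve for N_c and report Yec.
    """
    curve = build_downsampling_curve(cohort, analysis, metric, step, n_runs,
                                     base_seed, min_size, top_size, k_folds,
                                     nested)
    path = "ml" if isinstance(analysis, ClassifierSpec) else "univariate"
    return extrapolate_from_curve(curve, path)
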