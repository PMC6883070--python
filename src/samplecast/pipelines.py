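"""The nine multivariate classification protocols C1-C9.

Three linear base learners (logistic regression, linear SVM, LASSO used
as a thresholded regressor) alone or behind a dimensionality-reduction
step (recursive feature elimination, PCA, or univariate ROC-based
feature retention), evaluated with stratified K-fold cross-validation:

    C1 LR        C2 RFE-LR    C3 PCA-LR    C4 ROCfr-LR
    C5 SVM       C6 RFE-SVM   C7 PCA-SVM   C8 ROCfr-SVM
    C9 LASSO

Inside each fold the features are z-scored with the fold-train mean/SD
and the reducer is fitted on the fold-train only. Hyperparameters are
tuned jointly across the K folds (each candidate configuration scored by
its mean validation Youden index over the folds); the winning
configuration's fold model with the highest validation YI is frozen and
applied to TES.
Class imbalance is handled by weighting each class inversely to its
frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_selection import RFE
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .cohorts import Cohort
from .setups import SetUp, draw_split, split_rng
from .univariate import auc as roc_auc
from .univariate import youden_index_matrix

__all__ = [
    "ClassifierSpec",
    "classifier_spec",
    "CLASSIFIER_IDS",
    "zscore_fit_apply",
    "ZScore",
    "reduce_features",
    "CvRunResult",
    "run_skfcv",
    "skfcv_evaluate",
    "MlSetupResult",
    "run_ml_setup",
    "coverage_fraction",
]

# (base learner, reducer) for each protocol id
_COMBOS = {
    "C1": ("logistic_regression", "none"),
    "C2": ("logistic_regression", "rfe"),
    "C3": ("logistic_regression", "pca"),
    "C4": ("logistic_regression", "roc_fr"),
    "C5": ("linear_svm", "none"),
    "C6": ("linear_svm", "rfe"),
    "C7": ("linear_svm", "pca"),
    "C8": ("linear_svm", "roc_fr"),
    "C9": ("lasso", "none"),
}
CLASSIFIER_IDS = tuple(_COMBOS)

# Hyperparameter grids (the tuned parameters: inverse regularization
# strength for LR, penalty parameter for SVM, L1 constant for LASSO).
_DEFAULT_GRIDS = {
    "logistic_regression": {"C": np.logspace(-3, 3, 7)},
    "linear_svm": {"C": np.logspace(-3, 3, 7)},
    "lasso": {"alpha": np.logspace(-4, 0, 9)},
}
# RFE retained-feature fractions, tuned in the same fold grid search.
_RFE_FRACTIONS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the nine protocols, with its hyperparameter grid."""

    id: str
    base: str
    reducer: str
    hyper_grid: dict = field(default_factory=dict)
    roc_fr_threshold: float = 0.20
    rfe_fractions: tuple = _RFE_FRACTIONS

    def __post_init__(self) -> None:
        if _COMBOS.get(self.id) != (self.base, self.reducer):
            raise ValueError(
                f"({self.base}, {self.reducer}) is not the defined pair for {self.id}"
            )


def classifier_spec(cid: str, roc_fr_threshold: float = 0.20,
                    hyper_grid: dict | None = None) -> ClassifierSpec:
    """Build the :class:`ClassifierSpec` for a protocol id C1..C9."""
    if cid not in _COMBOS:
        raise ValueError(f"unknown classifier id {cid!r}; expected C1..C9")
    base, reducer = _COMBOS[cid]
    grid = hyper_grid if hyper_grid is not None else _DEFAULT_GRIDS[base]
    return ClassifierSpec(cid, base, reducer, dict(grid), roc_fr_threshold)


class ZScore:
    """Column-wise z-score with sample (n-1) SD, fitted on training rows.

    Zero-SD columns are mapped to 0 (with a warning at fit time)."""

    def fit(self, train: np.ndarray) -> "ZScore":
        train = np.asarray(train, float)
        if train.shape[0] < 2:
            raise ValueError("z-score needs at least 2 training rows")
        self.mean_ = train.mean(axis=0)
        self.sd_ = train.std(axis=0, ddof=1)
        self.constant_ = self.sd_ == 0
        if self.constant_.any():
            warnings.warn(
                f"{int(self.constant_.sum())} constant feature(s) mapped to 0 "
                "by z-score normalization", stacklevel=2,
            )
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        sd = np.where(self.constant_, 1.0, self.sd_)
        out = (np.asarray(x, float) - self.mean_) / sd
        out[:, self.constant_] = 0.0
        return out


def zscore_fit_apply(train: np.ndarray, *others: np.ndarray):
    """Normalize ``train`` to mean 0 / sample SD 1 per column and apply the
    train statistics to the other matrices. Returns the normalized matrices
    in the same order (a single ndarray when no others are given)."""
    scaler = ZScore().fit(train)
    out = (scaler.transform(train), *(scaler.transform(o) for o in others))
    return out[0] if not others else out


class _Identity:
    flags: tuple = ()

    def transform(self, x):
        return x


class _Subset:
    """Column-subset transformer (RFE / ROC-based retention)."""

    def __init__(self, support: np.ndarray, flags=()):
        self.support = np.asarray(support, bool)
        self.flags = tuple(flags)

    def transform(self, x):
        return x[:, self.support]


class _Projection:
    """Fitted PCA projection."""

    def __init__(self, pca: PCA):
        self.pca = pca
        self.flags = ()

    def transform(self, x):
        return self.pca.transform(x)


def _base_estimator(base: str, params: dict, seed: int):
    if base == "logistic_regression":
        return LogisticRegression(
            C=float(params["C"]), class_weight="balanced",
            solver="liblinear", max_iter=500, random_state=seed,
        )
    if base == "linear_svm":
        return LinearSVC(
            C=float(params["C"]), class_weight="balanced",
            dual=True, max_iter=20000, random_state=seed,
        )
    if base == "lasso":
        return Lasso(alpha=float(params["alpha"]), max_iter=5000)
    raise ValueError(f"unknown base learner {base!r}")


def _class_sample_weight(y: np.ndarray) -> np.ndarray:
    # inverse-frequency weights, mirroring class_weight='balanced'
    n, counts = len(y), np.bincount(y, minlength=2)
    return n / (2.0 * counts[y])


def _fit(base: str, params: dict, x, y, seed: int):
    est = _base_estimator(base, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if base == "lasso":
            est.fit(x, y, sample_weight=_class_sample_weight(y))
        else:
            est.fit(x, y)
    return est

def _predict(base: str, est, x) -> np.ndarray:
    if base == "lasso":
        return (est.predict(x) >= 0.5).astype(int)
    return est.predict(x).astype(int)


def _scores(base: str, est, x) -> np.ndarray:
    if base == "lasso":
        return est.predict(x)
    return est.decision_function(x)


def _youden_pred(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    se = float(y_pred[y_true == 1].mean())
    sp = float(1 - y_pred[y_true == 0].mean())
    return se + sp - 1.0


def reduce_features(spec: ClassifierSpec, train_features: np.ndarray,
                    train_labels: np.ndarray, n_features: float | None = None,
                    seed: int = 0):
    """Fit the protocol's dimensionality reducer on (normalized) train data.

    ``n_features`` (a fraction of columns) applies to RFE only. ROC-based
    retention keeps features whose train YI exceeds the spec threshold,
    falling back to the single best feature (flagged) when none pass. PCA
    keeps the smallest number of components explaining >= 95% variance,
    capped at n_rows - 1. Returns a transformer reapplicable to VS/TES.
    """
    x, y = np.asarray(train_features, float), np.asarray(train_labels, int)
    if spec.reducer == "none":
        return _Identity()
    if spec.reducer == "rfe":
        frac = 0.5 if n_features is None else float(n_features)
        k = max(1, int(round(frac * x.shape[1])))
        inner = _base_estimator(spec.base, {"C": 1.0}, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rfe = RFE(inner, n_features_to_select=k, step=0.25).fit(x, y)
        return _Subset(rfe.support_)
    if spec.reducer == "pca":
        cap = max(1, min(x.shape[0] - 1, x.shape[1]))
        pca = PCA(n_components=cap, svd_solver="full").fit(x)
        ratios = np.cumsum(pca.explained_variance_ratio_)
        ncomp = int(np.searchsorted(ratios, 0.95 - 1e-12) + 1)
        pca = PCA(n_components=min(ncomp, cap), svd_solver="full").fit(x)
        return _Projection(pca)
    if spec.reducer == "roc_fr":
        yis = youden_index_matrix(x, y)
        support = yis > spec.roc_fr_threshold
        flags = ()
        if not support.any():
            support = yis == yis.max()
            # keep only one when the max ties
            first = int(np.argmax(support))
            support = np.zeros_like(support)
            support[first] = True
            flags = ("roc_fr_fallback_single_feature",)
        return _Subset(support, flags)
    raise ValueError(f"unknown reducer {spec.reducer!r}")


@dataclass
class CvRunResult:
    """One run's SKFCV outcome for one protocol.

    ``yi_vs``/``sd_vs`` are the mean/sample SD of the K per-fold
    validation Youden indices; the fold with the best validation YI is
    frozen (normalization statistics, reducer, hyperparameters, fitted
    weights) and applied to TES.
    """

    run_index: int
    fold_yis: np.ndarray
    yi_vs: float
    sd_vs: float
    yi_tes: float
    auc_vs: float
    auc_tes: float
    selected_fold: int
    selected_params: dict
    flags: tuple = ()


def _grid_candidates(spec: ClassifierSpec):
    name = "C" if spec.base in ("logistic_regression", "linear_svm") else "alpha"
    values = spec.hyper_grid.get(name, _DEFAULT_GRIDS[spec.base][name])
    return name, list(values)


def skfcv_evaluate(x_trvs: np.ndarray, y_trvs: np.ndarray,
                   spec: ClassifierSpec, k_folds: int, seed: int,
                   x_tes: np.ndarray | None = None,
                   y_tes: np.ndarray | None = None,
                   run_index: int = 1) -> CvRunResult:
    """Stratified K-fold evaluation of one protocol on a TRS+VS matrix.

    See module docstring for the per-fold procedure. When no TES is given
    the test-side metrics are NaN.
    """
    y_trvs = np.asarray(y_trvs, int)
    counts = np.bincount(y_trvs, minlength=2)
    if counts.min() < k_folds:
        raise ValueError(
            f"minority class has {counts.min()} samples < K={k_folds}; "
            "use a smaller K so every fold keeps both classes"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**31))
    pname, pvalues = _grid_candidates(spec)
    rfe_fracs = spec.rfe_fractions if spec.reducer == "rfe" else (None,)
    config_keys = [(frac, v) for frac in rfe_fracs for v in pvalues]

    # Hyperparameters are tuned jointly across the K folds: each candidate
    # configuration is scored by its mean validation YI over the folds and a
    # single winner is kept (ties -> first in grid order). The winner's
    # per-fold validation YIs become fold_yis.
    folds, fold_flags = [], []
    for tr_idx, vs_idx in skf.split(x_trvs, y_trvs):
        scaler = ZScore().fit(x_trvs[tr_idx])
        xtr = scaler.transform(x_trvs[tr_idx])
        xvs = scaler.transform(x_trvs[vs_idx])
        ytr, yvs = y_trvs[tr_idx], y_trvs[vs_idx]
        per_config = {}
        for frac in rfe_fracs:
            reducer = reduce_features(spec, xtr, ytr, n_features=frac, seed=seed)
            fold_flags.extend(reducer.flags)
            xtr_r, xvs_r = reducer.transform(xtr), reducer.transform(xvs)
            for v in pvalues:
                est = _fit(spec.base, {pname: v}, xtr_r, ytr, seed)
                yi = _youden_pred(yvs, _predict(spec.base, est, xvs_r))
                auc_vs = roc_auc(_scores(spec.base, est, xvs_r), yvs)
                per_config[(frac, v)] = (yi, auc_vs, est, reducer)
        folds.append((scaler, per_config))

    mean_scores = [
        float(np.mean([pc[key][0] for _, pc in folds])) for key in config_keys
    ]
    best_key = config_keys[int(np.argmax(mean_scores))]
    params = {pname: best_key[1]}
    if best_key[0] is not None:
        params["rfe_fraction"] = best_key[0]
    fold_yis = np.asarray([pc[best_key][0] for _, pc in folds])
    fold_aucs = [pc[best_key][1] for _, pc in folds]
    sel = int(np.argmax(fold_yis))
    scaler, per_config = folds[sel]
    _, _, est, reducer = per_config[best_key]
    yi_tes = auc_tes = float("nan")
    if x_tes is not None and len(x_tes):
        xte = reducer.transform(scaler.transform(x_tes))
        yi_tes = _youden_pred(np.asarray(y_tes, int), _predict(spec.base, est, xte))
        auc_tes = roc_auc(_scores(spec.base, est, xte), np.asarray(y_tes, int))
    return CvRunResult(
        run_index=run_index,
        fold_yis=fold_yis,
        yi_vs=float(fold_yis.mean()),
        sd_vs=float(fold_yis.std(ddof=1)) if k_folds > 1 else 0.0,
        yi_tes=yi_tes,
        auc_vs=float(np.mean(fold_aucs)),
        auc_tes=auc_tes,
        selected_fold=sel,
        selected_params=params,
        flags=tuple(sorted(set(fold_flags))),
    )


def run_skfcv(cohort: Cohort, setup: SetUp, spec: ClassifierSpec,
              run_index: int, base_seed: int) -> CvRunResult:
    """One random split of a set-up, evaluated with SKFCV (see
    :func:`skfcv_evaluate`); TES metrics use the split's test subset."""
    plan = draw_split(cohort, setup, run_index, base_seed)
    rng = split_rng(base_seed, f"{setup.id}/{spec.id}", run_index)
    seed = int(rng.integers(2**31))
    x_tes = cohort.features[plan.tes_indices] if setup.n_tes else None
    y_tes = cohort.labels[plan.tes_indices] if setup.n_tes else None
    return skfcv_evaluate(
        cohort.features[plan.trvs_indices], cohort.labels[plan.trvs_indices],
        spec, setup.k_folds, seed, x_tes, y_tes, run_index,
    )


@dataclass
class MlSetupResult:
    """Aggregate of repeated SKFCV runs for one (set-up, protocol) pair."""

    setup_id: str
    classifier_id: str
    runs: list
    mean_vs: float
    sd_vs: float
    mean_tes: float
    sd_tes: float
    mean_auc_vs: float
    sd_auc_vs: float
    mean_auc_tes: float
    sd_auc_tes: float
    mean_diff: float
    mean_abs_diff: float
    n_runs: int
    low_precision: bool = False


def run_ml_setup(cohort: Cohort, setup: SetUp, spec: ClassifierSpec,
                 n_runs: int = 50, base_seed: int = 0) -> MlSetupResult:
    """Repeat :func:`run_skfcv` over random splits and aggregate.

    Reports mean/sample-SD of the validation and test Youden indices and
    AUCs, plus the mean (signed) and mean absolute difference between a
    run's validation and test YI.
    """
    runs = [run_skfcv(cohort, setup, spec, i, base_seed)
            for i in range(1, n_runs + 1)]
    vs = np.array([r.yi_vs for r in runs])
    tes = np.array([r.yi_tes for r in runs])
    avs = np.array([r.auc_vs for r in runs])
    ates = np.array([r.auc_tes for r in runs])
    sd = (lambda a: float(np.std(a, ddof=1))) if n_runs > 1 else (lambda a: 0.0)
    return MlSetupResult(
        setup.id, spec.id, runs,
        float(vs.mean()), sd(vs), float(tes.mean()), sd(tes),
        float(avs.mean()), sd(avs), float(ates.mean()), sd(ates),
        float((vs - tes).mean()), float(np.abs(vs - tes).mean()),
        n_runs, low_precision=n_runs < 3,
    )


def reference_lr_cv(cohort: Cohort, k_folds: int = 10, n_repeats: int = 20,
                    base_seed: int = 0) -> dict:
    """Replicate the classical logistic-regression cross-validation protocol
    used to benchmark the breast-FNA cohort.

    Plain maximum-likelihood logistic regression (no penalty, no class
    weighting — what "logistic regression" denotes in the clinical
    literature) on the raw features; stratified K-fold CV; Se/Sp/YI from
    the pooled out-of-fold class predictions at probability 0.5; means
    over repeated shuffles.
    """
    x, y = cohort.features, cohort.labels
    yis, ses, sps = [], [], []
    for rep in range(n_repeats):
        seed = int(split_rng(base_seed, "reference-lr-cv", rep).integers(2**31))
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        preds = np.empty_like(y)
        for tr, vs in skf.split(x, y):
            # liblinear with a huge C is an effectively unpenalized ML fit
            est = LogisticRegression(C=1e8, solver="liblinear", max_iter=10000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(x[tr], y[tr])
            preds[vs] = est.predict(x[vs])
        se = float(preds[y == 1].mean())
        sp = float(1 - preds[y == 0].mean())
        ses.append(se); sps.append(sp); yis.append(se + sp - 1)
    return {
        "yi": float(np.mean(yis)), "yi_sd": float(np.std(yis, ddof=1)),
        "se": float(np.mean(ses)), "sp": float(np.mean(sps)),
        "n_repeats": n_repeats, "k_folds": k_folds,
    }


def coverage_fraction(results) -> float:
    """Percentage of runs whose test YI falls inside the run's
    validation band yi_vs +/- sd_vs."""
    results = list(results)
    if not results:
        raise ValueError("coverage_fraction needs at least one run")
    hits = sum(abs(r.yi_tes - r.yi_vs) <= r.sd_vs for r in results)
    return 100.0 * hits / len(results)
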