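"""Feature-table cohorts: loading, serialization, permutation nulls, simulation.

A cohort is a numeric feature matrix with a binary label vector
(positive = group 1, negative = group 2). Real cohorts come from CSV
feature tables; synthetic cohorts are either label-permuted copies of a
real cohort (a no-information null preserving the class fractions) or
fully simulated class-conditional Gaussian tables with per-feature
standardized effect sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "SimulationSpec",
    "load_cohort",
    "write_cohort",
    "permute_labels",
    "simulate_cohort",
    "wdbc_cohort",
    "WDBC_FEATURE_NAMES",
]

# Canonical column names of the UCI Wisconsin Diagnostic Breast Cancer table:
# mean, standard error and "worst" (mean of the three largest values) of ten
# nuclear parameters measured on fine-needle-aspiration images.
_WDBC_PARAMS = [
    "radius", "texture", "perimeter", "area", "smoothness",
    "compactness", "concavity", "concave points", "symmetry",
    "fractal dimension",
]
WDBC_FEATURE_NAMES: list[str] = (
    [f"mean {p}" for p in _WDBC_PARAMS]
    + [f"{p} error" for p in _WDBC_PARAMS]
    + [f"worst {p}" for p in _WDBC_PARAMS]
)


class CohortError(ValueError):
    """Raised when a feature table cannot be assembled into a valid cohort."""


@dataclass
class Cohort:
    """A binary-class feature table.

    Attributes
    ----------
    features : ndarray of shape (n_samples, n_features)
    labels : ndarray of 0/1, 1 = positive class
    feature_names : unique column names
    name : free-form provenance tag
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise CohortError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise CohortError("labels length must match the number of rows")
        if not np.isfinite(self.features).all():
            raise CohortError("feature matrix contains missing/non-finite values")
        if set(np.unique(self.labels)) - {0, 1}:
            raise CohortError("labels must be encoded 0/1")
        if self.n_pos == 0 or self.n_neg == 0:
            raise CohortError("both classes must be non-empty")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise CohortError("feature names must be unique")
        if len(self.feature_names) != self.features.shape[1]:
            raise CohortError("feature_names length must match the number of columns")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def feature(self, name: str) -> np.ndarray:
        """Column vector for a named feature."""
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.features[:, j]

    def subset(self, indices: np.ndarray, name: str | None = None) -> "Cohort":
        """Row subset as a new cohort."""
        idx = np.asarray(indices, dtype=int)
        return Cohort(
            self.features[idx], self.labels[idx],
            list(self.feature_names), name or f"{self.name}[{len(idx)}]",
        )


@dataclass
class SimulationSpec:
    """Parameters of a fully simulated class-conditional Gaussian cohort.

    Each feature is Gaussian with standard deviation ``noise_sd`` in both
    classes; the positive-class mean is shifted by
    ``effect_size * noise_sd`` so that ``effect_sizes`` are standardized
    mean differences (Cohen's d). ``correlation`` lists equicorrelated
    blocks of consecutive features as ``(block_size, rho)`` pairs; features
    not covered by a block are independent.
    """

    n_pos: int
    n_neg: int
    n_features: int
    effect_sizes: Sequence[float]
    noise_sd: float = 1.0
    correlation: Sequence[tuple[int, float]] | None = None
    seed: int = 0
    name: str = "simulated"

    def __post_init__(self) -> None:
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if self.effect_sizes.shape != (self.n_features,):
            raise ValueError("effect_sizes length must equal n_features")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("both group sizes must be positive")

    def to_dict(self) -> dict:
        d = {
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "n_features": self.n_features,
            "effect_sizes": list(map(float, self.effect_sizes)),
            "noise_sd": self.noise_sd, "seed": self.seed, "name": self.name,
        }
        if self.correlation is not None:
            d["correlation"] = [list(b) for b in self.correlation]
        return d


def _parse_generic(path: Path, label_column: str, positive_label: str | None,
                   missing: str) -> tuple[pd.DataFrame, np.ndarray, str]:
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column is None or label_column not in df.columns:
        raise CohortError(
            f"label column {label_column!r} not found in {path.name}; "
            f"columns are {list(df.columns)}"
        )
    raw_labels = df[label_column]
    feats = df.drop(columns=[label_column])
    # locate non-numeric cells before coercion so the error names them
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & feats.notna()
    if bad.any().any():
        col = bad.any().idxmax()
        row = int(bad[col].idxmax())
        raise CohortError(
            f"non-numeric feature value at row {row}, column {col!r} in {path.name}"
        )
    if numeric.isna().any().any():
        if missing == "impute_median":
            numeric = numeric.fillna(numeric.median())
        else:
            rows = sorted(numeric.index[numeric.isna().any(axis=1)].tolist())
            raise CohortError(
                f"missing feature values in rows {rows} of {path.name}; "
                "pass missing='impute_median' to impute"
            )
    classes = sorted(map(str, pd.unique(raw_labels.astype(str))))
    if len(classes) != 2:
        raise CohortError(
            f"label column must contain exactly 2 classes, found {classes}"
        )
    if positive_label is None:
        positive_label = classes[0]
    elif str(positive_label) not in classes:
        raise CohortError(
            f"positive label {positive_label!r} not among classes {classes}"
        )
    labels = (raw_labels.astype(str) == str(positive_label)).to_numpy().astype(int)
    return numeric, labels, str(positive_label)


def _parse_wdbc(path: Path, positive_label: str | None) -> tuple[pd.DataFrame, np.ndarray, str]:
    # UCI layout: no header; column 1 = sample ID (dropped),
    # column 2 = diagnosis in {M, B}, columns 3-32 = the 30 features.
    df = pd.read_csv(path, header=None, float_precision="round_trip")
    if df.shape[1] != 32:
        raise CohortError(
            f"wdbc dialect expects 32 columns (ID, diagnosis, 30 features), "
            f"got {df.shape[1]} in {path.name}"
        )
    diag = df.iloc[:, 1].astype(str)
    if not set(diag) <= {"M", "B"}:
        raise CohortError("wdbc diagnosis column must contain only M and B")
    feats = df.iloc[:, 2:].copy()
    feats.columns = WDBC_FEATURE_NAMES
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna()
        col = bad.any().idxmax()
        row = int(bad[col].idxmax())
        raise CohortError(
            f"non-numeric feature value at row {row}, column {col!r} in {path.name}"
        )
    positive_label = positive_label or "M"
    labels = (diag == positive_label).to_numpy().astype(int)
    return numeric, labels, positive_label


def load_cohort(path: str | Path, label_column: str | None = None,
                positive_label: str | None = None,
                dialect: str = "generic_csv",
                missing: str = "reject") -> Cohort:
    """Load a feature table from CSV.

    ``dialect='generic_csv'`` expects a header row and a named label column
    with exactly two distinct values; ``dialect='wdbc'`` parses the UCI
    Wisconsin Diagnostic Breast Cancer layout (no header, ID column dropped,
    diagnosis M/B as label, malignant positive by default).
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    if dialect == "generic_csv":
        numeric, labels, pos = _parse_generic(path, label_column, positive_label, missing)
    elif dialect == "wdbc":
        numeric, labels, pos = _parse_wdbc(path, positive_label)
    else:
        raise CohortError(f"unknown dialect {dialect!r}")
    return Cohort(
        numeric.to_numpy(dtype=float), labels,
        [str(c) for c in numeric.columns],
        name=f"{path.stem} (positive={pos})",
    )


def write_cohort(cohort: Cohort, path: str | Path, label_column: str = "label") -> None:
    """Serialize a cohort as generic CSV (labels written as 1/0).

    Floats are written with 17 significant digits, so a subsequent
    :func:`load_cohort` reproduces the matrix bit-identically.
    """
    if label_column in cohort.feature_names:
        raise CohortError(f"label column name {label_column!r} collides with a feature")
    df = pd.DataFrame(cohort.features, columns=cohort.feature_names)
    df[label_column] = cohort.labels
    df.to_csv(path, index=False, float_format="%.17g")


def permute_labels(cohort: Cohort, seed: int) -> Cohort:
    """No-information null: randomly reassign labels, preserving class counts.

    The feature matrix is untouched; the label vector is a uniformly random
    permutation of the original one, so the class fractions of the real
    cohort are exactly preserved. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    permuted = cohort.labels[rng.permutation(cohort.n_samples)]
    return Cohort(cohort.features, permuted, list(cohort.feature_names),
                  name=f"{cohort.name} (permuted, seed={seed})")


def simulate_cohort(spec: SimulationSpec) -> Cohort:
    """Simulate a two-class Gaussian cohort from a :class:`SimulationSpec`.

    Negative-class features ~ N(0, noise_sd^2); positive-class features
    ~ N(effect_size * noise_sd, noise_sd^2). Correlated blocks share an
    equicorrelation rho while keeping unit-variance marginals, so effect
    sizes stay standardized.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    z = rng.standard_normal((n, spec.n_features))
    if spec.correlation:
        start = 0
        for size, rho in spec.correlation:
            if not (0 <= rho < 1):
                raise ValueError("block correlation must be in [0, 1)")
            stop = start + size
            if stop > spec.n_features:
                raise ValueError("correlation blocks exceed n_features")
            shared = rng.standard_normal((n, 1))
            z[:, start:stop] = (
                np.sqrt(rho) * shared + np.sqrt(1 - rho) * z[:, start:stop]
            )
            start = stop
    labels = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    x = z * spec.noise_sd
    x[labels == 1] += np.asarray(spec.effect_sizes) * spec.noise_sd
    names = [f"f{j:02d}" for j in range(spec.n_features)]
    return Cohort(x, labels, names, name=spec.name)


def wdbc_cohort() -> Cohort:
    """The 569-sample, 30-feature breast FNA cohort (malignant positive).

    Loaded from scikit-learn's bundled copy of the UCI WDBC table:
    212 malignant (MM) vs 357 benign (BM) lesions.
    """
    from sklearn.datasets import load_breast_cancer

    data = load_breast_cancer()
    labels = (data.target == 0).astype(int)  # sklearn codes malignant as 0
    return Cohort(data.data.copy(), labels, [str(f) for f in data.feature_names],
                  name="wdbc (positive=M)")


def write_simulation_sidecar(spec: SimulationSpec, csv_path: str | Path) -> Path:
    """Write the generating spec next to a simulated cohort's CSV."""
    sidecar = Path(csv_path).with_suffix(".spec.json")
    sidecar.write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    return sidecar
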