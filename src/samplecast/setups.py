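"""Experimental set-ups: per-class subset sizes and repeated random splits.

A set-up fixes the class composition of the model-building subset
(training + validation, TRS+VS) and of the held-out test subset (TES),
plus the fold count K for stratified cross-validation. Repeating the
random split many times (default 50) and aggregating measures how stable
a performance estimate is under that composition.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .cohorts import Cohort

__all__ = [
    "SetUp",
    "SplitPlan",
    "default_k",
    "build_setup_grid",
    "draw_split",
    "cohort1_setups",
    "cohort2_setups",
]


@dataclass(frozen=True)
class SetUp:
    """Group sizes for TRS+VS and TES plus the SKFCV fold count."""

    id: str
    n_pos_trvs: int
    n_neg_trvs: int
    n_pos_tes: int
    n_neg_tes: int
    k_folds: int

    def __post_init__(self) -> None:
        counts = (self.n_pos_trvs, self.n_neg_trvs, self.n_pos_tes, self.n_neg_tes)
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.id}: negative class count")
        if self.n_pos_trvs + self.n_neg_trvs < self.k_folds:
            raise ValueError(f"{self.id}: fewer TRS+VS samples than folds")
        if self.k_folds >= 2 and min(self.n_pos_trvs, self.n_neg_trvs) < self.k_folds:
            raise ValueError(
                f"{self.id}: minority TRS+VS count {min(self.n_pos_trvs, self.n_neg_trvs)}"
                f" < K={self.k_folds}; some folds would miss a class"
            )

    @property
    def n_trvs(self) -> int:
        return self.n_pos_trvs + self.n_neg_trvs

    @property
    def n_tes(self) -> int:
        return self.n_pos_tes + self.n_neg_tes


@dataclass
class SplitPlan:
    """One random split: disjoint TRS+VS and TES row indices."""

    run_index: int
    trvs_indices: np.ndarray
    tes_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.trvs_indices, self.tes_indices).size:
            raise ValueError("TRS+VS and TES index sets overlap")


def default_k(minority_count: int) -> int:
    """Default SKFCV fold count: ~10 minority samples per fold, in [2, 10]."""
    return int(np.clip(minority_count // 10, 2, 10))


def build_setup_grid(cohort: Cohort, mode: str, config: dict) -> list[SetUp]:
    """Build an increasing grid of set-ups over a cohort.

    ``config`` keys: ``start`` (pos, neg) counts of the first set-up;
    ``step`` (pos, neg) per-class increment; ``n_setups``; ``tes``
    (pos, neg) fixed test counts; optional ``k_folds`` list (one per
    set-up; otherwise the :func:`default_k` rule); optional ``id_prefix``.

    ``mode='unbalanced'`` keeps the start/step class ratio (typically the
    cohort's own); ``mode='balanced'`` requires equal per-class counts.
    """
    if mode not in ("unbalanced", "balanced"):
        raise ValueError(f"unknown mode {mode!r}")
    pos0, neg0 = config["start"]
    pos_s, neg_s = config["step"]
    n_setups = int(config["n_setups"])
    tes_pos, tes_neg = config["tes"]
    k_list = config.get("k_folds")
    prefix = config.get("id_prefix", "S")
    if mode == "balanced" and (pos0 != neg0 or pos_s != neg_s):
        raise ValueError("balanced mode requires equal per-class start and step")
    setups = []
    for i in range(n_setups):
        n_pos = pos0 + i * pos_s
        n_neg = neg0 + i * neg_s
        k = int(k_list[i]) if k_list is not None else default_k(min(n_pos, n_neg))
        s = SetUp(f"{prefix}{i + 1}", n_pos, n_neg, tes_pos, tes_neg, k)
        if n_pos + tes_pos > cohort.n_pos or n_neg + tes_neg > cohort.n_neg:
            raise ValueError(
                f"set-up {s.id} infeasible for cohort {cohort.name!r}: needs "
                f"{n_pos + tes_pos} positives / {n_neg + tes_neg} negatives, "
                f"cohort has {cohort.n_pos}/{cohort.n_neg}"
            )
        setups.append(s)
    return setups


def cohort1_setups() -> list[SetUp]:
    """The 14 lung-lesion (PET) set-ups: S1-S9 unbalanced at the cohort's
    3:1 ratio, S10-S14 balanced; TES fixed at 30 positives / 10 negatives.
    Fold counts follow the published grid."""
    ks_unbal = [2, 2, 3, 3, 3, 3, 3, 3, 3]
    setups = [
        SetUp(f"S{i + 1}", 30 * (i + 1), 10 * (i + 1), 30, 10, ks_unbal[i])
        for i in range(9)
    ]
    ks_bal = [3, 4, 6, 7, 9]
    setups += [
        SetUp(f"S{10 + i}", 30 + 15 * i, 30 + 15 * i, 30, 10, ks_bal[i])
        for i in range(5)
    ]
    return setups


def cohort2_setups() -> list[SetUp]:
    """The 18 breast-FNA set-ups (positive = malignant): S1-S8 unbalanced
    (10 MM / 17 BM steps), S9 = 160 MM / 270 BM, S10-S17 balanced 10..80
    per class, S18 = 160/160; TES fixed at 42 MM / 71 BM. Fold counts from
    the default minority rule."""
    setups = [
        SetUp(f"S{i + 1}", 10 * (i + 1), 17 * (i + 1), 42, 71,
              default_k(10 * (i + 1)))
        for i in range(8)
    ]
    setups.append(SetUp("S9", 160, 270, 42, 71, default_k(160)))
    setups += [
        SetUp(f"S{10 + i}", 10 * (i + 1), 10 * (i + 1), 42, 71,
              default_k(10 * (i + 1)))
        for i in range(8)
    ]
    setups.append(SetUp("S18", 160, 160, 42, 71, default_k(160)))
    return setups


def _setup_entropy(setup_id: str) -> int:
    return zlib.crc32(setup_id.encode())


def split_rng(base_seed: int, tag: str, run_index: int) -> np.random.Generator:
    """Deterministic per-(seed, tag, run) generator."""
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), _setup_entropy(tag), int(run_index)])
    )


def draw_split(cohort: Cohort, setup: SetUp, run_index: int,
               base_seed: int) -> SplitPlan:
    """Stratified random split into TRS+VS and TES, without replacement.

    Class counts match the set-up exactly; the draw is a pure function of
    (base_seed, setup.id, run_index). TRS+VS and TES are both redrawn each
    run — there is no frozen holdout.
    """
    need_pos = setup.n_pos_trvs + setup.n_pos_tes
    need_neg = setup.n_neg_trvs + setup.n_neg_tes
    if need_pos > cohort.n_pos or need_neg > cohort.n_neg:
        raise ValueError(
            f"set-up {setup.id} infeasible: needs {need_pos} positives / "
            f"{need_neg} negatives, cohort has {cohort.n_pos}/{cohort.n_neg}"
        )
    rng = split_rng(base_seed, setup.id, run_index)
    pos_idx = np.flatnonzero(cohort.labels == 1)
    neg_idx = np.flatnonzero(cohort.labels == 0)
    pos_perm = rng.permutation(pos_idx)
    neg_perm = rng.permutation(neg_idx)
    trvs = np.concatenate([
        pos_perm[: setup.n_pos_trvs], neg_perm[: setup.n_neg_trvs]
    ])
    tes = np.concatenate([
        pos_perm[setup.n_pos_trvs: need_pos],
        neg_perm[setup.n_neg_trvs: need_neg],
    ])
    return SplitPlan(run_index, np.sort(trvs), np.sort(tes), base_seed)
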