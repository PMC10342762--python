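"""Variable selection by exhaustive subset search with a Gower-distance KNN.

The classifier's six input variables were originally chosen by scoring every
non-empty subset of the candidate prebiopsy variables with a k-nearest-
neighbour classifier (k = 33) under the Gower dissimilarity, which averages
range-normalised absolute differences for numeric variables and simple
mismatch indicators for categoricals — the natural metric for mixed-type
clinical records.  This module reproduces that procedure on any labelled
cohort.

Ordinal scores (PI-RADS, lesion count) enter Gower as numerics so their
ordering is preserved; DRE, prior-biopsy and lesion-location are categorical.
Numeric ranges are min–max over the training cohort and are frozen with the
model so prediction-time distances use the training scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .cohort import (CATEGORICAL_VARIABLES, FIS_VARIABLES, NEGATIVE,
                     NUMERIC_VARIABLES, Cohort, CohortError, PatientRecord,
                     POSITIVE)

DEFAULT_K = 33  # neighbourhood size used in the original subset search


@dataclass(frozen=True)
class FeatureSubsetResult:
    subset: frozenset[str]
    score: float
    evaluation_scheme: str

    def __post_init__(self) -> None:
        if not self.subset:
            raise ValueError("subset must be non-empty")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def compute_ranges(cohort: Cohort,
                   variables: Sequence[str]) -> dict[str, float]:
    """Min–max range per numeric variable over the cohort."""
    ranges: dict[str, float] = {}
    for var in variables:
        if var in NUMERIC_VARIABLES:
            vals = [float(r.value(var)) for r in cohort]
            ranges[var] = max(vals) - min(vals)
    return ranges


def gower_distance(a: PatientRecord, b: PatientRecord,
                   variables: Sequence[str],
                   ranges: Mapping[str, float]) -> float:
    """Gower dissimilarity in [0, 1] over the named variables.

    Numeric contribution |a - b| / range (clipped to 1), categorical 0/1
    mismatch; the distance is their unweighted mean.
    """
    if not variables:
        raise ValueError("need at least one variable")
    total = 0.0
    for var in variables:
        va, vb = a.value(var), b.value(var)
        if var in CATEGORICAL_VARIABLES:
            total += 0.0 if va == vb else 1.0
        else:
            rng = ranges.get(var)
            if rng is None or rng <= 0:
                raise ValueError(f"non-positive range for numeric "
                                 f"variable {var!r}")
            total += min(abs(float(va) - float(vb)) / rng, 1.0)
    return total / len(variables)


def _encode(cohort: Cohort, variables: Sequence[str],
            ranges: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Columns scaled so that plain L1 row-mean equals the Gower distance.

    Categoricals become integer codes compared for equality; numerics are
    divided by their range.  Returns (numeric_matrix, is_categorical mask).
    """
    cols = []
    catmask = []
    for var in variables:
        if var in CATEGORICAL_VARIABLES:
            values = [r.value(var) for r in cohort]
            codes = {v: i for i, v in enumerate(sorted(set(values)))}
            cols.append(np.array([codes[v] for v in values], dtype=float))
            catmask.append(True)
        else:
            rng = ranges[var]
            if rng <= 0:
                raise ValueError(f"non-positive range for {var!r}")
            cols.append(np.array([float(r.value(var)) for r in cohort]) / rng)
            catmask.append(False)
    return np.column_stack(cols), np.array(catmask)


def _gower_matrix(query: np.ndarray, train: np.ndarray,
                  catmask: np.ndarray) -> np.ndarray:
    """Pairwise Gower distances between encoded query and train rows."""
    diff = np.abs(query[:, None, :] - train[None, :, :])
    per_var = np.where(catmask[None, None, :],
                       (diff > 0).astype(float),
                       np.minimum(diff, 1.0))
    return per_var.mean(axis=2)


def knn_classify(query: PatientRecord, train: Cohort, k: int,
                 variables: Sequence[str],
                 ranges: Mapping[str, float] | None = None) -> str:
    """Majority label among the k Gower-nearest training records.

    Records tied with the k-th neighbour's distance are all included; a vote
    tie resolves to ``negative`` (the clinically conservative default when
    the goal is a high negative predictive value).  The result is invariant
    to the order of the training records.
    """
    if k <= 0 or k > len(train):
        raise ValueError(f"k={k} outside [1, {len(train)}]")
    if any(not r.labeled for r in train):
        raise CohortError("training cohort contains unlabeled records")
    ranges = ranges if ranges is not None else compute_ranges(train, variables)
    dists = np.array([gower_distance(query, r, variables, ranges)
                      for r in train])
    kth = np.partition(dists, k - 1)[k - 1]
    include = dists <= kth + 1e-12
    labels = np.array(train.labels())[include]
    n_pos = int(np.sum(labels == POSITIVE))
    n_neg = int(np.sum(labels == NEGATIVE))
    return POSITIVE if n_pos > n_neg else NEGATIVE


def _knn_predict_matrix(dist: np.ndarray, train_labels: np.ndarray,
                        k: int) -> np.ndarray:
    """Vectorised KNN over a precomputed distance matrix (rows = queries)."""
    kth = np.partition(dist, k - 1, axis=1)[:, k - 1]
    include = dist <= kth[:, None] + 1e-12
    is_pos = (train_labels == POSITIVE)[None, :]
    n_pos = (include & is_pos).sum(axis=1)
    n_neg = (include & ~is_pos).sum(axis=1)
    return np.where(n_pos > n_neg, POSITIVE, NEGATIVE)


def _cv_accuracy(cohort: Cohort, variables: Sequence[str], k: int,
                 n_folds: int, seed: int) -> float:
    """Stratified n-fold cross-validated KNN accuracy."""
    labels = np.array(cohort.labels())
    rng = np.random.default_rng(seed)
    fold = np.empty(len(cohort), dtype=int)
    for cls in (NEGATIVE, POSITIVE):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    ranges = compute_ranges(cohort, variables)
    X, catmask = _encode(cohort, variables, ranges)
    correct = 0
    for f in range(n_folds):
        test = fold == f
        tr = ~test
        if k > int(tr.sum()):
            raise ValueError(f"k={k} exceeds training-fold size {tr.sum()}")
        dist = _gower_matrix(X[test], X[tr], catmask)
        pred = _knn_predict_matrix(dist, labels[tr], k)
        correct += int(np.sum(pred == labels[test]))
    return correct / len(cohort)


def exhaustive_subset_search(
    train: Cohort,
    candidates: Sequence[str] | None = None,
    k: int = DEFAULT_K,
    scheme: str = "cv5",
    seed: int = 0,
) -> list[FeatureSubsetResult]:
    """Score every non-empty candidate subset; best first.

    ``scheme`` is ``"cv5"`` (stratified 5-fold CV accuracy, the default) or
    ``"resub"`` (resubstitution accuracy with each query's own record
    excluded from its neighbourhood — leave-one-out).  Ties are broken
    toward smaller subsets, then lexicographically.
    """
    candidates = tuple(candidates if candidates is not None else FIS_VARIABLES)
    if len(candidates) > 15:
        raise ValueError(f"{len(candidates)} candidates: exhaustive search "
                         f"capped at 15 (2^p - 1 subsets)")
    if any(not r.labeled for r in train):
        raise CohortError("training cohort contains unlabeled records")

    results = []
    for size in range(1, len(candidates) + 1):
        for subset in combinations(candidates, size):
            if scheme == "cv5":
                score = _cv_accuracy(train, subset, k, 5, seed)
            elif scheme == "resub":
                score = _loo_accuracy(train, subset, k)
            else:
                raise ValueError(f"unknown evaluation scheme {scheme!r}")
            results.append(FeatureSubsetResult(frozenset(subset), score, scheme))
    results.sort(key=lambda r: (-r.score, len(r.subset), tuple(sorted(r.subset))))
    return results


def _loo_accuracy(cohort: Cohort, variables: Sequence[str], k: int) -> float:
    labels = np.array(cohort.labels())
    ranges = compute_ranges(cohort, variables)
    X, catmask = _encode(cohort, variables, ranges)
    dist = _gower_matrix(X, X, catmask)
    np.fill_diagonal(dist, np.inf)
    if k > len(cohort) - 1:
        raise ValueError(f"k={k} exceeds n-1={len(cohort) - 1}")
    pred = _knn_predict_matrix(dist, labels, k)
    return float(np.mean(pred == labels))
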