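"""Evaluation battery: confusion metrics, ROC, decision curves, baselines.

All derived metrics follow the standard confusion-matrix identities

    NPV  = TN / (TN + FN)        PPV  = TP / (TP + FP)
    spec = TN / (TN + FP)        sens = TP / (TP + FN)
    acc  = (TP + TN) / (TP + TN + FP + FN)

with the positive class meaning "biopsy detected cancer".  ROC curves are
swept over the unique scores, the area is trapezoidal, and the operating
threshold is read off the training curve (Youden's J by default); scores
greater than or equal to the threshold are called positive.  Decision-curve
analysis reports the net benefit  TP/n - FP/n * p_t / (1 - p_t)  across
threshold probabilities, against treat-all and treat-none references.

Comparator models: a logistic regression on the same six variables, and the
univariate thresholds on PSA, PSA density and PI-RADS.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn import metrics as skm

from .cohort import NEGATIVE, POSITIVE, Cohort, CohortError


class EvaluationError(ValueError):
    """Invalid evaluation request (label mismatch, single class, ...)."""


# ---------------------------------------------------------------------------
# Confusion counts and derived metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def predicted_negative(self) -> int:
        """TN + FN — biopsies the model would have called off."""
        return self.tn + self.fn


def confusion_counts(predictions: Sequence[str],
                     truth: Sequence[str]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN; positive = disease present at biopsy."""
    if len(predictions) != len(truth):
        raise EvaluationError(
            f"{len(predictions)} predictions vs {len(truth)} truths")
    bad = [t for t in truth if t not in (NEGATIVE, POSITIVE)]
    if bad:
        raise EvaluationError(f"truth labels must be negative/positive, "
                              f"found {bad[:3]}")
    tp = tn = fp = fn = 0
    for p, t in zip(predictions, truth):
        if t == POSITIVE:
            tp, fn = (tp + 1, fn) if p == POSITIVE else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if p == NEGATIVE else (tn, fp + 1)
    return ConfusionCounts(tp, tn, fp, fn)


def percent(fraction: float | None, decimals: int = 1) -> float | None:
    """Fraction -> percentage, rounded half-up (report convention)."""
    if fraction is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    """The five derived metrics as exact fractions (None when undefined)."""

    counts: ConfusionCounts
    npv: float | None
    ppv: float | None
    specificity: float | None
    sensitivity: float | None
    accuracy: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {name: percent(getattr(self, name))
                for name in ("npv", "ppv", "specificity",
                             "sensitivity", "accuracy")}


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """Apply the confusion-matrix identities; zero denominators -> None."""
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    c = counts
    return MetricsReport(
        counts=c,
        npv=ratio(c.tn, c.tn + c.fn),
        ppv=ratio(c.tp, c.tp + c.fp),
        specificity=ratio(c.tn, c.tn + c.fp),
        sensitivity=ratio(c.tp, c.tp + c.fn),
        accuracy=ratio(c.tp + c.tn, c.total),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    optimal_threshold: float


def roc_curve(scores: Sequence[float], truth: Sequence[str],
              criterion: str = "youden") -> ROCCurve:
    """Full ROC sweep with trapezoidal AUC and an optimal operating point.

    ``criterion`` selects the optimum on the curve: ``"youden"`` maximises
    sensitivity + specificity - 1; ``"closest"`` minimises the Euclidean
    distance to the perfect corner (0, 1).  The returned threshold follows
    the ">= threshold is positive" convention.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise EvaluationError("scores must be finite")
    y = np.asarray([1 if t == POSITIVE else 0 for t in truth])
    if y.min() == y.max():
        raise EvaluationError("both classes must be present for a ROC curve")
    fpr, tpr, thr = skm.roc_curve(y, scores, drop_intermediate=False)
    auc = float(skm.auc(fpr, tpr))
    finite = np.isfinite(thr)   # first sweep point is +inf sentinel
    if criterion == "youden":
        best = np.argmax((tpr - fpr)[finite])
    elif criterion == "closest":
        best = np.argmin((fpr[finite] ** 2 + (1 - tpr[finite]) ** 2))
    else:
        raise EvaluationError(f"unknown optimality criterion {criterion!r}")
    return ROCCurve(fpr, tpr, thr,
                    auc=auc, optimal_threshold=float(thr[finite][best]))


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DCACurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def decision_curve(truth: Sequence[str],
                   scores: Sequence[float] | None = None,
                   labels: Sequence[str] | None = None,
                   threshold_grid: Sequence[float] | None = None) -> DCACurve:
    """Net benefit across threshold probabilities p_t.

    net benefit(p_t) = TP/n - FP/n * p_t / (1 - p_t).  For a scoring model
    pass ``scores`` (called positive when score >= p_t); for a fixed
    classifier pass its ``labels`` (TP and FP then constant across the
    grid).  Treat-all and treat-none reference curves are included;
    treat-none is identically 0.
    """
    if (scores is None) == (labels is None):
        raise EvaluationError("pass exactly one of scores or labels")
    grid = np.asarray(threshold_grid if threshold_grid is not None
                      else np.arange(0.05, 1.0, 0.05))
    if np.any(grid <= 0.0) or np.any(grid >= 1.0):
        raise EvaluationError("threshold probabilities must lie in (0, 1)")
    y = np.asarray([1 if t == POSITIVE else 0 for t in truth])
    n = len(y)
    odds = grid / (1.0 - grid)

    if scores is not None:
        s = np.asarray(scores, dtype=float)
        tp = np.array([int(np.sum((s >= pt) & (y == 1))) for pt in grid])
        fp = np.array([int(np.sum((s >= pt) & (y == 0))) for pt in grid])
    else:
        pred = np.asarray(labels)
        tp_c = int(np.sum((pred == POSITIVE) & (y == 1)))
        fp_c = int(np.sum((pred == POSITIVE) & (y == 0)))
        tp = np.full_like(grid, tp_c, dtype=float)
        fp = np.full_like(grid, fp_c, dtype=float)

    nb = tp / n - fp / n * odds
    treat_all = y.sum() / n - (n - y.sum()) / n * odds
    return DCACurve(grid, nb, treat_all, np.zeros_like(grid))


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

#: design columns of the logistic baseline (binary categoricals as 0/1)
LR_COLUMNS = ("psa_density", "dre_positive", "prior_biopsy_yes",
              "n_lesions", "lesion_location_ta", "pirads")


def _lr_design(cohort: Cohort) -> np.ndarray:
    rows = []
    for r in cohort:
        rows.append([
            r.psa_density,
            1.0 if r.dre == POSITIVE else 0.0,
            1.0 if r.prior_biopsy == "yes" else 0.0,
            float(r.n_lesions),
            1.0 if r.lesion_location == "transitional_anterior" else 0.0,
            float(r.pirads),
        ])
    return np.asarray(rows)


@dataclass
class LRBaseline:
    """Maximum-likelihood logistic regression on the six variables."""

    params: np.ndarray        # intercept first, then LR_COLUMNS order
    bse: np.ndarray           # standard errors, same order
    threshold: float | None = None
    converged: bool = True

    def predict_proba(self, cohort: Cohort) -> np.ndarray:
        X = sm.add_constant(_lr_design(cohort), has_constant="add")
        eta = X @ self.params
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_labels(self, cohort: Cohort,
                       threshold: float | None = None) -> list[str]:
        thr = threshold if threshold is not None else self.threshold
        if thr is None:
            raise EvaluationError("no decision threshold set for the "
                                  "logistic baseline")
        return [POSITIVE if p >= thr else NEGATIVE
                for p in self.predict_proba(cohort)]


def fit_lr_baseline(train: Cohort, set_threshold: bool = True) -> LRBaseline:
    """Fit the logistic comparator; threshold from the training ROC.

    Raises with diagnostics if the likelihood maximisation does not
    converge (e.g. perfectly separable data).
    """
    labels = train.labels()
    if not {NEGATIVE, POSITIVE} <= set(labels):
        raise CohortError("training cohort must contain both classes")
    y = np.array([1 if lab == POSITIVE else 0 for lab in labels])
    X = sm.add_constant(_lr_design(train), has_constant="add")
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise EvaluationError(
            f"logistic regression did not converge: {res.mle_retvals}")
    model = LRBaseline(np.asarray(res.params), np.asarray(res.bse))
    if set_threshold:
        probs = model.predict_proba(train)
        model.threshold = roc_curve(probs, labels).optimal_threshold
    return model


def univariate_baseline(cohort: Cohort, variable: str,
                        threshold: float) -> list[str]:
    """Positive iff the variable's value is >= the threshold.

    The thresholds reported for the development cohort were 3.45 ng/mL for
    PSA, 0.10 ng/mL² for PSA density and 4 for the PI-RADS score.
    """
    if variable not in ("psa", "psa_density", "pirads"):
        raise EvaluationError(f"no univariate baseline for {variable!r}")
    labels = []
    for r in cohort:
        v = r.value(variable)
        if v is None:
            raise CohortError(f"patient {r.patient_id!r}: missing {variable}")
        labels.append(POSITIVE if float(v) >= threshold else NEGATIVE)
    return labels


# ---------------------------------------------------------------------------
# Published reference counts
# ---------------------------------------------------------------------------

#: Confusion counts reported for the five models on the original clinical
#: study's development (tabulated total 1447) and temporal validation
#: (n = 181) cohorts, keyed (set, model) -> (TP, TN, FP, FN).  They are the
#: fixture for checking the metric identities against the published derived
#: values; the underlying patient data are not public.
REFERENCE_COUNTS: dict[str, dict[str, ConfusionCounts]] = {
    "training": {
        "fis_svm": ConfusionCounts(759, 238, 385, 65),
        "lr": ConfusionCounts(684, 360, 263, 140),
        "psa": ConfusionCounts(792, 52, 571, 32),
        "psa_density": ConfusionCounts(683, 232, 391, 141),
        "pirads": ConfusionCounts(723, 302, 321, 101),
    },
    "validation": {
        "fis_svm": ConfusionCounts(108, 17, 45, 11),
        "lr": ConfusionCounts(93, 28, 34, 26),
        "psa": ConfusionCounts(108, 4, 58, 11),
        "psa_density": ConfusionCounts(96, 19, 43, 23),
        "pirads": ConfusionCounts(98, 25, 37, 21),
    },
}

#: Univariate decision thresholds reported for the development cohort.
REFERENCE_THRESHOLDS = {"psa": 3.45, "psa_density": 0.10, "pirads": 4.0}


def reference_metrics_table() -> pd.DataFrame:
    """Derived metrics (in %) recomputed from the reference counts."""
    rows = []
    for dataset, models in REFERENCE_COUNTS.items():
        for model, counts in models.items():
            rep = metrics_from_counts(counts)
            row = {"set": dataset, "model": model,
                   "tp": counts.tp, "tn": counts.tn,
                   "fp": counts.fp, "fn": counts.fn}
            row.update(rep.as_percent())
            rows.append(row)
    return pd.DataFrame(rows)
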