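"""The two-stage cascade: fuzzy rules first, linear SVM for the remainder.

Every patient is first put through the fuzzy inference system.  Patients
matched by at least one rule receive the FIS label (with the full list of
fired rules for explanation); patients matched by no rule — *not
classified* (NC) — are labelled by a support-vector machine with a linear
kernel, Phi(x_i, x_j) = x_i . x_j, trained on the entire training cohort
over the same six variables.  The cascade therefore labels 100% of
patients while keeping rule-level explainability wherever the rules reach.

For ranking purposes (ROC, decision curves) the cascade exposes a score in
[0, 1]: the defuzzified FIS score where the rules classified the patient,
and the SVM margin squashed through a logistic function where they did not
(the cascade is not a probability model; the score is a monotone ranking
device, documented as such).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .cohort import (CATEGORICAL_VARIABLES, FIS_VARIABLES, NEGATIVE, POSITIVE,
                     Cohort, CohortError, PatientRecord)
from .fis import FisResult, RuleBase, fis_infer, rulebase_from_candidates
from .rule_induction import (BinarizationScheme, InductionConfig,
                             default_binarization_scheme, induce_rule_base)

#: fixed category order per categorical variable (one-hot blocks)
_CATEGORY_LEVELS = {
    "dre": ("negative", "positive"),
    "prior_biopsy": ("no", "yes"),
    "lesion_location": ("peripheral", "transitional_anterior"),
}


@dataclass(frozen=True)
class FeatureEncoder:
    """Frozen encoding of the six variables into a numeric vector.

    Numerics are min-max scaled with training-cohort statistics (values
    outside the training range extrapolate linearly, they are not clipped);
    categoricals are one-hot with a fixed level order.  The encoder is
    fitted once at training time and serialized with the model.
    """

    numeric_bounds: Mapping[str, tuple[float, float]]
    variables: tuple[str, ...] = FIS_VARIABLES
    scale: bool = True

    @staticmethod
    def fit(cohort: Cohort, variables: Sequence[str] = FIS_VARIABLES,
            scale: bool = True) -> "FeatureEncoder":
        bounds = {}
        for var in variables:
            if var not in CATEGORICAL_VARIABLES:
                vals = [float(r.value(var)) for r in cohort]
                bounds[var] = (min(vals), max(vals))
        return FeatureEncoder(bounds, tuple(variables), scale)

    @property
    def feature_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for var in self.variables:
            if var in CATEGORICAL_VARIABLES:
                names.extend(f"{var}={lev}" for lev in _CATEGORY_LEVELS[var])
            else:
                names.append(var)
        return tuple(names)

    def transform(self, record: PatientRecord) -> np.ndarray:
        out: list[float] = []
        for var in self.variables:
            value = record.value(var)
            if value is None:
                raise CohortError(f"patient {record.patient_id!r}: "
                                  f"missing variable {var!r}")
            if var in CATEGORICAL_VARIABLES:
                out.extend(1.0 if value == lev else 0.0
                           for lev in _CATEGORY_LEVELS[var])
            else:
                x = float(value)
                if self.scale:
                    lo, hi = self.numeric_bounds[var]
                    x = (x - lo) / (hi - lo) if hi > lo else 0.0
                out.append(x)
        return np.array(out)

    def transform_cohort(self, cohort: Cohort) -> np.ndarray:
        return np.vstack([self.transform(r) for r in cohort])


@dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0
    scale_inputs: bool = True


@dataclass(frozen=True)
class Prediction:
    """One patient's cascade verdict with its provenance."""

    patient_id: str
    label: str
    stage: str                       # "fis" | "svm"
    fis_result: FisResult
    score: float                     # ranking score in [0, 1]
    svm_margin: float | None = None  # signed distance, SVM stage only

    def __post_init__(self) -> None:
        if (self.stage == "svm") != (not self.fis_result.classified):
            raise ValueError("stage must be 'svm' exactly when the FIS "
                             "returned not-classified")


@dataclass
class CascadeModel:
    """Fitted rule base + linear separator + frozen encoder, serializable."""

    rulebase: RuleBase
    fis_threshold: float
    svm_weights: np.ndarray
    svm_bias: float
    encoder: FeatureEncoder
    metadata: dict = field(default_factory=dict)

    # -- prediction ---------------------------------------------------------

    def svm_margin(self, record: PatientRecord) -> float:
        x = self.encoder.transform(record)
        if x.shape[0] != self.svm_weights.shape[0]:
            raise CohortError("encoded vector does not match the separator "
                              "dimensionality")
        return float(self.svm_weights @ x + self.svm_bias)

    def predict_record(self, record: PatientRecord) -> Prediction:
        res = fis_infer(self.rulebase, record, self.fis_threshold)
        if res.classified:
            return Prediction(record.patient_id, res.label, "fis", res,
                              score=res.score)
        margin = self.svm_margin(record)
        # tie at the separator resolves positive: missing a cancer is the
        # costlier error in the biopsy-triage setting
        label = POSITIVE if margin >= 0.0 else NEGATIVE
        return Prediction(record.patient_id, label, "svm", res,
                          score=_squash(margin), svm_margin=margin)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "fis_threshold": self.fis_threshold,
            "rulebase": self.rulebase.to_dict(),
            "svm": {"weights": self.svm_weights.tolist(),
                    "bias": self.svm_bias},
            "encoder": {
                "numeric_bounds": {k: list(v) for k, v
                                   in self.encoder.numeric_bounds.items()},
                "variables": list(self.encoder.variables),
                "scale": self.encoder.scale,
            },
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @staticmethod
    def from_dict(data: Mapping) -> "CascadeModel":
        enc = data["encoder"]
        return CascadeModel(
            rulebase=RuleBase.from_dict(data["rulebase"]),
            fis_threshold=data["fis_threshold"],
            svm_weights=np.array(data["svm"]["weights"]),
            svm_bias=data["svm"]["bias"],
            encoder=FeatureEncoder(
                {k: tuple(v) for k, v in enc["numeric_bounds"].items()},
                tuple(enc["variables"]), enc["scale"]),
            metadata=dict(data.get("metadata", {})),
        )

    @staticmethod
    def load(path: str | Path) -> "CascadeModel":
        return CascadeModel.from_dict(json.loads(Path(path).read_text()))


def _squash(margin: float) -> float:
    """Monotone map of the SVM margin onto the defuzzified-score scale.

    Centroid defuzzification against the two default output triangles can
    only produce scores in [1/3, 2/3] (the centroids of the pure negative
    and pure positive output sets), so the fallback margin is squashed into
    the same band: margin 0 maps to the 0.5 decision point, extreme margins
    approach the scale's extremes without overshooting the rule-based
    verdicts.  This keeps the pooled ranking score on one scale across the
    two stages.
    """
    return float(1.0 / 3.0 + (1.0 / 3.0) / (1.0 + np.exp(-margin)))


def linear_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """Phi(x_i, x_j) = x_i . x_j — the kernel of the fallback separator."""
    return float(np.dot(x, y))


def encode_features(record: PatientRecord,
                    encoder: FeatureEncoder) -> np.ndarray:
    """Encode one record with a fitted encoder (module-level convenience)."""
    return encoder.transform(record)


def train_cascade(train: Cohort,
                  induction_config: InductionConfig | None = None,
                  scheme: BinarizationScheme | None = None,
                  svm_config: SVMConfig | None = None,
                  fis_threshold: float = 0.5,
                  seed: int = 0) -> CascadeModel:
    """Fit the full cascade on a labelled cohort.

    The rule base is induced from the training cohort; the SVM is fitted on
    ALL training patients (not only those the rules miss) with a linear
    kernel over the same six encoded variables.  The separator is stored as
    an explicit weight vector and bias so that a saved and reloaded model
    predicts identically.
    """
    labels = np.array(train.labels())
    if not {NEGATIVE, POSITIVE} <= set(labels):
        raise CohortError("training cohort must contain both outcome classes")
    induction_config = induction_config or InductionConfig(
        som=_seeded_som(seed))
    svm_config = svm_config or SVMConfig()
    scheme = scheme or default_binarization_scheme()

    candidates = induce_rule_base(train, induction_config, scheme)
    if not candidates:
        raise CohortError("rule induction produced no rules; lower "
                          "min_support or the predominance threshold")
    rulebase = rulebase_from_candidates(candidates, scheme=scheme)

    encoder = FeatureEncoder.fit(train, scale=svm_config.scale_inputs)
    X = encoder.transform_cohort(train)
    y = (labels == POSITIVE).astype(int)
    svc = SVC(kernel="linear", C=svm_config.C)
    svc.fit(X, y)

    model = CascadeModel(
        rulebase=rulebase,
        fis_threshold=fis_threshold,
        svm_weights=svc.coef_.ravel().copy(),
        svm_bias=float(svc.intercept_[0]),
        encoder=encoder,
        metadata={
            "n_train": len(train),
            "n_rules": len(rulebase),
            "rules_by_class": rulebase.counts_by_class(),
            "seed": seed,
            "svm_C": svm_config.C,
            "min_support": induction_config.min_support,
            "predominance_threshold":
                induction_config.predominance_threshold,
        },
    )
    return model


def _seeded_som(seed: int):
    from .rule_induction import SOMConfig
    return SOMConfig(seed=seed)


def predict(model: CascadeModel, cohort: Cohort) -> list[Prediction]:
    """Label every patient (the cascade never returns not-classified)."""
    return [model.predict_record(r) for r in cohort]


def predict_scores(model: CascadeModel, cohort: Cohort) -> np.ndarray:
    """Ranking scores in [0, 1] for ROC / decision-curve analysis."""
    return np.array([p.score for p in predict(model, cohort)])


def coverage_summary(predictions: Sequence[Prediction]) -> dict:
    """How much of the cohort the rules reached vs the SVM fallback."""
    n = len(predictions)
    n_fis = sum(1 for p in predictions if p.stage == "fis")
    return {
        "n": n,
        "n_fis": n_fis,
        "n_svm": n - n_fis,
        "fis_fraction": n_fis / n if n else float("nan"),
        "svm_fraction": (n - n_fis) / n if n else float("nan"),
    }
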