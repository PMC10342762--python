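"""Mamdani fuzzy inference over the six prebiopsy variables.

The classifier's first stage is a fuzzy inference system: crisp inputs are
fuzzified through triangular/trapezoidal membership functions (crisp 0/1
memberships for the categorical inputs), the induced IF-THEN rules fire
with min-AND activation, the per-class activations clip two triangular
output membership functions (negative peaking at 0, positive at 1,
crossing at 0.5) which are max-aggregated and defuzzified by centroid to a
score in [0, 1].  A patient matched by no rule is *not classified* (NC)
and is deferred to the support-vector stage of the cascade.

The membership-function breakpoints shipped here are modelling choices
anchored to clinical practice (PSA-density cut-offs 0.10 and 0.15 ng/mL²);
every parameter can be overridden from a YAML config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import (FIS_VARIABLES, NEGATIVE, POSITIVE, PatientRecord)


class FisError(ValueError):
    """Invalid FIS configuration or inference request."""


# ---------------------------------------------------------------------------
# Membership functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership: triangular (3 params) or trapezoidal (4).

    Parameters are non-decreasing; the degree is 0 outside [first, last],
    1 on the peak (triangular) or plateau (trapezoidal), linear between.
    """

    label: str
    shape: str                      # "triangular" | "trapezoidal"
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = {"triangular": 3, "trapezoidal": 4}.get(self.shape)
        if expected is None:
            raise FisError(f"unknown MF shape {self.shape!r}")
        if len(self.params) != expected:
            raise FisError(f"{self.shape} MF needs {expected} parameters, "
                           f"got {len(self.params)}")
        if any(b < a for a, b in zip(self.params, self.params[1:])):
            raise FisError(f"MF parameters must be non-decreasing: "
                           f"{self.params}")

    def degree(self, x: float) -> float:
        if not np.isfinite(x):
            raise FisError(f"non-finite input {x!r} to membership function")
        if self.shape == "triangular":
            a, b, c = self.params
            d, e = b, b
        else:
            a, d, e, c = self.params
        if x < a or x > c:
            return 0.0
        if d <= x <= e:
            return 1.0
        if x < d:
            return (x - a) / (d - a) if d > a else 1.0
        return (c - x) / (c - e) if c > e else 1.0


@dataclass(frozen=True)
class CrispTerm:
    """Categorical term: membership 1 iff the value equals the category."""

    label: str

    def degree(self, value) -> float:
        return 1.0 if str(value) == self.label else 0.0


@dataclass(frozen=True)
class FuzzyVariable:
    """One input variable with its ordered linguistic terms."""

    name: str
    terms: tuple[MembershipFunction | CrispTerm, ...]
    categorical: bool = False

    def term(self, label: str) -> MembershipFunction | CrispTerm:
        for t in self.terms:
            if t.label == label:
                return t
        raise FisError(f"variable {self.name!r} has no term {label!r}")


def default_fis_variables() -> dict[str, FuzzyVariable]:
    """Default fuzzification of the six inputs.

    PSA-density terms low/medium/high overlap linearly and cross at 0.10
    and 0.15 ng/mL² (degree 0.5 at the clinical cut-offs); lesion counts
    1/2/3+ are triangles on the integer axis; PI-RADS scores and the three
    binary variables are crisp categories.
    """
    return {
        "psa_density": FuzzyVariable("psa_density", (
            MembershipFunction("low", "trapezoidal", (-0.1, 0.0, 0.08, 0.12)),
            MembershipFunction("medium", "trapezoidal",
                               (0.08, 0.12, 0.13, 0.17)),
            MembershipFunction("high", "trapezoidal", (0.13, 0.17, 10.0, 10.0)),
        )),
        "n_lesions": FuzzyVariable("n_lesions", (
            MembershipFunction("1", "triangular", (0.0, 1.0, 2.0)),
            MembershipFunction("2", "triangular", (1.0, 2.0, 3.0)),
            MembershipFunction("3+", "trapezoidal", (2.0, 3.0, 50.0, 50.0)),
        )),
        "pirads": FuzzyVariable("pirads",
                                (CrispTerm("3"), CrispTerm("4"), CrispTerm("5")),
                                categorical=True),
        "dre": FuzzyVariable("dre", (CrispTerm("negative"),
                                     CrispTerm("positive")),
                             categorical=True),
        "prior_biopsy": FuzzyVariable("prior_biopsy",
                                      (CrispTerm("no"), CrispTerm("yes")),
                                      categorical=True),
        "lesion_location": FuzzyVariable(
            "lesion_location",
            (CrispTerm("peripheral"), CrispTerm("transitional_anterior")),
            categorical=True),
    }


def membership_degree(mf: MembershipFunction | CrispTerm, x) -> float:
    """Degree of membership of ``x`` in the term, in [0, 1]."""
    return mf.degree(x)


# ---------------------------------------------------------------------------
# Rules and the rule base
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzyRule:
    """IF (var IS term) AND ... THEN class, with induction provenance."""

    antecedent: tuple[tuple[str, str], ...]   # ((variable, term label), ...)
    consequent: str
    n_match_pos: int = 0
    n_match_neg: int = 0
    predominance: float = 0.0
    provenance: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        variables = [v for v, _ in self.antecedent]
        if len(set(variables)) != len(variables):
            raise FisError("a rule may use each variable at most once")
        if self.consequent not in (NEGATIVE, POSITIVE):
            raise FisError(f"consequent must be a class, got "
                           f"{self.consequent!r}")

    def activation(self, record: PatientRecord,
                   variables: Mapping[str, FuzzyVariable]) -> float:
        """min over the antecedent terms' membership degrees."""
        deg = 1.0
        for var, term_label in self.antecedent:
            fv = variables[var]
            value = record.value(var)
            deg = min(deg, fv.term(term_label).degree(value))
            if deg == 0.0:
                return 0.0
        return deg

    def text(self) -> str:
        conds = " AND ".join(f"{v} IS {t}" for v, t in self.antecedent)
        return f"IF {conds} THEN {self.consequent}"


#: output membership functions: class score axis in [0, 1]
DEFAULT_OUTPUT_MFS = {
    NEGATIVE: MembershipFunction(NEGATIVE, "triangular", (0.0, 0.0, 1.0)),
    POSITIVE: MembershipFunction(POSITIVE, "triangular", (0.0, 1.0, 1.0)),
}


@dataclass
class RuleBase:
    """The induced rules plus the fuzzification they are expressed in."""

    rules: list[FuzzyRule]
    variables: dict[str, FuzzyVariable] = field(
        default_factory=default_fis_variables)
    output_mfs: dict[str, MembershipFunction] = field(
        default_factory=lambda: dict(DEFAULT_OUTPUT_MFS))

    def __len__(self) -> int:
        return len(self.rules)

    def counts_by_class(self) -> dict[str, int]:
        out = {NEGATIVE: 0, POSITIVE: 0}
        for r in self.rules:
            out[r.consequent] += 1
        return out

    # -- JSON serialization (the explainability contract) -------------------

    def to_dict(self) -> dict:
        def mf_dict(t):
            if isinstance(t, CrispTerm):
                return {"label": t.label, "shape": "crisp"}
            return {"label": t.label, "shape": t.shape,
                    "params": list(t.params)}

        return {
            "format_version": 1,
            "rules": [{
                "antecedent": [list(pair) for pair in r.antecedent],
                "consequent": r.consequent,
                "n_match_pos": r.n_match_pos,
                "n_match_neg": r.n_match_neg,
                "predominance": r.predominance,
                "provenance": list(r.provenance) if r.provenance else None,
            } for r in self.rules],
            "variables": {
                name: {"categorical": fv.categorical,
                       "terms": [mf_dict(t) for t in fv.terms]}
                for name, fv in self.variables.items()
            },
            "output_mfs": {cls: mf_dict(mf)
                           for cls, mf in self.output_mfs.items()},
        }

    @staticmethod
    def from_dict(data: Mapping) -> "RuleBase":
        def mf_from(d):
            if d["shape"] == "crisp":
                return CrispTerm(d["label"])
            return MembershipFunction(d["label"], d["shape"],
                                      tuple(d["params"]))

        variables = {
            name: FuzzyVariable(name,
                                tuple(mf_from(t) for t in v["terms"]),
                                v["categorical"])
            for name, v in data["variables"].items()
        }
        rules = [FuzzyRule(
            antecedent=tuple((v, t) for v, t in r["antecedent"]),
            consequent=r["consequent"],
            n_match_pos=r["n_match_pos"], n_match_neg=r["n_match_neg"],
            predominance=r["predominance"],
            provenance=tuple(r["provenance"]) if r["provenance"] else None,
        ) for r in data["rules"]]
        output = {cls: mf_from(d) for cls, d in data["output_mfs"].items()}
        return RuleBase(rules, variables, output)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @staticmethod
    def load(path: str | Path) -> "RuleBase":
        return RuleBase.from_dict(json.loads(Path(path).read_text()))


def rulebase_from_candidates(candidates, variables=None,
                             scheme=None) -> RuleBase:
    """Translate mined candidate rules into fuzzy rules.

    Because the binarization intervals coincide with the membership-function
    supports, an item ``var=label`` maps directly to the fuzzy term
    ``label`` of ``var``.
    """
    variables = variables or default_fis_variables()
    rules = []
    for cand in candidates:
        antecedent = []
        for item in sorted(cand.antecedent):
            var, _, label = item.partition("=")
            variables[var].term(label)      # validates the mapping
            antecedent.append((var, label))
        rules.append(FuzzyRule(tuple(antecedent), cand.consequent,
                               cand.n_match_pos, cand.n_match_neg,
                               cand.predominance, cand.provenance))
    return RuleBase(rules, variables)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

NOT_CLASSIFIED = "not_classified"
CLASSIFIED = "classified"

#: defuzzification grid resolution on the [0, 1] output axis
_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass(frozen=True)
class FisResult:
    """Outcome of one inference: a crisp score or the NC verdict."""

    status: str                               # classified | not_classified
    score: float | None
    label: str | None
    matched_rules: tuple[tuple[int, float], ...]   # (rule index, activation)

    @property
    def classified(self) -> bool:
        return self.status == CLASSIFIED


def fis_infer(rulebase: RuleBase, record: PatientRecord,
              threshold: float = 0.5) -> FisResult:
    """Mamdani inference for one patient.

    Per-rule activation is the min of its antecedent degrees; the maximum
    activation per class clips that class's output membership function; the
    two clipped sets are max-aggregated and the centroid of the result is
    the crisp score.  Label positive iff score >= threshold.  If no rule
    activates, the patient is NOT classified.
    """
    if len(rulebase) == 0:
        raise FisError("empty rule base")
    activations = [(i, r.activation(record, rulebase.variables))
                   for i, r in enumerate(rulebase.rules)]
    matched = tuple((i, a) for i, a in activations if a > 0.0)
    if not matched:
        return FisResult(NOT_CLASSIFIED, None, None, ())

    class_act = {NEGATIVE: 0.0, POSITIVE: 0.0}
    for i, a in matched:
        cls = rulebase.rules[i].consequent
        class_act[cls] = max(class_act[cls], a)

    score = defuzzify_centroid(class_act, rulebase.output_mfs)
    label = POSITIVE if score >= threshold else NEGATIVE
    return FisResult(CLASSIFIED, score, label, matched)


@lru_cache(maxsize=16)
def _mf_grid(mf: MembershipFunction) -> np.ndarray:
    return np.array([mf.degree(x) for x in _GRID])


def defuzzify_centroid(class_activations: Mapping[str, float],
                       output_mfs: Mapping[str, MembershipFunction]) -> float:
    """Centroid of the max-aggregate of the activation-clipped output MFs."""
    mu = np.zeros_like(_GRID)
    for cls, act in class_activations.items():
        if act <= 0.0:
            continue
        mu = np.maximum(mu, np.minimum(_mf_grid(output_mfs[cls]), act))
    area = np.trapezoid(mu, _GRID)
    if area <= 0.0:
        raise FisError("defuzzification of an empty fuzzy set")
    return float(np.trapezoid(mu * _GRID, _GRID) / area)


def explain(result: FisResult, rulebase: RuleBase) -> str:
    """Human-readable account of one inference, rule by rule."""
    if not result.classified:
        return "no rule matched; deferred to SVM stage"
    lines = []
    for idx, act in result.matched_rules:
        if idx < 0 or idx >= len(rulebase):
            raise FisError(f"matched rule index {idx} not in the rule base")
        lines.append(f"{rulebase.rules[idx].text()}  (activation {act:.3f})")
    lines.append(f"score {result.score:.3f} -> {result.label}")
    return "\n".join(lines)
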