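"""Patient records, cohorts, CSV I/O and synthetic-cohort generation.

A cohort is a list of prebiopsy patient records.  Each record carries the
variables available before a targeted (MRI/ultrasound fusion) prostate
biopsy — age, serum PSA, PSA density, digital rectal examination, prior
biopsy history, the mpMRI lesion description (count, location, PI-RADS
score, volumes) — plus the biopsy outcome when known.

The study population this package targets is not publicly deposited, so
:func:`generate_synthetic_cohort` emulates it: marginal distributions match
the published demographic table (mean PSA 8.4 ng/mL, 12% positive DRE,
PI-RADS 3/4/5 at roughly 28/57/16%, 56.9% positive biopsies in the
development cohort) and class-conditional shifts are applied to the
variables reported as significantly different between positive and negative
biopsies (age, PSA density via PSA and prostate volume, DRE rate, volumes,
PI-RADS distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

NEGATIVE = "negative"
POSITIVE = "positive"
UNKNOWN = "unknown"

DRE_LEVELS = (NEGATIVE, POSITIVE)
PRIOR_BIOPSY_LEVELS = ("no", "yes")
LOCATION_LEVELS = ("peripheral", "transitional_anterior")
PIRADS_LEVELS = (3, 4, 5)
LABEL_LEVELS = (NEGATIVE, POSITIVE, UNKNOWN)

#: The six prebiopsy variables driving the fuzzy classifier.
FIS_VARIABLES = (
    "psa_density",
    "dre",
    "prior_biopsy",
    "n_lesions",
    "lesion_location",
    "pirads",
)

#: Variables treated as numeric (ordinal scores included, to preserve order).
NUMERIC_VARIABLES = frozenset(
    {"age", "psa", "psa_density", "n_lesions", "pirads",
     "prostate_volume", "lesion_volume"}
)
#: Variables treated as unordered categories.
CATEGORICAL_VARIABLES = frozenset({"dre", "prior_biopsy", "lesion_location"})

# Aliases accepted (case-insensitively) when normalising categorical input.
_LOCATION_ALIASES = {
    "peripheral": "peripheral",
    "transitional_anterior": "transitional_anterior",
    "transitional/anterior": "transitional_anterior",
    "transitional": "transitional_anterior",
    "anterior": "transitional_anterior",
}
_YES_NO = {"no": "no", "yes": "yes", "0": "no", "1": "yes",
           "false": "no", "true": "yes"}
_NEG_POS = {"negative": NEGATIVE, "positive": POSITIVE,
            "neg": NEGATIVE, "pos": POSITIVE, "0": NEGATIVE, "1": POSITIVE}


class CohortError(ValueError):
    """Invalid cohort data (schema, domain or consistency violation)."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's prebiopsy variables plus the (optional) biopsy outcome.

    ``psa_density`` is PSA divided by the MRI-measured prostate volume
    (ng/mL²).  ``pirads`` is the lesion suspicion score, restricted to 3–5
    because only patients with at least one target lesion are biopsied.
    """

    patient_id: str
    age: float
    psa: float
    psa_density: float
    dre: str
    prior_biopsy: str
    n_lesions: int
    lesion_location: str
    pirads: int
    prostate_volume: float | None = None
    lesion_volume: float | None = None
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.psa < 0 or self.psa_density < 0:
            raise CohortError(
                f"patient {self.patient_id!r}: PSA and PSA density must be >= 0"
            )
        if self.n_lesions < 1:
            raise CohortError(
                f"patient {self.patient_id!r}: n_lesions must be >= 1"
            )
        if self.pirads not in PIRADS_LEVELS:
            raise CohortError(
                f"patient {self.patient_id!r}: pirads={self.pirads} "
                f"not in {PIRADS_LEVELS}"
            )
        for name, value, levels in (
            ("dre", self.dre, DRE_LEVELS),
            ("prior_biopsy", self.prior_biopsy, PRIOR_BIOPSY_LEVELS),
            ("lesion_location", self.lesion_location, LOCATION_LEVELS),
            ("label", self.label, LABEL_LEVELS),
        ):
            if value not in levels:
                raise CohortError(
                    f"patient {self.patient_id!r}: {name}={value!r} "
                    f"not in {levels}"
                )
        if self.prostate_volume is not None and self.prostate_volume > 0:
            implied = self.psa / self.prostate_volume
            # density must agree with psa/volume when both present (10% rel.)
            if self.psa > 0 and not math.isclose(
                self.psa_density, implied, rel_tol=0.10, abs_tol=0.01
            ):
                raise CohortError(
                    f"patient {self.patient_id!r}: psa_density "
                    f"{self.psa_density:.4f} inconsistent with "
                    f"psa/prostate_volume = {implied:.4f}"
                )

    def value(self, variable: str):
        """Return a named variable's value."""
        return getattr(self, variable)

    @property
    def labeled(self) -> bool:
        return self.label != UNKNOWN


@dataclass
class Cohort:
    """An ordered collection of :class:`PatientRecord` with unique ids."""

    records: list[PatientRecord]
    name: str = "cohort"

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient_id(s): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def subset(self, indices: Iterable[int], name: str | None = None) -> "Cohort":
        return Cohort([self.records[i] for i in indices], name or self.name)

    def complete_for_fis(self) -> "Cohort":
        """Records holding all six classifier variables (always true for
        validated records; hook kept for schema-mapped partial data)."""
        return self

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "patient_id": r.patient_id, "age": r.age, "psa": r.psa,
                "psa_density": r.psa_density, "dre": r.dre,
                "prior_biopsy": r.prior_biopsy, "n_lesions": r.n_lesions,
                "lesion_location": r.lesion_location, "pirads": r.pirads,
                "prostate_volume": r.prostate_volume,
                "lesion_volume": r.lesion_volume, "label": r.label,
            })
        return pd.DataFrame(
            rows,
            columns=["patient_id", "age", "psa", "psa_density", "dre",
                     "prior_biopsy", "n_lesions", "lesion_location", "pirads",
                     "prostate_volume", "lesion_volume", "label"],
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

#: canonical column order written by :func:`write_cohort_csv`
CSV_COLUMNS = ("patient_id", "age", "psa", "psa_density", "dre",
               "prior_biopsy", "n_lesions", "lesion_location", "pirads",
               "prostate_volume", "lesion_volume", "label")
_REQUIRED = ("patient_id", "age", "psa", "psa_density", "dre",
             "prior_biopsy", "n_lesions", "lesion_location", "pirads")


def _normalize_cat(raw, table: Mapping[str, str], column: str, row: int) -> str:
    key = str(raw).strip().lower()
    if key not in table:
        raise CohortError(f"row {row}: {column}={raw!r} not a recognised value")
    return table[key]


def read_cohort_csv(path: str | Path,
                    schema: Mapping[str, str] | None = None,
                    name: str | None = None) -> Cohort:
    """Read a cohort from CSV.

    Parameters
    ----------
    path : file path
    schema : optional mapping from the file's column names to the canonical
        names in :data:`CSV_COLUMNS` (e.g. ``{"PSAdens": "psa_density"}``).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise CohortError(f"{path.name}: missing required column(s) {missing}")

    records: list[PatientRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(_record_from_row(row, int(idx)))
        except (CohortError, ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise CohortError(
            f"{path.name}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors[:10])
        )
    return Cohort(records, name or path.stem)


def _record_from_row(row: pd.Series, idx: int) -> PatientRecord:
    def opt_float(col: str) -> float | None:
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
            return None
        return float(v)

    pirads_raw = float(row["pirads"])
    if not pirads_raw.is_integer():
        raise CohortError(f"pirads={row['pirads']!r} is not an integer")
    label_raw = row.get("label")
    if label_raw is None or str(label_raw).strip() == "" or \
            (isinstance(label_raw, float) and math.isnan(label_raw)):
        label = UNKNOWN
    else:
        key = str(label_raw).strip().lower()
        label = UNKNOWN if key == UNKNOWN else _NEG_POS.get(key)
        if label is None:
            raise CohortError(f"label={label_raw!r} not a recognised value")
    return PatientRecord(
        patient_id=str(row["patient_id"]).strip(),
        age=float(row["age"]),
        psa=float(row["psa"]),
        psa_density=float(row["psa_density"]),
        dre=_normalize_cat(row["dre"], _NEG_POS, "dre", idx),
        prior_biopsy=_normalize_cat(row["prior_biopsy"], _YES_NO,
                                    "prior_biopsy", idx),
        n_lesions=int(float(row["n_lesions"])),
        lesion_location=_normalize_cat(row["lesion_location"],
                                       _LOCATION_ALIASES, "lesion_location", idx),
        pirads=int(pirads_raw),
        prostate_volume=opt_float("prostate_volume"),
        lesion_volume=opt_float("lesion_volume"),
        label=label,
    )


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as UTF-8 comma-separated CSV with a header row.

    Numerics use repr-precision so that write→read round-trips losslessly.
    """
    df = cohort.to_dataframe()
    df.to_csv(Path(path), index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassEffects:
    """Multiplicative/additive shifts applied to positive-biopsy patients.

    The published cohort table reports which variables differ significantly
    between classes but not the per-class parameters, so these effect sizes
    are modelling assumptions (documented defaults, fully configurable).
    """

    psa_multiplier: float = 1.35          # positives: higher PSA (median ratio)
    volume_multiplier: float = 0.80       # positives: smaller prostates
    lesion_volume_multiplier: float = 1.30
    age_shift: float = 2.0                # years
    dre_positive_rate: tuple[float, float] = (0.07, 0.16)   # (neg, pos) classes
    prior_biopsy_rate: tuple[float, float] = (0.36, 0.25)
    pirads_probs: tuple[tuple[float, float, float],
                        tuple[float, float, float]] = (
        (0.44, 0.52, 0.04),   # negative biopsies: mostly PI-RADS 3-4
        (0.16, 0.58, 0.26),   # positive biopsies: shifted to 4-5
    )
    n_lesion_probs: tuple[tuple[float, float, float],
                          tuple[float, float, float]] = (
        (0.72, 0.21, 0.07), (0.68, 0.23, 0.09)
    )
    peripheral_rate: tuple[float, float] = (0.855, 0.855)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic study population.

    Defaults mirror the development cohort's demographics: n = 1448,
    prevalence 56.9%, PSA mean 8.4 / SD 7.5 ng/mL (lognormal — the SD is of
    the order of the mean, a normal would generate negative PSA), prostate
    volume mean 55.8 / SD 27.8 cc, lesion volume mean 0.98 / SD 1.91 cc,
    age mean 69 / SD 8 years.  PSA density is derived as psa / volume.
    """

    n: int = 1448
    prevalence: float = 0.569
    seed: int = 0
    psa_mean: float = 8.4
    psa_sd: float = 7.5
    volume_mean: float = 55.8
    volume_sd: float = 27.8
    lesion_volume_mean: float = 0.98
    lesion_volume_sd: float = 1.91
    age_mean: float = 69.0
    age_sd: float = 8.0
    effects: ClassEffects = field(default_factory=ClassEffects)
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise CohortError(f"prevalence {self.prevalence} outside [0, 1]")
        if self.n < 0:
            raise CohortError("n must be non-negative")
        for probs in self.effects.pirads_probs + self.effects.n_lesion_probs:
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise CohortError(f"category probabilities {probs} must sum to 1")

    @staticmethod
    def strong_signal(n: int = 2000, seed: int = 0) -> "CohortSpec":
        """A preset with large class separation on every informative
        variable — used for discrimination sanity checks where the
        classifier is expected to approach perfect ranking."""
        return CohortSpec(
            n=n, seed=seed, name="synthetic-strong",
            effects=ClassEffects(
                psa_multiplier=2.6,
                volume_multiplier=0.55,
                lesion_volume_multiplier=2.0,
                age_shift=6.0,
                dre_positive_rate=(0.04, 0.45),
                prior_biopsy_rate=(0.45, 0.15),
                pirads_probs=((0.70, 0.28, 0.02), (0.03, 0.37, 0.60)),
                n_lesion_probs=((0.85, 0.12, 0.03), (0.45, 0.35, 0.20)),
                peripheral_rate=(0.75, 0.93),
            ),
        )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_synthetic_cohort(spec: CohortSpec) -> Cohort:
    """Draw a synthetic cohort; identical spec (incl. seed) → identical cohort.

    Labels are i.i.d. Bernoulli(prevalence).  Numeric variables are drawn
    lognormally (PSA, volumes) or normally (age) with class-conditional
    shifts from ``spec.effects``; PSA density is psa / prostate_volume so
    that the record-level consistency invariant holds by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    pos = rng.random(n) < spec.prevalence

    mu_p, sig_p = _lognormal_params(spec.psa_mean, spec.psa_sd)
    mu_v, sig_v = _lognormal_params(spec.volume_mean, spec.volume_sd)
    mu_l, sig_l = _lognormal_params(spec.lesion_volume_mean, spec.lesion_volume_sd)
    eff = spec.effects

    # class multipliers are applied to positives and the whole sample is
    # renormalised so the MARGINAL mean stays at the spec's value
    def shifted_lognormal(mu, sigma, multiplier):
        x = rng.lognormal(mu, sigma, n)
        x[pos] *= multiplier
        return x / (1.0 - spec.prevalence + spec.prevalence * multiplier)

    psa = shifted_lognormal(mu_p, sig_p, eff.psa_multiplier)
    volume = shifted_lognormal(mu_v, sig_v, eff.volume_multiplier)
    lesion_vol = shifted_lognormal(mu_l, sig_l, eff.lesion_volume_multiplier)
    age = rng.normal(spec.age_mean - spec.prevalence * eff.age_shift,
                     spec.age_sd, n)
    age[pos] += eff.age_shift
    age = np.clip(age, 40.0, 95.0)

    cls = pos.astype(int)
    dre_rate = np.asarray(eff.dre_positive_rate)[cls]
    dre = rng.random(n) < dre_rate
    prior_rate = np.asarray(eff.prior_biopsy_rate)[cls]
    prior = rng.random(n) < prior_rate
    peri_rate = np.asarray(eff.peripheral_rate)[cls]
    peripheral = rng.random(n) < peri_rate

    pirads_p = np.asarray(eff.pirads_probs)[cls]            # (n, 3)
    u = rng.random(n)
    pirads = 3 + (u[:, None] >= np.cumsum(pirads_p, axis=1)).sum(axis=1)
    lesion_p = np.asarray(eff.n_lesion_probs)[cls]
    u2 = rng.random(n)
    n_lesions = 1 + (u2[:, None] >= np.cumsum(lesion_p, axis=1)).sum(axis=1)

    records = []
    width = len(str(max(n, 1)))
    for i in range(n):
        records.append(PatientRecord(
            patient_id=f"S{i:0{width}d}",
            age=round(float(age[i]), 1),
            psa=round(float(psa[i]), 3),
            psa_density=round(float(psa[i] / volume[i]), 4),
            dre=POSITIVE if dre[i] else NEGATIVE,
            prior_biopsy="yes" if prior[i] else "no",
            n_lesions=int(n_lesions[i]),
            lesion_location="peripheral" if peripheral[i]
                            else "transitional_anterior",
            pirads=int(pirads[i]),
            prostate_volume=round(float(volume[i]), 1),
            lesion_volume=round(float(lesion_vol[i]), 3),
            label=POSITIVE if pos[i] else NEGATIVE,
        ))
    return Cohort(records, spec.name)


def generate_logistic_cohort(
    n: int,
    coefficients: Mapping[str, float],
    intercept: float,
    seed: int,
    base: CohortSpec | None = None,
) -> Cohort:
    """Cohort whose labels follow a known logistic model on the raw variables.

    Features are drawn from the marginals of ``base`` (default study-like
    spec) with NO class conditioning; the label is then Bernoulli of the
    inverse-logit of ``intercept + Σ coef·x`` where binary categoricals enter
    as 0/1 indicators (dre=positive, prior_biopsy=yes,
    lesion_location=transitional_anterior).  Used to check that a logistic
    regression fitted downstream recovers the generating coefficients.
    """
    base = base or CohortSpec()
    null = replace(base, n=n, seed=seed, prevalence=0.5,
                   effects=ClassEffects(
                       psa_multiplier=1.0, volume_multiplier=1.0,
                       lesion_volume_multiplier=1.0, age_shift=0.0,
                       dre_positive_rate=(0.12, 0.12),
                       prior_biopsy_rate=(0.30, 0.30),
                       pirads_probs=((0.279, 0.566, 0.155),) * 2,
                       n_lesion_probs=((0.70, 0.22, 0.08),) * 2,
                       peripheral_rate=(0.855, 0.855)))
    features = generate_synthetic_cohort(null)
    rng = np.random.default_rng(seed + 1)
    records = []
    for rec in features:
        eta = intercept
        for var, beta in coefficients.items():
            v = rec.value(var)
            if var == "dre":
                v = 1.0 if v == POSITIVE else 0.0
            elif var == "prior_biopsy":
                v = 1.0 if v == "yes" else 0.0
            elif var == "lesion_location":
                v = 1.0 if v == "transitional_anterior" else 0.0
            eta += beta * float(v)
        p = 1.0 / (1.0 + math.exp(-eta))
        records.append(replace(rec, label=POSITIVE if rng.random() < p
                               else NEGATIVE))
    return Cohort(records, "synthetic-logistic")
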