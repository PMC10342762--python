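"""Shared fixtures: synthetic cohorts and a trained cascade.

Everything is generated programmatically with fixed seeds; heavier
artifacts (the strong-signal cascade) are session-scoped so the suite
trains them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import fuzzybiopsy as fb
from fuzzybiopsy.cohort import NEGATIVE, POSITIVE, Cohort, PatientRecord


@pytest.fixture(scope="session")
def study_cohort() -> Cohort:
    """Study-like synthetic cohort, moderate size for unit tests."""
    return fb.generate_synthetic_cohort(
        fb.CohortSpec(n=600, prevalence=0.569, seed=11))


@pytest.fixture(scope="session")
def strong_cohort() -> Cohort:
    """Large-separation cohort used for discrimination sanity checks."""
    return fb.generate_synthetic_cohort(fb.CohortSpec.strong_signal(2000, 2))


@pytest.fixture(scope="session")
def strong_model(strong_cohort):
    return fb.train_cascade(strong_cohort, seed=2)


def make_separable_cohort(n_per_class: int = 100,
                          seed: int = 7) -> Cohort:
    """PSA density and PI-RADS jointly determine the label exactly.

    Positives: density in the high band with PI-RADS 5; negatives: density
    in the low band with PI-RADS 3.  All remaining variables are constant,
    so any rule touching a determining item matches a single class only.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(2 * n_per_class):
        positive = i < n_per_class
        dens = (rng.uniform(0.16, 0.30) if positive
                else rng.uniform(0.02, 0.08))
        volume = 50.0
        records.append(PatientRecord(
            patient_id=f"P{i:04d}",
            age=68.0,
            psa=round(dens * volume, 4),
            psa_density=round(dens, 4),
            dre=NEGATIVE,
            prior_biopsy="no",
            n_lesions=1,
            lesion_location="peripheral",
            pirads=5 if positive else 3,
            prostate_volume=volume,
            label=POSITIVE if positive else NEGATIVE,
        ))
    return Cohort(records, "separable")


@pytest.fixture(scope="session")
def separable_cohort() -> Cohort:
    return make_separable_cohort()
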