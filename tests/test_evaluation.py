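"""Confusion metrics, ROC/AUC, decision curves and the comparator models."""

from __future__ import annotations

import numpy as np
import pytest

import fuzzybiopsy as fb
from fuzzybiopsy.cohort import (NEGATIVE, POSITIVE, CohortSpec,
                                generate_synthetic_cohort, ClassEffects)
from fuzzybiopsy.evaluation import (ConfusionCounts, EvaluationError,
                                    confusion_counts, decision_curve,
                                    fit_lr_baseline, metrics_from_counts,
                                    percent, roc_curve, univariate_baseline)


class TestConfusion:
    def test_all_correct_no_errors(self):
        truth = [POSITIVE, NEGATIVE, POSITIVE]
        c = confusion_counts(truth, truth)
        assert (c.fp, c.fn) == (0, 0) and c.total == 3

    def test_brute_force_tally(self):
        rng = np.random.default_rng(0)
        pred = rng.choice([NEGATIVE, POSITIVE], 100)
        truth = rng.choice([NEGATIVE, POSITIVE], 100)
        c = confusion_counts(list(pred), list(truth))
        tp = sum(p == POSITIVE and t == POSITIVE
                 for p, t in zip(pred, truth))
        tn = sum(p == NEGATIVE and t == NEGATIVE
                 for p, t in zip(pred, truth))
        fp = sum(p == POSITIVE and t == NEGATIVE
                 for p, t in zip(pred, truth))
        fn = sum(p == NEGATIVE and t == POSITIVE
                 for p, t in zip(pred, truth))
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            confusion_counts([POSITIVE], [POSITIVE, NEGATIVE])

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ConfusionCounts(-1, 0, 0, 0)


class TestMetrics:
    def test_cascade_development_npv(self):
        rep = metrics_from_counts(ConfusionCounts(759, 238, 385, 65))
        assert rep.as_percent()["npv"] == 78.5

    def test_cascade_validation_metrics(self):
        rep = metrics_from_counts(ConfusionCounts(108, 17, 45, 11))
        pct = rep.as_percent()
        assert pct["sensitivity"] == 90.8
        assert pct["accuracy"] == 69.1
        assert pct["npv"] == 60.7

    def test_perfect_classifier_all_hundred(self):
        pct = metrics_from_counts(ConfusionCounts(10, 5, 0, 0)).as_percent()
        assert all(v == 100.0 for v in pct.values())

    def test_zero_denominator_is_undefined_not_zero(self):
        rep = metrics_from_counts(ConfusionCounts(0, 5, 0, 0))
        assert rep.ppv is None
        assert rep.as_percent()["ppv"] is None

    def test_percent_rounds_half_up(self):
        assert percent(0.785) == 78.5
        assert percent(0.66345) == 66.3
        assert percent(0.0645) == 6.5      # 6.45 rounds up, not to even


class TestRoc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        truth = [POSITIVE, POSITIVE, NEGATIVE, NEGATIVE]
        roc = roc_curve(scores, truth)
        assert roc.auc == pytest.approx(1.0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        truth = list(rng.choice([NEGATIVE, POSITIVE], 2000))
        roc = roc_curve(rng.random(2000), truth)
        assert 0.45 <= roc.auc <= 0.55

    def test_auc_equals_mann_whitney_form(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        truth = [POSITIVE if rng.random() < 0.4 else NEGATIVE
                 for _ in range(50)]
        pos = scores[[t == POSITIVE for t in truth]]
        neg = scores[[t == NEGATIVE for t in truth]]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = u / (len(pos) * len(neg))
        assert roc_curve(scores, truth).auc == pytest.approx(expected)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        truth = [POSITIVE if s + rng.normal(0, 0.3) > 0.5 else NEGATIVE
                 for s in scores]
        if len(set(truth)) < 2:
            pytest.skip("degenerate draw")
        a = roc_curve(scores, truth).auc
        b = roc_curve(np.exp(5 * scores), truth).auc
        assert a == pytest.approx(b)

    def test_youden_threshold_respects_geq_convention(self):
        scores = [0.9, 0.7, 0.6, 0.3, 0.2]
        truth = [POSITIVE, POSITIVE, POSITIVE, NEGATIVE, NEGATIVE]
        roc = roc_curve(scores, truth)
        pred = [POSITIVE if s >= roc.optimal_threshold else NEGATIVE
                for s in scores]
        assert pred == truth

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_curve([0.1, 0.2], [POSITIVE, POSITIVE])


class TestDecisionCurve:
    def test_treat_none_identically_zero(self):
        truth = [POSITIVE, NEGATIVE] * 10
        dca = decision_curve(truth, scores=np.linspace(0, 1, 20))
        assert np.all(dca.treat_none == 0.0)

    def test_net_benefit_at_half_is_tp_minus_fp_over_n(self):
        truth = [POSITIVE] * 6 + [NEGATIVE] * 4
        labels = [POSITIVE] * 5 + [NEGATIVE] + [POSITIVE] * 2 + \
            [NEGATIVE] * 2
        dca = decision_curve(truth, labels=labels, threshold_grid=[0.5])
        tp, fp = 5, 2
        assert dca.net_benefit[0] == pytest.approx((tp - fp) / 10)

    def test_treat_all_approaches_prevalence(self):
        truth = [POSITIVE] * 3 + [NEGATIVE] * 7
        dca = decision_curve(truth, labels=[POSITIVE] * 10,
                             threshold_grid=[0.001])
        assert dca.treat_all[0] == pytest.approx(0.3, abs=0.01)

    def test_grid_bounds_enforced(self):
        with pytest.raises(EvaluationError):
            decision_curve([POSITIVE, NEGATIVE], labels=[POSITIVE, NEGATIVE],
                           threshold_grid=[1.0])

    def test_model_never_beats_perfect(self):
        rng = np.random.default_rng(4)
        truth = list(rng.choice([NEGATIVE, POSITIVE], 300))
        scores = rng.random(300)
        dca = decision_curve(truth, scores=scores)
        perfect = decision_curve(
            truth, scores=np.array([1.0 if t == POSITIVE else 0.0
                                    for t in truth]))
        assert np.all(dca.net_benefit <= perfect.net_benefit + 1e-12)


class TestBaselines:
    def test_univariate_geq_convention(self, study_cohort):
        import dataclasses
        r = dataclasses.replace(study_cohort[0], psa=3.45,
                                prostate_volume=None, psa_density=0.10)
        from fuzzybiopsy.cohort import Cohort
        c = Cohort([r])
        assert univariate_baseline(c, "psa", 3.45) == [POSITIVE]
        assert univariate_baseline(c, "psa_density", 0.10) == [POSITIVE]
        low = Cohort([dataclasses.replace(r, pirads=3)])
        assert univariate_baseline(low, "pirads", 4.0) == [NEGATIVE]

    def test_unknown_variable_rejected(self, study_cohort):
        with pytest.raises(EvaluationError):
            univariate_baseline(study_cohort, "age", 70)

    def test_lr_null_signal_auc_near_half(self):
        flat = ClassEffects(
            psa_multiplier=1.0, volume_multiplier=1.0,
            lesion_volume_multiplier=1.0, age_shift=0.0,
            dre_positive_rate=(0.12, 0.12), prior_biopsy_rate=(0.3, 0.3),
            pirads_probs=((0.28, 0.56, 0.16),) * 2,
            n_lesion_probs=((0.7, 0.22, 0.08),) * 2,
            peripheral_rate=(0.855, 0.855))
        cohort = generate_synthetic_cohort(
            CohortSpec(n=2000, seed=31, effects=flat))
        lr = fit_lr_baseline(cohort)
        roc = roc_curve(lr.predict_proba(cohort), cohort.labels())
        assert 0.45 <= roc.auc <= 0.58   # small optimism from refitting

    def test_lr_threshold_set_from_training_roc(self, study_cohort):
        lr = fit_lr_baseline(study_cohort)
        assert lr.threshold is not None
        labels = lr.predict_labels(study_cohort)
        assert set(labels) <= {NEGATIVE, POSITIVE}
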