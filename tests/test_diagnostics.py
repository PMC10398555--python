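"""Confusion-matrix reconstruction, accuracy metrics, kappa, ROC, Wald CIs."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eceq.diagnostics import (
    ConfusionMatrix,
    agreement_kappa,
    confusion_from_labels,
    diagnostic_report,
    format_report,
    kappa_from_confusion,
    reconstruct_confusion,
    report_frame,
    roc_and_optimal_cutoff,
    wald_or_ci,
)


class TestConfusionFromLabels:
    def test_perfect_agreement_has_no_errors(self):
        pred = [True, False, True, False, True]
        cm = confusion_from_labels(pred, pred)
        assert cm.fp == 0 and cm.fn == 0
        assert cm.total == 5

    def test_all_positive_predictions(self):
        cm = confusion_from_labels([True] * 4, [True, True, False, False])
        assert cm.as_dict() == {"tp": 2, "fp": 2, "fn": 0, "tn": 0}

    def test_matches_reconstructed_validation_counts(self):
        # 195 labels arranged to match the reconstructed six-month-rule table
        ref = [True] * 148 + [False] * 47
        pred = [True] * 120 + [False] * 28 + [True] * 4 + [False] * 43
        cm = confusion_from_labels(pred, ref)
        assert cm.as_dict() == {"tp": 120, "fp": 4, "fn": 28, "tn": 43}

    @pytest.mark.parametrize(
        "pred, ref", [([], []), ([True], [True, False]), ([True, False], [True])]
    )
    def test_empty_or_mismatched_inputs_rejected(self, pred, ref):
        with pytest.raises(ValueError):
            confusion_from_labels(pred, ref)


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "se, sp, expected",
        [
            # the published six-month rule: 28 false negatives
            (0.811, 0.915, (120, 4, 28, 43)),
            # the extended rule: 12 fewer false negatives, no new false positives
            (0.892, 0.915, (132, 4, 16, 43)),
        ],
    )
    def test_validation_cohort_tables(self, se, sp, expected):
        cm = reconstruct_confusion(195, 148, se, sp)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == expected

    def test_perfect_test(self):
        cm = reconstruct_confusion(100, 30, 1.0, 1.0)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (30, 0, 0, 70)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(100, 100, 0.8, 0.9)
        with pytest.raises(ValueError):
            reconstruct_confusion(100, 0, 0.8, 0.9)
        with pytest.raises(ValueError):
            reconstruct_confusion(100, 50, 1.2, 0.9)

    @given(
        n_diseased=st.integers(5, 500),
        n_healthy=st.integers(5, 500),
        se=st.floats(0.05, 0.95),
        sp=st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_recovers_inputs_within_half_a_count(
        self, n_diseased, n_healthy, se, sp
    ):
        n = n_diseased + n_healthy
        cm = reconstruct_confusion(n, n_diseased, se, sp)
        report = diagnostic_report(cm)
        assert abs(report.sensitivity - se) <= 0.5 / n_diseased + 1e-9
        assert abs(report.specificity - sp) <= 0.5 / n_healthy + 1e-9


class TestDiagnosticReport:
    def test_six_month_rule_predictive_values(self):
        report = diagnostic_report(ConfusionMatrix(120, 4, 28, 43))
        assert 100 * report.ppv == pytest.approx(96.8, abs=0.05)
        assert 100 * report.npv == pytest.approx(60.6, abs=0.05)

    def test_extended_rule_kappa(self):
        report = diagnostic_report(ConfusionMatrix(132, 4, 16, 43))
        assert report.kappa == pytest.approx(0.74, abs=0.005)

    def test_perfect_classification(self):
        report = diagnostic_report(ConfusionMatrix(7, 0, 0, 13))
        for value in (
            report.sensitivity,
            report.specificity,
            report.ppv,
            report.npv,
            report.kappa,
            report.auc,
        ):
            assert value == 1.0
        assert report.undefined == ()

    def test_degenerate_margin_signalled_not_silent(self):
        # reference all positive: no healthy subjects, Sp and AUC undefined
        report = diagnostic_report(ConfusionMatrix(5, 0, 3, 0))
        assert math.isnan(report.specificity)
        assert "specificity" in report.undefined
        assert "auc" in report.undefined
        assert report.npv == 0.0  # still defined: 0/3 negatives are healthy

    def test_predictive_values_obey_bayes_rule_exactly(self):
        cm = ConfusionMatrix(120, 4, 28, 43)
        r = diagnostic_report(cm)
        prev = cm.n_diseased / cm.total
        ppv = r.sensitivity * prev / (
            r.sensitivity * prev + (1 - r.specificity) * (1 - prev)
        )
        npv = r.specificity * (1 - prev) / (
            r.specificity * (1 - prev) + (1 - r.sensitivity) * prev
        )
        assert r.ppv == pytest.approx(ppv, rel=1e-12)
        assert r.npv == pytest.approx(npv, rel=1e-12)

    def test_binary_rule_auc_is_mean_of_se_and_sp(self):
        r = diagnostic_report(ConfusionMatrix(120, 4, 28, 43))
        assert r.auc == pytest.approx((r.sensitivity + r.specificity) / 2)


class TestAgreementKappa:
    def test_identical_predictions(self):
        pred = np.array([True, False, True, True, False])
        assert agreement_kappa(pred, pred) == 1.0

    def test_nested_rules_on_validation_cohort(self):
        """Two rules calling 136 and 139 of 195 positive, the smaller set
        nested in the larger, agree at kappa 0.963."""
        a = np.zeros(195, dtype=bool)
        b = np.zeros(195, dtype=bool)
        a[:136] = True
        b[:139] = True
        assert agreement_kappa(a, b) == pytest.approx(0.963, abs=0.0005)

    def test_chance_level_agreement_is_zero(self):
        # statistically independent raters at 50/50 margins
        a = np.array([True] * 50 + [False] * 50)
        b = np.array(([True] * 25 + [False] * 25) * 2)
        assert agreement_kappa(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(42)
        a = rng.random(200) < 0.4
        b = rng.random(200) < 0.6
        k = agreement_kappa(a, b)
        assert agreement_kappa(b, a) == pytest.approx(k)
        assert agreement_kappa(~a, ~b) == pytest.approx(k)

    def test_matches_scikit_learn_implementation(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.random(150) < rng.uniform(0.2, 0.8)
            b = rng.random(150) < rng.uniform(0.2, 0.8)
            if a.all() or not a.any() or b.all() or not b.any():
                continue
            assert agreement_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement_kappa([True, False], [True])


class TestROC:
    def test_perfectly_separated_scores(self):
        scores = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        ref = [False, False, False, True, True, True]
        result = roc_and_optimal_cutoff(scores, ref)
        assert result.auc == pytest.approx(1.0)
        assert 0.3 < result.cutoff < 0.7
        assert result.youden == pytest.approx(1.0)

    def test_uninformative_constant_score(self):
        result = roc_and_optimal_cutoff([0.5] * 10, [True] * 5 + [False] * 5)
        assert result.auc == pytest.approx(0.5)
        assert result.youden == pytest.approx(0.0)

    def test_toy_overlap_against_exhaustive_enumeration(self):
        """Six scores with one overlapping pair; the oracle enumerates every
        possible strict cutoff by brute force."""
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.6, 0.9])
        ref = np.array([False, False, True, True, False, True])

        best_j, best_c = -1.0, None
        for c in np.concatenate([[scores.min() - 1], np.unique(scores)]):
            called = scores > c
            se = (called & ref).sum() / ref.sum()
            sp = (~called & ~ref).sum() / (~ref).sum()
            if se + sp - 1 > best_j + 1e-12:
                best_j, best_c = se + sp - 1, c

        result = roc_and_optimal_cutoff(scores, ref)
        assert result.youden == pytest.approx(best_j)
        # same classification as the oracle's best threshold
        assert np.array_equal(scores > result.cutoff, scores > best_c)
        # trapezoid AUC equals the Mann-Whitney probability for this set
        from sklearn.metrics import roc_auc_score

        assert result.auc == pytest.approx(roc_auc_score(ref, scores))

    def test_binary_prediction_auc_equals_mean_of_se_and_sp(self):
        rng = np.random.default_rng(11)
        ref = rng.random(300) < 0.6
        pred = ref ^ (rng.random(300) < 0.2)  # noisy copy
        result = roc_and_optimal_cutoff(pred.astype(float), ref)
        report = diagnostic_report(confusion_from_labels(pred, ref))
        assert result.auc == pytest.approx(report.auc)

    def test_single_class_reference_rejected(self):
        with pytest.raises(ValueError):
            roc_and_optimal_cutoff([0.1, 0.2], [True, True])


class TestWaldOddsRatio:
    @pytest.mark.parametrize(
        "beta, se, expected_or",
        [(1.484, 0.61, 4.41), (2.749, 0.54, 15.63), (2.415, 0.71, 11.19)],
    )
    def test_point_estimates(self, beta, se, expected_or):
        or_, _, _ = wald_or_ci(beta, se)
        assert or_ == pytest.approx(expected_or, abs=0.005)

    def test_family_history_confidence_interval(self):
        or_, lo, hi = wald_or_ci(1.484, 0.61, 0.95)
        assert lo == pytest.approx(1.33, abs=0.01)
        assert hi == pytest.approx(14.6, rel=0.01)

    def test_null_effect_is_symmetric_on_log_scale(self):
        or_, lo, hi = wald_or_ci(0.0, 0.5)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_or_ci(1.0, 0.0)


class TestKappaFromConfusion:
    def test_total_concentration_on_one_cell_gives_one(self):
        assert kappa_from_confusion(ConfusionMatrix(10, 0, 0, 0)) == 1.0

    @given(
        tp=st.integers(0, 50),
        fp=st.integers(0, 50),
        fn=st.integers(0, 50),
        tn=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_by_one(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        k = kappa_from_confusion(ConfusionMatrix(tp, fp, fn, tn))
        assert k <= 1.0 + 1e-12


def test_report_frame_uses_printed_precision_and_column_order():
    reports = {"rule2": diagnostic_report(ConfusionMatrix(120, 4, 28, 43))}
    frame = report_frame(reports)
    assert list(frame.columns) == [
        "rule",
        "sensitivity_pct",
        "specificity_pct",
        "ppv_pct",
        "npv_pct",
        "kappa",
        "auc",
    ]
    row = frame.iloc[0]
    assert row["sensitivity_pct"] == 81.1
    assert row["specificity_pct"] == 91.5
    assert row["ppv_pct"] == 96.8
    assert row["npv_pct"] == 60.6
    assert row["kappa"] == 0.62
    assert row["auc"] == 0.86


def test_format_report_renders_undefined_metrics_as_none():
    formatted = format_report(diagnostic_report(ConfusionMatrix(5, 0, 3, 0)))
    assert formatted["specificity_pct"] is None
    assert formatted["auc"] is None
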