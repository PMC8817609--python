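import itertools
import math

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from ctifr.diagnostics import (ConfusionCounts, auc_empirical, bland_altman,
                               confusion_from_pairs, decision_curve,
                               delong_compare, diagnostic_metrics,
                               fisher_z_compare, net_benefit_from_counts,
                               round_half_up_percent, steiger_z_dependent,
                               evaluate_pairs)
from ctifr.errors import InvalidParameterError


class TestConfusion:
    def test_perfect_agreement_has_no_errors(self):
        v = np.array([0.7, 0.85, 0.92, 0.95])
        c = confusion_from_pairs(v, v, 0.89, 0.89)
        assert (c.fp, c.fn) == (0, 0)
        assert c.tp + c.tn == 4

    def test_worked_pairs(self):
        c = confusion_from_pairs([0.88, 0.95], [0.86, 0.93], 0.89, 0.89)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_boundary_value_is_positive(self):
        c = confusion_from_pairs([0.89], [0.90], 0.89, 0.89)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 1, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            confusion_from_pairs([0.9], [0.9, 0.8])


class TestDiagnosticMetrics:
    @pytest.mark.parametrize("counts,expected", [
        # (TP, FP, FN, TN) -> sens, spec, PPV, NPV, accuracy in percent
        ((11, 4, 4, 17), (73, 81, 73, 81, 78)),
        ((11, 3, 4, 18), (73, 86, 79, 82, 81)),
        ((1, 0, 0, 1), (100, 100, 100, 100, 100)),
    ])
    def test_point_estimates_round_to_reported_percents(self, counts, expected):
        m = diagnostic_metrics(ConfusionCounts(*counts))
        got = (m.sensitivity.percent, m.specificity.percent, m.ppv.percent,
               m.npv.percent, m.accuracy.percent)
        assert got == expected

    def test_estimates_inside_their_cis(self):
        m = diagnostic_metrics(ConfusionCounts(11, 4, 4, 17))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            e = getattr(m, name)
            assert e.ci_low <= e.value <= e.ci_high

    def test_clopper_pearson_matches_beta_quantiles(self):
        m = diagnostic_metrics(ConfusionCounts(11, 4, 4, 17))
        k, n = 11, 15
        assert m.sensitivity.ci_low == pytest.approx(
            stats.beta.ppf(0.025, k, n - k + 1))
        assert m.sensitivity.ci_high == pytest.approx(
            stats.beta.ppf(0.975, k + 1, n - k))

    def test_zero_denominator_flagged_undefined(self):
        m = diagnostic_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert not m.sensitivity.defined
        assert m.sensitivity.value is None
        assert m.specificity.value == 1.0

    def test_half_up_rounding(self):
        assert round_half_up_percent(0.775) == 78
        assert round_half_up_percent(0.805) == 81  # 80.5 rounds up
        assert round_half_up_percent(0.804999) == 80


class TestAUC:
    def test_perfect_separation(self):
        v = [0.5, 0.6, 0.95, 0.97]
        y = [True, True, False, False]
        assert auc_empirical(v, y).auc == 1.0

    def test_enumerated_half(self):
        # positives' scores {0.8, 0.7}, negatives' {0.9, 0.6}: 2 of 4
        # pairs concordant
        v = 1.0 - np.array([0.8, 0.7, 0.9, 0.6])
        y = [True, True, False, False]
        assert auc_empirical(v, y).auc == 0.5

    def test_all_tied_scores_give_half(self):
        assert auc_empirical([0.9] * 6, [1, 1, 0, 0, 0, 1]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            auc_empirical([0.8, 0.9], [True, True])

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        v = np.round(rng.uniform(0.3, 1.0, n), 2)  # rounding induces ties
        y = rng.integers(0, 2, n).astype(bool)
        if y.all() or not y.any():
            y[0] = ~y[0]
        score = 1.0 - v
        num, den = 0.0, 0
        for i, j in itertools.product(np.flatnonzero(y), np.flatnonzero(~y)):
            den += 1
            if score[i] > score[j]:
                num += 1.0
            elif score[i] == score[j]:
                num += 0.5
        assert auc_empirical(v, y).auc == pytest.approx(num / den, abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.4, 1.0, 50)
        y = rng.integers(0, 2, 50).astype(bool)
        assert auc_empirical(v, y).auc == pytest.approx(
            roc_auc_score(y, 1.0 - v), abs=1e-12)

    def test_roc_points_span_unit_square_monotonically(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.4, 1.0, 40)
        y = rng.integers(0, 2, 40).astype(bool)
        roc = auc_empirical(v, y)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)


def brute_force_delong_var(scores_a, scores_b, labels):
    """Placement-value covariance computed naively, for cross-checking."""
    y = np.asarray(labels, dtype=bool)
    out = []
    for s in (np.asarray(scores_a), np.asarray(scores_b)):
        pos, neg = s[y], s[~y]
        m, n = len(pos), len(neg)
        v10 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                                 for q in neg]) for p in pos])
        v01 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                                 for p in pos]) for q in neg])
        out.append((v10, v01))
    (v10a, v01a), (v10b, v01b) = out
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    return cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]


class TestDeLong:
    def test_identical_indices_give_zero_z(self):
        v = [0.7, 0.8, 0.92, 0.95, 0.85, 0.9]
        y = [1, 1, 0, 0, 1, 0]
        res = delong_compare(v, v, y)
        assert res.z == 0.0
        assert res.p_value == 1.0

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.4, 1.0, 20)
        b = np.clip(a + rng.normal(0, 0.05, 20), 0, 1)
        y = rng.integers(0, 2, 20).astype(bool)
        ab = delong_compare(a, b, y)
        ba = delong_compare(b, a, y)
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_variance_matches_brute_force_on_small_sample(self):
        a = np.array([0.85, 0.71, 0.62, 0.61, 0.93, 0.97])
        b = np.array([0.95, 0.79, 0.56, 0.51, 0.88, 0.97])
        y = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        var = brute_force_delong_var(1 - a, 1 - b, y)
        res = delong_compare(a, b, y)
        auc_a = auc_empirical(a, y).auc
        auc_b = auc_empirical(b, y).auc
        assert res.z == pytest.approx((auc_a - auc_b) / math.sqrt(var),
                                      abs=1e-10)

    def test_degenerate_variance_flagged(self):
        # both ROCs perfectly separate: placement values constant
        a = [0.5, 0.6, 0.95, 0.97]
        b = [0.55, 0.65, 0.96, 0.98]
        y = [1, 1, 0, 0]
        res = delong_compare(a, b, y)
        assert res.z == 0.0 and res.p_value == 1.0  # equal AUCs, zero var


class TestBlandAltman:
    def test_identical_vectors(self):
        r = bland_altman([0.8, 0.9, 0.85], [0.8, 0.9, 0.85])
        assert (r.bias, r.loa_low, r.loa_high) == (0.0, 0.0, 0.0)

    def test_hand_computed_differences(self):
        r = bland_altman([1.0, 1.1, 1.2], [1.0, 1.0, 1.0])
        assert r.bias == pytest.approx(0.1)
        assert r.sd == pytest.approx(0.1)
        assert r.loa_low == pytest.approx(-0.096)
        assert r.loa_high == pytest.approx(0.296)

    def test_reported_agreement_scale(self):
        # bias 0.003, sd 0.046 -> upper limit 0.093 (0.094 under coarser
        # intermediate rounding)
        assert 0.003 + 1.96 * 0.046 == pytest.approx(0.093, abs=5e-4)

    def test_limits_bracket_195_sd_coverage(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.01, 0.05, 5000)
        r = bland_altman(d, np.zeros_like(d))
        frac = np.mean((d >= r.loa_low) & (d <= r.loa_high))
        assert frac >= 0.93

    def test_needs_two_pairs(self):
        with pytest.raises(InvalidParameterError):
            bland_altman([1.0], [1.0])


class TestCorrelationComparison:
    def test_equal_correlations_give_p_one(self):
        assert fisher_z_compare(0.5, 30, 0.5, 30).p_value == 1.0

    def test_reported_study_comparison(self):
        """r = 0.67 vs 0.68 on n = 36 each -> two-sided p = 0.941."""
        res = fisher_z_compare(0.67, 36, 0.68, 36)
        assert round(res.p_value, 3) == 0.941

    def test_large_difference_is_significant(self):
        res = fisher_z_compare(0.9, 50, 0.0, 50)
        assert abs(res.z) > 7.0
        assert res.p_value < 0.001

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(InvalidParameterError):
            fisher_z_compare(1.0, 30, 0.5, 30)
        with pytest.raises(InvalidParameterError):
            fisher_z_compare(0.5, 3, 0.5, 30)

    def test_steiger_dependent_variant_sane(self):
        res = steiger_z_dependent(0.67, 0.68, 0.8, 36)
        assert res.p_value > 0.5  # nearly equal dependent correlations
        same = steiger_z_dependent(0.6, 0.6, 0.5, 40)
        assert same.z == 0.0


class TestDecisionCurve:
    def test_treat_none_is_zero_and_low_threshold_limit(self):
        v = np.array([0.7, 0.95, 0.85, 0.92])
        y = np.array([1, 0, 1, 0], dtype=bool)
        res = decision_curve(v, y, thresholds=[0.001, 0.2, 0.5])
        assert np.all(res.net_benefit_none == 0.0)
        assert res.net_benefit_all[0] == pytest.approx(res.prevalence, abs=1e-2)

    def test_printed_formula_from_counts(self):
        assert net_benefit_from_counts(11, 4, 36, 0.2) == pytest.approx(
            11 / 36 - (4 / 36) * 0.25, abs=1e-12)
        assert net_benefit_from_counts(11, 4, 36, 0.2) == pytest.approx(0.278,
                                                                        abs=5e-4)

    def test_treat_all_formula(self):
        v = np.linspace(0.5, 1.0, 36)
        y = np.zeros(36, dtype=bool)
        y[:15] = True
        res = decision_curve(v, y, thresholds=[0.2])
        assert res.net_benefit_all[0] == pytest.approx(
            15 / 36 - (21 / 36) * 0.25, abs=1e-12)

    def test_model_nb_bounded_by_prevalence(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0.5, 1.0, 60)
        y = v + rng.normal(0, 0.1, 60) < 0.85
        res = decision_curve(v, y)
        assert np.all(res.net_benefit_model <= res.prevalence + 1e-12)

    def test_no_false_positives_makes_nb_flat(self):
        v = np.array([0.7, 0.8, 0.95, 0.97])
        y = np.array([1, 1, 0, 0], dtype=bool)
        res = decision_curve(v, y)
        assert np.allclose(res.net_benefit_model, 2 / 4)

    def test_thresholds_must_be_interior(self):
        with pytest.raises(InvalidParameterError):
            decision_curve([0.7, 0.95], [True, False], thresholds=[0.0, 0.5])


class TestEvaluatePairs:
    def test_full_report_structure(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.6, 1.0, 40)
        y = np.clip(x + rng.normal(0, 0.04, 40), 0.01, 1.0)
        report = evaluate_pairs(x, y, reference_cutoff=0.89)
        assert report["n"] == 40
        assert set(report["metrics"]) >= {"sensitivity", "specificity", "ppv",
                                          "npv", "accuracy", "tp", "fp", "fn",
                                          "tn"}
        assert "roc" in report and 0.0 <= report["roc"]["auc"] <= 1.0
        assert "bland_altman" in report and "correlation" in report
        assert report["dca"]["prevalence"] == pytest.approx(
            float(np.mean(y <= 0.89)))
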