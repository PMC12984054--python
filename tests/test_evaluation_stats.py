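import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest
from scipy import stats

from stas_habitat.evaluation_stats import (
    ContingencyTable2x2,
    auc_delong,
    cohens_kappa,
    confusion_metrics,
    decision_curve,
    delong_paired_test,
    hosmer_lemeshow,
    logistic_regression,
    odds_ratio_wald,
)


def brute_force_auc(scores, labels):
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return wins / (pos.size * neg.size)


class TestAucDelong:
    def test_four_patient_example(self):
        res = auc_delong([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation_has_zero_variance(self):
        res = auc_delong([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0 and res.variance == 0.0
        assert res.ci_low == res.ci_high == 1.0

    def test_total_ties_give_half(self):
        res = auc_delong([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert res.auc == pytest.approx(0.5)

    def test_matches_pairwise_count_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 500))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # force ties
            res = auc_delong(scores, labels)
            npt.assert_allclose(res.auc, brute_force_auc(scores, labels), atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong([0.1, 0.2], [1, 1])


class TestDelongPairedTest:
    def test_identical_scores_give_p_one(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        z, p = delong_paired_test(scores, scores, labels)
        assert p == 1.0

    def test_antisymmetric_in_model_order(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a, b = rng.random(60), rng.random(60)
        z1, p1 = delong_paired_test(a, b, labels)
        z2, p2 = delong_paired_test(b, a, labels)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_agrees_with_bootstrap_difference_test(self, rng):
        n = 150
        x = rng.normal(size=n)
        labels = (rng.random(n) < 1 / (1 + np.exp(-1.2 * x))).astype(int)
        score_a = x + rng.normal(0, 0.8, n)
        score_b = x + rng.normal(0, 2.0, n)
        _, p = delong_paired_test(score_a, score_b, labels)
        diffs = []
        idx = np.arange(n)
        for _ in range(2000):
            s = rng.choice(idx, n, replace=True)
            if labels[s].min() == labels[s].max():
                continue
            diffs.append(
                brute_force_auc(score_a[s], labels[s])
                - brute_force_auc(score_b[s], labels[s])
            )
        diffs = np.array(diffs)
        observed = brute_force_auc(score_a, labels) - brute_force_auc(score_b, labels)
        shifted = diffs - diffs.mean()  # null-centred bootstrap
        p_boot = np.mean(np.abs(shifted) >= abs(observed))
        assert abs(p - p_boot) <= 0.05


class TestConfusionMetrics:
    def test_printed_2x2_example(self):
        scores = np.r_[np.ones(30), np.ones(10), np.zeros(5), np.zeros(55)]
        labels = np.r_[np.ones(30), np.zeros(10), np.ones(5), np.zeros(55)]
        m = confusion_metrics(scores, labels, 0.5)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["ppv"] == pytest.approx(0.75)

    def test_threshold_extremes(self, rng):
        scores = rng.uniform(0.05, 0.95, 50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        lo = confusion_metrics(scores, labels, 0.0)
        assert lo["sensitivity"] == 1.0 and lo["specificity"] == 0.0
        hi = confusion_metrics(scores, labels, 1.0)
        assert hi["sensitivity"] == 0.0
        assert hi["npv"] == pytest.approx(1 - labels.mean())

    def test_undefined_ppv_is_nan_sentinel(self):
        m = confusion_metrics(np.array([0.1, 0.2]), np.array([0, 1]), 0.9)
        assert np.isnan(m["ppv"])


class TestHosmerLemeshow:
    def test_probabilities_equal_to_prevalence_fit_perfectly(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 400)
        p = np.full(400, y.mean())
        chi2, pval = hosmer_lemeshow(p, y)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_null_calibration_p_values_are_uniform(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(60):
            probs = rng.uniform(0.05, 0.95, 2000)
            y = (rng.random(2000) < probs).astype(int)
            _, p = hosmer_lemeshow(probs, y, fitted=False)
            pvals.append(p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_miscalibration_detected_with_high_power(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_seeds = 20
        for _ in range(n_seeds):
            probs = rng.uniform(0.05, 0.95, 2000)
            y = (rng.random(2000) < probs).astype(int)
            _, p = hosmer_lemeshow(probs**2, y, fitted=False)  # squared probabilities
            rejections += p < 0.05
        assert rejections >= 0.9 * n_seeds


class TestDecisionCurve:
    def test_treat_all_equals_prevalence_at_zero_threshold(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        df = decision_curve(scores, labels, np.array([0.0, 0.2, 0.5]))
        assert df.loc[0, "treat_all"] == pytest.approx(labels.mean())
        assert (df["treat_none"] == 0).all()

    def test_printed_net_benefit_example(self):
        # n=100, TP=30, FP=10 at p_t = 0.2 -> NB = 0.3 - 0.1 * 0.25 = 0.275
        scores = np.r_[np.ones(40), np.zeros(60)]
        labels = np.r_[np.ones(30), np.zeros(10), np.ones(5), np.zeros(55)]
        df = decision_curve(scores, labels, np.array([0.2]))
        assert df.loc[0, "net_benefit"] == pytest.approx(0.275)

    def test_perfect_model_net_benefit_is_prevalence_everywhere(self):
        labels = np.r_[np.ones(30), np.zeros(70)]
        scores = labels.astype(float)
        df = decision_curve(scores, labels, np.linspace(0.01, 0.95, 20))
        npt.assert_allclose(df["net_benefit"], 0.3, atol=1e-12)

    def test_threshold_grid_validated(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], np.array([1.0]))


class TestOddsRatio:
    def test_bronchial_cutoff_contingency(self):
        res = odds_ratio_wald(ContingencyTable2x2(21, 14, 61, 121))
        assert round(res.odds_ratio, 2) == 2.98
        assert round(res.ci_low, 2) == 1.42
        assert round(res.ci_high, 2) == 6.25

    def test_symmetric_table_is_null(self):
        res = odds_ratio_wald(ContingencyTable2x2(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_lobulation_contingency(self):
        res = odds_ratio_wald(ContingencyTable2x2(74, 121, 8, 14))
        assert round(res.odds_ratio, 2) == 1.07
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.43, 2.67)

    def test_zero_cell_triggers_haldane_correction(self):
        res = odds_ratio_wald(ContingencyTable2x2(0, 10, 10, 10))
        assert res.corrected
        assert np.isfinite(res.odds_ratio)

    def test_zero_margin_is_undefined_sentinel(self):
        res = odds_ratio_wald(ContingencyTable2x2(0, 0, 10, 10))
        assert np.isnan(res.odds_ratio)


class TestLogisticRegression:
    def test_single_binary_covariate_matches_contingency_or(self, rng):
        x = rng.integers(0, 2, 300)
        y = (rng.random(300) < np.where(x == 1, 0.6, 0.35)).astype(int)
        design = pd.DataFrame({"x": x})
        report = logistic_regression(design, y)
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        ref = odds_ratio_wald(ContingencyTable2x2(a, b, c, d))
        npt.assert_allclose(report.univariable.loc["x", "or"], ref.odds_ratio, atol=1e-6)

    def test_null_covariate_p_values_are_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(100):
            x = rng.normal(size=150)
            y = rng.integers(0, 2, 150)
            report = logistic_regression(pd.DataFrame({"x": x}), y)
            pvals.append(report.univariable.loc["x", "p"])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_multivariable_set_is_nested_in_significant_set(self, rng):
        x1 = rng.normal(size=400)
        x2 = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-1.2 * x1))).astype(int)
        report = logistic_regression(pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert set(report.independent_predictors) <= set(report.significant)
        assert set(report.multivariable.index) == set(report.significant)


class TestCohensKappa:
    def test_identical_ratings_give_one(self, rng):
        r = rng.integers(0, 2, 50)
        assert cohens_kappa(r, r) == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 500)
        b = rng.integers(0, 2, 500)
        assert abs(cohens_kappa(a, b)) < 0.1

    def test_agreement_table_example_and_sklearn_oracle(self):
        from sklearn.metrics import cohen_kappa_score

        a = np.r_[np.ones(40), np.ones(5), np.zeros(5), np.zeros(50)]
        b = np.r_[np.ones(40), np.zeros(5), np.ones(5), np.zeros(50)]
        # p_o = 0.9, p_e = 0.45*0.45 + 0.55*0.55 = 0.505
        expected = (0.9 - 0.505) / (1 - 0.505)
        assert cohens_kappa(a, b) == pytest.approx(expected)
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))
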