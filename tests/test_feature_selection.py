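import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest

from stas_habitat.feature_selection import (
    icc_2_1,
    icc_filter,
    lasso_select,
    mannwhitney_filter,
    mrmr_select,
    pearson_prune,
    run_cascade,
    zscore_fit_apply,
)


def _table(rng, n=60, p=10, index_prefix="p"):
    idx = pd.Index([f"{index_prefix}{i}" for i in range(n)])
    return pd.DataFrame(rng.normal(size=(n, p)), index=idx,
                        columns=[f"f{j}" for j in range(p)])


class TestIcc:
    def test_perfect_agreement_gives_one_and_survives(self, rng):
        col = rng.normal(size=20)
        ratings = {"feat": np.column_stack([col, col, col])}
        survivors, values = icc_filter(ratings)
        assert survivors == ["feat"]
        assert values["feat"] == pytest.approx(1.0)

    def test_independent_noise_is_dropped(self, rng):
        ratings = {"noise": rng.normal(size=(50, 2))}
        survivors, values = icc_filter(ratings)
        assert survivors == []
        assert abs(values["noise"]) < 0.5

    def test_matches_anova_mean_squares_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        # classic 6 cases x 4 raters reliability table
        ratings = np.array(
            [
                [9.0, 2.0, 5.0, 8.0],
                [6.0, 1.0, 3.0, 2.0],
                [8.0, 4.0, 6.0, 8.0],
                [7.0, 1.0, 2.0, 6.0],
                [10.0, 5.0, 6.0, 9.0],
                [6.0, 2.0, 4.0, 7.0],
            ]
        )
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(6), 4),
                "raters": np.tile(np.arange(4), 6),
                "scores": ratings.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="scores"
        )
        # two-way random, absolute agreement, single rater
        row = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        expected = float(ref.loc[row, "ICC"].iloc[0])
        assert icc_2_1(ratings) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.29, abs=0.005)  # classic worked table

    def test_zero_between_case_variance_dropped_with_warning(self):
        ratings = {"const": np.ones((10, 2))}
        survivors, values = icc_filter(ratings)
        assert survivors == [] and "const" not in values

    def test_requires_both_matrices_to_clear_threshold(self, rng):
        col = rng.normal(size=30)
        good = np.column_stack([col, col + rng.normal(0, 0.01, 30)])
        bad = rng.normal(size=(30, 2))
        survivors, _ = icc_filter([{"f": good}, {"f": bad}])
        assert survivors == []


class TestZscore:
    def test_training_column_population_standardization(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 10.0]}, index=list("abcd"))
        out, scaler = zscore_fit_apply(table, train_index=list("abc"))
        npt.assert_allclose(
            out.loc[list("abc"), "x"], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )
        assert scaler.loc["sd", "x"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_validation_row_at_training_mean_is_zero(self, rng):
        table = _table(rng, n=12, p=3)
        train = table.index[:8]
        table.loc["p11"] = table.loc[train].mean()
        out, _ = zscore_fit_apply(table, train)
        npt.assert_allclose(out.loc["p11"], 0.0, atol=1e-10)

    def test_constant_training_column_is_dropped(self, rng):
        table = _table(rng, n=10, p=2)
        table["c"] = 3.0
        out, _ = zscore_fit_apply(table, table.index[:6])
        assert "c" not in out.columns


class TestMannWhitney:
    def test_constant_feature_has_p_one_and_is_dropped(self, rng):
        table = pd.DataFrame({"const": np.ones(20), "noise": rng.normal(size=20)})
        labels = pd.Series([0] * 10 + [1] * 10)
        survivors, p = mannwhitney_filter(table, labels, table.index)
        assert "const" not in survivors
        assert p["const"] == 1.0

    def test_separated_feature_kept_with_tiny_p(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 20)])
        table = pd.DataFrame({"sep": x})
        labels = pd.Series([0] * 20 + [1] * 20)
        survivors, p = mannwhitney_filter(table, labels, table.index)
        assert survivors == ["sep"] and p["sep"] < 1e-6

    def test_exact_small_sample_p_value(self):
        # {1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 0.1
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        labels = pd.Series([0, 0, 0, 1, 1, 1])
        _, p = mannwhitney_filter(table, labels, table.index)
        assert p["x"] == pytest.approx(0.1)

    def test_tiny_class_rejected(self, rng):
        table = _table(rng, n=5, p=2)
        labels = pd.Series([1, 0, 0, 0, 0], index=table.index)
        with pytest.raises(ValueError):
            mannwhitney_filter(table, labels, table.index)


class TestPearsonPrune:
    def test_duplicated_column_keeps_exactly_one(self, rng):
        table = _table(rng, n=30, p=3)
        table["dup"] = table["f0"]
        survivors, pruned = pearson_prune(
            table, {c: 0.5 for c in table.columns}, table.index
        )
        assert ("f0" in survivors) != ("dup" in survivors)
        assert len(pruned) == 1

    def test_independent_features_all_survive(self, rng):
        table = _table(rng, n=200, p=8)
        survivors, pruned = pearson_prune(table, {}, table.index)
        assert survivors == list(table.columns) and pruned == []

    def test_mutually_correlated_triple_keeps_single_feature(self, rng):
        base = rng.normal(size=40)
        table = pd.DataFrame(
            {
                "a": base,
                "b": base + rng.normal(0, 0.01, 40),
                "c": base + rng.normal(0, 0.01, 40),
            }
        )
        pvals = {"a": 0.01, "b": 0.02, "c": 0.03}
        survivors, _ = pearson_prune(table, pvals, table.index)
        assert survivors == ["a"]  # smallest U-test p wins every duel

    def test_smaller_p_value_wins_the_duel(self, rng):
        base = rng.normal(size=40)
        table = pd.DataFrame({"worse": base, "better": base + rng.normal(0, 0.01, 40)})
        survivors, _ = pearson_prune(
            table, {"worse": 0.04, "better": 0.001}, table.index
        )
        assert survivors == ["better"]


class TestMrmr:
    def test_deterministic_label_feature_ranked_first(self, rng):
        table = _table(rng, n=80, p=5)
        y = pd.Series(rng.integers(0, 2, 80), index=table.index)
        table["signal"] = y.to_numpy() + 0.01 * rng.normal(size=80)
        ranked, _ = mrmr_select(table, y, table.index, m=3)
        assert ranked[0] == "signal"

    def test_redundant_copy_penalized_against_informative_feature(self, rng):
        n = 300
        a = rng.normal(size=n)
        c = rng.normal(size=n)
        # a dominates relevance, c adds independent signal, b is a near-copy of a
        y = pd.Series(((1.6 * a + 0.8 * c) > 0).astype(int))
        table = pd.DataFrame({"a": a, "b": a + 0.001 * rng.normal(size=n), "c": c})
        table.index = y.index
        ranked, _ = mrmr_select(table, y, table.index, m=2)
        assert ranked[0] in ("a", "b")
        assert ranked[1] == "c"  # the near-copy is penalized for redundancy

    def test_m_equal_to_feature_count_returns_permutation(self, rng):
        y = pd.Series(rng.integers(0, 2, 40))
        table = _table(rng, n=40, p=6)
        table.index = y.index
        ranked, _ = mrmr_select(table, y, table.index, m=6)
        assert sorted(ranked) == sorted(table.columns)

    def test_nonpositive_m_rejected(self, rng):
        y = pd.Series(rng.integers(0, 2, 10))
        table = _table(rng, n=10, p=2)
        table.index = y.index
        with pytest.raises(ValueError):
            mrmr_select(table, y, table.index, m=0)


class TestLasso:
    def test_vanishing_penalty_limit_matches_unpenalized_fit(self, rng):
        import statsmodels.api as sm
        from sklearn.linear_model import LogisticRegression

        n = 300
        X = rng.normal(size=(n, 2))
        eta = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int))
        ref = sm.Logit(y.to_numpy(), sm.add_constant(X)).fit(disp=0)
        lam_max = np.abs(X.T @ (y - y.mean())).max() / n
        tiny = LogisticRegression(
            penalty="l1", C=1.0 / (1e-5 * lam_max * n), solver="liblinear",
            tol=1e-10, max_iter=5000,
        ).fit(X, y)
        npt.assert_allclose(tiny.coef_.ravel(), ref.params[1:], atol=1e-3)

    def test_planted_support_recovered_across_seeds(self):
        """Signals always survive; the 1-SE parsimony rule also keeps the
        noise admission low (min-deviance trades sparsity for fit)."""
        always_signals = 0
        sparse_hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 200
            X = r.normal(size=(n, 23))
            eta = 1.5 * X[:, 0] - 1.2 * X[:, 1] + 1.0 * X[:, 2]
            y = pd.Series((r.random(n) < 1 / (1 + np.exp(-eta))).astype(int))
            table = pd.DataFrame(
                X, columns=[f"s{j}" if j < 3 else f"n{j}" for j in range(23)],
                index=y.index,
            )
            feats_min, _, _, _, _ = lasso_select(
                table, y, y.index, seed=seed, n_lambdas=50
            )
            always_signals += sum(f.startswith("s") for f in feats_min) == 3
            feats_1se, _, _, _, _ = lasso_select(
                table, y, y.index, seed=seed, n_lambdas=50, rule="1se"
            )
            signals = sum(f.startswith("s") for f in feats_1se)
            noise = sum(f.startswith("n") for f in feats_1se)
            sparse_hits += signals == 3 and noise <= 2
        assert always_signals >= 0.8 * n_seeds
        assert sparse_hits >= 0.8 * n_seeds

    def test_cv_deviance_curve_has_expected_length(self, rng):
        y = pd.Series(rng.integers(0, 2, 60))
        table = _table(rng, n=60, p=4)
        table.index = y.index
        _, _, lam, grid, dev = lasso_select(table, y, y.index, seed=1, n_lambdas=25)
        assert grid.shape == dev.shape == (25,)
        assert lam in grid


class TestCascade:
    @pytest.fixture()
    def planted(self, rng):
        n = 120
        X = rng.normal(size=(n, 30))
        eta = 1.6 * X[:, 0] + 1.3 * X[:, 1] - 1.1 * X[:, 2]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int),
                      index=[f"p{i}" for i in range(n)])
        table = pd.DataFrame(
            X, index=y.index,
            columns=[f"sig{j}" if j < 3 else f"noise{j}" for j in range(30)],
        )
        return table, y

    def test_stage_nesting_holds(self, planted):
        table, y = planted
        _, report = run_cascade(table, y, y.index[:90], seed=0)
        stages = list(report.stages.values())
        for earlier, later in zip(stages, stages[1:]):
            assert set(later) <= set(earlier)

    def test_training_only_fitting_ignores_other_splits(self, planted):
        table, y = planted
        train = y.index[:80]
        _, rep1 = run_cascade(table, y, train, seed=0)
        perturbed = table.copy()
        perturbed.loc[y.index[80:]] = 999.0  # wreck the held-out rows
        _, rep2 = run_cascade(perturbed, y, train, seed=0)
        assert rep1.stages == rep2.stages
        for k, v in rep1.lasso_coefficients.items():
            # identical to floating-point noise: pandas reductions round
            # differently on differently-blocked frames
            assert rep2.lasso_coefficients[k] == pytest.approx(v, abs=1e-12)

    def test_label_permutation_selects_far_fewer_features(self, planted):
        table, y = planted
        train = y.index[:90]
        selected, report = run_cascade(table, y, train, seed=0)
        n_true = len(report.final_features)
        assert n_true >= 3
        rng = np.random.default_rng(0)
        null_counts = []
        for _ in range(10):
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            _, rep = run_cascade(table, y_perm, train, seed=0)
            null_counts.append(len(rep.final_features))
        assert np.mean(null_counts) <= 0.5 * n_true
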