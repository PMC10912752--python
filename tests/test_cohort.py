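import numpy as np
import pandas as pd
import pytest

from tmztk import simulate
from tmztk.cohort import (
    adjust_expression,
    logistic_fit,
    proliferation_score,
    tertile_stratify,
)


class TestProliferationScore:
    def test_constant_genes_score_zero(self):
        mat = pd.DataFrame(
            {"s1": [5.0, 2.0], "s2": [5.0, 2.0], "s3": [5.0, 2.0]},
            index=["g1", "g2"],
        )
        scores = proliferation_score(mat, ["g1", "g2"])
        assert (scores == 0).all()

    def test_uniform_plus_one_sd_sample_scores_one(self):
        # every set gene has cohort mean 0 and SD 1, with sample s0
        # sitting exactly +1 SD above the mean on each gene
        row = [1.0, 1.0, -1.0, -1.0, 0.0]
        mat = pd.DataFrame(
            [row] * 4, index=[f"g{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(5)],
        )
        scores = proliferation_score(mat, list(mat.index))
        assert scores["s0"] == pytest.approx(1.0, abs=1e-12)
        assert scores["s4"] == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance_and_gene_order(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(0, 1, (6, 8)),
                           index=[f"g{i}" for i in range(6)],
                           columns=[f"s{i}" for i in range(8)])
        genes = [f"g{i}" for i in range(4)]
        s1 = proliferation_score(mat, genes)
        rescaled = mat.mul(pd.Series([2, 3, 0.5, 7, 1, 1], index=mat.index), axis=0)
        rescaled = rescaled.add(pd.Series(range(6), index=mat.index), axis=0)
        s2 = proliferation_score(rescaled, genes)
        np.testing.assert_allclose(s1, s2, atol=1e-12)
        s3 = proliferation_score(mat, genes[::-1])
        np.testing.assert_allclose(s1, s3, atol=1e-12)

    def test_disjoint_gene_set_rejected(self):
        mat = pd.DataFrame({"s": [1.0]}, index=["g1"])
        with pytest.raises(KeyError):
            proliferation_score(mat, ["nope"])


class TestAdjustExpression:
    def test_exactly_linear_gives_zero_residuals(self):
        x = pd.Series([0.0, 1.0, 2.0, 3.0])
        y = 2.5 * x + 1.0
        np.testing.assert_allclose(adjust_expression(y, x), 0.0, atol=1e-12)

    def test_closed_form_three_points(self):
        # OLS through (0,1),(1,2),(2,4): slope 1.5, intercept 5/6
        y = pd.Series([1.0, 2.0, 4.0])
        x = pd.Series([0.0, 1.0, 2.0])
        resid = adjust_expression(y, x)
        np.testing.assert_allclose(resid, [1 / 6, -1 / 3, 1 / 6], atol=1e-12)

    def test_orthogonality_and_zero_sum(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(0, 1, 500))
        y = pd.Series(0.75 * x + rng.normal(0, 0.5, 500))
        resid = adjust_expression(y, x)
        assert abs(resid.sum()) < 1e-9 * resid.abs().sum()
        assert abs((resid * x).sum()) < 1e-9 * (resid.abs() * x.abs()).sum()

    def test_intercept_absorption(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.normal(0, 1, 50))
        y = pd.Series(rng.normal(0, 1, 50))
        r1 = adjust_expression(y, x)
        r2 = adjust_expression(y + 10.0, x)
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            adjust_expression(pd.Series([1.0, 2.0, 3.0]), pd.Series([1.0, 1.0, 1.0]))


class TestTertiles:
    def test_one_to_nine(self):
        labels = tertile_stratify(pd.Series(range(1, 10), dtype=float))
        assert labels.tolist() == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3

    def test_ten_distinct_values_split_4_3_3(self):
        labels = tertile_stratify(pd.Series(range(1, 11), dtype=float))
        counts = labels.value_counts()
        assert counts["low"] == 4 and counts["medium"] == 3 and counts["high"] == 3

    def test_all_equal_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = tertile_stratify(pd.Series([2.0, 2.0, 2.0, 2.0]))
        assert (labels == "medium").all()

    def test_labels_monotone_in_value(self):
        rng = np.random.default_rng(4)
        v = pd.Series(rng.normal(0, 1, 100))
        labels = tertile_stratify(v)
        order = {"low": 0, "medium": 1, "high": 2}
        ranked = labels.map(order)[v.sort_values().index]
        assert ranked.is_monotonic_increasing


class TestLogisticFit:
    def test_two_by_two_closed_form(self):
        # cells: x=0 (a=40 events, b=60 non), x=1 (c=20 events, d=80 non)
        y = np.concatenate([np.ones(40), np.zeros(60), np.ones(20), np.zeros(80)])
        x = np.concatenate([np.zeros(100), np.ones(100)])
        fit = logistic_fit(y, pd.DataFrame({"x": x}))
        odds_ratio = (20 / 80) / (40 / 60)
        assert fit.params["x"] == pytest.approx(np.log(odds_ratio), abs=1e-8)
        assert fit.params["intercept"] == pytest.approx(np.log(40 / 60), abs=1e-8)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x1 = rng.normal(0, 1, 400)
        x2 = rng.binomial(1, 0.4, 400)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x1 - 1.2 * x2)))
        y = rng.binomial(1, p)
        fit = logistic_fit(y, pd.DataFrame({"x1": x1, "x2": x2}))
        X = sm.add_constant(np.column_stack([x1, x2]))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-6)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), ref.pvalues, atol=1e-6)

    def test_null_covariate_rarely_significant(self):
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(0, 1, 2000)
            y = rng.binomial(1, 0.3, 2000)
            fit = logistic_fit(y, pd.DataFrame({"x": x}))
            hits += abs(fit.zvalues["x"]) >= 3
        assert hits == 0

    def test_separation_detected(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x = np.array([-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0])
        with pytest.raises(ValueError, match="separation"):
            logistic_fit(y, pd.DataFrame({"x": x}))

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_recovers_generator_truth_within_3_se(self):
        design = simulate.CohortDesign(n_samples=5000)
        table, truth = simulate.gen_cohort(design, seed=6)
        adj = adjust_expression(table["rad18"], table["proliferation"])
        fit = logistic_fit(
            table["hypermutation"],
            pd.DataFrame({"rad18_adj": adj, "mgmt_low": table["mgmt_low"]}),
        )
        for name, true_val in [
            ("rad18_adj", truth["beta_rad18"]),
            ("mgmt_low", truth["beta_mgmt"]),
            ("intercept", truth["beta0"]),
        ]:
            assert abs(fit.params[name] - true_val) < 3 * fit.bse[name]


class TestEndToEnd:
    def test_expression_matrix_score_tracks_true_proliferation(self):
        table, _ = simulate.gen_cohort(simulate.CohortDesign(n_samples=300), seed=8)
        mat, gene_set = simulate.gen_expression_matrix(table, seed=9)
        scores = proliferation_score(mat, gene_set)
        r = np.corrcoef(scores, table.set_index("sample")["proliferation"])[0, 1]
        assert r > 0.95


    def test_hypermutants_concentrate_in_low_tertile_of_mgmt_low(self):
        table, _ = simulate.gen_cohort(
            simulate.CohortDesign(n_samples=3000), seed=7
        )
        table = table[~table.pole_mutant].reset_index(drop=True)
        adj = adjust_expression(table["rad18"], table["proliferation"])
        tert = tertile_stratify(adj)
        fit = logistic_fit(
            table["hypermutation"],
            pd.DataFrame({"rad18_adj": adj, "mgmt_low": table["mgmt_low"]}),
        )
        assert fit.params["rad18_adj"] < 0
        assert fit.pvalues["rad18_adj"] < 0.01
        mgmt_low = table[table.mgmt_low == 1]
        rate = (
            table.assign(tertile=tert)[lambda d: d.mgmt_low == 1]
            .groupby("tertile")["hypermutation"].mean()
        )
        assert rate["low"] > rate["high"]
        assert len(mgmt_low) > 0
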