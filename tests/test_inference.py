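"""Logistic LRT / LOOCV classification and nested linear-model comparison,
each checked against an independent oracle route."""

import subprocess
import sys
import warnings

import numpy as np
import pandas as pd
import pytest

from eegvrp.inference import (
    LinearFitResult,
    NestedLinearComparison,
    VRPLogisticScreen,
    compare_nested,
    fit_linear,
    fit_logistic_lrt,
    loocv_confusion,
    predict_future_visit,
    same_visit_table,
)
from eegvrp.simulate import SimulationConfig, generate_cohort

TOY_X = np.array([1.0, 2.0, 3.0, 4.0, 3.0, 4.0, 5.0, 6.0])
TOY_Y = np.array([0, 0, 0, 0, 1, 1, 1, 1])


def _grid_search_lrt(x, y):
    """Dense two-stage grid maximization of the Bernoulli likelihood."""

    def llf(b0, b1):
        eta = b0 + b1 * x
        return np.sum(y * eta - np.logaddexp(0.0, eta))

    b0s = np.linspace(-20, 20, 201)
    b1s = np.linspace(-10, 10, 201)
    ll = np.array([[llf(a, b) for b in b1s] for a in b0s])
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    # refine around the coarse optimum
    b0s = np.linspace(b0s[max(i - 2, 0)], b0s[min(i + 2, 200)], 201)
    b1s = np.linspace(b1s[max(j - 2, 0)], b1s[min(j + 2, 200)], 201)
    ll = np.array([[llf(a, b) for b in b1s] for a in b0s])
    p = y.mean()
    ll_null = len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p))
    return 2 * (ll.max() - ll_null)


class TestLogisticLrt:
    def test_toy_set_matches_grid_search_likelihood(self):
        res = fit_logistic_lrt(TOY_X, TOY_Y)
        assert res.lrt_chi2 == pytest.approx(_grid_search_lrt(TOY_X, TOY_Y), abs=1e-3)
        assert res.odds_ratio == pytest.approx(np.exp(res.slope))
        assert res.df == 1

    def test_constant_feature_degenerate(self):
        res = fit_logistic_lrt(np.full(8, 3.3), TOY_Y)
        assert res.lrt_chi2 <= 1e-6
        assert res.odds_ratio == 1.0
        assert res.degenerate

    def test_complete_separation_warns_with_finite_estimates(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        with pytest.warns(UserWarning, match="separation"):
            res = fit_logistic_lrt(x, TOY_Y)
        assert res.separation
        assert np.isfinite(res.slope) and np.isfinite(res.lrt_chi2)
        # with separation the LRT approaches the saturated bound 2*n*ln2
        assert res.lrt_chi2 <= 2 * len(x) * np.log(2) + 1e-6

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_logistic_lrt(TOY_X, np.zeros(8))

    def test_nonfinite_feature_error(self):
        x = TOY_X.copy()
        x[0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_logistic_lrt(x, TOY_Y)

    @pytest.mark.parametrize("a, b", [(100.0, 0.0), (3.0, -7.0), (0.01, 2.0)])
    def test_lrt_invariant_to_affine_feature_rescaling(self, a, b):
        base = fit_logistic_lrt(TOY_X, TOY_Y)
        res = fit_logistic_lrt(a * TOY_X + b, TOY_Y)
        assert res.lrt_chi2 == pytest.approx(base.lrt_chi2, abs=1e-6)
        # the slope changes with the units; the per-SD odds ratio does not
        assert res.odds_ratio_per_sd == pytest.approx(
            base.odds_ratio_per_sd, rel=1e-4
        )

    def test_estimator_api(self):
        est = VRPLogisticScreen(threshold=0.5).fit(TOY_X.reshape(-1, 1), TOY_Y)
        assert est.get_params() == {"threshold": 0.5}
        proba = est.predict_proba([[1.0], [6.0]])
        assert proba.shape == (2, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert est.predict([[6.0]])[0] == 1
        assert 0.5 <= est.score(TOY_X, TOY_Y) <= 1.0


class TestLoocv:
    def test_matches_explicit_sklearn_loop(self):
        """Two overlapping clusters: our LOOCV equals a hand-rolled loop
        using sklearn's (effectively unpenalized) logistic regression."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(2.5, 1, 12)])
        y = np.array([0] * 15 + [1] * 12)
        ours = loocv_confusion(x, y)

        tp = tn = fp = fn = 0
        for i in range(len(x)):
            mask = np.arange(len(x)) != i
            clf = LogisticRegression(C=1e8, tol=1e-10, max_iter=10000)
            clf.fit(x[mask, None], y[mask])
            pred = int(clf.predict_proba([[x[i]]])[0, 1] > 0.5)
            tp += pred == 1 and y[i] == 1
            tn += pred == 0 and y[i] == 0
            fp += pred == 1 and y[i] == 0
            fn += pred == 0 and y[i] == 1
        assert (ours.tp, ours.tn, ours.fp, ours.fn) == (tp, tn, fp, fn)
        assert ours.n == len(x)

    def test_counts_sum_and_rates(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = np.array([0] * 12 + [1] * 8)
        c = loocv_confusion(x, y)
        assert c.tp + c.tn + c.fp + c.fn == 20
        assert c.accuracy == pytest.approx((c.tp + c.tn) / 20)
        assert c.sensitivity == pytest.approx(c.tp / (c.tp + c.fn))
        assert c.specificity == pytest.approx(c.tn / (c.tn + c.fp))

    def test_label_swap_exchanges_sensitivity_and_specificity(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 14), rng.normal(1.5, 1, 10)])
        y = np.array([0] * 14 + [1] * 10)
        c1 = loocv_confusion(x, y)
        c2 = loocv_confusion(x, 1 - y)
        assert c1.sensitivity == pytest.approx(c2.specificity)
        assert c1.specificity == pytest.approx(c2.sensitivity)
        assert (c1.tp, c1.fn) == (c2.tn, c2.fp)

    def test_noise_feature_collapses_to_majority_class(self):
        """With an uninformative feature and 21/11 class imbalance the
        LOOCV predictions drift to the majority class."""
        rng = np.random.default_rng(3)
        sens_list, spec_list = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(40):
                x = rng.normal(size=32)
                y = np.array([0] * 21 + [1] * 11)
                c = loocv_confusion(x, y)
                sens_list.append(c.sensitivity)
                spec_list.append(c.specificity)
        assert np.mean(spec_list) > 0.8
        assert np.mean(sens_list) < 0.3


class TestLinearFits:
    def test_five_point_toy_matches_normal_equations(self):
        x1 = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        x2 = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        fit = fit_linear(y, pd.DataFrame({"x1": x1, "x2": x2}))
        X = np.column_stack([np.ones(5), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)
        rss = float(((y - X @ beta) ** 2).sum())
        assert fit.rss == pytest.approx(rss, abs=1e-10)
        # BIC from first principles: Gaussian MLE sigma^2 = rss/n, k = p+2
        n, k = 5, 4
        llf = -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
        assert fit.bic == pytest.approx(k * np.log(n) - 2 * llf, abs=1e-6)
        assert fit.adj_r2 == pytest.approx(
            1 - (1 - fit.r2) * (n - 1) / (n - 2 - 1), abs=1e-12
        )

    def test_exact_linear_data_perfect_fit(self):
        x = np.arange(10.0)
        y = 2.0 + 3.0 * x
        fit = fit_linear(y, pd.DataFrame({"x": x}))
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_names_collinear_columns(self):
        x = np.arange(8.0)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(np.random.default_rng(4).normal(size=8), df)

    def test_bic_and_anova_match_r(self, tmp_path):
        """Cross-check BIC and the nested ANOVA p-value against R's lm()."""
        rng = np.random.default_rng(5)
        n = 24
        df = pd.DataFrame(
            {
                "age": rng.uniform(38, 203, n),
                "risk": rng.integers(0, 2, n).astype(float),
                "vrp": rng.uniform(0.02, 0.1, n),
            }
        )
        df["y"] = 5 + 0.1 * df.age + 2 * df.risk - 40 * df.vrp + rng.normal(0, 2, n)
        null = fit_linear(df.y, df[["age", "risk"]])
        full = fit_linear(df.y, df[["age", "risk", "vrp"]])
        cmp_ = compare_nested(null, full)

        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = f"""
        d <- read.csv("{csv}")
        m0 <- lm(y ~ age + risk, data = d)
        m1 <- lm(y ~ age + risk + vrp, data = d)
        a <- anova(m0, m1)
        cat(sprintf("%.12g", c(BIC(m0), BIC(m1), a[["Pr(>F)"]][2], a[["F"]][2],
            summary(m1)$adj.r.squared)), sep = "\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        ).stdout.split()
        r_bic0, r_bic1, r_p, r_f, r_adj = map(float, out)
        assert null.bic == pytest.approx(r_bic0, abs=1e-6)
        assert full.bic == pytest.approx(r_bic1, abs=1e-6)
        assert cmp_.anova_p == pytest.approx(r_p, abs=1e-9)
        assert cmp_.partial_f == pytest.approx(r_f, abs=1e-7)
        assert full.adj_r2 == pytest.approx(r_adj, abs=1e-9)


class TestCompareNested:
    def test_plugin_formula_rss_10_5(self):
        """RSS0=10, RSS1=5, n=20, q=1, p1=2 -> F = (5/1)/(5/17) = 17."""
        mk = lambda preds, rss: LinearFitResult(
            outcome="y", predictors=preds, params=np.zeros(len(preds) + 1),
            n=20, rss=rss, r2=0, adj_r2=0, llf=0, bic=0,
        )
        cmp_ = compare_nested(mk(("a",), 10.0), mk(("a", "b"), 5.0))
        assert cmp_.partial_f == pytest.approx(17.0)
        assert cmp_.df_num == 1
        assert cmp_.df_den == 17

    def test_identical_models_give_f0_p1(self):
        x = np.arange(12.0)
        y = x + np.random.default_rng(6).normal(size=12)
        fit = fit_linear(y, pd.DataFrame({"x": x}))
        cmp_ = compare_nested(fit, fit)
        assert cmp_.partial_f == 0.0
        assert cmp_.anova_p == 1.0

    def test_non_nested_pair_rejected(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=10)
        f1 = fit_linear(y, pd.DataFrame({"a": rng.normal(size=10)}))
        f2 = fit_linear(y, pd.DataFrame({"b": rng.normal(size=10)}))
        with pytest.raises(ValueError, match="nested"):
            compare_nested(f1, f2)

    def test_different_outcomes_rejected(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame({"a": rng.normal(size=10)})
        f1 = fit_linear(rng.normal(size=10), x)
        f2 = fit_linear(rng.normal(size=10), x[["a"]].assign(b=rng.normal(size=10)))
        with pytest.raises(ValueError, match="outcome"):
            compare_nested(f1, f2)


class TestCohortLevel:
    def test_same_visit_table_shape_and_holm(self):
        c = generate_cohort(
            SimulationConfig(seed=20, visit3_n_td=1, visit3_n_ar=1),
            render_eeg=False,
        ).cohort.assign(vrp=lambda d: d.vrp_true)
        tab = same_visit_table(c)
        assert len(tab) == 12
        assert set(tab.columns) >= {
            "outcome", "adj_r2_null", "adj_r2_full", "bic_null", "bic_full",
            "anova_p", "anova_p_holm",
        }
        assert (tab.anova_p_holm >= tab.anova_p - 1e-12).all()
        assert (tab.bic_full > 0).all()

    def test_null_model_definition_switch(self):
        c = generate_cohort(
            SimulationConfig(seed=21, visit3_n_td=1, visit3_n_ar=1),
            render_eeg=False,
        ).cohort.assign(vrp=lambda d: d.vrp_true)
        with_risk = same_visit_table(c, null_includes_risk=True)
        age_only = same_visit_table(c, null_includes_risk=False)
        assert not np.allclose(
            with_risk.adj_r2_null.values, age_only.adj_r2_null.values
        )

    def test_future_visit_null_vrp_adds_nothing(self):
        """beta_vrp = 0 everywhere: the added-VRP adjusted-R^2 gain is
        centered at or below zero across seeds."""
        coefs = {"bayley_raw_fine_motor": (8.0, 0.10, 1.0, 0.0)}
        deltas = []
        for seed in range(60):
            cfg = SimulationConfig(
                seed=seed, bayley_coefficients=coefs, bayley_noise_sd=2.0,
                heterogeneity_ar=0.2,
            )
            c = generate_cohort(cfg, render_eeg=False).cohort.assign(
                vrp=lambda d: d.vrp_true
            )
            deltas.append(predict_future_visit(c).delta_adj_r2)
        assert np.mean(deltas) < 0.01

    def test_future_visit_strong_effect_detected(self):
        """Large beta_vrp, low noise: the 3-regressor model's partial-F
        p < 0.001 in nearly all seeds."""
        coefs = {"bayley_raw_fine_motor": (8.0, 0.10, 0.0, -400.0)}
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                seed=seed, bayley_coefficients=coefs, bayley_noise_sd=0.5,
                visit_stability=1.0,
            )
            c = generate_cohort(cfg, render_eeg=False).cohort.assign(
                vrp=lambda d: d.vrp_true
            )
            hits += predict_future_visit(c).anova_p < 0.001
        assert hits >= 0.95 * n_seeds

    def test_future_visit_requires_linked_subjects(self):
        c = generate_cohort(
            SimulationConfig(seed=22, visit3_n_td=1, visit3_n_ar=1),
            render_eeg=False,
        ).cohort.assign(vrp=lambda d: d.vrp_true)
        with pytest.raises(ValueError, match=">= 3"):
            predict_future_visit(c[c.visit == 1])


def test_nested_comparison_estimator_api():
    rng = np.random.default_rng(9)
    n = 30
    df = pd.DataFrame(
        {
            "age_days_adjusted": rng.uniform(38, 203, n),
            "at_risk": rng.integers(0, 2, n).astype(float),
            "vrp": rng.uniform(0.02, 0.1, n),
        }
    )
    y = 3 + 0.1 * df.age_days_adjusted - 30 * df.vrp + rng.normal(0, 1, n)
    est = NestedLinearComparison().fit(df, y, outcome_name="score")
    assert est.comparison_.outcome == "score"
    assert est.full_fit_.predictors == (
        "age_days_adjusted", "at_risk", "vrp",
    )
    assert est.get_params()["added_predictors"] == ("vrp",)
    assert est.comparison_.df_num == 1
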