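import numpy as np
import pandas as pd
import pytest

import chromaqbd as cq
from chromaqbd import build_model_matrix, term_labels
from chromaqbd.rsm import goodness_of_fit, sequential_order_report


def normal_equations_fit(X, y):
    """Independent brute-force OLS oracle."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    return beta, sigma2 * np.linalg.inv(XtX)


class TestModelMatrix:
    def test_center_and_edge_rows_expand_correctly(self):
        m = build_model_matrix([[0, 0, 0], [-1, 1, 0]], list("ABC"), "quadratic")
        assert m.iloc[0].tolist() == [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        assert m.iloc[1].tolist() == [1, -1, 1, 0, -1, 0, 0, 1, 1, 0]

    def test_term_order_matches_convention(self):
        assert term_labels(list("ABC"), "quadratic") == [
            "1", "A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2",
        ]
        assert term_labels(list("ABC"), "linear") == ["1", "A", "B", "C"]

    def test_bbd_quadratic_matrix_has_full_rank(self, bbd_table):
        m = build_model_matrix(bbd_table.coded.to_numpy(), bbd_table.symbols, "quadratic")
        assert m.shape == (16, 10)
        assert np.linalg.matrix_rank(m.to_numpy()) == 10

    def test_unknown_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            build_model_matrix([[0, 0, 0]], list("ABC"), "cubic")


class TestFitOLS:
    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(42)
        specs = cq.default_bbd_specs()
        for trial in range(5):
            design = cq.make_box_behnken(specs, n_center=4)
            y = rng.normal(10, 1, design.n_runs)
            table = design.with_responses(pd.DataFrame({"y": y}))
            fit = cq.fit_ols(table, "y", "quadratic")
            beta, cov = normal_equations_fit(fit.model_matrix, y)
            assert fit.beta == pytest.approx(beta, abs=1e-9)
            assert fit.cov_beta == pytest.approx(cov, abs=1e-9)

    def test_constant_response_gives_pure_intercept(self, bbd_table):
        table = bbd_table.with_responses(pd.DataFrame({"y": np.full(16, 4.2)}))
        fit = cq.fit_ols(table, "y", "quadratic")
        assert fit.beta[0] == pytest.approx(4.2)
        assert fit.beta[1:] == pytest.approx(np.zeros(9), abs=1e-9)
        assert goodness_of_fit(fit).degenerate

    def test_too_few_runs_and_missing_response_rejected(self, bbd_table):
        small = cq.DesignTable(bbd_table.factors, bbd_table.data.iloc[:8])
        with pytest.raises(ValueError, match="runs"):
            cq.fit_ols(small, "t_e_bup", "quadratic")
        with pytest.raises(KeyError):
            cq.fit_ols(bbd_table, "nope", "linear")

    def test_fit_invariant_to_run_order_and_linear_in_scale(self, bbd_table):
        base = cq.fit_ols(bbd_table, "t_e_bup", "quadratic")
        perm = np.random.default_rng(0).permutation(16)
        shuffled = cq.DesignTable(bbd_table.factors, bbd_table.data.iloc[perm])
        fit_p = cq.fit_ols(shuffled, "t_e_bup", "quadratic")
        assert fit_p.beta == pytest.approx(base.beta)
        scaled = bbd_table.with_responses(
            pd.DataFrame({"y": 2.5 * bbd_table.data["t_e_bup"]})
        )
        fit_s = cq.fit_ols(scaled, "y", "quadratic")
        assert fit_s.beta == pytest.approx(2.5 * base.beta)

    def test_roundtrip_through_json(self, bbd_table, tmp_path):
        fit = cq.fit_ols(bbd_table, "t_b_imp2", "quadratic")
        fit.to_json(tmp_path / "m.json")
        back = cq.ModelFit.from_json(tmp_path / "m.json")
        assert back.beta == pytest.approx(fit.beta)
        assert back.terms == fit.terms
        assert back.sigma2 == pytest.approx(fit.sigma2)


class TestGoodnessOfFit:
    def test_noiseless_data_has_unit_r2(self):
        specs = cq.default_bbd_specs()
        design = cq.make_box_behnken(specs, n_center=4)
        x = design.coded.to_numpy()
        y = 3.0 + 1.0 * x[:, 0] - 0.5 * x[:, 1]
        fit = cq.fit_ols(design.with_responses(pd.DataFrame({"y": y})), "y", "linear")
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_press_at_least_residual_sum_of_squares(self, bbd_table):
        for resp in bbd_table.response_names:
            fit = cq.fit_ols(bbd_table, resp, "quadratic")
            rss = float(np.sum((fit.y - fit.model_matrix @ fit.beta) ** 2))
            assert fit.press >= rss

    def test_press_residuals_equal_leave_one_out_errors(self, bbd_table):
        """Hat-matrix identity e_i/(1-h_ii) vs an explicit refit without run i."""
        fit = cq.fit_ols(bbd_table, "t_e_bup", "quadratic")
        X, y = fit.model_matrix, fit.y
        hat = np.diag(X @ np.linalg.inv(X.T @ X) @ X.T)
        resid = y - X @ fit.beta
        for i in (0, 5, 11):
            keep = np.arange(len(y)) != i
            beta_i, _ = normal_equations_fit(X[keep], y[keep])
            loo_err = y[i] - X[i] @ beta_i
            assert loo_err == pytest.approx(resid[i] / (1 - hat[i]), abs=1e-8)

    def test_r2_hierarchy(self, bbd_table):
        for resp in bbd_table.response_names:
            fit = cq.fit_ols(bbd_table, resp, "quadratic")
            assert 0.0 <= fit.r2 <= 1.0
            assert fit.adj_r2 <= fit.r2
            assert fit.pred_r2 <= fit.r2


class TestInference:
    def test_t_statistics_recompute_from_covariance(self, bbd_table):
        fit = cq.fit_ols(bbd_table, "t_e_bup", "quadratic")
        table = cq.coefficient_inference(fit)
        se = np.sqrt(np.diag(fit.cov_beta))
        assert table["t"].to_numpy() == pytest.approx(fit.beta / se)

    def test_dominant_main_effect_highly_significant(self, bbd_table):
        table = cq.coefficient_inference(cq.fit_ols(bbd_table, "t_e_bup", "quadratic"))
        assert table.loc["A", "p"] < 0.001
        assert table.loc["A", "stars"] == "***"

    def test_zero_coefficient_has_p_one(self, bbd_table):
        y = bbd_table.coded["A"].to_numpy() * 2.0  # exactly orthogonal to B
        rng = np.random.default_rng(1)
        table = bbd_table.with_responses(pd.DataFrame({"y": y + rng.normal(0, 0.1, 16)}))
        inf = cq.coefficient_inference(cq.fit_ols(table, "y", "linear"))
        assert inf.loc["A", "p"] < 0.001


class TestPrediction:
    def test_center_prediction_is_intercept(self, bbd_table):
        fit = cq.fit_ols(bbd_table, "t_e_bup", "quadratic")
        mean, var_mean, var_new = fit.predict_mean([0.0, 0.0, 0.0])
        assert mean == pytest.approx(fit.beta[0])
        assert var_new > var_mean > 0

    def test_dimension_mismatch_raises(self, bbd_table):
        fit = cq.fit_ols(bbd_table, "t_e_bup", "quadratic")
        with pytest.raises(ValueError, match="coordinates"):
            fit.predict_mean([0.0, 0.0])


class TestCoverage:
    def test_confidence_intervals_cover_truth_at_nominal_rate(self):
        """95% coefficient CIs over 500 simulated studies, pooled across terms."""
        from scipy import stats

        surfaces = cq.default_true_surfaces(noise_sd=0.09)
        truth = np.asarray(surfaces["t_e_bup"].beta)
        hits = total = 0
        for seed in range(500):
            table = cq.simulate_bbd_study({"t_e_bup": surfaces["t_e_bup"]}, seed=seed)
            fit = cq.fit_ols(table, "t_e_bup", "quadratic")
            se = np.sqrt(np.diag(fit.cov_beta))
            tcrit = stats.t.ppf(0.975, fit.dof)
            covered = np.abs(fit.beta - truth) <= tcrit * se
            hits += covered.sum()
            total += covered.size
        assert 0.92 <= hits / total <= 0.98


def test_sequential_order_report_flags_curvature_when_present(bbd_table):
    report = sequential_order_report(bbd_table, "t_e_bup")
    assert report.loc[1, "extra_p"] < 0.05  # quadratic terms needed
    lin_only = sequential_order_report(bbd_table, "t_b_imp3")
    assert lin_only.loc[1, "extra_p"] > 0.05  # linear model suffices
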