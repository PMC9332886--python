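"""OLS fitting and the validation battery against independent oracles."""

import numpy as np
import pytest

from pairqsar.errors import SingularDesignError, UndefinedStatisticError
from pairqsar.synthetic import make_planted
from pairqsar.validation import (
    applicability_domain,
    ccc,
    external_validation,
    fit_ols,
    golbraikh_tropsha,
    k_index,
    q2_lmo,
    q2_loo,
    q2_loo_brute,
    quik_check,
    rm2_metrics,
    y_randomization,
)


class TestFitOLS:
    def test_exact_linear_fit(self, rng):
        X = rng.standard_normal((20, 3))
        y = 2.0 + X @ np.array([1.0, -0.5, 0.3])
        m = fit_ols(X, y)
        assert m.r2 == pytest.approx(1.0)
        assert m.rss_tr == pytest.approx(0.0, abs=1e-18)

    def test_constant_response(self, rng):
        X = rng.standard_normal((15, 2))
        y = np.full(15, 3.3)
        m = fit_ols(X, y)
        assert (m.r2, m.f_stat) == (0.0, 0.0)

    def test_normal_equations_oracle(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        m = fit_ols(X, y)
        D = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        assert np.allclose(m.coefficients, beta[1:], atol=1e-10)
        # standard errors from the unbiased residual variance
        resid = y - D @ beta
        s2 = resid @ resid / (30 - 4)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(D.T @ D)))
        assert np.allclose(
            np.concatenate([[m.intercept_se], m.coefficient_se]), se, atol=1e-10
        )

    def test_singular_design_names_columns(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(SingularDesignError) as exc:
            fit_ols(X, rng.standard_normal(20), descriptor_names=["a", "b", "c"])
        assert "c" in exc.value.columns

    def test_fit_invariants(self, rng):
        X = rng.standard_normal((25, 4))
        y = X[:, 0] + 0.5 * rng.standard_normal(25)
        m = fit_ols(X, y)
        assert m.r2_adj <= m.r2
        assert m.rss_tr == pytest.approx(m.rmse_tr**2 * m.n_train)
        assert len(m.coefficients) == 4

    def test_equation_formats_and_parses_back(self, rng):
        from pairqsar.pipeline import parse_equation

        X = rng.standard_normal((25, 2))
        y = 1.0 + X @ np.array([2.0, -3.0]) + 0.1 * rng.standard_normal(25)
        m = fit_ols(X, y, descriptor_names=["alpha", "beta"])
        parsed = parse_equation(m.equation())
        assert parsed["intercept"] == pytest.approx(m.intercept, abs=5e-4)
        assert parsed["alpha"] == pytest.approx(m.coefficients[0], abs=5e-4)
        assert parsed["beta"] == pytest.approx(m.coefficients[1], abs=5e-4)


class TestQ2LOO:
    def test_deletion_identity_matches_brute_force(self, rng):
        X = rng.standard_normal((20, 4))
        y = X[:, 0] + rng.standard_normal(20)
        assert q2_loo(X, y)["q2_loo"] == pytest.approx(
            q2_loo_brute(X, y), abs=1e-10
        )

    def test_perfect_linear(self, rng):
        X = rng.standard_normal((15, 2))
        y = 1.0 + X @ np.array([1.0, 2.0])
        assert q2_loo(X, y)["q2_loo"] == pytest.approx(1.0)

    def test_pure_noise_q2_below_r2_and_nonpositive_mean(self):
        q2s, gaps = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((50, 3))
            y = rng.standard_normal(50)
            m = fit_ols(X, y)
            res = q2_loo(X, y)
            gaps.append(m.r2 - res["q2_loo"])
            q2s.append(res["q2_loo"])
        assert all(g > 0 for g in gaps)
        assert np.mean(q2s) <= 0

    def test_press_dominates_rss(self, rng):
        for _ in range(5):
            X = rng.standard_normal((25, 3))
            y = X[:, 1] + 0.5 * rng.standard_normal(25)
            assert q2_loo(X, y)["press"] >= fit_ols(X, y).rss_tr

    def test_zero_variance_response(self, rng):
        with pytest.raises(UndefinedStatisticError):
            q2_loo(rng.standard_normal((10, 2)), np.ones(10))


class TestQ2LMO:
    def test_exhaustive_loo_limit(self, rng):
        X = rng.standard_normal((20, 3))
        y = X[:, 0] + 0.3 * rng.standard_normal(20)
        assert q2_lmo(X, y, exhaustive_loo=True) == pytest.approx(
            q2_loo(X, y)["q2_loo"]
        )

    def test_close_to_loo_on_strong_signal(self):
        d = make_planted(n=67, p=5, k=5, target_r2=0.85, seed=4)
        loo = q2_loo(d.X, d.y)["q2_loo"]
        lmo = q2_lmo(d.X, d.y, leave_fraction=0.3, n_iter=500, seed=4)
        assert abs(lmo - loo) < 0.05

    def test_deterministic(self, rng):
        X = rng.standard_normal((30, 3))
        y = X[:, 0] + 0.3 * np.random.default_rng(0).standard_normal(30)
        assert q2_lmo(X, y, seed=9, n_iter=50) == q2_lmo(X, y, seed=9, n_iter=50)

    def test_infeasible_group_size(self, rng):
        X = rng.standard_normal((10, 5))
        y = rng.standard_normal(10)
        with pytest.raises(UndefinedStatisticError):
            q2_lmo(X, y, leave_fraction=0.9)


class TestCCC:
    def test_self_concordance(self, rng):
        x = rng.standard_normal(20)
        assert ccc(x, x) == pytest.approx(1.0)

    def test_shift_closed_form(self, rng):
        # for a pure location shift c: cov = var = S and the location
        # penalty is c^2, so CCC = 2S / (2S + c^2)
        x = rng.standard_normal(50)
        c = 1.7
        s = x.var()
        assert ccc(x, x + c) == pytest.approx(2 * s / (2 * s + c**2))

    def test_perfect_discordance(self, rng):
        x = rng.standard_normal(30)
        assert ccc(x, -x + 2 * x.mean()) == pytest.approx(-1.0)

    def test_bounded(self, rng):
        for _ in range(10):
            a, b = rng.standard_normal(15), rng.standard_normal(15)
            assert -1.0 <= ccc(a, b) <= 1.0


class TestExternal:
    def worked_vectors(self):
        y = np.array([6.1, 7.3, 5.8, 8.0, 6.9, 7.7, 5.2, 6.6])
        yhat = np.array([6.3, 7.0, 6.0, 7.7, 7.1, 7.4, 5.6, 6.4])
        return y, yhat

    def fitted_toy_model(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 1))
        y = 7.0 + X[:, 0]
        return fit_ols(X, y)

    def test_mean_prediction_zeroes_qf1(self):
        m = self.fitted_toy_model()
        # descriptor value whose prediction is exactly the training mean
        x_star = (m.y_train_mean - m.intercept) / m.coefficients[0]
        Xext = np.full((3, 1), x_star)
        yext = np.array([7.5, 6.5, 7.2])
        out = external_validation(m, Xext, yext)
        assert out["q2_f1"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_prediction(self):
        m = self.fitted_toy_model()
        Xext = np.array([[0.5], [-0.2], [1.1]])
        yext = m.predict(Xext)
        out = external_validation(m, Xext, yext)
        for key in ("q2_f1", "q2_f2", "q2_f3", "ccc_ex"):
            assert out[key] == pytest.approx(1.0)
        assert out["rm2_delta"] == pytest.approx(0.0, abs=1e-9)

    def test_worked_vectors_against_arithmetic_oracle(self):
        # spreadsheet-style recomputation with explicit sums
        y, f = self.worked_vectors()
        n = len(y)
        m = self.fitted_toy_model()
        ytr_mean, tss_tr, n_tr = m.y_train_mean, m.tss_tr, m.n_train
        press = sum((a - b) ** 2 for a, b in zip(f, y))
        qf1 = 1 - press / sum((a - ytr_mean) ** 2 for a in y)
        qf2 = 1 - press / sum((a - sum(y) / n) ** 2 for a in y)
        qf3 = 1 - (press / n) / (tss_tr / n_tr)

        # drive the model to emit exactly f: one descriptor = f - intercept
        Xext = (f - m.intercept)[:, None] / m.coefficients[0]
        out = external_validation(m, Xext, y)
        assert out["q2_f1"] == pytest.approx(qf1, abs=1e-10)
        assert out["q2_f2"] == pytest.approx(qf2, abs=1e-10)
        assert out["q2_f3"] == pytest.approx(qf3, abs=1e-10)
        # CCC by its definition with n-denominator moments
        cov = sum(
            (a - sum(y) / n) * (b - sum(f) / n) for a, b in zip(y, f)
        ) / n
        va = sum((a - sum(y) / n) ** 2 for a in y) / n
        vb = sum((b - sum(f) / n) ** 2 for b in f) / n
        ccc_expected = 2 * cov / (va + vb + (sum(y) / n - sum(f) / n) ** 2)
        assert out["ccc_ex"] == pytest.approx(ccc_expected, abs=1e-10)

    def test_rm2_and_gt_on_worked_vectors(self):
        y, f = self.worked_vectors()
        out = rm2_metrics(y, f)
        assert 0 <= out["rm2_avg"] <= 1
        assert out["rm2_delta"] >= 0
        gt = golbraikh_tropsha(y, f, q2_loo_value=0.8)
        assert gt["all_pass"] is True
        assert 0.85 <= gt["k"] <= 1.15

    def test_too_few_compounds(self):
        m = self.fitted_toy_model()
        with pytest.raises(UndefinedStatisticError):
            external_validation(m, np.zeros((2, 1)), np.array([1.0, 2.0]))


class TestYRandomization:
    def test_identity_permutation_reproduces_r2(self, rng):
        X = rng.standard_normal((30, 3))
        y = X[:, 0] + 0.3 * rng.standard_normal(30)
        m = fit_ols(X, y)
        out = y_randomization(X, y, permutations=[np.arange(30)])
        assert out["r2"][0] == pytest.approx(m.r2)

    def test_zero_iterations_flagged(self, rng):
        out = y_randomization(
            rng.standard_normal((10, 2)), rng.standard_normal(10), n_iter=0
        )
        assert out["no_op"] and len(out["r2"]) == 0

    def test_scrambled_r2_far_below_signal(self):
        d = make_planted(n=67, p=5, k=5, target_r2=0.85, seed=1)
        true_r2 = fit_ols(d.X, d.y).r2
        out = y_randomization(d.X, d.y, n_iter=200, seed=1)
        assert out["r2_mean"] < 0.2
        assert out["r2_max"] < true_r2


class TestQUIK:
    def test_identical_columns_extreme_k(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([x, x])
        assert k_index(X) == pytest.approx(1.0)
        out = quik_check(X, rng.standard_normal(20))
        assert out["pass"] is False

    def test_orthonormal_columns_zero_k(self):
        # exactly uncorrelated columns via Gram-Schmidt
        rng = np.random.default_rng(3)
        A = rng.standard_normal((40, 2))
        A -= A.mean(axis=0)
        A[:, 1] -= (A[:, 0] @ A[:, 1]) / (A[:, 0] @ A[:, 0]) * A[:, 0]
        assert k_index(A) == pytest.approx(0.0, abs=1e-12)

    def test_response_correlation_raises_k(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((40, 3))
        y = A[:, 0] + 0.1 * rng.standard_normal(40)
        out = quik_check(A, y)
        assert out["k_xxy"] > out["k_xx"]

    def test_constant_column_undefined(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        with pytest.raises(UndefinedStatisticError):
            k_index(X)


class TestApplicabilityDomain:
    def test_hat_trace_equals_p_plus_one(self, rng):
        X = rng.standard_normal((20, 3))
        y = X[:, 0] + 0.2 * rng.standard_normal(20)
        m = fit_ols(X, y)
        ad = applicability_domain(m, X, y)
        train = ad[ad.role == "train"]
        assert train.leverage.sum() == pytest.approx(4.0)

    def test_query_at_training_mean_has_minimal_leverage(self, rng):
        x = rng.standard_normal(25)
        x -= x.mean()  # centered single predictor
        y = 2 * x + 0.1 * rng.standard_normal(25)
        m = fit_ols(x[:, None], y)
        ad = applicability_domain(m, x[:, None], y, np.array([[0.0]]))
        q = ad[ad.role == "query"].iloc[0]
        assert q.leverage == pytest.approx(1.0 / 25)

    def test_far_point_flagged_x_outlier(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.standard_normal(9), [15.0]])
        y = 0.5 * x + 0.1 * rng.standard_normal(10)
        m = fit_ols(x[:, None], y)
        ad = applicability_domain(m, x[:, None], y)
        labels = list(ad.label)
        assert labels[9] in ("X_outlier", "XY_outlier")
        assert ad.attrs["h_star"] == pytest.approx(3 * 2 / 10)

    def test_every_compound_gets_one_label(self, rng):
        X = rng.standard_normal((30, 2))
        y = X[:, 0] + 0.3 * rng.standard_normal(30)
        m = fit_ols(X, y)
        ad = applicability_domain(m, X, y)
        assert set(ad.label) <= {
            "inside",
            "X_outlier",
            "Y_outlier",
            "XY_outlier",
            "model_outlier",
        }
        assert len(ad) == 30


class TestBatteryOrdering:
    def test_strong_signal_reproduces_statistic_ordering(self):
        # R2 > Q2_LOO >= Q2_LMO and CCC_tr > CCC_cv on a strong signal
        d = make_planted(n=67, p=5, k=5, target_r2=0.83, seed=6)
        m = fit_ols(d.X, d.y)
        loo = q2_loo(d.X, d.y)
        lmo = q2_lmo(d.X, d.y, n_iter=1000, seed=6)
        assert m.r2 > loo["q2_loo"] >= lmo
        assert m.ccc_tr > loo["ccc_cv"]
        assert loo["press"] >= m.rss_tr

    def test_parameter_recovery_coverage(self):
        from pairqsar.benchmark import parameter_recovery_experiment

        out = parameter_recovery_experiment(n_replicates=40, base_seed=7)
        assert out["min_coverage"] >= 0.85 * 40
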