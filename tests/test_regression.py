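import numpy as np
import pytest

from lcpmap import SparseModel, fit_sparse_model, select_penalty, truncate_confound
from lcpmap.regression import (
    PenaltySelector,
    _logistic_lasso_path,
    lambda_max,
    lambda_path,
)


def _orthogonal_design(rng, n, d):
    """Columns exactly orthogonal with unit sample SD (ddof=0)."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, d + 1)))
    Q = Q - Q.mean(axis=0)
    Q, _ = np.linalg.qr(Q)
    X = Q[:, :d]
    return X / X.std(axis=0, ddof=0)


class TestOrthogonalDesignOracle:
    def test_lasso_equals_soft_thresholding(self, rng):
        """Under an orthogonal standardized design the LASSO solution is the
        soft-thresholded per-component least-squares solution — the natural
        regime here, because the component scores U S have orthogonal
        columns."""
        n, d = 40, 6
        X = _orthogonal_design(rng, n, d)
        beta_true = np.array([3.0, -2.0, 1.0, 0.5, 0.0, 0.0])
        y = X @ beta_true + 0.1 * rng.standard_normal(n)
        for lam in (0.05, 0.3, 1.0):
            m = fit_sparse_model(X, None, y, "linear", lam)
            ols = X.T @ (y - y.mean()) / n
            expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            assert np.allclose(m.beta, expected, atol=1e-6)


class TestSelectPenalty:
    def test_null_response_one_se_rule_picks_path_top(self, rng):
        """With y independent of all predictors the conservative rule should
        land at (or near) the all-zero end of the path in >= 90% of runs."""
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            Z = r.standard_normal((80, 10))
            icv = np.exp(0.08 * r.standard_normal(80) + 14)
            y = r.standard_normal(80)
            Z_aug = np.column_stack([Z, icv])
            lam = select_penalty(Z_aug, y, "linear", rule="1se", seed=seed)
            m = fit_sparse_model(Z, icv, y, "linear", lam)
            hits += m.is_intercept_only
        assert hits >= 45

    def test_strong_signal_selects_correct_component(self, rng):
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            Z = r.standard_normal((100, 8))
            icv = np.exp(0.08 * r.standard_normal(100) + 14)
            y = 2.5 * Z[:, 0] + 0.3 * r.standard_normal(100)
            lam = select_penalty(np.column_stack([Z, icv]), y, "linear",
                                 rule="1se", seed=seed)
            m = fit_sparse_model(Z, icv, y, "linear", lam)
            assert m.beta[0] > 0

    def test_same_seed_same_lambda(self, rng):
        Z = rng.standard_normal((60, 6))
        y = Z[:, 1] + rng.standard_normal(60)
        lams = {select_penalty(Z, y, "linear", seed=42) for _ in range(3)}
        assert len(lams) == 1

    def test_degenerate_responses_rejected(self, rng):
        Z = rng.standard_normal((40, 4))
        with pytest.raises(ValueError, match="constant"):
            select_penalty(Z, np.ones(40), "linear", seed=0)
        with pytest.raises(ValueError, match="single class"):
            select_penalty(Z, np.zeros(40), "logistic", seed=0)


class TestFitSparseModel:
    def test_exact_linear_signal_recovered_at_small_lambda(self, rng):
        Z = rng.standard_normal((50, 5))
        y = 2.0 * Z[:, 0]
        m = fit_sparse_model(Z, None, y, "linear", 1e-6)
        assert m.beta[0] == pytest.approx(2.0, abs=1e-4)
        assert np.all(np.abs(np.delete(m.beta, 0)) < 1e-4)

    def test_lambda_max_gives_null_models(self, rng):
        Z = rng.standard_normal((60, 5))
        icv = np.exp(0.08 * rng.standard_normal(60) + 14)
        y = Z[:, 0] + rng.standard_normal(60)
        Xs = np.column_stack([Z, icv])
        Xs = Xs / Xs.std(axis=0, ddof=0)
        lmax = lambda_max(Xs, y, "linear")
        m = fit_sparse_model(Z, icv, y, "linear", lmax * 1.01)
        assert m.is_intercept_only
        assert m.intercept == pytest.approx(y.mean(), abs=1e-8)
        yb = (rng.random(60) < 0.3).astype(int)
        lmax_b = lambda_max(Xs, yb, "logistic")
        mb = fit_sparse_model(Z, icv, yb, "logistic", lmax_b * 1.01)
        assert mb.is_intercept_only
        base = yb.mean()
        assert mb.intercept == pytest.approx(np.log(base / (1 - base)), abs=1e-4)

    def test_stochastic_optimality_probe(self, rng):
        """The fitted coefficients should beat 1000 random perturbations of
        themselves on the penalized objective."""
        n, d = 30, 5
        Z = rng.standard_normal((n, d))
        y = Z[:, 0] - 0.5 * Z[:, 3] + 0.2 * rng.standard_normal(n)
        lam = 0.1
        m = fit_sparse_model(Z, None, y, "linear", lam)
        Zs = Z / Z.std(axis=0, ddof=0)
        beta_std = m.beta * Z.std(axis=0, ddof=0)

        def objective(b, b0):
            resid = y - Zs @ b - b0
            return 0.5 * np.mean(resid**2) + lam * np.sum(np.abs(b))

        base = objective(beta_std, m.intercept)
        for _ in range(1000):
            pert = beta_std + rng.normal(0, 0.01, size=d)
            assert objective(pert, m.intercept) >= base - 1e-9

    def test_penalty_monotone_sparsity(self, rng):
        Z = rng.standard_normal((80, 12))
        y = Z[:, 0] + 0.5 * Z[:, 5] + rng.standard_normal(80)
        Zs = Z / Z.std(axis=0, ddof=0)
        path = lambda_path(lambda_max(Zs, y, "linear"), 25, 1e-3)
        nnz = [fit_sparse_model(Z, None, y, "linear", lam).n_nonzero for lam in path]
        # path is descending in lambda, so the active set can only grow
        assert np.all(np.diff(nnz) >= 0)

    def test_json_round_trip(self, rng):
        Z = rng.standard_normal((40, 6))
        icv = np.exp(0.08 * rng.standard_normal(40) + 14)
        y = Z[:, 2] + 0.3 * rng.standard_normal(40)
        m = fit_sparse_model(Z, icv, y, "linear", 0.05, selection_rule="min")
        m2 = SparseModel.from_json(m.to_json())
        assert np.allclose(m.beta, m2.beta)
        assert m2.beta_icv == m.beta_icv and m2.lam == m.lam


class TestLogisticPath:
    def test_agrees_with_liblinear(self, rng):
        """Dual-route check of the warm-started IRLS path against an
        independent solver (liblinear at high precision)."""
        from sklearn.linear_model import LogisticRegression

        n, d = 150, 12
        X = rng.standard_normal((n, d))
        beta = np.zeros(d)
        beta[:3] = [1.2, -0.8, 0.5]
        p = 1 / (1 + np.exp(-(X @ beta - 0.4)))
        y = (rng.random(n) < p).astype(float)
        path = lambda_path(lambda_max(X, y, "logistic"), 12, 1e-2)
        coefs, b0s = _logistic_lasso_path(X, y, path)
        for i in (0, 4, 8, 11):
            ref = LogisticRegression(
                l1_ratio=1, C=1 / (n * path[i]), solver="liblinear",
                intercept_scaling=1e4, tol=1e-10, max_iter=100000,
            ).fit(X, y)
            assert np.allclose(coefs[:, i], ref.coef_.ravel(), atol=2e-5)
            assert b0s[i] == pytest.approx(float(ref.intercept_[0]), abs=1e-3)


class TestGramKernelEquivalence:
    def test_gram_kernel_matches_public_lasso_path(self, rng):
        """The warm-started Gram kernel must reproduce sklearn's lasso_path
        coefficients when run at a matched tight tolerance."""
        from sklearn.linear_model import lasso_path

        from lcpmap.regression import _gram_cd_path_warm

        n, d = 70, 12
        X = rng.standard_normal((n, d))
        y = X[:, 0] * 2 - X[:, 5] + rng.standard_normal(n)
        Xc = X - X.mean(axis=0)
        yc = np.ascontiguousarray(y - y.mean())
        path = lambda_path(np.max(np.abs(Xc.T @ yc)) / n, 25, 1e-3)
        mine = _gram_cd_path_warm(np.ascontiguousarray(Xc.T @ Xc), Xc.T @ yc,
                                  np.zeros(d), path * n, yc,
                                  tol=1e-10, max_iter=20000)
        _, ref, _ = lasso_path(Xc, yc, alphas=path, tol=1e-10, max_iter=20000)
        assert np.allclose(mine, ref, atol=1e-6)

    def test_selected_penalty_agrees_with_public_path_selection(self, rng):
        """Selection through the fast path must pick the same penalty as a
        reimplementation of the inner CV on sklearn's public lasso_path."""
        from sklearn.linear_model import lasso_path

        X = rng.standard_normal((80, 15))
        y = X[:, 0] * 2 + rng.standard_normal(80)
        sel = PenaltySelector(X, "linear", n_inner_folds=5, seed=0, n_lambda=30)
        path = lambda_path(lambda_max(sel.Xs, y, "linear"), 30, 1e-4)
        dev = np.empty((5, len(path)))
        for f, (tr, va) in enumerate(sel.splits):
            Xtr, ytr = sel.Xs[tr], y[tr]
            mu = Xtr.mean(axis=0)
            _, coefs, _ = lasso_path(Xtr - mu, ytr - ytr.mean(), alphas=path,
                                     max_iter=5000)
            pred = (sel.Xs[va] - mu) @ coefs + ytr.mean()
            dev[f] = ((y[va][:, None] - pred) ** 2).mean(axis=0)
        expected = float(path[int(np.argmin(dev.mean(axis=0)))])
        assert sel.select(y, rule="min") == pytest.approx(expected, rel=1e-9)


class TestTruncateConfound:
    def test_component_coefficients_pass_through(self):
        m = SparseModel("linear", [0.3, 0.0, -1.2], 0.5, 0.1, 0.2)
        assert np.array_equal(truncate_confound(m), [0.3, 0.0, -1.2])

    def test_zero_icv_coefficient_identity(self):
        m = SparseModel("linear", [1.0, 2.0], 0.0, 0.0, 0.1)
        assert np.array_equal(truncate_confound(m), m.beta)

    def test_logistic_truncation_unsupported(self):
        m = SparseModel("logistic", [0.5], 0.2, 0.0, 0.1)
        with pytest.raises(ValueError, match="linear"):
            truncate_confound(m)
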