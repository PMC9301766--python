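import numpy as np
import pytest
from sklearn.linear_model import Lasso

from panelnet import FitConfig, fit_clpn, fit_lasso, select_lambda, simulate_scenario
from tests.conftest import continuous_scenario


def standardized(X, y):
    Xc = X - X.mean(axis=0)
    Xs = Xc / Xc.std(axis=0)
    return Xs, y - y.mean()


def make_instance(seed, n=50, m=4, beta=None, sigma=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    if beta is None:
        beta = rng.normal(size=m)
    y = X @ beta + rng.normal(size=n) * sigma
    return X, y


class TestFitLasso:
    def test_unpenalized_fit_matches_least_squares(self):
        X, y = make_instance(0)
        fit = fit_lasso(y, X, 0.0)
        Xs, yc = standardized(X, y)
        ols = np.linalg.lstsq(Xs, yc, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols, atol=1e-6)
        assert fit.intercept == pytest.approx(y.mean())

    def test_entry_threshold_gives_exact_null_model(self):
        X, y = make_instance(1)
        Xs, yc = standardized(X, y)
        lmax = np.abs(Xs.T @ yc).max() / len(y)
        fit = fit_lasso(y, X, lmax * 1.0001)
        assert (fit.coef == 0.0).all()  # exact zeros, not small floats

    def test_matches_sklearn_lasso_on_unit_weights(self):
        """Independent solver cross-check: sklearn minimizes the identical
        (1/2n) least squares + alpha*L1 objective."""
        for seed in range(5):
            X, y = make_instance(seed, n=80, m=6)
            Xs, yc = standardized(X, y)
            lam = 0.08
            mine = fit_lasso(yc, Xs, lam, standardize=False)
            ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                        max_iter=100_000).fit(Xs, yc)
            np.testing.assert_allclose(mine.coef, ref.coef_, atol=1e-6)

    def test_unpenalized_covariate_survives_any_penalty(self):
        X, y = make_instance(2, m=5)
        w = np.array([1.0, 1.0, 1.0, 1.0, 0.0])
        fit = fit_lasso(y, X, 10.0, penalty_factors=w)
        assert (fit.coef[:4] == 0.0).all()
        assert fit.coef[4] != 0.0

    def test_zero_variance_predictor_warns_and_zeroes(self):
        X, y = make_instance(3)
        X[:, 2] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_lasso(y, X, 0.01)
        assert fit.coef[2] == 0.0
        assert fit.dropped == [2]

    def test_missing_values_rejected(self):
        X, y = make_instance(4)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            fit_lasso(y, X, 0.1)

    def test_kkt_conditions_hold(self):
        """Subgradient optimality on standardized designs: |g_j| <= lam*w_j
        at zeros, g_j = lam*w_j*sign(b_j) at nonzeros."""
        for seed in range(10):
            X, y = make_instance(seed + 20, n=60, m=5)
            Xs, yc = standardized(X, y)
            lam = 0.05
            fit = fit_lasso(yc, Xs, lam, standardize=False)
            g = Xs.T @ (yc - Xs @ fit.coef) / len(yc)
            for j in range(5):
                if fit.coef[j] == 0.0:
                    assert abs(g[j]) <= lam + 1e-6
                else:
                    assert g[j] == pytest.approx(lam * np.sign(fit.coef[j]),
                                                 abs=1e-6)


class TestSelectLambda:
    def test_same_fold_seed_selects_identical_lambda(self):
        X, y = make_instance(5, n=120, m=8)
        cfg = FitConfig(fold_seed=3)
        a = select_lambda(y, X, config=cfg)
        b = select_lambda(y, X, config=cfg)
        assert a.lam == b.lam
        np.testing.assert_array_equal(a.mean_mse, b.mean_mse)

    def test_pure_noise_selects_near_null_model(self):
        """Under a global null the one-standard-error rule keeps at most one
        spurious predictor in the vast majority of replicates."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 10))
            y = rng.normal(size=200)
            sel = select_lambda(y, X, config=FitConfig(fold_seed=seed))
            fit = fit_lasso(y, X, sel.lam)
            hits += (fit.coef != 0).sum() <= 1
        assert hits >= 0.8 * n_rep

    def test_strong_signal_always_recovered(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(100, 6))
            y = X[:, 2] + rng.normal(size=100) * 0.1
            sel = select_lambda(y, X, config=FitConfig(fold_seed=seed))
            fit = fit_lasso(y, X, sel.lam)
            hits += fit.coef[2] != 0
        assert hits == 50

    def test_cv_1se_never_below_cv_min(self):
        X, y = make_instance(6, n=150, m=8)
        lam_min = select_lambda(y, X, config=FitConfig(lambda_rule="cv_min")).lam
        lam_1se = select_lambda(y, X, config=FitConfig(lambda_rule="cv_1se")).lam
        assert lam_1se >= lam_min


class TestFitCLPN:
    def test_missing_cells_rejected(self, study_panel):
        data, _ = study_panel
        with pytest.raises(ValueError, match="impute"):
            fit_clpn(data)

    def test_edge_structure_is_bit_reproducible(self, small_completed_panel):
        data, _ = small_completed_panel
        cfg = FitConfig(fold_seed=9)
        a = fit_clpn(data, cfg)
        b = fit_clpn(data, cfg)
        np.testing.assert_array_equal(a.B, b.B)
        np.testing.assert_array_equal(a.lambdas, b.lambdas)

    def test_standardized_weights_invariant_to_affine_rescaling(
        self, small_completed_panel
    ):
        data, _ = small_completed_panel
        cfg = FitConfig(fold_seed=4)
        base = fit_clpn(data, cfg)
        rescaled = data.take(range(data.n))
        rescaled.X1[:, 0] = 10.0 * rescaled.X1[:, 0] - 3.0
        rescaled.X2[:, 1] = 0.25 * rescaled.X2[:, 1] + 7.0
        other = fit_clpn(rescaled, cfg)
        np.testing.assert_allclose(other.B, base.B, atol=1e-8)

    def test_autoregressive_only_truth_recovered_on_diagonal(self):
        """Truth with diagonal 0.5 and no cross-lagged edges; residual sd
        set so wave-2 variances are unit and the standardized diagonal
        equals the generating value."""
        diags = []
        for seed in range(10):
            cfg = continuous_scenario(
                seed, n=1000, p=6, density=1e-9,
                auto_range=(0.4999999, 0.5000001),
                sigma=float(np.sqrt(1 - 0.25)),
            )
            data, truth = simulate_scenario(cfg)
            # cv_min keeps shrinkage bias small for point recovery
            net = fit_clpn(data, FitConfig(fold_seed=seed,
                                           lambda_rule="cv_min"))
            off = ~np.eye(6, dtype=bool)
            assert (truth.B_true[off] == 0).all()
            diags.append(net.autoregressive().mean())
        assert 0.35 <= np.mean(diags) <= 0.55

    def test_small_sample_warning_recorded(self):
        data, _ = simulate_scenario(continuous_scenario(3, n=10, p=10))
        net = fit_clpn(data, FitConfig(n_folds=2, lambda_rule="fixed",
                                       fixed_lambda=0.2))
        assert any("penalty" in w for w in net.warnings_)

    def test_covariate_block_shapes(self, study_panel):
        from panelnet import random_forest_impute
        data, _ = study_panel
        res = random_forest_impute(data.item_matrix(), trees=20, seed=0)
        p = data.p
        completed = data.take(range(data.n))
        completed.X1[:] = res.completed[:, :p]
        completed.X2[:] = res.completed[:, p:]
        net = fit_clpn(completed, FitConfig(n_folds=5, n_lambdas=40))
        c = completed.expand_covariates()[0].shape[1]
        assert net.G.shape == (c, p)
        assert len(net.covariate_names) == c
        assert net.edge_list(include_covariates=True)["type"].isin(
            ["autoregressive", "cross-lagged", "covariate"]
        ).all()
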