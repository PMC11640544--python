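"""Box-Cox transform, exact ridge solution, penalty selection, per-drug
training, and patient imputation."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from reposcreen import SimulationConfig
from reposcreen.imputation import (DEFAULT_LAMBDA_GRID, PowerTransformParams,
                                   apply_power_transform, boxcox_grid_llf,
                                   fit_power_transform, fit_ridge, impute,
                                   select_lambda, train_all_drugs)
from reposcreen.pipeline import run_screen
from reposcreen.synthetic import (SENSITIVE, generate_cell_line_panel,
                                  generate_patient_cohort)


class TestPowerTransform:
    def test_llf_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.normal(1.0, 0.5, 200))
        lams = np.array([-1.5, -0.3, 0.0, 0.4, 1.0, 2.0])
        ours = boxcox_grid_llf(y, lams)
        ref = np.array([stats.boxcox_llf(l, y) for l in lams])
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_gaussian_data_gives_lambda_near_one(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10.0, 3.0, 500)
        params = fit_power_transform(y)
        assert abs(params.lam - 1.0) < 0.25

    def test_lognormal_data_gives_lambda_near_zero(self):
        rng = np.random.default_rng(2)
        y = np.exp(rng.normal(1.0, 0.4, 500))
        params = fit_power_transform(y)
        assert abs(params.lam) < 0.15

    def test_shift_makes_values_positive(self):
        y = np.array([0.0, 0.5, 1.0] * 5)
        params = fit_power_transform(y)
        assert params.shift > 0
        assert np.all(y + params.shift > 0)
        apply_power_transform(y, params)  # must not raise

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_power_transform(np.full(20, 3.0))

    def test_identity_and_log_closed_forms(self):
        y = np.array([0.5, 1.0, np.e, 4.0])
        ident = apply_power_transform(y, PowerTransformParams(lam=1.0))
        np.testing.assert_allclose(ident, y - 1.0)
        logged = apply_power_transform(y, PowerTransformParams(lam=0.0))
        np.testing.assert_allclose(logged, np.log(y))
        assert logged[2] == pytest.approx(1.0)

    @given(lam=st.floats(-2, 2), shift=st.floats(0, 2))
    @settings(max_examples=50, deadline=None)
    def test_transform_is_strictly_increasing(self, lam, shift):
        params = PowerTransformParams(lam=round(lam, 3), shift=shift)
        y = np.linspace(0.1, 20.0, 50)
        t = apply_power_transform(y, params)
        assert np.all(np.diff(t) > 0)


class TestRidge:
    def _system(self, seed, n=30, p=10):
        rng = np.random.default_rng(seed)
        X = rng.normal(5, 2, (n, p))
        y = rng.normal(0, 1, n) + X[:, 0]
        return X, y

    def test_huge_penalty_shrinks_to_mean(self):
        X, y = self._system(0)
        fit = fit_ridge(X, y, 1e12)
        assert np.max(np.abs(fit.beta)) < 1e-9
        Z = (X - fit.gene_means) / fit.gene_sds
        np.testing.assert_allclose(fit.intercept + Z @ fit.beta,
                                   np.full(len(y), y.mean()), atol=1e-6)

    def test_zero_penalty_matches_ols_normal_equations(self):
        X, y = self._system(1, n=40, p=8)
        fit = fit_ridge(X, y, 0.0)
        Z = (X - X.mean(0)) / X.std(0)
        beta_ols = np.linalg.solve(Z.T @ Z, Z.T @ (y - y.mean()))
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)

    def test_toy_system_matches_direct_inversion(self):
        X, y = self._system(2, n=5, p=3)
        fit = fit_ridge(X, y, 1.0)
        Z = (X - X.mean(0)) / X.std(0)
        expected = np.linalg.solve(Z.T @ Z + np.eye(3), Z.T @ (y - y.mean()))
        np.testing.assert_allclose(fit.beta, expected, atol=1e-10)

    def test_matches_sklearn_reference(self):
        from sklearn.linear_model import Ridge

        X, y = self._system(3, n=50, p=12)
        lam = 4.2
        fit = fit_ridge(X, y, lam)
        Z = (X - X.mean(0)) / X.std(0)
        ref = Ridge(alpha=lam, fit_intercept=True).fit(Z, y)
        np.testing.assert_allclose(fit.beta, ref.coef_, atol=1e-8)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_normal_equations_residual_is_tiny(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(5, 30), rng.integers(2, 10)
        X = rng.normal(0, 1, (int(n), int(p)))
        y = rng.normal(0, 1, int(n))
        lam = float(rng.uniform(0, 10))
        fit = fit_ridge(X, y, lam)
        Z = (X - fit.gene_means) / fit.gene_sds
        resid = (Z.T @ Z + lam * np.eye(int(p))) @ fit.beta \
            - Z.T @ (y - y.mean())
        assert np.max(np.abs(resid)) < 1e-8

    def test_negative_penalty_and_tiny_sample_rejected(self):
        X, y = self._system(4)
        with pytest.raises(ValueError):
            fit_ridge(X, y, -1.0)
        with pytest.raises(ValueError):
            fit_ridge(X[:1], y[:1], 1.0)


class TestSelectLambda:
    def test_noiseless_response_picks_grid_minimum(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (60, 10))
        w = rng.normal(0, 1, 10)
        y = X @ w
        lam = select_lambda(X, y, seed=0)
        assert lam == min(DEFAULT_LAMBDA_GRID)

    def test_pure_noise_wide_design_prefers_large_penalty(self):
        grid = np.asarray(DEFAULT_LAMBDA_GRID)
        median = np.median(grid)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (20, 50))
            y = rng.normal(0, 1, 20)
            if select_lambda(X, y, k_folds=5, seed=seed) >= median:
                hits += 1
        assert hits >= 16

    def test_same_seed_same_choice(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (40, 15))
        y = rng.normal(0, 1, 40)
        assert select_lambda(X, y, seed=3) == select_lambda(X, y, seed=3)

    def test_bad_grid_and_degenerate_folds_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (10, 3))
        y = rng.normal(0, 1, 10)
        with pytest.raises(ValueError):
            select_lambda(X, y, grid=[1.0], seed=0)
        with pytest.raises(ValueError):
            select_lambda(X, y, grid=[-1.0, 1.0], seed=0)
        with pytest.raises(ValueError):
            select_lambda(X, y, k_folds=11, seed=0)


def _small_training(seed=0, n_drugs=3, noise_sd=0.0):
    cfg = SimulationConfig(n_genes=30, n_cell_lines=60, n_drugs=n_drugs,
                           n_causal_genes_per_drug=3, noise_sd=noise_sd,
                           seed=seed)
    expr, auc, truth = generate_cell_line_panel(cfg)
    return cfg, expr, auc, truth


class TestTrainAllDrugs:
    def test_drugs_below_min_lines_are_skipped(self):
        _, expr, auc, _ = _small_training()
        auc = auc.copy()
        auc.iloc[25:, 0] = np.nan  # first drug keeps 25 lines only
        bundle = train_all_drugs(expr, auc, min_lines=30)
        assert auc.columns[0] in bundle.skipped
        assert len(bundle.models) == 2

    def test_noiseless_training_fit_is_perfect(self):
        _, expr, auc, _ = _small_training(noise_sd=0.0)
        bundle = train_all_drugs(expr, auc, lambda_grid=[1e-8, 1e-6],
                                 power_transform=False)
        scores = impute(bundle, expr)
        for d in bundle.drugs:
            r2 = np.corrcoef(scores[d], auc[d])[0, 1] ** 2
            assert r2 > 1.0 - 1e-6

    def test_cell_line_order_invariance(self):
        _, expr, auc, _ = _small_training(seed=3)
        perm = np.random.default_rng(0).permutation(expr.shape[1])
        bundle_a = train_all_drugs(expr, auc, seed=9)
        bundle_b = train_all_drugs(expr.iloc[:, perm], auc.iloc[perm[::-1]],
                                   seed=9)
        for d in bundle_a.drugs:
            np.testing.assert_allclose(bundle_a.models[d].fit.beta,
                                       bundle_b.models[d].fit.beta,
                                       atol=1e-10)

    def test_all_drugs_too_sparse_is_an_error(self):
        _, expr, auc, _ = _small_training()
        with pytest.raises(ValueError):
            train_all_drugs(expr, auc, min_lines=10_000)


class TestImpute:
    def test_training_line_reproduces_its_own_response(self):
        _, expr, auc, _ = _small_training(seed=5, noise_sd=0.0)
        bundle = train_all_drugs(expr, auc, lambda_grid=[1e-10, 1e-8],
                                 power_transform=False)
        scores = impute(bundle, expr[[expr.columns[0]]])
        for d in bundle.drugs:
            assert scores.loc[expr.columns[0], d] == pytest.approx(
                auc.loc[expr.columns[0], d], abs=1e-4)

    def test_zeroed_coefficients_give_constant_intercept(self):
        _, expr, auc, _ = _small_training(seed=6)
        bundle = train_all_drugs(expr, auc, power_transform=False)
        d = bundle.drugs[0]
        bundle.models[d].fit.beta[:] = 0.0
        scores = impute(bundle, expr)
        np.testing.assert_allclose(scores[d].values,
                                   bundle.models[d].fit.intercept)

    def test_missing_training_gene_named(self):
        _, expr, auc, _ = _small_training(seed=7)
        bundle = train_all_drugs(expr, auc)
        with pytest.raises(ValueError, match=expr.index[0]):
            impute(bundle, expr.iloc[1:])

    def test_gene_and_sample_order_invariance(self):
        _, expr, auc, _ = _small_training(seed=8)
        bundle = train_all_drugs(expr, auc)
        rng = np.random.default_rng(1)
        shuffled = expr.iloc[rng.permutation(expr.shape[0]),
                             rng.permutation(expr.shape[1])]
        a = impute(bundle, expr)
        b = impute(bundle, shuffled)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


@pytest.fixture(scope="module")
def big_screen():
    cfg = SimulationConfig(n_cell_lines=400, seed=42)
    return run_screen(cfg, cohort_seed=43, cv_seed=0)


class TestGenerativeRecovery:
    """Imputation must rediscover the generating model through the whole
    preprocessing chain.

    Recovery is measured at 400 training lines for 500 genes: with fewer
    lines than genes, ridge can only recover the row-space projection of
    the causal coefficients (correlation capped near sqrt(n/p)), so the
    n > p regime is where fidelity is diagnostic.
    """

    def test_mean_imputed_vs_true_response_correlation(self, big_screen):
        res = big_screen
        clean = res.truth.remove_batch(res.patient_expr)
        true_resp = res.truth.implied_response(clean)
        cors = [np.corrcoef(res.scores[d], true_resp[d])[0, 1]
                for d in res.scores.columns]
        assert float(np.nanmean(cors)) > 0.7

    def test_planted_drug_detected_through_transcriptome(self, big_screen):
        res = big_screen
        planted = res.truth.planted_drug
        sens = res.scores.loc[res.labels == SENSITIVE, planted]
        other = res.scores.loc[res.labels != SENSITIVE, planted]
        assert sens.mean() < other.mean()
        clean = res.truth.remove_batch(res.patient_expr)
        true_resp = res.truth.implied_response(clean)[planted]
        rho = stats.spearmanr(res.scores[planted], true_resp).statistic
        assert rho > 0.7

    def test_monotone_transform_preserves_training_ranking(self, big_screen):
        res = big_screen
        d = res.truth.planted_drug
        model = res.bundle.models[d]
        y = res.auc[d].dropna()
        t = apply_power_transform(y.values, model.transform)
        assert stats.spearmanr(y.values, t).statistic == pytest.approx(1.0)
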