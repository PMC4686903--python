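"""Design matrices, regression fits, correlation matrix, column rules."""

import numpy as np
import pytest

from metimpute import (
    NRMImputer,
    build_design,
    correlation_R,
    impute_cells_nrm,
    impute_column_avg,
    impute_column_linreg,
    nrm_gibbs,
    nrm_mle,
    standardize,
)
from metimpute.core import METArray, StandardizedMET
from metimpute.nrm import CorrelationR, NrmParams, average_residual_sd


def _std(values: np.ndarray) -> StandardizedMET:
    I, J, K = values.shape
    return StandardizedMET(
        values.astype(float),
        np.isfinite(values),
        np.zeros((J, K)),
        np.ones((J, K)),
        [f"G{i}" for i in range(I)],
        [f"E{j}" for j in range(J)],
        [f"A{k}" for k in range(K)],
    )


@pytest.fixture
def std632():
    rng = np.random.default_rng(8)
    return _std(rng.normal(size=(6, 3, 2)))


class TestBuildDesign:
    @pytest.mark.parametrize("option,expected_n", [(1, 5), (2, 4), (3, 5), (4, 1)])
    def test_column_counts(self, std632, option, expected_n):
        R = correlation_R(std632)
        d = build_design(std632, (1, 0), option, R)
        assert d.n == expected_n

    def test_option4_columns_verbatim(self, std632):
        d = build_design(std632, (1, 0), 4)
        np.testing.assert_array_equal(d.matrix[:, 0], std632.values[:, 1, 1])

    def test_masked_cell_is_zero(self, std632):
        std632.values[2, 0, 1] = np.nan
        std632.mask[2, 0, 1] = False
        d = build_design(std632, (1, 0), 1)
        # wide column of (j=0, k=1) survives the drop of target (1, 0)
        assert 0.0 in d.matrix[2]
        cols_with_zero = np.flatnonzero(d.matrix[2] == 0.0)
        assert cols_with_zero.size >= 1

    def test_option3_scales_within_environment_columns(self, std632):
        R = correlation_R(std632)
        d1 = build_design(std632, (1, 0), 1)
        d3 = build_design(std632, (1, 0), 3, R)
        r = R.get(1, 0, 1)
        # the env-1 other-attribute column is rescaled by r, rest untouched
        diff = np.abs(d3.matrix - d1.matrix).sum(axis=0)
        changed = np.flatnonzero(diff > 1e-12)
        assert changed.size == 1
        np.testing.assert_allclose(
            d3.matrix[:, changed[0]], d1.matrix[:, changed[0]] * r
        )

    def test_option3_requires_R(self, std632):
        with pytest.raises(ValueError, match="correlation matrix"):
            build_design(std632, (1, 0), 3, None)


class TestNrmMLE:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        b = np.array([1.0, -2.0, 0.5])
        p = nrm_mle(X @ b, X)
        np.testing.assert_allclose(p.beta_hat, b, atol=1e-10)
        assert p.sigma2_hat == pytest.approx(0.0, abs=1e-18)

    def test_single_column_slope(self):
        p = nrm_mle(np.array([2.0, 4.0, 6.0]), np.array([[1.0], [2.0], [3.0]]))
        assert p.beta_hat[0] == pytest.approx(2.0)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        p = nrm_mle(y, X)
        beta_ref = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(p.beta_hat, beta_ref, atol=1e-10)
        rss = float((y - X @ beta_ref) @ (y - X @ beta_ref))
        assert p.sigma2_hat == pytest.approx(rss / (20 - 2))

    def test_observed_rows_only_and_minimum(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 2))
        y = X @ np.array([1.0, 1.0])
        y[4] = np.nan
        p = nrm_mle(y, X)
        assert p.n_obs == 5
        with pytest.raises(ValueError, match="3 observed"):
            nrm_mle(np.array([1.0, 2.0, np.nan, np.nan]), np.ones((4, 1)))


class TestNrmGibbs:
    def test_flat_prior_limit_approaches_mle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = X @ np.array([0.5, -1.0, 2.0]) + 0.3 * rng.normal(size=40)
        mle = nrm_mle(y, X)
        g = nrm_gibbs(y, X, tau2=1e8, n_samples=20_000, burn_in=1_000, random_state=0)
        np.testing.assert_allclose(g.beta_hat, mle.beta_hat, atol=0.05)

    def test_parameter_recovery_within_posterior_sd(self):
        rng = np.random.default_rng(5)
        n = 200
        X = rng.normal(size=(n, 4))
        b = np.array([1.0, -0.5, 0.0, 2.0])
        sigma = 0.7
        y = X @ b + sigma * rng.normal(size=n)
        g = nrm_gibbs(y, X, n_samples=4_000, burn_in=500, random_state=1)
        post_sd = sigma / np.sqrt(n)  # approximate scale of the posterior
        assert np.all(np.abs(g.beta_hat - b) < 3 * post_sd + 0.05)
        assert g.sigma2_hat == pytest.approx(sigma**2, rel=0.3)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        a = nrm_gibbs(y, X, n_samples=150, burn_in=50, random_state=9)
        b2 = nrm_gibbs(y, X, n_samples=150, burn_in=50, random_state=9)
        np.testing.assert_array_equal(a.beta_hat, b2.beta_hat)
        assert a.sigma2_hat == b2.sigma2_hat


class TestImputeCells:
    def test_zero_variance_deterministic(self):
        p = NrmParams(np.array([2.0]), 0.0, "mle", 5)
        vals = impute_cells_nrm(p, np.array([[3.0]]), random_state=0)
        assert vals[0] == pytest.approx(6.0)

    def test_zero_design_row_pure_noise(self):
        p = NrmParams(np.array([2.0]), 4.0, "mle", 5)
        draws = np.array(
            [impute_cells_nrm(p, np.zeros((1, 1)), random_state=s)[0] for s in range(4000)]
        )
        assert draws.mean() == pytest.approx(0.0, abs=0.1)
        assert draws.std() == pytest.approx(2.0, abs=0.1)

    def test_mean_converges_to_linear_prediction(self):
        p = NrmParams(np.array([1.0, 1.0]), 1.0, "mle", 5)
        Xm = np.array([[1.0, 2.0]])
        rng_draws = [impute_cells_nrm(p, Xm, random_state=s)[0] for s in range(4000)]
        assert np.mean(rng_draws) == pytest.approx(3.0, abs=0.08)


class TestCorrelationR:
    def test_duplicated_attribute_gives_one(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(8, 3))
        vals = np.stack([base, base], axis=2)  # two identical attributes
        std = _std(vals)
        R = correlation_R(std)
        np.testing.assert_allclose(R.matrix[:, R.slot(0, 1)], 1.0)

    def test_wholly_missing_column_row_is_nan(self, std632):
        std632.values[:, 2, 1] = np.nan
        std632.mask[:, 2, 1] = False
        R = correlation_R(std632)
        assert np.isnan(R.get(2, 0, 1))

    def test_hand_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        vals = np.stack([x, y], axis=1)[:, None, :]  # (5, 1, 2)
        vals = np.concatenate([vals, vals], axis=1)  # J=2 copies
        std = _std(vals)
        R = correlation_R(std)
        expect = np.corrcoef(x, y)[0, 1]
        assert R.get(0, 0, 1) == pytest.approx(expect)

    def test_short_pair_warns_nan(self):
        vals = np.random.default_rng(0).normal(size=(5, 2, 2))
        vals[2:, 0, 1] = np.nan
        std = _std(vals)
        with pytest.warns(UserWarning, match="jointly"):
            R = correlation_R(std)
        assert np.isnan(R.get(0, 0, 1))


class TestColumnRules:
    def test_perfect_correlation_copies_other_attribute(self):
        rng = np.random.default_rng(9)
        col = rng.normal(size=6)
        vals = np.empty((6, 3, 2))
        for j in range(3):
            base = rng.normal(size=6)
            vals[:, j, 0] = base
            vals[:, j, 1] = 2.0 * base  # r = 1 everywhere
        vals[:, 0, 1] = np.nan
        std = _std(vals)
        std.values[:, 0, 0] = col
        R = correlation_R(std)
        got = impute_column_avg(std, (0, 1), R, sigma_bar=0.0, noise=False)
        np.testing.assert_allclose(got, col, atol=1e-10)  # K=2: rbar=1, pred = x(j,0)

    def test_zero_correlation_predicts_zero(self):
        K = 3
        R = CorrelationR(np.zeros((4, K * (K - 1) // 2)), K)
        vals = np.random.default_rng(1).normal(size=(5, 4, K))
        vals[:, 1, 2] = np.nan
        std = _std(vals)
        got = impute_column_avg(std, (1, 2), R, sigma_bar=0.0, noise=False)
        np.testing.assert_allclose(got, 0.0)

    def test_avg_rule_hand_evaluation(self):
        # 3 environments, 3 attributes; correlations fixed by hand
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(4, 3, 3))
        vals[:, 0, 2] = np.nan
        std = _std(vals)
        K = 3
        mat = np.array(
            [
                [0.1, np.nan, np.nan],  # row j'=0: pairs (0,1), (0,2), (1,2)
                [0.2, 0.5, 0.7],
                [0.3, 0.9, 0.5],
            ]
        )
        R = CorrelationR(mat, K)
        got = impute_column_avg(std, (0, 2), R, sigma_bar=0.0, noise=False)
        rbar02 = (0.5 + 0.9) / 2
        rbar12 = (0.7 + 0.5) / 2
        expect = (rbar02 * std.values[:, 0, 0] + rbar12 * std.values[:, 0, 1]) / (K - 1)
        np.testing.assert_allclose(got, expect)

    def test_linreg_identical_rows_reduces_to_avg(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 4, 3))
        vals[:, 1, 0] = np.nan
        std = _std(vals)
        K = 3
        common = np.array([0.4, 0.6, 0.2])
        mat = np.tile(common, (4, 1))
        mat[1, [0, 1]] = np.nan  # pairs involving attribute 0 in env 1
        R = CorrelationR(mat, K)
        a = impute_column_avg(std, (1, 0), R, sigma_bar=0.0, noise=False)
        b = impute_column_linreg(std, (1, 0), R, sigma_bar=0.0, noise=False)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_linreg_recovers_exact_linear_structure(self):
        # row j' = 0.5 * donor rows on the observed slots
        K = 3
        base = np.array([0.8, 0.4, 0.6])  # pairs (0,1), (0,2), (1,2)
        mat = np.vstack([base, base, 0.5 * base])
        mat[2, [1, 2]] = np.nan  # pairs involving attribute 2 in env 2
        vals = np.random.default_rng(4).normal(size=(5, 3, 3))
        vals[:, 2, 2] = np.nan
        std = _std(vals)
        R = CorrelationR(mat, K)
        from metimpute.nrm import _linreg_correlations

        rhat = _linreg_correlations(R, 2, 2)
        # observed slot (0,1) = 0.5*0.8 against donors 0.8 -> slope 0.5
        np.testing.assert_allclose(rhat[[0, 1]], 0.5 * base[[1, 2]], atol=1e-12)

    def test_column_rule_errors(self, std632):
        R = correlation_R(std632)
        vals = np.random.default_rng(5).normal(size=(6, 3, 1))
        single = _std(vals)
        with pytest.raises(ValueError, match="2 attributes"):
            impute_column_avg(single, (0, 0), R, 0.0)


class TestNRMImputer:
    def test_same_seed_identical(self, masked_sim):
        masked, _, _ = masked_sim
        a = NRMImputer(n_imputations=4, random_state=5).fit(masked)
        b = NRMImputer(n_imputations=4, random_state=5).fit(masked)
        np.testing.assert_array_equal(a.estimates_, b.estimates_)

    @pytest.mark.parametrize("method", ["mle", "gibbs"])
    @pytest.mark.parametrize("design", [1, 2, 3, 4])
    def test_all_designs_complete(self, masked_sim, method, design):
        masked, _, _ = masked_sim
        imp = NRMImputer(
            design=design, method=method, n_imputations=2,
            gibbs_samples=120, burn_in=20, random_state=1,
        ).fit(masked)
        assert np.isfinite(imp.estimate_mean_).all()

    def test_mean_estimate_converges_to_regression_prediction(self, masked_sim):
        masked, _, _ = masked_sim
        imp = NRMImputer(design=4, method="mle", n_imputations=600, random_state=0).fit(masked)
        # pick a missing cell (not in the wholly missing column)
        from metimpute.base import pattern_from_mask

        pat = pattern_from_mask(masked.mask)
        t = sorted(pat.cells)[0]
        m = list(map(tuple, imp.missing_indices_)).index(t)
        R = correlation_R(masked)
        d = build_design(masked, (t[1], t[2]), 4, R)
        p = nrm_mle(masked.values[:, t[1], t[2]], d)
        pred = d.matrix[t[0]] @ p.beta_hat
        se = np.sqrt(p.sigma2_hat / 600)
        assert imp.estimates_[:, m].mean() == pytest.approx(pred, abs=4 * se + 1e-6)

    def test_sigma_bar_from_option4_fits(self, masked_sim):
        masked, _, _ = masked_sim
        sbar = average_residual_sd(masked)
        assert sbar > 0
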