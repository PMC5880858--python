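import numpy as np
import pytest
import statsmodels.api as sm

from netpredict.data import MixedDataset, VariableSpec, center_continuous
from netpredict.nodewise import (
    ConstantColumnError,
    default_lambda_path,
    encode_predictors,
    fit_node,
    select_lambda,
)
from netpredict.simulate import SimulationSpec, gaussian_specs, sample_ggm


class TestEncode:
    def test_mixed_column_count(self, mixed3):
        # predictors of node 1: one gaussian + one gaussian -> 2 columns;
        # predictors of node 0: gaussian + categorical K=2 -> 1 + 2 columns
        X, bmap, _ = encode_predictors(mixed3, 0)
        assert X.shape[1] == 3
        assert [(j, sl.stop - sl.start) for j, sl in bmap] == [(1, 2), (2, 1)]

    def test_all_gaussian_count(self, gauss4):
        X, bmap, _ = encode_predictors(gauss4, 2)
        assert X.shape[1] == 3
        assert [j for j, _ in bmap] == [0, 1, 3]

    def test_indicator_coding_is_overparameterized(self, mixed3):
        X, bmap, _ = encode_predictors(mixed3, 0)
        ind = X[:, bmap[0][1]]
        assert np.all(ind.sum(axis=1) == 1)  # one indicator per level, no reference

    def test_constant_column_error(self):
        d = MixedDataset(
            np.column_stack([np.arange(5.0), np.ones(5), np.arange(5.0) ** 2]),
            [VariableSpec("a", "gaussian"), VariableSpec("b", "gaussian"),
             VariableSpec("c", "gaussian")],
        )
        with pytest.raises(ConstantColumnError, match="'b'"):
            encode_predictors(d, 2)

    def test_single_level_categorical_error(self):
        d = MixedDataset(
            np.column_stack([np.arange(5.0), np.ones(5)]),
            [VariableSpec("a", "gaussian"), VariableSpec("b", "categorical", 2)],
        )
        with pytest.raises(ConstantColumnError):
            encode_predictors(d, 0)

    def test_standardized_columns_unit_variance(self, gauss4):
        X, _, scales = encode_predictors(gauss4, 0, standardize=True)
        assert np.allclose(X.std(axis=0), 1.0)
        assert np.all(scales > 0)


class TestGaussianFit:
    def test_lambda_zero_matches_ols(self):
        """Unpenalized nodewise fit equals the closed-form least-squares
        solution (independent oracle: statsmodels OLS)."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 2))
        y = 0.6 * X[:, 0] - 0.3 * X[:, 1] + rng.normal(size=200)
        d = MixedDataset(np.column_stack([y, X]), gaussian_specs(3))
        d = center_continuous(d)
        m = fit_node(d, 0, lambda_path=np.array([0.0]), cv_folds=2, seed=0)
        ols = sm.OLS(d.values[:, 0], sm.add_constant(d.values[:, 1:])).fit()
        assert abs(float(m.intercepts) - ols.params[0]) < 1e-6
        assert abs(m.coef_blocks[1][0] - ols.params[1]) < 1e-6
        assert abs(m.coef_blocks[2][0] - ols.params[2]) < 1e-6

    def test_strong_effect_recovered(self):
        """Y = 0.8 X + noise: CV-selected lasso coefficient within 0.1."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        z = rng.normal(size=2000)
        y = 0.8 * x + 0.6 * rng.normal(size=2000)
        d = center_continuous(
            MixedDataset(np.column_stack([y, x, z]), gaussian_specs(3)))
        m = fit_node(d, 0, cv_folds=10, seed=3)
        assert abs(m.coef_blocks[1][0] - 0.8) < 0.1
        assert m.lambda_selected in m.lambda_path

    def test_pure_noise_target_all_zero(self):
        """A target independent of all predictors gets an empty
        neighborhood at the CV-selected penalty."""
        rng = np.random.default_rng(2)
        d = center_continuous(
            MixedDataset(rng.normal(size=(1000, 4)), gaussian_specs(4)))
        m = fit_node(d, 0, cv_folds=10, seed=5)
        assert m.neighborhood() == []

    def test_residual_scale_stored(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = 0.8 * x + 0.6 * rng.normal(size=500)
        d = center_continuous(
            MixedDataset(np.column_stack([y, x]), gaussian_specs(2)))
        m = fit_node(d, 0, cv_folds=5, seed=0)
        assert 0.5 < m.residual_scale < 0.7


class TestCategoricalFit:
    @pytest.fixture()
    def logistic_data(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 2))
        logit = 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = (rng.random(200) < 1 / (1 + np.exp(-logit))).astype(float) + 1
        specs = [VariableSpec("t", "categorical", 2),
                 VariableSpec("a", "gaussian"), VariableSpec("b", "gaussian")]
        return center_continuous(
            MixedDataset(np.column_stack([y, X]), specs))

    def test_lambda_zero_matches_mnlogit_probabilities(self, logistic_data):
        """Unpenalized multinomial fit agrees with the Newton-solved
        statsmodels MNLogit on predicted probabilities (coefficients are
        only identified up to a per-predictor shift at lambda = 0)."""
        from netpredict.predict import predict_categorical_node

        d = logistic_data
        m = fit_node(d, 0, lambda_path=np.array([0.0]), cv_folds=2, seed=0)
        probs, _ = predict_categorical_node(
            m, {1: d.values[:, 1], 2: d.values[:, 2]})
        ref = sm.MNLogit(d.values[:, 0] - 1,
                         sm.add_constant(d.values[:, 1:])).fit(disp=0)
        ref_p = ref.predict()
        assert np.max(np.abs(probs - ref_p)) < 1e-4

    def test_symmetric_representation(self, logistic_data):
        """Binary blocks use the over-parameterized coding with one row per
        category, opposite in sign."""
        m = fit_node(logistic_data, 0, cv_folds=5, seed=1)
        for b in m.coef_blocks.values():
            assert b.shape == (2, 1)
            assert np.allclose(b[0], -b[1], atol=1e-10)

    def test_missing_target_level_rejected(self):
        values = np.column_stack([np.ones(20), np.arange(20.0)])
        d = MixedDataset(values, [VariableSpec("t", "categorical", 3),
                                  VariableSpec("a", "gaussian")])
        with pytest.raises(ValueError, match="levels"):
            fit_node(d, 0, cv_folds=2, seed=0)


class TestPathAndSelection:
    def test_sparsity_monotone_along_path(self):
        """The number of active coefficients never grows as the penalty
        grows along the solver path."""
        from sklearn.linear_model import lasso_path

        spec = SimulationSpec(specs=gaussian_specs(6), n=300, seed=9,
                              precision=np.eye(6) * 1.0)
        omega = np.eye(6)
        for i in range(5):
            omega[i, i + 1] = omega[i + 1, i] = -0.3
        spec.precision = omega
        d = center_continuous(sample_ggm(spec))
        X, _, _ = encode_predictors(d, 0, standardize=True)
        y = d.values[:, 0]
        path = default_lambda_path(X, y, "gaussian")
        _, coefs, _ = lasso_path(X - X.mean(0), y - y.mean(), alphas=path)
        nnz = (np.abs(coefs) > 0).sum(axis=0)  # path ordered high -> low lambda
        assert np.all(np.diff(nnz) >= 0)

    def test_path_spans_lambda_max(self, gauss4):
        d = center_continuous(gauss4)
        X, _, _ = encode_predictors(d, 0, standardize=True)
        path = default_lambda_path(X, d.values[:, 0], "gaussian")
        assert len(path) == 50
        assert np.all(np.diff(path) < 0)
        assert np.isclose(path[-1], path[0] * 1e-4)

    def test_selection_rules(self):
        path = np.array([1.0, 0.5, 0.25, 0.125])
        losses = np.array([[4.0, 2.0, 1.0, 1.05],
                           [4.2, 2.1, 1.1, 1.15],
                           [3.8, 1.9, 0.9, 0.95]])
        assert select_lambda(path, losses, "min") == 0.25
        # 1se picks the most regularized lambda within one SE of the minimum
        assert select_lambda(path, losses, "1se") >= 0.25

    def test_cv_folds_bounds(self, gauss4):
        with pytest.raises(ValueError, match="cv_folds"):
            fit_node(center_continuous(gauss4), 0, cv_folds=1)
        with pytest.raises(ValueError, match="exceeds"):
            fit_node(center_continuous(gauss4), 0, cv_folds=51)
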