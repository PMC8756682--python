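"""OLS and ML spatial-model fitting, likelihood identities, AIC ranking."""

import numpy as np
import pytest

from spatialepi import (DesignMatrix, compare_models, fit_ols,
                        fit_spatial_error, fit_spatial_lag, make_grid_frame,
                        queen_adjacency, row_standardize, simulate_sem,
                        simulate_slm)
from spatialepi.errors import CollinearityError, FormatError
from spatialepi.regression import (sem_concentrated_loglik,
                                   slm_concentrated_loglik)


@pytest.fixture(scope="module")
def lattice_20x20():
    frame = make_grid_frame(20, 20)
    return row_standardize(queen_adjacency(frame))


@pytest.fixture(scope="module")
def design_20x20(lattice_20x20):
    rng = np.random.default_rng(99)
    n = lattice_20x20.n
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    return X


def _design(X, y, name="y"):
    return DesignMatrix(outcome_name=name,
                        predictor_names=[f"x{i}" for i in range(1, X.shape[1])],
                        y=y, X=X)


class TestOls:
    def test_exact_noiseless_fit(self):
        x = np.arange(10, dtype=float)
        y = 3.0 + 2.0 * x
        res = fit_ols(_design(np.column_stack([np.ones(10), x]), y))
        assert res.coefficients["intercept"].estimate == pytest.approx(3.0)
        assert res.coefficients["x1"].estimate == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        n, p = 50, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        y = rng.normal(size=n)
        res = fit_ols(_design(X, y))
        closed_form = np.linalg.solve(X.T @ X, X.T @ y)
        got = np.array([res.coefficients[name].estimate
                        for name in ["intercept", "x1", "x2", "x3"]])
        np.testing.assert_allclose(got, closed_form, atol=1e-10)

    def test_duplicated_column_rejected(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, x])
        with pytest.raises(CollinearityError) as err:
            _design(X, rng.normal(size=30))
        assert "x1" in err.value.columns or "x2" in err.value.columns

    def test_aic_identity(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        res = fit_ols(_design(X, rng.normal(size=40)))
        assert res.aic == pytest.approx(2 * res.k - 2 * res.log_likelihood,
                                        abs=1e-9)


class TestSpatialLag:
    def test_recovers_delta_on_average(self, lattice_20x20, design_20x20):
        beta = np.array([0.0, 1.0, 2.0])
        estimates, b1, b2 = [], [], []
        for s in range(50):
            y = simulate_slm(lattice_20x20, design_20x20, beta, 0.5, 1.0,
                             seed=5000 + s)
            res = fit_spatial_lag(lattice_20x20, _design(design_20x20, y))
            estimates.append(res.spatial_parameter[1].estimate)
            b1.append(res.coefficients["x1"].estimate)
            b2.append(res.coefficients["x2"].estimate)
        assert abs(np.mean(estimates) - 0.5) < 0.05
        for sample, true in ((b1, 1.0), (b2, 2.0)):
            mc_se = np.std(sample, ddof=1) / np.sqrt(len(sample))
            assert abs(np.mean(sample) - true) < 3 * mc_se

    def test_null_data_close_to_ols(self, lattice_20x20, design_20x20):
        beta = np.array([1.0, 1.0, 2.0])
        deltas = []
        for s in range(20):
            y = simulate_slm(lattice_20x20, design_20x20, beta, 0.0, 1.0,
                             seed=6000 + s)
            design = _design(design_20x20, y)
            slm = fit_spatial_lag(lattice_20x20, design)
            ols = fit_ols(design)
            deltas.append(slm.spatial_parameter[1].estimate)
            for name in ("x1", "x2"):
                diff = abs(slm.coefficients[name].estimate
                           - ols.coefficients[name].estimate)
                assert diff < 2 * ols.coefficients[name].se
        assert abs(np.mean(deltas)) < 0.08

    def test_concentrated_loglik_at_zero_equals_ols(self, lattice_20x20,
                                                    design_20x20, rng):
        design = _design(design_20x20, rng.normal(size=400))
        ols = fit_ols(design)
        assert slm_concentrated_loglik(lattice_20x20, design, 0.0) == \
            pytest.approx(ols.log_likelihood, abs=1e-9)

    def test_logdet_matches_dense_determinant(self):
        weights = row_standardize(queen_adjacency(make_grid_frame(5, 5)))
        dense = weights.matrix.toarray()
        evals = weights.eigenvalues()
        for delta in (-0.3, 0.4, 0.9):
            via_eigs = np.sum(np.log(1.0 - delta * evals))
            sign, via_dense = np.linalg.slogdet(np.eye(25) - delta * dense)
            assert sign == 1.0
            assert abs(via_eigs - via_dense) < 1e-8

    def test_delta_inside_admissible_interval(self, lattice_20x20,
                                              design_20x20):
        y = simulate_slm(lattice_20x20, design_20x20,
                         np.array([0.0, 1.0, 2.0]), 0.8, 1.0, seed=1)
        res = fit_spatial_lag(lattice_20x20, _design(design_20x20, y))
        lo, hi = lattice_20x20.spatial_parameter_interval()
        assert lo < res.spatial_parameter[1].estimate < hi

    def test_perfect_fit_rejected(self, lattice_20x20, design_20x20):
        """An outcome that is an exact linear combination of the predictors
        has an unbounded ML likelihood and must be refused, not fitted."""
        from spatialepi.errors import DegenerateInputError
        noiseless = _design(design_20x20[:, :2],
                            design_20x20 @ np.array([1.0, 2.0, 0.0]))
        with pytest.raises(DegenerateInputError, match="residual variance"):
            fit_spatial_lag(lattice_20x20, noiseless)
        with pytest.raises(DegenerateInputError, match="residual variance"):
            fit_spatial_error(lattice_20x20, noiseless)


class TestSpatialError:
    def test_recovers_lambda_on_average(self, lattice_20x20, design_20x20):
        beta = np.array([0.0, 1.0, 2.0])
        estimates = []
        for s in range(50):
            y = simulate_sem(lattice_20x20, design_20x20, beta, 0.7, 1.0,
                             seed=7000 + s)
            res = fit_spatial_error(lattice_20x20, _design(design_20x20, y))
            estimates.append(res.spatial_parameter[1].estimate)
        assert abs(np.mean(estimates) - 0.7) < 0.05

    def test_null_limit_matches_ols_loglik(self, lattice_20x20, design_20x20):
        beta = np.array([1.0, 1.0, 2.0])
        lambdas = []
        for s in range(20):
            y = simulate_sem(lattice_20x20, design_20x20, beta, 0.0, 1.0,
                             seed=8000 + s)
            design = _design(design_20x20, y)
            ols = fit_ols(design)
            assert sem_concentrated_loglik(lattice_20x20, design, 0.0) == \
                pytest.approx(ols.log_likelihood, abs=1e-6)
            lambdas.append(fit_spatial_error(lattice_20x20, design)
                           .spatial_parameter[1].estimate)
        assert abs(np.mean(lambdas)) < 0.08

    def test_spatial_fit_never_below_its_null_point(self, lattice_20x20,
                                                    design_20x20, rng):
        design = _design(design_20x20, rng.normal(size=400) * 2 + 50)
        ols = fit_ols(design)
        for fit in (fit_spatial_lag, fit_spatial_error):
            res = fit(lattice_20x20, design)
            assert res.log_likelihood >= ols.log_likelihood - 1e-9

    def test_requires_row_standardized_weights(self, design_20x20, rng):
        binary = queen_adjacency(make_grid_frame(20, 20))
        design = _design(design_20x20, rng.normal(size=400))
        with pytest.raises(FormatError, match="row-standardized"):
            fit_spatial_error(binary, design)


class TestCompareModels:
    def test_ranked_by_ascending_aic(self, lattice_20x20, design_20x20):
        y = simulate_sem(lattice_20x20, design_20x20,
                         np.array([0.0, 1.0, 2.0]), 0.7, 1.0, seed=42)
        design = _design(design_20x20, y)
        table = compare_models([fit_ols(design),
                                fit_spatial_lag(lattice_20x20, design),
                                fit_spatial_error(lattice_20x20, design)])
        assert list(table["aic"]) == sorted(table["aic"])

    def test_sem_wins_on_sem_generated_data(self, lattice_20x20,
                                            design_20x20):
        beta = np.array([0.0, 1.0, 2.0])
        wins = 0
        for s in range(50):
            y = simulate_sem(lattice_20x20, design_20x20, beta, 0.7, 1.0,
                             seed=9000 + s)
            design = _design(design_20x20, y)
            table = compare_models([fit_ols(design),
                                    fit_spatial_lag(lattice_20x20, design),
                                    fit_spatial_error(lattice_20x20, design)])
            wins += table["model"].iloc[0] == "sem"
        assert wins >= 40  # >= 80% of replicates

    def test_mismatched_n_rejected(self, lattice_20x20, design_20x20, rng):
        small = row_standardize(queen_adjacency(make_grid_frame(5, 5)))
        X_small = np.column_stack([np.ones(25), rng.normal(size=25)])
        a = fit_ols(_design(design_20x20, rng.normal(size=400)))
        b = fit_ols(_design(X_small, rng.normal(size=25)))
        with pytest.raises(FormatError, match="mismatched n"):
            compare_models([a, b])

    def test_mismatched_outcome_rejected(self, design_20x20, rng):
        y = rng.normal(size=400)
        a = fit_ols(_design(design_20x20, y, name="a"))
        b = fit_ols(_design(design_20x20, y, name="b"))
        with pytest.raises(FormatError, match="outcome"):
            compare_models([a, b])

    def test_pseudo_r2_in_unit_interval(self, lattice_20x20, design_20x20):
        y = simulate_slm(lattice_20x20, design_20x20,
                         np.array([0.0, 1.0, 2.0]), 0.5, 1.0, seed=3)
        res = fit_spatial_lag(lattice_20x20, _design(design_20x20, y))
        assert res.r2_kind == "pseudo_r2"
        assert 0.0 <= res.r2 <= 1.0
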