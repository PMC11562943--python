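"""LASSO linear probability model and .632 bootstrap penalty selection."""

import numpy as np
import pandas as pd
import pytest

from straticare.prognostic import (
    Dot632Point,
    LambdaGrid,
    dot632_error,
    fit_lasso,
    predict_score,
    select_lambda,
)
from straticare.synthetic import CohortConfig, generate_cohort
from straticare.cohort import encode_cohort, impute_missing


def _toy_design(n=60, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.array([1.0, -0.5, 0.0, 0.25])
    y = 0.3 + X @ beta + rng.normal(0, 0.1, n)
    return X, y


# ---------------------------------------------------------------------------
# fit_lasso


def test_full_shrinkage_gives_intercept_only():
    X, y = _toy_design()
    lam_max = np.abs(((X - X.mean(0)) / X.std(0)).T @ (y - y.mean())).max() / len(y)
    model = fit_lasso(X, y, lam_max * 1.01)
    assert all(w == 0.0 for w in model.coefficients.values())
    assert model.intercept == pytest.approx(y.mean())
    assert model.nonzero_features == []


def test_unpenalized_fit_matches_closed_form_ols():
    """lambda = 0 reduces to least squares; oracle is the normal-equations
    solve on the raw (unstandardised) design."""
    X, y = _toy_design(n=40, p=4, seed=3)
    Z = np.column_stack([np.ones(len(y)), X])
    coef_ols = np.linalg.solve(Z.T @ Z, Z.T @ y)
    model = fit_lasso(X, y, 0.0)
    assert model.intercept == pytest.approx(coef_ols[0], abs=1e-8)
    got = [model.coefficients[f"x{j}"] for j in range(4)]
    assert got == pytest.approx(list(coef_ols[1:]), abs=1e-8)


def test_orthonormal_design_matches_soft_threshold_oracle():
    """With standardised orthogonal predictors the LASSO solution is the
    soft-thresholded OLS coefficient, computed here in closed form."""
    rng = np.random.default_rng(8)
    n = 256
    A = rng.normal(size=(n, 3))
    Q, _ = np.linalg.qr(A - A.mean(0))
    X = Q * np.sqrt(n)  # columns: mean ~0, variance 1, orthogonal
    beta = np.array([0.8, -0.3, 0.05])
    y = 0.1 + X @ beta
    lam = 0.2
    rho = X.T @ (y - y.mean()) / n
    expected = np.sign(rho) * np.maximum(np.abs(rho) - lam, 0.0)
    model = fit_lasso(X, y, lam)
    sd = X.std(0)
    got_std_scale = np.array([model.coefficients[f"x{j}"] for j in range(3)]) * sd
    assert got_std_scale == pytest.approx(expected, abs=1e-4)


def test_constant_design_yields_intercept_only_without_error():
    X = np.ones((30, 2))
    y = np.repeat([0.0, 1.0], 15)
    model = fit_lasso(X, y, 0.01)
    assert all(w == 0.0 for w in model.coefficients.values())
    assert model.intercept == pytest.approx(0.5)


def test_mismatched_lengths_error():
    with pytest.raises(ValueError, match="rows"):
        fit_lasso(np.ones((5, 2)), np.ones(4), 0.01)


def test_l1_norm_shrinks_as_lambda_grows():
    X, y = _toy_design(n=120, seed=5)
    lams = np.geomspace(1e-4, 1.0, 12)
    norms = [sum(abs(w) for w in fit_lasso(X, y, lam).coefficients.values()) for lam in lams]
    assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


def test_recovers_strong_signal_and_zeroes_nulls():
    """On generator data where only the initial score drives the outcome,
    a moderate penalty keeps that coefficient and drops the null features."""
    cfg = CohortConfig(
        n_clients=2000, seed=7,
        true_coefficients={"PHQ9": {"initial_score": 0.4}, "GAD7": {"initial_score": 0.4}},
        noise_sd={"PHQ9": 2.0, "GAD7": 2.0},
    )
    records, truth = generate_cohort(cfg)
    X = impute_missing(encode_cohort(records, "PHQ9"))
    y = truth.true_rcsi["PHQ9"].astype(float)
    model = fit_lasso(X, y, 0.02)
    assert model.coefficients["initial_score"] > 0
    nulls = [v for k, v in model.coefficients.items() if k != "initial_score"]
    assert np.mean([v == 0.0 for v in nulls]) > 0.8


# ---------------------------------------------------------------------------
# predict_score


def test_constant_model_scores_intercept():
    X, y = _toy_design()
    model = fit_lasso(X, y, 1e9)
    scores = predict_score(model, X)
    assert np.allclose(scores, model.intercept)


def test_score_arithmetic():
    from straticare.prognostic import FittedLassoModel

    model = FittedLassoModel(instrument="PHQ9", intercept=0.4,
                             coefficients={"initial_score": 0.02}, lambda_selected=0.0)
    assert predict_score(model, {"initial_score": 15.0})[0] == pytest.approx(0.7)


def test_score_ranking_matches_dot_product_oracle(small_cohort):
    records, truth = small_cohort
    X = impute_missing(encode_cohort(records, "GAD7"))
    y = truth.true_rcsi["GAD7"].astype(float)
    model = fit_lasso(X, y, 0.01)
    scores = predict_score(model, X)
    beta = np.array([model.coefficients[c] for c in X.columns])
    oracle = model.intercept + X.to_numpy() @ beta
    assert np.array_equal(np.argsort(scores, kind="stable"),
                          np.argsort(oracle, kind="stable"))
    assert scores == pytest.approx(oracle)


def test_missing_feature_names_listed():
    from straticare.prognostic import FittedLassoModel

    model = FittedLassoModel(instrument="PHQ9", intercept=0.0,
                             coefficients={"a": 1.0, "b": 2.0}, lambda_selected=0.0)
    with pytest.raises(ValueError, match="b"):
        predict_score(model, pd.DataFrame({"a": [1.0]}))


def test_unclipped_by_default_clipped_on_request():
    from straticare.prognostic import FittedLassoModel

    model = FittedLassoModel(instrument="PHQ9", intercept=1.5,
                             coefficients={"a": 0.0}, lambda_selected=0.0)
    x = pd.DataFrame({"a": [0.0]})
    assert predict_score(model, x)[0] == pytest.approx(1.5)
    assert predict_score(model, x, clip=True)[0] == 1.0


def test_logistic_family_scores_are_probabilities():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(400, 3))
    y = (rng.random(400) < 1 / (1 + np.exp(-(0.5 + X @ np.array([1.0, -0.5, 0.0]))))).astype(float)
    model = fit_lasso(X, y, 0.01, family="logistic")
    scores = predict_score(model, X)
    assert np.all((scores > 0) & (scores < 1))


def test_unpenalized_logistic_matches_statsmodels_mle():
    """family='logistic' at lambda=0 agrees with an independent maximum-
    likelihood fit."""
    import statsmodels.api as sm

    rng = np.random.default_rng(15)
    X = rng.normal(size=(500, 2))
    eta = 0.3 + X @ np.array([0.8, -0.6])
    y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
    model = fit_lasso(X, y, 0.0, family="logistic")
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert model.intercept == pytest.approx(ref.params[0], abs=5e-3)
    assert model.coefficients["x0"] == pytest.approx(ref.params[1], abs=5e-3)
    assert model.coefficients["x1"] == pytest.approx(ref.params[2], abs=5e-3)


def test_unknown_family_rejected():
    X, y = _toy_design()
    with pytest.raises(ValueError, match="family"):
        fit_lasso(X, y, 0.01, family="probit")


# ---------------------------------------------------------------------------
# .632 bootstrap


def test_err632_weighted_sum_arithmetic():
    assert Dot632Point(0.1, 0.2).err632 == pytest.approx(0.1632)


def test_zero_error_limit():
    """A noiseless linear outcome at lambda=0 gives apparent error 0 and
    near-zero out-of-bag error."""
    rng = np.random.default_rng(2)
    X = rng.normal(size=(80, 2))
    y = 0.2 + X @ np.array([0.5, -0.25])
    res = dot632_error(X, y, 0.0, B=30, seed=1)
    assert res.apparent_error == pytest.approx(0.0, abs=1e-12)
    assert res.oob_error < 1e-10
    assert res.err632 < 1e-10


def test_bootstrap_iteration_count_convergence():
    """Doubling B moves err632 by no more than the Monte-Carlo noise
    implied by the bootstrap replicate spread."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(150, 3))
    y = (rng.random(150) < 0.4).astype(float)
    a = dot632_error(X, y, 0.01, B=1000, seed=0)
    b = dot632_error(X, y, 0.01, B=500, seed=1)
    # replicate-level SD of oob MSE is ~ mse * sqrt(2/oob_n); be generous
    tol = 3 * a.oob_error * np.sqrt(2 / 150) * (1 / np.sqrt(500))
    assert abs(a.err632 - b.err632) < max(tol * 10, 0.01)


def test_err632_between_apparent_and_oob(small_cohort):
    records, truth = small_cohort
    X = impute_missing(encode_cohort(records, "PHQ9"))
    y = truth.true_rcsi["PHQ9"].astype(float)
    _, curve = select_lambda(X, y, LambdaGrid(n_points=8), B=25, seed=3)
    lo = np.minimum(curve.apparent_error, curve.oob_error)
    hi = np.maximum(curve.apparent_error, curve.oob_error)
    assert np.all(curve.err632 >= lo - 1e-12) and np.all(curve.err632 <= hi + 1e-12)
    assert np.allclose(curve.err632, 0.368 * curve.apparent_error + 0.632 * curve.oob_error)


def test_singleton_grid_selects_its_only_point():
    X, y = _toy_design()
    lam, curve = select_lambda(X, y, [0.01], B=10, seed=0)
    assert lam == 0.01
    assert curve.lambdas.tolist() == [0.01]


def test_select_lambda_consistent_with_pointwise_dot632():
    """The curve equals per-lambda dot632_error calls at the same seed
    (the bootstrap draws are lambda-independent)."""
    X, y = _toy_design(n=100)
    grid = LambdaGrid(n_points=5)
    _, curve = select_lambda(X, y, grid, B=20, seed=6)
    for k, lam in enumerate(grid.values()):
        pt = dot632_error(X, y, float(lam), B=20, seed=6)
        # single-lambda refits agree with the warm-started path up to the
        # coordinate-descent solver tolerance
        assert pt.apparent_error == pytest.approx(curve.apparent_error[k], rel=1e-4)
        assert pt.oob_error == pytest.approx(curve.oob_error[k], rel=1e-4)


def test_select_lambda_reproducible():
    X, y = _toy_design(n=100)
    a = select_lambda(X, y, LambdaGrid(n_points=6), B=15, seed=4)
    b = select_lambda(X, y, LambdaGrid(n_points=6), B=15, seed=4)
    assert a[0] == b[0]
    assert np.array_equal(a[1].err632, b[1].err632)


def test_pure_noise_selects_sparse_upper_grid():
    """With no signal the selector prefers heavy shrinkage: over repeated
    seeds the chosen lambda mostly falls in the upper half of the grid
    with a near-empty support."""
    rng = np.random.default_rng(10)
    X = rng.normal(size=(1000, 10))
    y = (rng.random(1000) < 0.5).astype(float)
    grid = LambdaGrid(n_points=10)
    upper, sparse = 0, 0
    for seed in range(5):
        lam, _ = select_lambda(X, y, grid, B=40, seed=seed)
        model = fit_lasso(X, y, lam)
        upper += lam >= np.median(grid.values())
        sparse += len(model.nonzero_features) <= 2
    assert upper >= 3
    assert sparse >= 3


def test_invalid_grid_rejected():
    with pytest.raises(ValueError):
        LambdaGrid(lower=0.1, upper=0.01)
    with pytest.raises(ValueError):
        LambdaGrid(n_points=1)
    with pytest.raises(ValueError):
        dot632_error(np.ones((5, 1)), np.ones(5), 0.01, B=0)
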