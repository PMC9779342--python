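import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskshare.design import AnalysisConfig, StudyDesign, VariableSpec
from riskshare.ridge import (
    NearCancellationError,
    RidgeProblem,
    cv_select_lambda,
    fit_ridge,
    lambda_grid,
    learn_category_weights,
    normalize_weights,
)


def random_problem(rng, n=30, p=12, n_unpenalized=3, noise=1.0):
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    penalized = np.arange(p) >= n_unpenalized
    return RidgeProblem(X, y, penalized)


def ridge_objective(problem, lam, intercept, gamma):
    resid = problem.y - intercept - problem.X @ gamma
    pf = problem.penalized.astype(float)
    n = len(problem.y)
    return float((resid**2).sum() / (2 * n) + lam * (pf * gamma**2).sum())


def test_lambda_zero_reproduces_ols(rng):
    problem = random_problem(rng, n=40, p=6)
    b0, g = fit_ridge(problem, 0.0)
    M = np.column_stack([np.ones(40), problem.X])
    ols = np.linalg.lstsq(M, problem.y, rcond=None)[0]
    np.testing.assert_allclose(np.r_[b0, g], ols, atol=1e-10)


def test_single_penalized_predictor_closed_form(rng):
    """One standardized penalized predictor: gamma = x'y / (x'x + 2 n lam)
    on centered data, from differentiating the stated objective."""
    n = 50
    x = rng.standard_normal(n)
    y = 0.7 * x + rng.standard_normal(n)
    xc = x - x.mean()
    yc = y - y.mean()
    problem = RidgeProblem(x[:, None], y, np.array([True]))
    for lam in [0.0, 0.05, 0.3, 2.0]:
        _, g = fit_ridge(problem, lam)
        expected = (xc @ yc) / (xc @ xc + 2 * n * lam)
        np.testing.assert_allclose(g[0], expected, rtol=1e-12)


def test_huge_lambda_zeroes_penalized_block_only(rng):
    problem = random_problem(rng, n=60, p=8, n_unpenalized=3)
    b0, g = fit_ridge(problem, 1e8)
    assert np.all(np.abs(g[problem.penalized]) < 1e-6)
    Xs = problem.X[:, :3]
    M = np.column_stack([np.ones(60), Xs])
    ols = np.linalg.lstsq(M, problem.y, rcond=None)[0]
    np.testing.assert_allclose(np.r_[b0, g[:3]], ols, atol=1e-5)


def test_fit_matches_numerical_minimizer(rng):
    from scipy.optimize import minimize

    for _ in range(5):
        problem = random_problem(rng, n=30, p=10, n_unpenalized=4)
        lam = float(rng.uniform(0.01, 1.0))
        b0, g = fit_ridge(problem, lam)

        def obj(theta):
            return ridge_objective(problem, lam, theta[0], theta[1:])

        res = minimize(obj, np.zeros(11), method="BFGS", tol=1e-14)
        np.testing.assert_allclose(np.r_[b0, g], res.x, atol=1e-6)
        assert ridge_objective(problem, lam, b0, g) <= res.fun + 1e-10


def test_shrinkage_monotone_in_lambda(rng):
    problem = random_problem(rng, n=50, p=10)
    lams = np.geomspace(1e-4, 10, 12)
    norms = [np.linalg.norm(fit_ridge(problem, lam)[1][problem.penalized])
             for lam in lams]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


# -- lambda grid ------------------------------------------------------------


def test_grid_log_spacing_and_descending(rng):
    problem = random_problem(rng)
    grid = lambda_grid(problem, n_lambda=3, min_ratio=0.01)
    np.testing.assert_allclose(grid[1] / grid[0], 0.1, rtol=1e-12)
    np.testing.assert_allclose(grid[2] / grid[1], 0.1, rtol=1e-12)
    full = lambda_grid(problem, n_lambda=100, min_ratio=1e-4)
    assert np.all(np.diff(full) < 0)
    np.testing.assert_allclose(full[0], np.max(
        np.abs((problem.X - problem.X.mean(0)).T[problem.penalized]
               @ (problem.y - problem.y.mean()))) / 30, rtol=1e-12)


def test_grid_positive_for_orthogonal_response(rng):
    X = rng.standard_normal((40, 3))
    Q, _ = np.linalg.qr(np.column_stack([np.ones(40), X]))
    y = rng.standard_normal(40)
    y = y - Q @ (Q.T @ y)  # empirically orthogonal to X and constant
    problem = RidgeProblem(X, y, np.array([True] * 3))
    grid = lambda_grid(problem, 10, 1e-2)
    assert np.all(grid > 0)


def test_grid_rejects_constant_penalized_block():
    X = np.column_stack([np.ones(20), np.ones(20) * 2.0])
    problem = RidgeProblem(X, np.arange(20.0), np.array([True, True]))
    with pytest.raises(ValueError):
        lambda_grid(problem)


# -- cross-validation -------------------------------------------------------


def test_cv_deterministic_given_seed(rng):
    problem = random_problem(rng, n=60)
    grid = lambda_grid(problem, 30, 1e-3)
    assert cv_select_lambda(problem, 10, grid, 7) == cv_select_lambda(
        problem, 10, grid, 7
    )


def test_cv_prefers_small_lambda_under_strong_signal(rng):
    X = rng.standard_normal((100, 5))
    y = X @ np.array([1.0, -2.0, 1.5, 0.5, -1.0])  # noiseless
    problem = RidgeProblem(X, y, np.ones(5, bool))
    grid = lambda_grid(problem, 100, 1e-4)
    lam = cv_select_lambda(problem, 10, grid, 3)
    assert lam <= grid[89]  # smallest decile of the descending grid


def test_cv_prefers_shrinkage_under_pure_noise(rng):
    X = rng.standard_normal((100, 5))
    y = rng.standard_normal(100)
    problem = RidgeProblem(X, y, np.ones(5, bool))
    grid = lambda_grid(problem, 100, 1e-4)
    lam = cv_select_lambda(problem, 10, grid, 3)
    assert lam >= grid[49]  # larger half of the descending grid


def test_cv_rejects_tiny_folds(rng):
    problem = random_problem(rng, n=12, p=2, n_unpenalized=0)
    with pytest.raises(ValueError):
        cv_select_lambda(problem, 10, np.array([0.1, 0.01]), 0)


# -- weight normalization ---------------------------------------------------


def test_all_zero_coefficients_give_uniform_weights():
    w, fb = normalize_weights(np.zeros(3))
    np.testing.assert_allclose(w, [1 / 3] * 3)
    assert fb == "all_zero"


def test_signed_sum_normalization_examples():
    w, fb = normalize_weights(np.array([2.0, 1.0, 1.0]))
    np.testing.assert_allclose(w, [0.5, 0.25, 0.25])
    assert fb is None
    # sign-mixed coefficients: weights sum to 1 but leave [-1, 1]
    w, _ = normalize_weights(np.array([3.0, -1.0]))
    np.testing.assert_allclose(w, [1.5, -0.5])
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.max(np.abs(w)) > 1.0


def test_near_cancellation_raises():
    with pytest.raises(NearCancellationError):
        normalize_weights(np.array([1.0, -1.0 + 1e-12]))


@settings(deadline=None, max_examples=60)
@given(
    gamma=st.lists(
        st.floats(-1e6, 1e6, allow_nan=False).filter(lambda v: abs(v) > 1e-6),
        min_size=1, max_size=9,
    ),
    scale=st.floats(1e-3, 1e3),
)
def test_weights_sum_to_one_and_scale_invariant(gamma, scale):
    gamma = np.asarray(gamma)
    try:
        w, _ = normalize_weights(gamma)
    except NearCancellationError:
        return
    assert abs(w.sum() - 1.0) < 1e-10
    w2, _ = normalize_weights(scale * gamma)
    np.testing.assert_allclose(w2, w, rtol=1e-9, atol=1e-12)


# -- weight learning --------------------------------------------------------


def two_category_design():
    variables = [VariableSpec("y", "outcome"), VariableSpec("s1", "single")]
    variables += [VariableSpec(f"a{j}", "member", category="air") for j in range(3)]
    variables += [VariableSpec(f"b{j}", "member", category="obesity") for j in range(2)]
    return StudyDesign(variables)


def make_training_table(rng, n=200, noise=0.5):
    design = two_category_design()
    cols = {"s1": rng.standard_normal(n)}
    for j in range(3):
        cols[f"a{j}"] = rng.standard_normal(n)
    for j in range(2):
        cols[f"b{j}"] = rng.standard_normal(n)
    y = (0.3 * cols["s1"] + 1.0 * cols["a0"] + 0.5 * cols["a1"] + 0.5 * cols["a2"]
         + noise * rng.standard_normal(n))
    table = pd.DataFrame({"y": y, **cols})
    return design, table


def test_single_repeat_equals_one_cv_fit_run(rng):
    design, table = make_training_table(rng)
    config = AnalysisConfig(cv_repeats=1, seed=0)
    weights, _ = learn_category_weights(table, design, config, np.random.default_rng(5))

    cols = ["s1", "a0", "a1", "a2", "b0", "b1"]
    problem = RidgeProblem(
        table[cols].to_numpy(), table["y"].to_numpy(),
        np.array([False] + [True] * 5),
    )
    grid = lambda_grid(problem, config.n_lambda, config.lambda_min_ratio)
    lam = cv_select_lambda(problem, config.cv_folds, grid, np.random.default_rng(5))
    _, g = fit_ridge(problem, lam)
    w_air, _ = normalize_weights(g[1:4])
    np.testing.assert_allclose(weights[0].weights, w_air, rtol=1e-10)
    assert weights[0].lambdas == [lam]


def test_weights_track_true_coefficients_for_noiseless_signal(rng):
    design, table = make_training_table(rng, n=400, noise=0.0)
    config = AnalysisConfig(cv_repeats=3, seed=0)
    weights, _ = learn_category_weights(table, design, config, rng)
    air = next(w for w in weights if w.category == "air")
    np.testing.assert_allclose(air.weights, np.array([1.0, 0.5, 0.5]) / 2.0, atol=0.02)
    assert air.fallback is None


def test_repeat_averaging_is_order_invariant(rng):
    """Averaged coefficients do not depend on the order of CV repeats:
    two learners with the same rng stream give identical weights."""
    design, table = make_training_table(rng)
    config = AnalysisConfig(cv_repeats=4, seed=0)
    w1, _ = learn_category_weights(table, design, config, np.random.default_rng(9))
    w2, _ = learn_category_weights(table, design, config, np.random.default_rng(9))
    for a, b in zip(w1, w2):
        np.testing.assert_array_equal(a.weights, b.weights)
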