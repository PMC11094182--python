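import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from mutlike.glm import (
    PenalizedModel,
    evaluate_classifier,
    fit_penalized_logistic,
    penalized_objective,
    score_samples,
    select_lambda_cv,
)
from mutlike.io import ExpressionMatrix


def as_matrix(A: np.ndarray) -> ExpressionMatrix:
    """A is samples x features; wrap as a genes x samples matrix."""
    df = pd.DataFrame(
        A.T,
        index=[f"g{j}" for j in range(A.shape[1])],
        columns=[f"s{i}" for i in range(A.shape[0])],
    )
    return ExpressionMatrix(df, stage="zscore")


def reference_solution(A, y, lam, alpha):
    """Independent convex-optimizer solution of the stated objective."""

    def obj(w):
        return penalized_objective(w[0], w[1:], A, y, lam, alpha)

    best = None
    for x0 in (np.zeros(A.shape[1] + 1), 0.1 * np.ones(A.shape[1] + 1)):
        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"maxiter": 200000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best:
            best = res.fun
    return best


def toy_problem(seed=0, n=40, p=2):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, p))
    eta = 1.5 * A[:, 0]  # only the first feature is informative
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    if len(np.unique(y)) < 2:
        y[0] = 1 - y[0]
    return A, y


class TestFit:
    @pytest.mark.parametrize("lam,alpha", [(0.1, 0.0), (0.05, 0.5), (0.02, 1.0)])
    def test_objective_matches_reference_optimizer(self, lam, alpha):
        A, y = toy_problem()
        m = fit_penalized_logistic(as_matrix(A), y, lam, alpha, tol=1e-12)
        ours = penalized_objective(m.beta0, m.beta, A, y, lam, alpha)
        ref = reference_solution(A, y, lam, alpha)
        assert ours <= ref + 1e-6

    def test_huge_ridge_penalty_shrinks_to_null_model(self):
        A, y = toy_problem(seed=1)
        m = fit_penalized_logistic(as_matrix(A), y, 1e6, 0.0)
        assert np.all(np.abs(m.beta) < 1e-3)
        logit = np.log(y.mean() / (1 - y.mean()))
        assert m.beta0 == pytest.approx(logit, abs=1e-2)

    def test_large_lasso_penalty_gives_exact_zeros(self):
        A, y = toy_problem(seed=2)
        m = fit_penalized_logistic(as_matrix(A), y, 10.0, 1.0)
        assert np.all(m.beta == 0.0)

    def test_single_class_rejected(self):
        A, _ = toy_problem()
        with pytest.raises(ValueError):
            fit_penalized_logistic(as_matrix(A), np.zeros(A.shape[0]), 0.1, 0.0)

    def test_non_finite_matrix_rejected(self):
        A, y = toy_problem()
        A[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_penalized_logistic(as_matrix(A), y, 0.1, 0.0)

    def test_objective_beats_null_model(self):
        A, y = toy_problem(seed=3, n=60, p=5)
        for lam in (0.01, 0.1, 1.0):
            m = fit_penalized_logistic(as_matrix(A), y, lam, 0.0)
            fitted = penalized_objective(m.beta0, m.beta, A, y, lam, 0.0)
            null = penalized_objective(
                np.log(y.mean() / (1 - y.mean())), np.zeros(A.shape[1]), A, y, lam, 0.0
            )
            assert fitted <= null + 1e-12

    def test_ridge_norm_shrinks_monotonically_in_lambda(self):
        A, y = toy_problem(seed=4, n=80, p=6)
        norms = []
        for lam in (0.001, 0.01, 0.1, 1.0, 10.0):
            m = fit_penalized_logistic(as_matrix(A), y, lam, 0.0)
            norms.append(np.linalg.norm(m.beta))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


class TestScores:
    def test_zero_coefficients_give_constant_score(self):
        m = PenalizedModel(["g0", "g1"], np.zeros(2), 0.5, 0.1, 0.0)
        A = np.ones((3, 2))
        s = score_samples(m, as_matrix(A))
        assert np.allclose(s["ridge_score"], 0.5)
        assert np.allclose(s["probability"], 1 / (1 + np.exp(-0.5)))

    def test_linear_predictor_arithmetic(self):
        m = PenalizedModel(["g0"], np.array([2.0]), 0.0, 0.1, 0.0)
        s = score_samples(m, as_matrix(np.array([[1.5]])))
        assert s["ridge_score"].iloc[0] == pytest.approx(3.0)

    def test_invariant_to_gene_row_order(self):
        A, y = toy_problem(seed=5, p=4)
        X = as_matrix(A)
        m = fit_penalized_logistic(X, y, 0.1, 0.0)
        shuffled = ExpressionMatrix(X.values.iloc[::-1], stage="zscore")
        pd.testing.assert_frame_equal(score_samples(m, X), score_samples(m, shuffled))

    def test_missing_model_gene_rejected(self):
        m = PenalizedModel(["g0", "gZ"], np.ones(2), 0.0, 0.1, 0.0)
        with pytest.raises(ValueError, match="gZ"):
            score_samples(m, as_matrix(np.ones((2, 2))))

    def test_probability_is_logistic_of_score(self):
        A, y = toy_problem(seed=6)
        m = fit_penalized_logistic(as_matrix(A), y, 0.1, 0.0)
        s = score_samples(m, as_matrix(A))
        np.testing.assert_allclose(
            s["probability"], 1 / (1 + np.exp(-s["ridge_score"])), atol=1e-12
        )

    def test_serialization_round_trip_bit_exact(self, tmp_path):
        A, y = toy_problem(seed=7, p=5)
        m = fit_penalized_logistic(as_matrix(A), y, 0.1, 0.0)
        m.to_json(tmp_path / "m.json")
        m2 = PenalizedModel.from_json(tmp_path / "m.json")
        s1 = score_samples(m, as_matrix(A))["ridge_score"].to_numpy()
        s2 = score_samples(m2, as_matrix(A))["ridge_score"].to_numpy()
        assert (s1 == s2).all()


class TestLambdaCV:
    def test_singleton_grid_returned(self):
        A, y = toy_problem(n=60)
        lam, _ = select_lambda_cv(as_matrix(A), y, (0.37,), n_folds=3)
        assert lam == 0.37

    def test_same_seed_same_choice(self):
        A, y = toy_problem(n=60)
        grid = (0.01, 0.1, 1.0)
        r1 = select_lambda_cv(as_matrix(A), y, grid, seed=5, n_folds=3)
        r2 = select_lambda_cv(as_matrix(A), y, grid, seed=5, n_folds=3)
        assert r1[0] == r2[0]
        pd.testing.assert_frame_equal(r1[1], r2[1])

    def test_cv_table_matches_independent_refit_loop(self):
        from sklearn.metrics import log_loss
        from sklearn.model_selection import StratifiedKFold

        A, y = toy_problem(n=60, p=3)
        X = as_matrix(A)
        grid = (0.05, 0.5)
        lam_best, table = select_lambda_cv(X, y, grid, seed=2, n_folds=3)
        # brute-force recomputation over the same folds
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=2)
        for i, lam in enumerate(grid):
            devs = []
            for tr, val in skf.split(A, y):
                m = fit_penalized_logistic(
                    ExpressionMatrix(X.values.iloc[:, tr], stage="zscore"),
                    y[tr], lam, 0.0, tol=1e-6, max_iter=5000,
                )
                p = 1 / (1 + np.exp(-(m.beta0 + A[val] @ m.beta)))
                devs.append(2 * log_loss(y[val], p, labels=[0.0, 1.0]))
            assert table["mean_deviance"].iloc[i] == pytest.approx(
                np.mean(devs), abs=1e-10
            )


class TestEvaluate:
    def make_scores(self, vals):
        return pd.DataFrame(
            {"ridge_score": vals, "probability": 1 / (1 + np.exp(-np.asarray(vals)))},
            index=[f"s{i}" for i in range(len(vals))],
        )

    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1])
        m = evaluate_classifier(self.make_scores([-2, -1, 0, 1, 2]), y)
        assert m["auroc"] == 1.0

    def test_score_negation_flips_auroc(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=12)
        y = rng.integers(0, 2, size=12).astype(float)
        y[:2] = [0, 1]
        a1 = evaluate_classifier(self.make_scores(vals), y)["auroc"]
        a2 = evaluate_classifier(self.make_scores(-vals), y)["auroc"]
        assert a1 + a2 == pytest.approx(1.0)

    def test_auroc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        vals = np.round(rng.normal(size=10), 1)  # rounding forces some ties
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0], dtype=float)
        auroc = evaluate_classifier(self.make_scores(vals), y)["auroc"]
        pos = vals[y == 1]
        neg = vals[y == 0]
        conc = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert auroc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_classifier(self.make_scores([1, 2]), np.array([1.0, 1.0]))
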