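"""Penalized logistic regression on z-scored expression.

The model minimized is, over intercept b0 and per-gene coefficients b,

    (1/n) * sum_i [ -y_i log p_i - (1 - y_i) log(1 - p_i) ]
        + lam * ( alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 ),

with p_i = logistic(b0 + x_i . b); the intercept is never penalized.
``alpha = 0`` is ridge, ``alpha = 1`` is the lasso; features are assumed
already standardized (:func:`mutlike.io.normalize`) so coefficients are
comparable across genes. The "ridge score" of a sample is the linear
predictor b0 + x . b.

The optimizer is scikit-learn's LogisticRegression with the penalty
mapped onto its ``C``/``l1_ratio`` convention (``C = 1 / (n * lam)``);
:func:`penalized_objective` exposes the objective itself so any solver
can be checked against an independent convex optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json
import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-3, 2, 11))


@dataclass
class PenalizedModel:
    gene_ids: list[str]
    beta: np.ndarray  # shape (n_genes,)
    beta0: float
    lam: float
    alpha: float
    input_stage: str = "zscore"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.gene_ids),):
            raise ValueError("beta length must match gene_ids")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "gene_ids": self.gene_ids,
                    "beta": self.beta.tolist(),
                    "beta0": self.beta0,
                    "lambda": self.lam,
                    "alpha": self.alpha,
                    "input_stage": self.input_stage,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PenalizedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_ids=list(d["gene_ids"]),
            beta=np.asarray(d["beta"], dtype=float),
            beta0=float(d["beta0"]),
            lam=float(d["lambda"]),
            alpha=float(d["alpha"]),
            input_stage=d.get("input_stage", "zscore"),
        )


def _design(X: ExpressionMatrix) -> np.ndarray:
    # samples x genes, as the solver expects
    return X.values.to_numpy().T


def penalized_objective(
    beta0: float,
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
) -> float:
    """The fitting objective at (beta0, beta); X is samples x features."""
    eta = beta0 + X @ beta
    # log(1 + exp(-s*eta)) computed stably
    s = 2.0 * y - 1.0
    nll = np.logaddexp(0.0, -s * eta).mean()
    penalty = lam * (alpha * np.abs(beta).sum() + (1 - alpha) / 2 * beta @ beta)
    return float(nll + penalty)


def _fit_elasticnet_fista(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> tuple[float, np.ndarray]:
    """Accelerated proximal-gradient (FISTA) solver for the mixed penalty.

    The L1 part of the penalty is handled by soft-thresholding; the
    smooth part (logistic likelihood + L2 ridge term) by its gradient
    with a fixed step 1/L from the spectral norm of the design.
    Convergence is declared when the relative objective change over a
    50-iteration window drops below ``tol``.
    """
    n, p = X.shape
    ones = np.ones((n, 1))
    sv = np.linalg.norm(np.hstack([ones, X]), 2)
    L = sv**2 / (4 * n) + lam * (1 - alpha)
    step = 1.0 / L
    thresh = step * lam * alpha
    b = np.zeros(p)
    b0 = 0.0
    zb, zb0 = b.copy(), b0
    theta = 1.0
    prev_obj = np.inf
    for it in range(max_iter):
        eta = zb0 + X @ zb
        pr = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (pr - y) / n + lam * (1 - alpha) * zb
        bn = zb - step * grad
        bn = np.sign(bn) * np.maximum(np.abs(bn) - thresh, 0.0)
        b0n = zb0 - step * (pr - y).mean()
        theta_n = (1 + np.sqrt(1 + 4 * theta**2)) / 2
        zb = bn + (theta - 1) / theta_n * (bn - b)
        zb0 = b0n + (theta - 1) / theta_n * (b0n - b0)
        b, b0, theta = bn, b0n, theta_n
        if it % 50 == 49:
            obj = penalized_objective(b0, b, X, y, lam, alpha)
            if abs(prev_obj - obj) < tol * max(1.0, abs(obj)):
                break
            prev_obj = obj
    return b0, b


def fit_penalized_logistic(
    X: ExpressionMatrix,
    y: np.ndarray | pd.Series,
    lam: float,
    alpha: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> PenalizedModel:
    """Fit the penalized logistic model on a z-scored expression matrix.

    ``y`` is binary, aligned with ``X.sample_ids`` (a pandas Series is
    reindexed onto them).
    """
    if isinstance(y, pd.Series):
        y = y.reindex(X.sample_ids).to_numpy()
    y = np.asarray(y, dtype=float)
    if y.shape != (X.shape[1],):
        raise ValueError("y must have one label per sample")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class; cannot fit a classifier")
    A = _design(X)
    if not np.isfinite(A).all():
        raise ValueError("expression matrix contains non-finite values")
    n = A.shape[0]
    if lam > 0 and alpha > 0:
        # mixed penalty: accelerated proximal gradient (exact zeros via
        # soft-thresholding); smooth penalties below go through lbfgs
        scaled_tol = min(tol, 1e-8)
        beta0, beta = _fit_elasticnet_fista(
            A, y, lam, alpha, tol=scaled_tol, max_iter=max_iter
        )
        return PenalizedModel(
            gene_ids=X.gene_ids,
            beta=beta,
            beta0=beta0,
            lam=float(lam),
            alpha=float(alpha),
            input_stage=X.stage,
        )
    if lam == 0:
        clf = LogisticRegression(penalty=None, tol=tol, max_iter=max_iter)
    else:
        clf = LogisticRegression(
            penalty="l2", C=1.0 / (n * lam), tol=tol, max_iter=max_iter
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(A, y)
    beta = clf.coef_.ravel().copy()
    return PenalizedModel(
        gene_ids=X.gene_ids,
        beta=beta,
        beta0=float(clf.intercept_[0]),
        lam=float(lam),
        alpha=float(alpha),
        input_stage=X.stage,
    )


def score_samples(model: PenalizedModel, X: ExpressionMatrix) -> pd.DataFrame:
    """Ridge scores (linear predictor) and probabilities for every sample.

    ``X`` may contain extra genes; every model gene must be present.
    """
    missing = [g for g in model.gene_ids if g not in X.values.index]
    if missing:
        raise ValueError(f"expression matrix is missing model genes: {missing[:10]}")
    A = X.values.loc[model.gene_ids].to_numpy().T
    score = model.beta0 + A @ model.beta
    return pd.DataFrame(
        {
            "ridge_score": score,
            "probability": 1.0 / (1.0 + np.exp(-score)),
        },
        index=pd.Index(X.sample_ids, name="sample_id"),
    )


def select_lambda_cv(
    X: ExpressionMatrix,
    y: np.ndarray | pd.Series,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    alpha: float = 0.0,
    n_folds: int = 5,
    seed: int = 0,
    one_se_rule: bool = False,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> tuple[float, pd.DataFrame]:
    """Pick lambda by stratified K-fold CV on mean held-out binomial deviance.

    Returns ``(lambda_best, cv_table)``; the table has one row per grid
    value with mean and standard error of the per-fold deviance. With
    ``one_se_rule`` the largest lambda within one standard error of the
    minimum is chosen instead of the minimizer.
    """
    if not lambda_grid:
        raise ValueError("lambda grid is empty")
    if isinstance(y, pd.Series):
        y = y.reindex(X.sample_ids).to_numpy()
    y = np.asarray(y, dtype=float)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    A = X.values.to_numpy().T
    folds = list(skf.split(A, y))
    for _, val in folds:
        if len(np.unique(y[val])) < 2:
            raise ValueError("a CV fold contains a single class; reduce n_folds")
    dev = np.empty((len(lambda_grid), n_folds))
    for j, (tr, val) in enumerate(folds):
        Xtr = ExpressionMatrix(X.values.iloc[:, tr], stage=X.stage)
        Xval = X.values.iloc[:, val].to_numpy().T
        for i, lam in enumerate(lambda_grid):
            m = fit_penalized_logistic(Xtr, y[tr], lam, alpha, tol=tol, max_iter=max_iter)
            p = 1.0 / (1.0 + np.exp(-(m.beta0 + Xval @ m.beta)))
            dev[i, j] = 2.0 * log_loss(y[val], p, labels=[0.0, 1.0])
    mean = dev.mean(axis=1)
    se = dev.std(axis=1, ddof=1) / np.sqrt(n_folds)
    table = pd.DataFrame(
        {"lambda": lambda_grid, "mean_deviance": mean, "se_deviance": se}
    )
    best_i = int(np.argmin(mean))
    if one_se_rule:
        cutoff = mean[best_i] + se[best_i]
        best_i = max(
            (i for i in range(len(lambda_grid)) if mean[i] <= cutoff),
            key=lambda i: lambda_grid[i],
        )
    return float(lambda_grid[best_i]), table


def evaluate_classifier(
    scores: pd.DataFrame, y: np.ndarray | pd.Series, threshold: float = 0.5
) -> dict[str, float]:
    """AUROC (rank-based, ties half-credit) plus sensitivity/specificity
    at the given probability threshold."""
    if isinstance(y, pd.Series):
        y = y.reindex(scores.index).to_numpy()
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to evaluate a classifier")
    pred = (scores["probability"].to_numpy() >= threshold).astype(float)
    pos, neg = y == 1, y == 0
    return {
        "auroc": float(roc_auc_score(y, scores["ridge_score"].to_numpy())),
        "sensitivity": float((pred[pos] == 1).mean()),
        "specificity": float((pred[neg] == 0).mean()),
        "n_pos": float(pos.sum()),
        "n_neg": float(neg.sum()),
    }
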