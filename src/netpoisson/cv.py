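"""K-fold cross-validation and min/1se model selection.

Hyperparameters (penalty family, elastic-net weight alpha, concavity
gamma, and the overall strength lambda) are tuned by 10-fold
cross-validation scored with mean absolute error (MAE) on the count
scale. For each grid cell the lambda path is computed once on the full
data and shared across folds. Two selection rules are first-class:

* ``min``  — the (cell, lambda) minimizing the mean MAE across folds;
* ``1se``  — within the winning cell, the largest lambda whose mean MAE
  is within one standard error of the minimum (the sparser model with
  statistically indistinguishable prediction error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .design import SplineDesign
from .penalized import (
    FitResult,
    PenaltySpec,
    Solution,
    fit_path,
    lambda_sequence,
)

__all__ = [
    "kfold_split",
    "cv_score",
    "CVCell",
    "CVResult",
    "cv_fit",
    "cross_validate",
    "select",
    "GroupElasticNetPoissonCV",
]

ALPHA_GRID = (0.01, 0.25, 0.5, 0.75, 1.0)
GAMMA_GRID = (3.0, 4.0, 5.0)


def kfold_split(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random fold assignment (length n, values 0..k-1) with fold sizes
    differing by at most one; reproducible under the seed."""
    if n < k:
        raise ValueError(f"cannot split n={n} subjects into k={k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    fold[perm] = np.arange(n) % k
    return fold


def cv_score(y_held: np.ndarray, mu_held: np.ndarray) -> float:
    """Mean absolute error between observed counts and response-scale
    predictions."""
    y_held = np.asarray(y_held, dtype=float)
    mu_held = np.asarray(mu_held, dtype=float)
    if y_held.shape != mu_held.shape:
        raise ValueError("length mismatch between observed and predicted")
    return float(np.mean(np.abs(y_held - mu_held)))


@dataclass
class CVCell:
    """Fold-averaged MAE along the lambda path for one grid cell."""

    family: str
    alpha: float
    gamma: float | None
    lambda_path: np.ndarray
    mean_mae: np.ndarray
    se_mae: np.ndarray
    fold_mae: np.ndarray  # (k, n_lambda)

    @property
    def index_min(self) -> int:
        # argmin returns the first (= largest-lambda) minimizer: sparser
        return int(np.argmin(self.mean_mae))

    @property
    def index_1se(self) -> int:
        i = self.index_min
        thr = self.mean_mae[i] + self.se_mae[i]
        return int(np.flatnonzero(self.mean_mae <= thr)[0])

    @property
    def lambda_min(self) -> float:
        return float(self.lambda_path[self.index_min])

    @property
    def lambda_1se(self) -> float:
        return float(self.lambda_path[self.index_1se])


@dataclass
class CVResult:
    """Cross-validation surface with the winning cell and both rules."""

    cells: list[CVCell]
    fold_assignment: np.ndarray
    fold_seed: int
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    groups: Sequence = field(repr=False)
    group_weights: object = field(repr=False, default=None)

    @property
    def best_cell(self) -> int:
        keys = []
        for i, c in enumerate(self.cells):
            keys.append(
                (
                    float(c.mean_mae[c.index_min]),
                    -c.lambda_min,  # ties -> sparser model
                    c.family,
                    c.alpha,
                    -1.0 if c.gamma is None else c.gamma,
                )
            )
        return int(min(range(len(keys)), key=keys.__getitem__))

    @property
    def lambda_min(self) -> float:
        return self.cells[self.best_cell].lambda_min

    @property
    def lambda_1se(self) -> float:
        return self.cells[self.best_cell].lambda_1se

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.cells):
            for j, lam in enumerate(c.lambda_path):
                rows.append(
                    {
                        "cell": i,
                        "family": c.family,
                        "alpha": c.alpha,
                        "gamma": np.nan if c.gamma is None else c.gamma,
                        "lambda": lam,
                        "mean_mae": c.mean_mae[j],
                        "se_mae": c.se_mae[j],
                    }
                )
        return pd.DataFrame(rows)


def _grid(family: str, alpha_grid, gamma_grid):
    if family == "lasso":
        return [(family, a, None) for a in alpha_grid]
    # concavity bounds: gamma > 2 for MCP, > 3 for SCAD
    lo = 2.0 if family == "mcp" else 3.0
    valid = [g for g in gamma_grid if g > lo]
    if len(valid) < len(gamma_grid):
        dropped = sorted(set(gamma_grid) - set(valid))
        warnings.warn(
            f"gamma values {dropped} are invalid for {family} "
            f"(need gamma > {lo:g}); dropped from the grid",
            UserWarning,
        )
    return [(family, a, g) for a in alpha_grid for g in valid]


def cv_fit(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence,
    family: str = "lasso",
    alpha_grid: Sequence[float] = ALPHA_GRID,
    gamma_grid: Sequence[float] = GAMMA_GRID,
    k: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    group_weights=None,
    tol: float = 1e-5,
    max_iter: int = 10_000,
) -> CVResult:
    """Cross-validate one penalty family over its (alpha, gamma) grid.

    The fold-fit tolerance is looser than the final-refit tolerance:
    MAE selection is insensitive to the last decimals of the
    coefficients, and ``select`` refits at full precision.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fold = kfold_split(len(y), k=k, seed=seed)
    cells = []
    for fam, a, g in _grid(family, alpha_grid, gamma_grid):
        lambdas = lambda_sequence(
            X, y, groups, alpha=a, n_lambda=n_lambda,
            ratio=lambda_min_ratio, group_weights=group_weights,
        )
        fold_mae = np.empty((k, len(lambdas)))
        for f in range(k):
            held = fold == f
            y_held = y[held]
            if np.all(y_held == y_held[0]):
                warnings.warn(
                    f"fold {f} has a zero-variance outcome; fold kept",
                    UserWarning,
                )
            res = fit_path(
                X[~held], y[~held], groups,
                family=fam, alpha=a, gamma=4.0 if g is None else g,
                lambdas=lambdas, group_weights=group_weights,
                tol=tol, max_iter=max_iter,
            )
            mu = res.predict(X[held])  # (n_held, n_lambda)
            fold_mae[f] = np.mean(np.abs(y_held[:, None] - mu), axis=0)
        mean_mae = fold_mae.mean(axis=0)
        se_mae = fold_mae.std(axis=0, ddof=1) / np.sqrt(k)
        cells.append(
            CVCell(
                family=fam, alpha=a, gamma=g, lambda_path=lambdas,
                mean_mae=mean_mae, se_mae=se_mae, fold_mae=fold_mae,
            )
        )
    return CVResult(
        cells=cells, fold_assignment=fold, fold_seed=seed,
        X=X, y=y, groups=groups, group_weights=group_weights,
    )


def select(
    cv: CVResult,
    rule: str = "1se",
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> tuple[PenaltySpec, FitResult, Solution]:
    """Refit on the full data at the selected hyperparameters.

    Returns the selected penalty, the warm-started refit path down to
    the selected lambda, and the solution at that lambda.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    cell = cv.cells[cv.best_cell]
    idx = cell.index_1se if rule == "1se" else cell.index_min
    lambdas = cell.lambda_path[: idx + 1]
    gamma = 4.0 if cell.gamma is None else cell.gamma
    res = fit_path(
        cv.X, cv.y, cv.groups,
        family=cell.family, alpha=cell.alpha, gamma=gamma,
        lambdas=lambdas, group_weights=cv.group_weights,
        tol=tol, max_iter=max_iter,
    )
    sol = res.solution(len(lambdas) - 1)
    return sol.spec, res, sol


def cross_validate(
    table: pd.DataFrame,
    terms: Sequence[str] | Mapping[str, str],
    outcome: str,
    families: Sequence[str] = ("lasso", "mcp", "scad"),
    alpha_grid: Sequence[float] = ALPHA_GRID,
    gamma_grid: Sequence[float] = GAMMA_GRID,
    k: int = 10,
    seed: int = 0,
    basis_df: int = 5,
    **kwargs,
) -> dict[str, CVResult]:
    """Design-then-cross-validate convenience wrapper; one CVResult per
    penalty family."""
    design = SplineDesign(terms=terms, basis_df=basis_df).fit(table).design(table)
    y = table[outcome].to_numpy(dtype=float)
    out = {}
    for fam in families:
        out[fam] = cv_fit(
            design.X, y, design.group_index, family=fam,
            alpha_grid=alpha_grid, gamma_grid=gamma_grid, k=k, seed=seed,
            group_weights=design.group_weights(), **kwargs,
        )
    return out


class GroupElasticNetPoissonCV(RegressorMixin, BaseEstimator):
    """Cross-validated group elastic net Poisson estimator.

    Tunes (alpha, gamma, lambda) for one penalty family by k-fold MAE
    cross-validation, then refits on the full data at the rule-selected
    lambda.

    Attributes
    ----------
    cv_result_ : CVResult
    spec_ : PenaltySpec selected hyperparameters
    intercept_, coef_ : refit solution
    """

    def __init__(
        self,
        family: str = "lasso",
        alpha_grid: Sequence[float] = ALPHA_GRID,
        gamma_grid: Sequence[float] = GAMMA_GRID,
        cv: int = 10,
        rule: str = "1se",
        seed: int = 0,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        cv_tol: float = 1e-5,
        tol: float = 1e-7,
        max_iter: int = 10_000,
    ):
        self.family = family
        self.alpha_grid = alpha_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.rule = rule
        self.seed = seed
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv_tol = cv_tol
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, groups=None, group_weights=None):
        X = np.asarray(X, dtype=float)
        if groups is None:
            groups = list(range(X.shape[1]))
        self.cv_result_ = cv_fit(
            X, y, groups, family=self.family,
            alpha_grid=self.alpha_grid, gamma_grid=self.gamma_grid,
            k=self.cv, seed=self.seed, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            group_weights=group_weights, tol=self.cv_tol,
            max_iter=self.max_iter,
        )
        self.spec_, self.refit_path_, self.solution_ = select(
            self.cv_result_, rule=self.rule, tol=self.tol,
            max_iter=self.max_iter,
        )
        self.intercept_ = self.solution_.intercept
        self.coef_ = self.solution_.coef
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return self.solution_.predict(np.asarray(X, dtype=float))
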