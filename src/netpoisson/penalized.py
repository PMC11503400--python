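"""Group elastic net Poisson regression with LASSO, MCP and SCAD penalties.

Model: counts y with log link, ``log mu = b0 + X beta``, where the
columns of X are partitioned into groups (one group per original
predictor). The fitted objective is

    (1/n) sum_i [mu_i - y_i eta_i]  +  sum_g P(||beta_g||_2; lambda w_g)

with the group penalty mixing an L1-type component (LASSO, MCP or SCAD
applied to the group norm) with a group-ridge component through the
elastic-net weight ``alpha``:

    P(t; l) = alpha * rho(t; l, gamma) + (1 - alpha) * (l / 2) * t^2.

The solver is a monotone accelerated proximal-gradient method with
backtracking line search, warm starts along a decreasing lambda path,
sequential strong-rule screening and a full KKT verification pass at
every lambda. The intercept is never penalized. MCP and SCAD are
nonconvex: the guarantee is first-order stationarity and monotone
objective descent, not global optimality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PenaltySpec",
    "FitResult",
    "Solution",
    "poisson_deviance",
    "penalty_value",
    "prox_step",
    "lambda_sequence",
    "fit_path",
    "GroupElasticNetPoisson",
]

FAMILIES = ("lasso", "mcp", "scad")


@dataclass
class PenaltySpec:
    """Penalty family with its tuning parameters."""

    family: str = "lasso"
    alpha: float = 1.0
    gamma: float = 4.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.family == "mcp" and self.gamma <= 2:
            raise ValueError("gamma must exceed 2 for MCP")
        if self.family == "scad" and self.gamma <= 3:
            raise ValueError("gamma must exceed 3 for SCAD")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


# ---------------------------------------------------------------------------
# loss and penalty primitives


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance ``2 sum[y log(y/mu) - (y - mu)]``; the y log
    term is zero where y == 0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(t - (y - mu)))


def _rho(t: np.ndarray, lam: np.ndarray, family: str, gamma: float) -> np.ndarray:
    """Scalar sparsity penalty rho(t; lam, gamma) applied to group norms."""
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if family == "lasso":
        return lam * t
    if family == "mcp":
        return np.where(
            t <= gamma * lam,
            lam * t - t**2 / (2.0 * gamma),
            gamma * lam**2 / 2.0,
        )
    # scad
    mid = (2.0 * gamma * lam * t - t**2 - lam**2) / (2.0 * (gamma - 1.0))
    return np.where(
        t <= lam,
        lam * t,
        np.where(t <= gamma * lam, mid, lam**2 * (gamma + 1.0) / 2.0),
    )


def _rho_prime(t: np.ndarray, lam: np.ndarray, family: str,
               gamma: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if family == "lasso":
        return lam * np.ones_like(t)
    if family == "mcp":
        return np.where(t <= gamma * lam, lam - t / gamma, 0.0)
    return np.where(
        t <= lam,
        lam,
        np.where(t <= gamma * lam,
                 (gamma * lam - t) / (gamma - 1.0), 0.0),
    )


def penalty_value(beta_g: np.ndarray, spec: PenaltySpec, w_g: float = 1.0) -> float:
    """Group penalty evaluated at one coefficient block."""
    t = float(np.linalg.norm(beta_g))
    lam_g = spec.lam * w_g
    val = spec.alpha * _rho(t, lam_g, spec.family, spec.gamma)
    val += (1.0 - spec.alpha) * (lam_g / 2.0) * t * t
    return float(val)


def _total_penalty(norms: np.ndarray, lam_g: np.ndarray, family: str,
                   alpha: float, gamma: float) -> float:
    vals = alpha * _rho(norms, lam_g, family, gamma)
    vals = vals + (1.0 - alpha) * (lam_g / 2.0) * norms**2
    return float(np.sum(vals))


def _prox_norms(nz: np.ndarray, step: float, lam_g: np.ndarray, family: str,
                alpha: float, gamma: float) -> np.ndarray:
    """Exact scalar prox of the composite group penalty.

    Solves ``argmin_s (s - nz)^2 / (2 step) + alpha rho(s) +
    (1 - alpha) lam_g s^2 / 2`` for s >= 0 given the norms ``nz`` of the
    gradient-step points; candidate stationary points of every penalty
    region are clamped into their region and compared on the objective,
    which is robust for the nonconvex families.
    """
    a, r = alpha, 1.0 - alpha
    dr = 1.0 + step * r * lam_g  # ridge scaling, always > 0

    def h(s):
        return ((s - nz) ** 2 / (2.0 * step)
                + a * _rho(s, lam_g, family, gamma)
                + r * lam_g * s**2 / 2.0)

    cands = [np.zeros_like(nz)]
    if family == "lasso":
        cands.append(np.maximum(0.0, nz - step * a * lam_g) / dr)
    elif family == "mcp":
        den1 = dr - step * a / gamma
        if np.any(den1 <= 0):
            raise ValueError(
                "step too large for a single-valued MCP prox; "
                "require step * alpha < gamma * (1 + step*(1-alpha)*lam)"
            )
        s1 = np.maximum(0.0, nz - step * a * lam_g) / den1
        cands.append(np.minimum(s1, gamma * lam_g))
        cands.append(np.maximum(nz / dr, gamma * lam_g))
    else:  # scad
        den2 = dr - step * a / (gamma - 1.0)
        if np.any(den2 <= 0):
            raise ValueError(
                "step too large for a single-valued SCAD prox; "
                "require step * alpha < (gamma-1) * (1 + step*(1-alpha)*lam)"
            )
        sA = np.maximum(0.0, nz - step * a * lam_g) / dr
        cands.append(np.minimum(sA, lam_g))
        sB = (nz - step * a * gamma * lam_g / (gamma - 1.0)) / den2
        cands.append(np.clip(sB, lam_g, gamma * lam_g))
        cands.append(np.maximum(nz / dr, gamma * lam_g))

    best = cands[0]
    hbest = h(best)
    for s in cands[1:]:
        hs = h(s)
        take = hs < hbest
        best = np.where(take, s, best)
        hbest = np.where(take, hs, hbest)
    return best


def _group_slices(groups: Sequence) -> tuple[list, list[slice]]:
    """Contiguous group labels -> (names, column slices)."""
    labels = list(groups)
    names: list = []
    slices: list[slice] = []
    start = 0
    for j in range(1, len(labels) + 1):
        if j == len(labels) or labels[j] != labels[start]:
            if labels[start] in names:
                raise ValueError(
                    f"group {labels[start]!r} occupies non-contiguous columns"
                )
            names.append(labels[start])
            slices.append(slice(start, j))
            start = j
    return names, slices


def prox_step(
    z: Mapping | Sequence[np.ndarray],
    step: float,
    spec: PenaltySpec,
    weights: Mapping[object, float] | Sequence[float] | None = None,
) -> list[np.ndarray] | dict:
    """Exact proximal operator of the group penalty, block by block."""
    if step <= 0:
        raise ValueError("step must be positive")
    if isinstance(z, Mapping):
        keys = list(z.keys())
        blocks = [np.asarray(z[k], dtype=float) for k in keys]
        w = [1.0 if weights is None else float(weights[k]) for k in keys]
    else:
        keys = None
        blocks = [np.asarray(b, dtype=float) for b in z]
        w = [1.0] * len(blocks) if weights is None else [float(x) for x in weights]
    nz = np.array([np.linalg.norm(b) for b in blocks])
    lam_g = spec.lam * np.asarray(w)
    s = _prox_norms(nz, step, lam_g, spec.family, spec.alpha, spec.gamma)
    out = []
    for b, n0, s0 in zip(blocks, nz, s):
        out.append(b * (s0 / n0) if n0 > 0 else np.zeros_like(b))
    if keys is not None:
        return dict(zip(keys, out))
    return out


# ---------------------------------------------------------------------------
# lambda path


def lambda_sequence(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence,
    alpha: float = 1.0,
    n_lambda: int = 100,
    ratio: float = 0.01,
    group_weights: Mapping | Sequence[float] | None = None,
) -> np.ndarray:
    """Log-spaced decreasing lambda path from the smallest lambda that
    keeps every group at zero (intercept-only KKT bound)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.any(X):
        raise ValueError("design matrix is all zero")
    names, slices = _group_slices(groups)
    w = _resolve_weights(names, slices, group_weights)
    n = len(y)
    mu0 = np.full(n, y.mean())
    grad = X.T @ (mu0 - y) / n
    gnorm = np.array([np.linalg.norm(grad[s]) for s in slices])
    a_eff = alpha
    if alpha <= 0:
        warnings.warn(
            "alpha = 0 has no finite lambda_max; using a fixed large cap",
            UserWarning,
        )
        a_eff = 1e-3
    lam_max = float(np.max(gnorm / (a_eff * w)))
    if lam_max <= 0:
        raise ValueError("degenerate problem: zero gradient at the null fit")
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _resolve_weights(names, slices, group_weights) -> np.ndarray:
    if group_weights is None:
        return np.array([np.sqrt(s.stop - s.start) for s in slices])
    if isinstance(group_weights, Mapping):
        return np.array([float(group_weights[nm]) for nm in names])
    return np.asarray(group_weights, dtype=float)


# ---------------------------------------------------------------------------
# results


@dataclass
class Solution:
    """One fitted model (a single point on the lambda path)."""

    intercept: float
    coef: np.ndarray
    group_names: list
    group_slices: list[slice]
    group_weights: np.ndarray
    spec: PenaltySpec

    def predict_link(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_link(X))

    @property
    def active_groups(self) -> list:
        return [
            nm
            for nm, s in zip(self.group_names, self.group_slices)
            if np.linalg.norm(self.coef[s]) > 0
        ]

    def coef_block(self, name) -> np.ndarray:
        i = self.group_names.index(name)
        return self.coef[self.group_slices[i]]


@dataclass
class FitResult:
    """Fits along a decreasing lambda path (warm-started)."""

    lambda_path: np.ndarray
    intercept_path: np.ndarray
    coef_path: np.ndarray  # (n_lambda, p)
    active_sets: list[list]
    deviance_path: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray
    group_names: list
    group_slices: list[slice]
    group_weights: np.ndarray
    family: str
    alpha: float
    gamma: float

    def solution(self, index: int) -> Solution:
        return Solution(
            intercept=float(self.intercept_path[index]),
            coef=self.coef_path[index].copy(),
            group_names=list(self.group_names),
            group_slices=list(self.group_slices),
            group_weights=self.group_weights,
            spec=PenaltySpec(
                family=self.family,
                alpha=self.alpha,
                gamma=self.gamma,
                lam=float(self.lambda_path[index]),
            ),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Response-scale predictions at every path point, (n, n_lambda)."""
        eta = np.asarray(X, dtype=float) @ self.coef_path.T + self.intercept_path
        return np.exp(eta)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "family": self.family,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "lambda_path": self.lambda_path.tolist(),
            "intercept_path": self.intercept_path.tolist(),
            "group_names": [str(g) for g in self.group_names],
            "group_columns": [[s.start, s.stop] for s in self.group_slices],
            "coef_path": self.coef_path.tolist(),
            "converged": self.converged.tolist(),
            "n_iter": self.n_iter.tolist(),
        }
        Path(path).write_text(json.dumps(obj))


# ---------------------------------------------------------------------------
# solver


def _nll(mu: np.ndarray, y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.mean(mu - y * eta))


def _solve_at_lambda(
    X: np.ndarray,
    y: np.ndarray,
    slices: list[slice],
    lam_g: np.ndarray,
    family: str,
    alpha: float,
    gamma: float,
    b0: float,
    beta: np.ndarray,
    tol: float,
    max_iter: int,
    step: float,
) -> tuple[float, np.ndarray, int, bool, float]:
    """Monotone accelerated proximal gradient on one restricted problem.

    Returns (b0, beta, n_iter, converged, step). The objective never
    increases: an accelerated candidate that fails to descend triggers a
    restart from the last accepted point, where the backtracked proximal
    step is a guaranteed descent step.
    """
    n = len(y)
    starts = np.array([s.start for s in slices], dtype=int)
    stops = np.array([s.stop for s in slices], dtype=int)

    def group_norms(v):
        return np.sqrt(np.add.reduceat(v * v, starts))

    def prox(v, t):
        nz = group_norms(v)
        s = _prox_norms(nz, t, lam_g, family, alpha, gamma)
        scale = np.where(nz > 0, s / np.where(nz > 0, nz, 1.0), 0.0)
        return v * np.repeat(scale, stops - starts)

    eta = b0 + X @ beta
    mu = np.exp(eta)
    L_x = _nll(mu, y, eta)
    F_x = L_x + _total_penalty(group_norms(beta), lam_g, family, alpha, gamma)

    vb0, vbeta, veta = b0, beta, eta
    theta = 1.0
    b0_prev, beta_prev, eta_prev = b0, beta, eta
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        mu_v = np.exp(veta)
        L_v = _nll(mu_v, y, veta)
        r = (mu_v - y) / n
        g_beta = X.T @ r
        g_b0 = float(r.sum())

        accepted = False
        for attempt in range(2):
            # attempt 0: accelerated step from v; attempt 1: plain
            # descent step from the last accepted point
            if attempt == 1:
                vb0, vbeta, veta = b0, beta, eta
                mu_v = np.exp(veta)
                L_v = _nll(mu_v, y, veta)
                r = (mu_v - y) / n
                g_beta = X.T @ r
                g_b0 = float(r.sum())
                theta = 1.0
            while True:
                b0_new = vb0 - step * g_b0
                beta_new = prox(vbeta - step * g_beta, step)
                eta_new = b0_new + X @ beta_new
                mu_new = np.exp(eta_new)
                L_new = _nll(mu_new, y, eta_new)
                db = beta_new - vbeta
                d0 = b0_new - vb0
                quad = (L_v + g_beta @ db + g_b0 * d0
                        + (db @ db + d0 * d0) / (2.0 * step))
                if L_new <= quad + 1e-12 or step < 1e-14:
                    break
                step *= 0.5
            F_new = L_new + _total_penalty(
                group_norms(beta_new), lam_g, family, alpha, gamma
            )
            if F_new <= F_x + 1e-12:
                accepted = True
                break
        if not accepted:
            converged = True  # no descent direction left at machine scale
            break

        delta = max(abs(b0_new - b0), float(np.max(np.abs(beta_new - beta)))
                    if beta.size else 0.0)
        b0_prev, beta_prev, eta_prev = b0, beta, eta
        b0, beta, eta, F_x = b0_new, beta_new, eta_new, F_new
        if delta < tol:
            converged = True
            break

        theta_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * theta * theta))
        mom = (theta - 1.0) / theta_new
        vb0 = b0 + mom * (b0 - b0_prev)
        vbeta = beta + mom * (beta - beta_prev)
        veta = eta + mom * (eta - eta_prev)
        theta = theta_new
        step *= 1.05  # cautious step growth; backtracking will rein it in
    return b0, beta, n_it, converged, step


def kkt_violation(
    X: np.ndarray,
    y: np.ndarray,
    b0: float,
    beta: np.ndarray,
    slices: list[slice],
    weights: np.ndarray,
    spec: PenaltySpec,
) -> tuple[float, float]:
    """(worst active-group stationarity sup-norm, worst inactive-group
    KKT excess); both are ~0 at a first-order stationary point."""
    n = len(y)
    eta = b0 + X @ beta
    mu = np.exp(eta)
    grad = X.T @ (mu - y) / n
    lam_g = spec.lam * weights
    worst_active = 0.0
    worst_inactive = 0.0
    for s, lg in zip(slices, lam_g):
        bg = beta[s]
        ng = float(np.linalg.norm(bg))
        if ng > 0:
            rp = float(_rho_prime(ng, lg, spec.family, spec.gamma))
            # gradient of the composite penalty at bg (smooth away from 0)
            v = grad[s] + (1 - spec.alpha) * lg * bg + spec.alpha * rp * bg / ng
            worst_active = max(worst_active, float(np.max(np.abs(v))))
        else:
            excess = float(np.linalg.norm(grad[s])) - spec.alpha * lg
            worst_inactive = max(worst_inactive, max(0.0, excess))
    return worst_active, worst_inactive


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence,
    family: str = "lasso",
    alpha: float = 1.0,
    gamma: float = 4.0,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    group_weights: Mapping | Sequence[float] | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    screen: bool = True,
) -> FitResult:
    """Fit the penalized Poisson model along a decreasing lambda path.

    Warm-started along the path; at each lambda the strong rule
    pre-screens candidate groups and the solution is verified (and the
    candidate set enlarged) against the full KKT conditions. The
    intercept is unpenalized and initialized at its null MLE
    ``log(mean(y))``, so the first path point is the intercept-only
    model.
    """
    spec_check = PenaltySpec(family=family, alpha=alpha, gamma=gamma)  # validates
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be non-negative counts")
    if y.mean() <= 0:
        raise ValueError("y must contain at least one positive count")
    n, p = X.shape
    names, slices = _group_slices(groups)
    w = _resolve_weights(names, slices, group_weights)
    if lambdas is None:
        lambdas = lambda_sequence(
            X, y, groups, alpha=alpha, n_lambda=n_lambda,
            ratio=lambda_min_ratio, group_weights=group_weights,
        )
    lambdas = np.asarray(lambdas, dtype=float)

    b0 = float(np.log(y.mean()))
    beta = np.zeros(p)
    mu0 = np.full(n, y.mean())
    grad0 = X.T @ (mu0 - y) / n
    gnorm_prev = np.array([np.linalg.norm(grad0[s]) for s in slices])

    intercepts = np.empty(len(lambdas))
    coefs = np.empty((len(lambdas), p))
    active_sets: list[list] = []
    deviances = np.empty(len(lambdas))
    conv = np.zeros(len(lambdas), dtype=bool)
    iters = np.zeros(len(lambdas), dtype=int)

    a_scr = max(alpha, 1e-3)
    step = 1.0 / max(1e-8, float(np.mean(mu0)) * float(np.mean(X * X)) * p)
    step = min(max(step, 1e-4), 1e2)
    lam_prev = lambdas[0]
    for k, lam in enumerate(lambdas):
        lam_g = lam * w
        if screen:
            thresh = a_scr * w * (2.0 * lam - lam_prev)
            cand = set(np.flatnonzero(gnorm_prev >= thresh - 1e-12))
        else:
            cand = set(range(len(slices)))
        cand |= {
            i for i, s in enumerate(slices) if np.linalg.norm(beta[s]) > 0
        }

        while True:
            cand_sorted = sorted(cand)
            cols = np.concatenate(
                [np.arange(s.start, s.stop) for s in
                 (slices[i] for i in cand_sorted)]
            ) if cand_sorted else np.array([], dtype=int)
            sub_slices = []
            pos = 0
            for i in cand_sorted:
                sz = slices[i].stop - slices[i].start
                sub_slices.append(slice(pos, pos + sz))
                pos += sz
            Xs = X[:, cols]
            bs = beta[cols]
            b0, bs, n_it, ok, step = _solve_at_lambda(
                Xs, y, sub_slices, lam_g[cand_sorted], family, alpha, gamma,
                b0, bs, tol, max_iter, step,
            )
            beta = np.zeros(p)
            beta[cols] = bs
            # full KKT pass over excluded groups
            eta = b0 + Xs @ bs
            mu = np.exp(eta)
            grad = X.T @ (mu - y) / n
            gnorm = np.array([np.linalg.norm(grad[s]) for s in slices])
            viol = [
                i
                for i in range(len(slices))
                if i not in cand and gnorm[i] > alpha * lam_g[i] + 1e-9
            ]
            if not viol:
                gnorm_prev = gnorm
                break
            cand |= set(viol)

        intercepts[k] = b0
        coefs[k] = beta
        active_sets.append(
            [names[i] for i, s in enumerate(slices)
             if np.linalg.norm(beta[s]) > 0]
        )
        deviances[k] = poisson_deviance(y, mu)
        conv[k] = ok
        iters[k] = n_it
        lam_prev = lam
        if not np.isfinite(deviances[k]):
            raise RuntimeError(
                f"solver diverged at lambda index {k} (lambda={lam:.4g})"
            )

    return FitResult(
        lambda_path=lambdas,
        intercept_path=intercepts,
        coef_path=coefs,
        active_sets=active_sets,
        deviance_path=deviances,
        converged=conv,
        n_iter=iters,
        group_names=names,
        group_slices=slices,
        group_weights=w,
        family=family,
        alpha=alpha,
        gamma=gamma,
    )


class GroupElasticNetPoisson(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for the group elastic net Poisson path.

    Parameters mirror :func:`fit_path`; ``fit`` accepts the group labels
    of the design columns via the ``groups`` fit parameter (defaulting
    to one group per column). After fitting, ``predict`` uses the end of
    the path unless ``lambda_index`` is set.

    Attributes
    ----------
    path_ : FitResult
        Full warm-started path.
    intercept_, coef_ : selected solution (see ``lambda_index``).
    """

    def __init__(
        self,
        family: str = "lasso",
        alpha: float = 1.0,
        gamma: float = 4.0,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        lambdas: np.ndarray | None = None,
        tol: float = 1e-7,
        max_iter: int = 10_000,
        lambda_index: int = -1,
    ):
        self.family = family
        self.alpha = alpha
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.lambdas = lambdas
        self.tol = tol
        self.max_iter = max_iter
        self.lambda_index = lambda_index

    def fit(self, X, y, groups=None, group_weights=None):
        X = np.asarray(X, dtype=float)
        if groups is None:
            groups = list(range(X.shape[1]))
        self.path_ = fit_path(
            X,
            y,
            groups,
            family=self.family,
            alpha=self.alpha,
            gamma=self.gamma,
            lambdas=self.lambdas,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            group_weights=group_weights,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        idx = self.lambda_index % len(self.path_.lambda_path)
        sol = self.path_.solution(idx)
        self.intercept_ = sol.intercept
        self.coef_ = sol.coef
        self.solution_ = sol
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return np.exp(self.intercept_ + np.asarray(X, float) @ self.coef_)
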