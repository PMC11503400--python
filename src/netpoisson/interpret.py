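"""Model interpretation: deviance R2, variable importance, and
multiplicative effect tables/curves.

Under the log link the fitted model decomposes multiplicatively,

    mu_i = exp(f0) * prod_j exp(f_j(x_ij)),

so ``exp(f0)`` is the baseline predicted count (term contributions are
centered to sample mean zero) and ``exp(f_j)`` is the multiplicative
effect of predictor j. Variable importance distributes the model's
explained variation across terms via the covariance share of each term
contribution with the linear predictor,

    VI_j = 100 * sum_i f_ji (eta_i - etabar) / sum_i (eta_i - etabar)^2,

which sums to exactly 100 across terms by construction (negative values
are possible and reported: they flag terms anti-correlated with the
overall prediction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignMatrix, SplineEncoder
from .penalized import Solution, poisson_deviance

__all__ = [
    "deviance_r2",
    "importance",
    "effect_table",
    "effect_curve",
    "baseline",
    "term_contributions",
    "EffectCurve",
]


def term_contributions(sol: Solution, X: np.ndarray) -> pd.DataFrame:
    """Per-subject contribution f_j(x_ij) of every group, one column per
    term (all terms, zeros for inactive groups)."""
    X = np.asarray(X, dtype=float)
    cols = {}
    for name, s in zip(sol.group_names, sol.group_slices):
        cols[name] = X[:, s] @ sol.coef[s]
    return pd.DataFrame(cols)


def deviance_r2(sol: Solution, X: np.ndarray, y: np.ndarray) -> float:
    """Percentage of the Poisson deviance explained relative to the
    intercept-only model."""
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("constant outcome: null deviance is zero")
    d_model = poisson_deviance(y, sol.predict(X))
    d_null = poisson_deviance(y, np.full(len(y), y.mean()))
    return 100.0 * (1.0 - d_model / d_null)


def importance(sol: Solution, X: np.ndarray) -> pd.Series:
    """Variable importance indices (percentage points, summing to 100)
    for the active terms."""
    contrib = term_contributions(sol, X)
    active = [nm for nm in contrib.columns
              if np.any(contrib[nm].to_numpy() != 0)]
    if not active:
        raise ValueError("no active terms: importance undefined")
    eta = sol.intercept + contrib.to_numpy().sum(axis=1)
    dev = eta - eta.mean()
    ss = float(dev @ dev)
    if ss <= 0:
        raise ValueError("constant linear predictor: importance undefined")
    vi = {
        nm: 100.0 * float(contrib[nm].to_numpy() @ dev) / ss for nm in active
    }
    return pd.Series(vi, name="importance").sort_values(ascending=False)


def baseline(sol: Solution) -> float:
    """Baseline predicted count, ``exp(f0)``."""
    return float(np.exp(sol.intercept))


def effect_table(sol: Solution, design: DesignMatrix, term: str) -> pd.Series:
    """Per-level multiplicative effect ``exp(f_j)`` of a categorical
    term. Values above 1 raise the baseline prediction, values below 1
    lower it."""
    ttype = design.term_types.get(term)
    if ttype is None:
        raise KeyError(f"unknown term {term!r}")
    if ttype == "numeric":
        raise ValueError(
            f"term {term!r} is numeric: use effect_curve instead"
        )
    enc = design.encoders[term]
    beta_g = sol.coef_block(term)
    f = enc.level_rows() @ beta_g
    return pd.Series(np.exp(f), index=enc.levels_, name=f"exp(f_{term})")


@dataclass
class EffectCurve:
    """Multiplicative effect of a numeric term over a value grid."""

    term: str
    grid: np.ndarray
    link: np.ndarray  # f_j on the log scale
    response: np.ndarray  # exp(f_j)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": self.grid, "link": self.link, "response": self.response}
        )


def effect_curve(
    sol: Solution,
    design: DesignMatrix,
    term: str,
    grid: np.ndarray | None = None,
    n_points: int = 100,
) -> EffectCurve:
    """Effect curve of a numeric (spline-expanded) term.

    The default grid is ``n_points`` equally spaced values across the
    observed training range; explicit grids outside that range are
    rejected (the spline basis does not extrapolate).
    """
    ttype = design.term_types.get(term)
    if ttype is None:
        raise KeyError(f"unknown term {term!r}")
    if ttype != "numeric":
        raise ValueError(f"term {term!r} is categorical: use effect_table")
    enc: SplineEncoder = design.encoders[term]
    lo = enc.x_mean_ + enc.lo_ * enc.x_sd_
    hi = enc.x_mean_ + enc.hi_ * enc.x_sd_
    if grid is None:
        grid = np.linspace(lo, hi, n_points)
    grid = np.asarray(grid, dtype=float)
    eps = 1e-9 * max(1.0, abs(hi - lo))
    if grid.min() < lo - eps or grid.max() > hi + eps:
        raise ValueError(
            f"grid for {term!r} extends outside the observed range "
            f"[{lo:.4g}, {hi:.4g}]"
        )
    beta_g = sol.coef_block(term)
    f = enc.evaluate(grid) @ beta_g
    return EffectCurve(term=term, grid=grid, link=f, response=np.exp(f))
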