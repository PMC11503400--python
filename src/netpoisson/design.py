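"""Grouped design matrices: factor codings and spline basis expansion.

Each model term (one original predictor) expands into a block of
columns that is penalized as a group:

* unordered factors -> one indicator column per level (no reference
  level dropped; the group penalty resolves the aliasing, and keeping
  all levels makes per-level multiplicative effects directly
  reportable);
* ordered factors -> orthogonal polynomial contrasts up to degree
  ``levels - 1``;
* numeric predictors -> a cubic B-spline basis of dimension
  ``basis_df`` with interior knots at equally spaced quantiles, rotated
  into the spectral coordinates of the curvature (roughness) penalty so
  that columns are ordered from smooth to wiggly and are mutually
  penalty-orthogonal.

All columns are centered to sample mean zero, which anchors the model
intercept at the cohort baseline. Group weights are ``sqrt(group
size)`` following standard group-lasso practice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["DesignMatrix", "SplineDesign", "encode_term", "build_design"]


class DegenerateTermError(ValueError):
    """Raised when a term carries no usable variation."""


# ---------------------------------------------------------------------------
# encoders


def _poly_contrasts(k: int) -> np.ndarray:
    """Orthonormal polynomial contrasts for k ordered levels
    (k x (k-1): linear, quadratic, ...)."""
    x = np.arange(k, dtype=float)
    V = np.vander(x, k, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))  # deterministic sign: leading coef > 0
    return Q[:, 1:]


class FactorEncoder:
    """All-level indicator coding of an unordered factor."""

    kind = "factor"

    def fit(self, col: pd.Series) -> "FactorEncoder":
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = [str(c) for c in col.cat.categories if (col == c).any()]
        else:
            levels = sorted(col.astype(str).unique())
        if len(levels) < 2:
            raise DegenerateTermError(
                f"factor {col.name!r} has fewer than 2 observed levels"
            )
        self.levels_ = levels
        raw = self._raw(col)
        self.means_ = raw.mean(axis=0)
        return self

    def _raw(self, col: pd.Series) -> np.ndarray:
        vals = col.astype(str).to_numpy()
        out = np.zeros((len(vals), len(self.levels_)))
        pos = {lev: j for j, lev in enumerate(self.levels_)}
        for i, v in enumerate(vals):
            if v not in pos:
                raise ValueError(
                    f"unseen level {v!r} for factor {col.name!r}"
                )
            out[i, pos[v]] = 1.0
        return out

    def transform(self, col: pd.Series) -> np.ndarray:
        return self._raw(col) - self.means_

    def level_rows(self) -> np.ndarray:
        """Centered encoding of each level (levels x columns); used for
        per-level effect tables."""
        return np.eye(len(self.levels_)) - self.means_

    def column_names(self, term: str) -> list[str]:
        return [f"{term}[{lev}]" for lev in self.levels_]

    def meta(self) -> dict:
        return {"kind": self.kind, "levels": self.levels_,
                "means": self.means_.tolist()}


class OrderedEncoder(FactorEncoder):
    """Polynomial-contrast coding of an ordered factor."""

    kind = "ordered"

    def fit(self, col: pd.Series) -> "OrderedEncoder":
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = [str(c) for c in col.cat.categories if (col == c).any()]
        else:
            levels = sorted(col.astype(str).unique())
        if len(levels) < 2:
            raise DegenerateTermError(
                f"ordered factor {col.name!r} has fewer than 2 observed levels"
            )
        self.levels_ = levels
        self.contrasts_ = _poly_contrasts(len(levels))
        raw = self._raw(col)
        self.means_ = raw.mean(axis=0)
        return self

    def _raw(self, col: pd.Series) -> np.ndarray:
        vals = col.astype(str).to_numpy()
        pos = {lev: j for j, lev in enumerate(self.levels_)}
        try:
            codes = np.array([pos[v] for v in vals])
        except KeyError as e:
            raise ValueError(
                f"unseen level {e.args[0]!r} for ordered factor {col.name!r}"
            ) from None
        return self.contrasts_[codes]

    def level_rows(self) -> np.ndarray:
        return self.contrasts_ - self.means_

    def column_names(self, term: str) -> list[str]:
        deg = ["linear", "quadratic", "cubic"] + [
            f"deg{d}" for d in range(4, len(self.levels_))
        ]
        return [f"{term}.{deg[j]}" for j in range(len(self.levels_) - 1)]

    def meta(self) -> dict:
        return {
            "kind": self.kind,
            "levels": self.levels_,
            "contrasts": self.contrasts_.tolist(),
            "means": self.means_.tolist(),
        }


def _roughness_penalty(t: np.ndarray, m: int) -> np.ndarray:
    """Exact integral of products of second derivatives of the cubic
    B-spline basis (piecewise quadratic integrand; 3-point Gauss)."""
    spl = BSpline(t, np.eye(m), 3)
    d2 = spl.derivative(2)
    knots = np.unique(t)
    gx, gw = np.polynomial.legendre.leggauss(3)
    omega = np.zeros((m, m))
    for lo, hi in zip(knots[:-1], knots[1:]):
        mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
        pts = mid + half * gx
        vals = d2(pts)  # (3, m)
        omega += half * (vals.T * gw) @ vals
    return omega


class SplineEncoder:
    """Spectral smoothing-spline basis for a numeric predictor.

    The predictor is standardized, expanded in a cubic B-spline basis of
    dimension ``basis_df`` (interior knots at equally spaced quantiles),
    and rotated by the eigenvectors of the curvature penalty; columns
    are then scaled to unit sample variance and centered. Falls back to
    orthogonal polynomials when too few distinct values support a cubic
    basis.
    """

    kind = "numeric"

    def __init__(self, basis_df: int = 5):
        self.basis_df = basis_df

    def fit(self, col: pd.Series) -> "SplineEncoder":
        x = col.to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"non-finite values in numeric term {col.name!r}")
        distinct = np.unique(x)
        if distinct.size < 2:
            raise DegenerateTermError(f"numeric term {col.name!r} is constant")
        df = self.basis_df
        if distinct.size < df:
            warnings.warn(
                f"term {col.name!r}: only {distinct.size} distinct values; "
                f"reducing basis dimension from {df} to {distinct.size - 1}",
                UserWarning,
            )
            df = distinct.size - 1
        self.df_ = df
        self.x_mean_ = float(x.mean())
        self.x_sd_ = float(x.std())
        z = (x - self.x_mean_) / self.x_sd_
        self.lo_, self.hi_ = float(z.min()), float(z.max())

        if df >= 3:
            # m = df + 1 B-spline functions; the constant direction is
            # projected out below, leaving df centered columns of full
            # rank (B-splines sum to one, so the raw span contains the
            # constant). Boundary knots sit at trimmed quantiles so the
            # basis has no free curvature in the extreme, data-starved
            # tails; beyond them the basis continues as a constant.
            m = df + 1
            self.tlo_, self.thi_ = (
                float(np.quantile(z, 0.005)), float(np.quantile(z, 0.995)))
            if self.thi_ <= self.tlo_:
                self.tlo_, self.thi_ = self.lo_, self.hi_
            n_int = m - 4
            if n_int > 0:
                qs = np.linspace(0, 1, n_int + 2)[1:-1]
                interior = np.quantile(z, qs)
                interior = np.clip(interior, self.tlo_, self.thi_)
            else:
                interior = np.array([])
            t = np.concatenate(
                [[self.tlo_] * 4, interior, [self.thi_] * 4])
            self.knots_ = t
            omega = _roughness_penalty(t, m)
            # orthonormal complement of the constant coefficient
            # direction, then spectral ordering of the curvature
            # penalty restricted to that complement
            c0 = np.full(m, 1.0 / np.sqrt(m))
            u, s2, _ = np.linalg.svd(np.eye(m) - np.outer(c0, c0))
            q = u[:, s2 > 0.5]  # (m, df)
            w, vv = np.linalg.eigh(q.T @ omega @ q)
            rot = q @ vv  # smooth-to-wiggly ordering
            # deterministic signs: largest-magnitude entry positive
            lead = np.argmax(np.abs(rot), axis=0)
            rot = rot * np.sign(rot[lead, np.arange(rot.shape[1])])
            self.rotation_ = rot
            # roughness-weighted scaling: a coefficient on a wiggly
            # column buys less function than the same coefficient on a
            # smooth column, so the group-norm penalty discourages
            # wiggliness (the smoothing-spline prior)
            rough = np.sqrt(1.0 + np.clip(w, 0.0, None))
        else:
            self.knots_ = None
            self.rotation_ = None
            rough = np.ones(df)

        raw = self._raw(z)
        col_sd = raw.std(axis=0)
        if np.any(col_sd <= 0):
            raise DegenerateTermError(
                f"degenerate spline basis for term {col.name!r}"
            )
        # one block-level constant keeps terms comparable under a
        # shared lambda without disturbing the within-group weighting
        block = float(np.mean(col_sd / rough))
        self.scales_ = rough * block
        scaled = raw / self.scales_
        self.means_ = scaled.mean(axis=0)
        return self

    def _raw(self, z: np.ndarray) -> np.ndarray:
        if self.knots_ is None:
            # low-information fallback: plain polynomial columns
            return np.vander(z, self.df_ + 1, increasing=True)[:, 1:]
        zc = np.clip(z, self.tlo_, self.thi_)
        B = BSpline.design_matrix(zc, self.knots_, 3).toarray()
        return B @ self.rotation_

    def transform(self, col: pd.Series) -> np.ndarray:
        z = (col.to_numpy(dtype=float) - self.x_mean_) / self.x_sd_
        return self._raw(z) / self.scales_ - self.means_

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        """Centered basis at arbitrary values (original scale); used by
        effect curves."""
        return self.transform(pd.Series(np.asarray(values, dtype=float)))

    def column_names(self, term: str) -> list[str]:
        return [f"{term}.s{j + 1}" for j in range(self.df_)]

    def meta(self) -> dict:
        return {
            "kind": self.kind,
            "df": self.df_,
            "x_mean": self.x_mean_,
            "x_sd": self.x_sd_,
            "range": [self.lo_, self.hi_],
            "knots": None if self.knots_ is None else self.knots_.tolist(),
            "rotation": None
            if self.rotation_ is None
            else self.rotation_.tolist(),
            "scales": self.scales_.tolist(),
            "means": self.means_.tolist(),
        }


_ENCODERS = {
    "factor": lambda df: FactorEncoder(),
    "ordered": lambda df: OrderedEncoder(),
    "numeric": lambda df: SplineEncoder(df),
}


def encode_term(
    column: pd.Series, type: str, basis_df: int = 5
) -> tuple[np.ndarray, dict]:
    """Encode one predictor into its centered column block.

    Returns the block and a metadata dict sufficient to re-evaluate the
    encoding at new values.
    """
    if type not in _ENCODERS:
        raise ValueError(f"unknown term type {type!r}")
    enc = _ENCODERS[type](basis_df).fit(column)
    return enc.transform(column), enc.meta()


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Column-expanded design with group bookkeeping."""

    X: np.ndarray
    column_names: list[str]
    group_index: list[str]  # term name per column
    term_types: dict[str, str]
    basis_meta: dict[str, dict]
    encoders: dict[str, object] = field(repr=False, default_factory=dict)

    @property
    def terms(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.group_index:
            seen.setdefault(t)
        return list(seen)

    @property
    def column_means(self) -> np.ndarray:
        return self.X.mean(axis=0)

    def group_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        gi = self.group_index
        start = 0
        for j in range(1, len(gi) + 1):
            if j == len(gi) or gi[j] != gi[start]:
                out[gi[start]] = slice(start, j)
                start = j
        return out

    def group_weights(self) -> dict[str, float]:
        return {
            t: float(np.sqrt(s.stop - s.start))
            for t, s in self.group_slices().items()
        }

    def save(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        pd.DataFrame(self.X, columns=self.column_names).to_csv(
            matrix_path, index=False
        )
        meta = {
            "group_index": self.group_index,
            "term_types": self.term_types,
            "basis_meta": self.basis_meta,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=1))


def infer_term_type(col: pd.Series) -> str:
    if isinstance(col.dtype, pd.CategoricalDtype):
        return "ordered" if col.dtype.ordered else "factor"
    if col.dtype == object or pd.api.types.is_bool_dtype(col):
        return "factor"
    return "numeric"


class SplineDesign(TransformerMixin, BaseEstimator):
    """Transformer building the grouped, centered design matrix.

    Parameters
    ----------
    terms : sequence of str or mapping str -> {"factor","ordered","numeric"}
        Predictors to include; with a plain sequence, types are inferred
        from the column dtypes (ordered categoricals -> ordered).
    basis_df : int
        Basis dimension per numeric term.
    """

    def __init__(self, terms: Sequence[str] | Mapping[str, str] | None = None,
                 basis_df: int = 5):
        self.terms = terms
        self.basis_df = basis_df

    def fit(self, table: pd.DataFrame, y=None) -> "SplineDesign":
        if self.terms is None:
            term_types = {c: infer_term_type(table[c]) for c in table.columns}
        elif isinstance(self.terms, Mapping):
            term_types = dict(self.terms)
        else:
            term_types = {}
            for t in self.terms:
                if t not in table.columns:
                    raise ValueError(f"term {t!r} not in table")
                term_types[t] = infer_term_type(table[t])
        for t in term_types:
            if t not in table.columns:
                raise ValueError(f"term {t!r} not in table")
        self.term_types_ = term_types
        self.encoders_ = {}
        names: list[str] = []
        gindex: list[str] = []
        for t, ttype in term_types.items():
            enc = _ENCODERS[ttype](self.basis_df).fit(table[t])
            self.encoders_[t] = enc
            cn = enc.column_names(t)
            names.extend(cn)
            gindex.extend([t] * len(cn))
        self.column_names_ = names
        self.group_index_ = gindex
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        blocks = [self.encoders_[t].transform(table[t]) for t in self.term_types_]
        return np.hstack(blocks)

    def design(self, table: pd.DataFrame) -> DesignMatrix:
        return DesignMatrix(
            X=self.transform(table),
            column_names=list(self.column_names_),
            group_index=list(self.group_index_),
            term_types=dict(self.term_types_),
            basis_meta={t: e.meta() for t, e in self.encoders_.items()},
            encoders=dict(self.encoders_),
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.column_names_, dtype=object)


def build_design(
    table: pd.DataFrame,
    terms: Sequence[str] | Mapping[str, str] | None = None,
    basis_df: int = 5,
) -> DesignMatrix:
    """Fit-and-build convenience wrapper over :class:`SplineDesign`."""
    return SplineDesign(terms=terms, basis_df=basis_df).fit(table).design(table)
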