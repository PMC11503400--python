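"""Synthetic cohort generator for the connectivity-to-attention analysis.

Emulates the statistical structure of a large developmental-cohort
dataset: categorical demographic risk factors with realistic marginals,
uniformly distributed age around 10 years, 78 correlated network-pair
connectivity features on the averaged Fisher-z scale, and a count-valued
attention-problem outcome drawn from a log-link additive Poisson model

    log mu_i = f0 + sum_j f_j(x_ij),      y_i ~ Poisson(mu_i),

so that every downstream stage (design expansion, penalized fitting,
cross-validation, interpretation) can be exercised and validated without
access to restricted data. Default factor marginals, the baseline rate
``exp(f0)`` and the multiplicative factor effects follow published
estimates for this population; the default connectivity effect is a
smooth monotone curve on the default-mode / dorsal-attention feature
(canonical column name ``DLA_DT``), whose observed values lie mostly in [-0.8, 0.2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .connectivity import NETWORKS, NONE_LABEL, feature_names

__all__ = [
    "GeneratorSpec",
    "gen_demographics",
    "gen_fc_features",
    "gen_outcome",
    "gen_roi_timeseries",
    "generate_dataset",
    "centered_log_effects",
    "FACTOR_LEVELS",
    "DEFAULT_MARGINALS",
    "DEFAULT_EFFECTS",
    "OUTCOME_COLUMN",
    "DT_DLA_FEATURE",
]

OUTCOME_COLUMN = "attention"

#: Canonical column name of the default-mode / dorsal-attention pair
#: (networks sorted lexicographically, so DLA precedes DT).
DT_DLA_FEATURE = "DLA_DT"

#: Declared level sets for every categorical predictor.
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "site": tuple(f"site{i:02d}" for i in range(1, 23)),
    "sex": ("Male", "Female"),
    "race": (
        "White",
        "Black",
        "Native",
        "Asian",
        "Hispanic",
        "Multiple",
    ),
    "income": ("<50k", "50-100k", ">100k"),
    "education": ("HS or Less", "Some College", "Bachelor", "Graduate"),
    "alcohol": ("None", "Father Only", "Mother Only", "Both Parents"),
    "drugs": ("None", "Father Only", "Mother Only", "Both Parents"),
}

#: Ordered factors (levels above are in increasing order).
ORDERED_FACTORS = ("income", "education")


def _norm(d: Mapping[str, float]) -> dict[str, float]:
    s = float(sum(d.values()))
    return {k: v / s for k, v in d.items()}


#: Default marginal distributions (renormalized to machine precision).
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "site": {lev: 1.0 / 22.0 for lev in FACTOR_LEVELS["site"]},
    "sex": _norm({"Male": 0.49994, "Female": 0.50006}),
    "race": _norm(
        {
            "White": 0.56937,
            "Black": 0.12094,
            "Native": 0.00251,
            "Asian": 0.01466,
            "Hispanic": 0.19539,
            "Multiple": 0.09713,
        }
    ),
    "income": _norm({"<50k": 0.27334, "50-100k": 0.28688, ">100k": 0.43978}),
    "education": _norm(
        {
            "HS or Less": 0.11342,
            "Some College": 0.25116,
            "Bachelor": 0.26983,
            "Graduate": 0.36559,
        }
    ),
    "alcohol": _norm(
        {
            "None": 0.85061,
            "Father Only": 0.11067,
            "Mother Only": 0.02231,
            "Both Parents": 0.01642,
        }
    ),
    "drugs": _norm(
        {
            "None": 0.69207,
            "Father Only": 0.08059,
            "Mother Only": 0.16155,
            "Both Parents": 0.06580,
        }
    ),
}


def centered_log_effects(
    multiplicative: Mapping[str, float], marginal: Mapping[str, float]
) -> dict[str, float]:
    """Log per-level effects, mean-centered under the factor marginal.

    Centering shifts all levels by a common constant, so between-level
    ratios are preserved while the weighted mean effect is absorbed into
    the intercept (keeping ``exp(f0)`` interpretable as the baseline).
    """
    logs = {k: math.log(v) for k, v in multiplicative.items()}
    mean = sum(marginal[k] * logs[k] for k in logs)
    return {k: v - mean for k, v in logs.items()}


def default_dt_dla_effect(z: np.ndarray) -> np.ndarray:
    """Monotone increasing log-effect of the DT-DLA connectivity.

    Rises steeply as the anticorrelation weakens from -0.8 to about
    -0.4 and then flattens, spanning roughly a 6-fold multiplicative
    range over [-0.8, 0.2].
    """
    z = np.asarray(z, dtype=float)
    return 0.9 * np.tanh((z + 0.5) / 0.25)


def _default_effects() -> dict[str, object]:
    eff: dict[str, object] = {}
    mult = {
        "sex": {"Male": 1.17, "Female": 0.85},
        "income": {"<50k": 1.13, "50-100k": 0.99, ">100k": 0.89},
        "alcohol": {
            "None": 0.87,
            "Father Only": 0.93,
            "Mother Only": 1.03,
            "Both Parents": 1.19,
        },
        "drugs": {
            "None": 0.76,
            "Father Only": 0.93,
            "Mother Only": 1.12,
            "Both Parents": 1.27,
        },
    }
    for name, levels in mult.items():
        eff[name] = centered_log_effects(levels, DEFAULT_MARGINALS[name])
    eff[DT_DLA_FEATURE] = default_dt_dla_effect
    return eff


DEFAULT_EFFECTS: dict[str, object] = _default_effects()


def _default_fc_moments() -> tuple[dict[str, float], dict[str, float]]:
    means, sds = {}, {}
    for name in feature_names():
        a, b = name.split("_", 1)
        means[name] = 0.45 if a == b else 0.10
        sds[name] = 0.15
    means[DT_DLA_FEATURE] = -0.35
    return means, sds


@dataclass
class GeneratorSpec:
    """Configuration of the synthetic cohort generator.

    Parameters
    ----------
    n_subjects : int
        Cohort size.
    seed : int
        Base seed; every stage derives its own stream from it.
    factor_marginals : dict
        Factor name -> {level: probability}. Probabilities must sum to 1.
    intercept_log_scale : float
        f0, the intercept of the log-link model. The default gives a
        baseline expected count ``exp(f0) = 1.452``.
    effect_spec : dict
        Term name -> per-level log-effects (factors) or a callable
        mapping values to log-effects (numeric terms). Factor effects
        must be mean-centered under the factor marginal.
    fc_correlation : None | float | array | dict
        Correlation structure of the 78 connectivity features: ``None``
        for identity, a scalar for exchangeable correlation, a full
        78x78 matrix, or a ``{(name_a, name_b): rho}`` override of the
        identity.
    fc_means, fc_sds : dict
        Per-feature mean and sd on the averaged-z scale.
    outcome_cap : int | None
        If set, outcome values above the cap are redrawn (truncation);
        off by default because the fitted likelihood is uncapped
        Poisson.
    """

    n_subjects: int = 1000
    seed: int = 0
    factor_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    intercept_log_scale: float = math.log(1.452)
    effect_spec: dict[str, object] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    fc_correlation: object = 0.2
    fc_means: dict[str, float] = field(
        default_factory=lambda: _default_fc_moments()[0]
    )
    fc_sds: dict[str, float] = field(
        default_factory=lambda: _default_fc_moments()[1]
    )
    age_range: tuple[float, float] = (9.0, 11.0)
    outcome_cap: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, marg in self.factor_marginals.items():
            if name not in FACTOR_LEVELS:
                raise ValueError(f"unknown factor name: {name!r}")
            unknown = set(marg) - set(FACTOR_LEVELS[name])
            if unknown:
                raise ValueError(
                    f"unknown levels for factor {name!r}: {sorted(unknown)}"
                )
            s = sum(marg.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(
                    f"marginal probabilities for {name!r} sum to {s}, not 1"
                )
            if any(p < 0 for p in marg.values()):
                raise ValueError(f"negative probability in factor {name!r}")
            # exact renormalization so the invariant holds to 1e-12
            self.factor_marginals[name] = _norm(marg)

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream for a pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage)))


def build_fc_correlation(spec: GeneratorSpec) -> np.ndarray:
    """Materialize the 78x78 feature correlation matrix and check PSD."""
    names = feature_names()
    k = len(names)
    c = spec.fc_correlation
    if c is None:
        corr = np.eye(k)
    elif np.isscalar(c):
        rho = float(c)
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
    elif isinstance(c, dict):
        corr = np.eye(k)
        pos = {n: i for i, n in enumerate(names)}
        for (a, b), rho in c.items():
            if a not in pos or b not in pos:
                raise ValueError(f"unknown feature in fc_correlation: {(a, b)}")
            corr[pos[a], pos[b]] = corr[pos[b], pos[a]] = float(rho)
    else:
        corr = np.asarray(c, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"fc_correlation must be {k}x{k}")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("fc_correlation must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("fc_correlation must have unit diagonal")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-8:
        raise ValueError("fc_correlation is not positive semi-definite")
    return corr


def gen_demographics(spec: GeneratorSpec) -> pd.DataFrame:
    """Sample the categorical risk factors and age, independently
    across columns and subjects."""
    rng = spec.rng(1)
    n = spec.n_subjects
    out = {}
    for name in FACTOR_LEVELS:
        marg = spec.factor_marginals.get(name)
        if marg is None:
            raise ValueError(f"no marginal defined for factor {name!r}")
        levels = [lev for lev in FACTOR_LEVELS[name] if lev in marg]
        probs = np.array([marg[lev] for lev in levels])
        draws = rng.choice(len(levels), size=n, p=probs)
        col = pd.Categorical.from_codes(
            draws, categories=levels, ordered=name in ORDERED_FACTORS
        )
        out[name] = col
    lo, hi = spec.age_range
    out["age"] = rng.uniform(lo, hi, size=n)
    return pd.DataFrame(out)


def gen_fc_features(spec: GeneratorSpec) -> pd.DataFrame:
    """Draw the 78 connectivity features from a correlated Gaussian on
    the averaged Fisher-z scale, each column mapped to its declared
    mean and sd."""
    corr = build_fc_correlation(spec)
    names = feature_names()
    rng = spec.rng(2)
    # eigh-based square root: robust to semi-definite structures
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((spec.n_subjects, len(names))) @ root.T
    means = np.array([spec.fc_means[n] for n in names])
    sds = np.array([spec.fc_sds[n] for n in names])
    if np.any(sds <= 0):
        raise ValueError("fc sds must be positive")
    return pd.DataFrame(z * sds + means, columns=names)


def _term_contribution(
    table: pd.DataFrame, name: str, effect: object
) -> np.ndarray:
    if name not in table.columns:
        raise ValueError(f"effect refers to unknown column {name!r}")
    col = table[name]
    if callable(effect):
        f = np.asarray(effect(col.to_numpy(dtype=float)), dtype=float)
        return f - f.mean()  # numeric effects centered empirically
    effect = dict(effect)
    vals = col.astype(str).map(effect)
    if vals.isna().any():
        missing = sorted(set(col.astype(str)) - set(effect))
        raise ValueError(f"effect for {name!r} missing levels: {missing}")
    return vals.to_numpy(dtype=float)


def gen_outcome(table: pd.DataFrame, spec: GeneratorSpec) -> pd.DataFrame:
    """Fill the count outcome from the log-link additive model.

    ``log mu = f0 + sum_j f_j(x_j)`` with ``y ~ Poisson(mu)``; if
    ``outcome_cap`` is set, values above the cap are redrawn.
    """
    rng = spec.rng(3)
    eta = np.full(len(table), spec.intercept_log_scale)
    for name, effect in spec.effect_spec.items():
        eta = eta + _term_contribution(table, name, effect)
    mu = np.exp(eta)
    y = rng.poisson(mu)
    if spec.outcome_cap is not None:
        cap = int(spec.outcome_cap)
        bad = y > cap
        while bad.any():
            y[bad] = rng.poisson(mu[bad])
            bad = y > cap
    out = table.copy()
    out[OUTCOME_COLUMN] = y.astype(int)
    return out


def generate_dataset(spec: GeneratorSpec) -> pd.DataFrame:
    """Full synthetic subject table: demographics + connectivity
    features + Poisson outcome."""
    demo = gen_demographics(spec)
    fc = gen_fc_features(spec)
    table = pd.concat([demo, fc], axis=1)
    return gen_outcome(table, spec)


def write_subject_table(table: pd.DataFrame, path) -> None:
    """Write a subject table as CSV with a header row."""
    table.to_csv(path, index=False)


def read_subject_table(path) -> pd.DataFrame:
    """Read a subject table CSV, restoring categorical dtypes (ordered
    for income and education) and integer outcome."""
    df = pd.read_csv(path)
    for name, levels in FACTOR_LEVELS.items():
        if name in df.columns:
            df[name] = pd.Categorical(
                df[name].astype(str),
                categories=list(levels),
                ordered=name in ORDERED_FACTORS,
            )
    if OUTCOME_COLUMN in df.columns:
        df[OUTCOME_COLUMN] = df[OUTCOME_COLUMN].astype(int)
    return df


def full_term_list() -> dict[str, str]:
    """The standard model's term inventory: 7 factors + age + 78
    connectivity features (86 groups), with their design types."""
    terms: dict[str, str] = {}
    for name in FACTOR_LEVELS:
        terms[name] = "ordered" if name in ORDERED_FACTORS else "factor"
    terms["age"] = "numeric"
    for name in feature_names():
        terms[name] = "numeric"
    return terms


def gen_roi_timeseries(
    n_rois_per_network: Mapping[str, int] | None = None,
    T: int = 500,
    fd_spike_rate: float = 0.05,
    seed: int = 0,
    latent_share: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One subject's synthetic ROI time series with an FD trace.

    Each ROI signal is ``sqrt(latent_share)`` times its network's latent
    factor plus ``sqrt(1 - latent_share)`` independent noise, so the
    expected within-network correlation equals ``latent_share`` and
    between-network correlations are zero. The FD trace has a low-motion
    baseline below 0.2 mm with spikes above it at ``fd_spike_rate``.

    Returns ``(data, fd, labels)`` with ``data`` of shape (T, R).
    """
    if n_rois_per_network is None:
        n_rois_per_network = {net: 3 for net in NETWORKS}
    allowed = set(NETWORKS) | {NONE_LABEL}
    unknown = set(n_rois_per_network) - allowed
    if unknown:
        raise ValueError(f"unknown network names: {sorted(unknown)}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0.0 <= latent_share <= 1.0:
        raise ValueError("latent_share must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    a, b = math.sqrt(latent_share), math.sqrt(1.0 - latent_share)
    for net, r in n_rois_per_network.items():
        if r < 0:
            raise ValueError("ROI counts must be non-negative")
        latent = rng.standard_normal((T, 1))
        noise = rng.standard_normal((T, r))
        blocks.append(a * latent + b * noise)
        labels.extend([net] * r)
    data = np.hstack(blocks) if blocks else np.empty((T, 0))

    fd = rng.uniform(0.02, 0.15, size=T)
    spikes = rng.random(T) < fd_spike_rate
    fd[spikes] = 0.2 + rng.exponential(0.15, size=int(spikes.sum()))
    return data, fd, labels
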