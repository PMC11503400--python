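import numpy as np
import pytest

from netpoisson.connectivity import feature_names
from netpoisson.design import build_design
from netpoisson.synthetic import (
    DEFAULT_EFFECTS,
    DT_DLA_FEATURE,
    GeneratorSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_cohort():
    """n=2000 cohort with sex, drugs and DT-DLA effects only."""
    eff = {k: DEFAULT_EFFECTS[k] for k in ("sex", "drugs", DT_DLA_FEATURE)}
    spec = GeneratorSpec(n_subjects=2000, seed=101, effect_spec=eff)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    """Design over sex, drugs and five connectivity features."""
    fc = [DT_DLA_FEATURE] + [n for n in feature_names()[:5]]
    terms = {"sex": "factor", "drugs": "factor"}
    terms.update({n: "numeric" for n in fc})
    return build_design(small_cohort, terms)


@pytest.fixture(scope="session")
def small_xy(small_cohort, small_design):
    y = small_cohort["attention"].to_numpy(float)
    return small_design.X, y


def random_poisson_instance(seed, n=200, n_groups=5, group_size=1,
                            coef_scale=0.3):
    """Random design + Poisson outcome for solver tests; groups are
    contiguous column blocks."""
    rng = np.random.default_rng(seed)
    p = n_groups * group_size
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    beta = rng.normal(0, coef_scale, p)
    eta = 0.3 + X @ beta
    y = rng.poisson(np.exp(eta))
    groups = np.repeat(np.arange(n_groups), group_size)
    return X, y, groups
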