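import numpy as np
import pytest

from netpoisson.interpret import (
    baseline,
    deviance_r2,
    effect_curve,
    effect_table,
    importance,
    term_contributions,
)
from netpoisson.penalized import PenaltySpec, Solution, fit_path
from netpoisson.synthetic import DT_DLA_FEATURE


def make_solution(coef, slices, names, intercept=0.0):
    return Solution(
        intercept=intercept,
        coef=np.asarray(coef, dtype=float),
        group_names=list(names),
        group_slices=list(slices),
        group_weights=np.ones(len(names)),
        spec=PenaltySpec(lam=0.1),
    )


@pytest.fixture(scope="module")
def fitted(small_cohort, small_design):
    y = small_cohort["attention"].to_numpy(float)
    res = fit_path(small_design.X, y, small_design.group_index, n_lambda=40,
                   group_weights=small_design.group_weights())
    return res.solution(25), small_design, y


class TestDevianceR2:
    def test_intercept_only_is_zero(self):
        y = np.random.default_rng(0).poisson(2.0, 200)
        X = np.zeros((200, 1))
        sol = make_solution([0.0], [slice(0, 1)], ["a"],
                            intercept=np.log(y.mean()))
        assert deviance_r2(sol, X, y) == pytest.approx(0.0, abs=1e-10)

    def test_saturated_is_hundred(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = (np.log(y) - 1.0)[:, None]
        sol = make_solution([1.0], [slice(0, 1)], ["a"], intercept=1.0)
        assert deviance_r2(sol, X, y) == pytest.approx(100.0, abs=1e-10)

    def test_matches_independent_plugin_formula(self, fitted):
        """Cross-check against a from-scratch recomputation of
        100*(1 - D_model/D_null)."""
        sol, design, y = fitted
        mu = np.exp(sol.intercept + design.X @ sol.coef)
        ybar = y.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            t_model = np.where(y > 0, y * np.log(np.where(y > 0, y, 1) / mu),
                               0.0) - (y - mu)
            t_null = np.where(y > 0,
                              y * np.log(np.where(y > 0, y, 1) / ybar),
                              0.0) - (y - ybar)
        expected = 100.0 * (1.0 - t_model.sum() / t_null.sum())
        assert deviance_r2(sol, design.X, y) == pytest.approx(expected,
                                                              abs=1e-10)

    def test_constant_outcome_rejected(self):
        sol = make_solution([0.0], [slice(0, 1)], ["a"])
        with pytest.raises(ValueError, match="constant"):
            deviance_r2(sol, np.zeros((5, 1)), np.ones(5))


class TestImportance:
    def test_sums_to_100(self, fitted):
        sol, design, y = fitted
        assert len(sol.active_groups) >= 1
        vi = importance(sol, design.X)
        assert vi.sum() == pytest.approx(100.0, abs=1e-8)

    def test_single_active_term_is_100(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 2))
        X -= X.mean(axis=0)
        sol = make_solution([0.5, -0.2, 0.0], [slice(0, 1), slice(1, 2),
                                               slice(2, 3)], list("abc"))
        sol.coef[1] = 0.0
        vi = importance(sol, np.hstack([X, np.zeros((100, 1))]))
        assert list(vi.index) == ["a"]
        assert vi["a"] == pytest.approx(100.0, abs=1e-10)

    def test_orthogonal_equal_terms_split_evenly(self):
        n = 64
        t = np.arange(n)
        c1 = np.cos(2 * np.pi * t / n)
        c2 = np.sin(2 * np.pi * t / n)  # orthogonal, equal variance
        X = np.column_stack([c1, c2])
        sol = make_solution([1.0, 1.0], [slice(0, 1), slice(1, 2)], ["a", "b"])
        vi = importance(sol, X)
        assert vi["a"] == pytest.approx(50.0, abs=1e-8)
        assert vi["b"] == pytest.approx(50.0, abs=1e-8)

    def test_intercept_only_rejected(self):
        sol = make_solution([0.0], [slice(0, 1)], ["a"])
        with pytest.raises(ValueError, match="no active terms"):
            importance(sol, np.ones((10, 1)))

    def test_negative_importance_reported_not_clipped(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        x -= x.mean()
        # second term anti-correlated with the dominant one
        X = np.column_stack([x, -0.3 * x + 0.01 * rng.standard_normal(500)])
        X -= X.mean(axis=0)
        sol = make_solution([1.0, 1.0], [slice(0, 1), slice(1, 2)], ["a", "b"])
        vi = importance(sol, X)
        assert vi.sum() == pytest.approx(100.0, abs=1e-8)
        assert (vi < 0).any()


class TestEffects:
    def test_baseline_is_exp_intercept(self, fitted):
        sol, _, y = fitted
        assert baseline(sol) == pytest.approx(np.exp(sol.intercept))

    def test_zero_block_gives_unit_effects(self, fitted):
        sol, design, _ = fitted
        sol0 = make_solution(np.zeros_like(sol.coef), sol.group_slices,
                             sol.group_names)
        eff = effect_table(sol0, design, "drugs")
        assert np.allclose(eff.to_numpy(), 1.0)

    def test_centering_makes_weighted_geomean_one(self, small_cohort, fitted):
        sol, design, _ = fitted
        eff = effect_table(sol, design, "sex")
        freq = small_cohort["sex"].value_counts(normalize=True)
        logmean = sum(freq[lev] * np.log(eff[lev]) for lev in eff.index)
        assert logmean == pytest.approx(0.0, abs=1e-10)

    def test_numeric_term_needs_curve(self, fitted):
        sol, design, _ = fitted
        with pytest.raises(ValueError, match="effect_curve"):
            effect_table(sol, design, DT_DLA_FEATURE)
        with pytest.raises(ValueError, match="effect_table"):
            effect_curve(sol, design, "sex")

    def test_flat_curve_for_zero_coefficients(self, fitted):
        sol, design, _ = fitted
        sol0 = make_solution(np.zeros_like(sol.coef), sol.group_slices,
                             sol.group_names)
        curve = effect_curve(sol0, design, DT_DLA_FEATURE)
        assert np.allclose(curve.link, 0.0, atol=1e-12)
        assert np.allclose(curve.response, 1.0, atol=1e-12)

    def test_no_extrapolation(self, fitted):
        sol, design, _ = fitted
        with pytest.raises(ValueError, match="outside the observed range"):
            effect_curve(sol, design, DT_DLA_FEATURE,
                         grid=np.array([-5.0, 0.0]))

    def test_multiplicative_decomposition_exact(self, fitted):
        """exp(f0) * prod_j exp(f_j(x_ij)) reproduces every fitted mean."""
        sol, design, _ = fitted
        contrib = term_contributions(sol, design.X).to_numpy()
        mu_prod = baseline(sol) * np.exp(contrib).prod(axis=1)
        mu_direct = sol.predict(design.X)
        assert np.allclose(mu_prod, mu_direct, rtol=1e-10)
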