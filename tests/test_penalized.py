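import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from conftest import random_poisson_instance
from netpoisson.penalized import (
    PenaltySpec,
    fit_path,
    kkt_violation,
    lambda_sequence,
    penalty_value,
    poisson_deviance,
    prox_step,
)
from netpoisson.penalized import _prox_norms, _rho


class TestPoissonDeviance:
    def test_saturated_is_zero(self):
        y = np.array([1.0, 2.0, 5.0])
        assert poisson_deviance(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # y=[0,2], mu=[1,1]: D = 4 log 2
        assert poisson_deviance([0, 2], [1, 1]) == pytest.approx(
            4 * np.log(2), abs=1e-12)

    def test_intercept_mle_is_mean(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(2.0, 500)
        grid = np.linspace(1.0, 3.5, 401)
        dev = [poisson_deviance(y, np.full(500, m)) for m in grid]
        assert grid[int(np.argmin(dev))] == pytest.approx(y.mean(), abs=0.01)

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(ValueError):
            poisson_deviance([1.0], [0.0])


class TestPenaltyValue:
    @pytest.mark.parametrize("family,gamma", [("lasso", 4.0), ("mcp", 3.0),
                                              ("scad", 3.7)])
    def test_zero_block_is_zero(self, family, gamma):
        spec = PenaltySpec(family=family, gamma=gamma, lam=1.0, alpha=0.7)
        assert penalty_value(np.zeros(4), spec) == 0.0

    def test_lasso_linear(self):
        spec = PenaltySpec(family="lasso", alpha=1.0, lam=2.0)
        assert penalty_value(np.array([3.0]), spec) == pytest.approx(6.0)

    def test_mcp_plateau(self):
        # ||beta|| = 5 > gamma*lam = 3: value = gamma*lam^2/2 = 1.5
        spec = PenaltySpec(family="mcp", alpha=1.0, gamma=3.0, lam=1.0)
        assert penalty_value(np.array([5.0]), spec) == pytest.approx(1.5)

    def test_scad_plateau(self):
        spec = PenaltySpec(family="scad", alpha=1.0, gamma=3.7, lam=1.0)
        assert penalty_value(np.array([10.0]), spec) == pytest.approx(
            (3.7 + 1) / 2)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            PenaltySpec(family="ridge")

    def test_gamma_range_enforced(self):
        with pytest.raises(ValueError):
            PenaltySpec(family="mcp", gamma=2.0)
        with pytest.raises(ValueError):
            PenaltySpec(family="scad", gamma=3.0)


class TestProx:
    @pytest.mark.parametrize("family,gamma", [("lasso", 4.0), ("mcp", 3.0),
                                              ("scad", 3.7)])
    def test_below_threshold_maps_to_zero(self, family, gamma):
        spec = PenaltySpec(family=family, alpha=1.0, gamma=gamma, lam=1.0)
        z = np.array([0.3, 0.2])  # ||z|| < step*lam*alpha = 0.5
        (out,) = prox_step([z], step=0.5, spec=spec)
        assert np.all(out == 0.0)

    @pytest.mark.parametrize("family,gamma", [("lasso", 4.0), ("mcp", 3.0),
                                              ("scad", 3.7)])
    def test_pure_ridge_scaling(self, family, gamma):
        spec = PenaltySpec(family=family, alpha=0.0, gamma=gamma, lam=2.0)
        z = np.array([1.0, -2.0, 0.5])
        (out,) = prox_step([z], step=0.25, spec=spec)
        assert np.allclose(out, z / (1 + 0.25 * 2.0), atol=1e-12)

    def test_mcp_no_shrinkage_beyond_plateau(self):
        spec = PenaltySpec(family="mcp", alpha=1.0, gamma=3.0, lam=1.0)
        z = np.array([4.0, 3.0])  # ||z|| = 5 > gamma*lam = 3
        (out,) = prox_step([z], step=0.1, spec=spec)
        assert np.allclose(out, z, atol=1e-12)

    @pytest.mark.parametrize("family,gamma", [("lasso", 4.0), ("mcp", 2.5),
                                              ("mcp", 4.0), ("scad", 3.2),
                                              ("scad", 5.0)])
    def test_scalar_prox_matches_numeric_minimizer(self, family, gamma):
        """The closed-form prox agrees with brute-force 1-d minimization
        of its defining objective for random (norm, step, lam, alpha)."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            nz = float(rng.uniform(0, 6))
            step = float(rng.uniform(0.01, 0.4))
            lam = float(rng.uniform(0.1, 2.0))
            alpha = float(rng.uniform(0.05, 1.0))
            s = _prox_norms(np.array([nz]), step, np.array([lam]), family,
                            alpha, gamma)[0]

            def h(t):
                pen = alpha * _rho(np.array([t]), np.array([lam]), family,
                                   gamma)[0]
                return ((t - nz) ** 2 / (2 * step) + pen
                        + (1 - alpha) * lam * t**2 / 2)

            res = minimize_scalar(h, bounds=(0.0, nz + 1.0),
                                  method="bounded",
                                  options={"xatol": 1e-12})
            assert h(s) <= h(res.x) + 1e-10

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            prox_step([np.ones(2)], step=0.0, spec=PenaltySpec(lam=1.0))


class TestLambdaSequence:
    def test_default_length_100(self, small_xy, small_design):
        X, y = small_xy
        lam = lambda_sequence(X, y, small_design.group_index,
                              group_weights=small_design.group_weights())
        assert len(lam) == 100
        assert np.all(np.diff(lam) < 0)
        assert lam[-1] == pytest.approx(lam[0] * 0.01)

    def test_null_fit_at_lambda_max(self, small_xy, small_design):
        X, y = small_xy
        w = small_design.group_weights()
        res = fit_path(X, y, small_design.group_index, n_lambda=5,
                       group_weights=w)
        assert res.active_sets[0] == []
        assert np.exp(res.intercept_path[0]) == pytest.approx(y.mean(),
                                                              rel=1e-12)

    def test_weights_homogeneity(self, small_xy, small_design):
        X, y = small_xy
        w = small_design.group_weights()
        lam1 = lambda_sequence(X, y, small_design.group_index,
                               group_weights=w)
        lam2 = lambda_sequence(X, y, small_design.group_index,
                               group_weights={k: 2 * v for k, v in w.items()})
        assert np.allclose(lam2, lam1 / 2.0)

    def test_alpha_zero_flagged(self, small_xy, small_design):
        X, y = small_xy
        with pytest.warns(UserWarning, match="alpha = 0"):
            lambda_sequence(X, y, small_design.group_index, alpha=0.0)


class TestFitPath:
    def test_pure_noise_large_lambda_intercept_only(self):
        rng = np.random.default_rng(3)
        n = 500
        X = rng.standard_normal((n, 10))
        X -= X.mean(axis=0)
        y = rng.poisson(1.0, n)
        res = fit_path(X, y, np.repeat(np.arange(5), 2), n_lambda=3,
                       lambda_min_ratio=0.5)
        assert res.active_sets[0] == []
        assert np.exp(res.intercept_path[0]) == pytest.approx(y.mean())

    def test_informative_group_enters_first(self):
        """With one strong group among nulls, the lasso path activates
        the informative group before any null group."""
        rng = np.random.default_rng(11)
        n = 2000
        X = rng.standard_normal((n, 12))
        X -= X.mean(axis=0)
        eta = 0.2 + 0.5 * X[:, 0] - 0.4 * X[:, 1]
        y = rng.poisson(np.exp(eta))
        groups = np.repeat(np.arange(6), 2)  # group 0 is informative
        res = fit_path(X, y, groups, family="lasso")
        first_active = next(a for a in res.active_sets if a)
        assert first_active == [0]

    def test_deviance_monotone_along_path(self, small_xy, small_design):
        X, y = small_xy
        res = fit_path(X, y, small_design.group_index, n_lambda=40,
                       group_weights=small_design.group_weights())
        assert np.all(np.diff(res.deviance_path) <= 1e-6)

    def test_path_continuity_lasso(self, small_xy, small_design):
        X, y = small_xy
        res = fit_path(X, y, small_design.group_index, n_lambda=60,
                       group_weights=small_design.group_weights())
        jumps = np.abs(np.diff(res.coef_path, axis=0)).max(axis=1)
        assert jumps.max() < 0.2

    @pytest.mark.parametrize("family,gamma", [("lasso", 4.0), ("mcp", 3.0),
                                              ("scad", 4.0)])
    def test_kkt_conditions_along_path(self, family, gamma):
        X, y, groups = random_poisson_instance(21, n=400, n_groups=6,
                                               group_size=3)
        res = fit_path(X, y, groups, family=family, gamma=gamma, n_lambda=20)
        for k in (5, 12, 19):
            sol = res.solution(k)
            wa, wi = kkt_violation(X, y, sol.intercept, sol.coef,
                                   res.group_slices, res.group_weights,
                                   sol.spec)
            assert wa < 1e-4
            assert wi < 1e-4

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_path(np.ones((4, 2)), np.array([1, -1, 0, 2]), [0, 0])
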