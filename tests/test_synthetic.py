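import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netpoisson.synthetic import (
    DEFAULT_MARGINALS,
    DT_DLA_FEATURE,
    GeneratorSpec,
    centered_log_effects,
    gen_demographics,
    gen_fc_features,
    gen_outcome,
    gen_roi_timeseries,
    generate_dataset,
)


class TestDemographics:
    def test_sex_marginal_recovered(self):
        spec = GeneratorSpec(n_subjects=10**6, seed=1)
        demo = gen_demographics(spec)
        p = DEFAULT_MARGINALS["sex"]["Male"]
        se = np.sqrt(p * (1 - p) / 10**6)
        assert abs((demo["sex"] == "Male").mean() - p) < 3 * se

    def test_point_mass_marginal(self):
        spec = GeneratorSpec(
            n_subjects=50, seed=2,
            factor_marginals={**DEFAULT_MARGINALS,
                              "sex": {"Male": 1.0, "Female": 0.0}},
        )
        demo = gen_demographics(spec)
        assert (demo["sex"] == "Male").all()

    def test_drugs_marginal_gof(self):
        spec = GeneratorSpec(n_subjects=10**5, seed=3)
        demo = gen_demographics(spec)
        marg = spec.factor_marginals["drugs"]
        counts = demo["drugs"].value_counts()
        obs = np.array([counts.get(lev, 0) for lev in marg])
        exp = np.array([p * 10**5 for p in marg.values()])
        res = stats.chisquare(obs, exp)
        assert res.pvalue > 0.001

    def test_age_uniform_support(self):
        spec = GeneratorSpec(n_subjects=5000, seed=4)
        demo = gen_demographics(spec)
        assert demo["age"].between(9.0, 11.0).all()
        assert demo["age"].mean() == pytest.approx(10.0, abs=0.05)

    def test_bad_marginals_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            GeneratorSpec(factor_marginals={"handedness": {"L": 1.0}})
        with pytest.raises(ValueError, match="sum to"):
            GeneratorSpec(
                factor_marginals={**DEFAULT_MARGINALS,
                                  "sex": {"Male": 0.6, "Female": 0.6}}
            )

    def test_marginals_sum_to_one_exactly(self):
        spec = GeneratorSpec(seed=0)
        for marg in spec.factor_marginals.values():
            assert abs(sum(marg.values()) - 1.0) < 1e-12


class TestFCFeatures:
    def test_identity_structure_near_zero_correlations(self):
        spec = GeneratorSpec(n_subjects=10**5, seed=5, fc_correlation=None)
        fc = gen_fc_features(spec)
        corr = np.corrcoef(fc.to_numpy(), rowvar=False)
        off = corr[~np.eye(78, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_targeted_pair_correlation(self):
        a, b = "AD_CA", "DT_FO"
        spec = GeneratorSpec(
            n_subjects=10**5, seed=6, fc_correlation={(a, b): 0.6}
        )
        fc = gen_fc_features(spec)
        r = np.corrcoef(fc[a], fc[b])[0, 1]
        assert r == pytest.approx(0.6, abs=0.02)

    def test_dt_dla_bulk_in_plotted_range(self):
        spec = GeneratorSpec(n_subjects=10**4, seed=7)
        fc = gen_fc_features(spec)
        frac = fc[DT_DLA_FEATURE].between(-0.8, 0.2).mean()
        assert frac >= 0.99

    def test_non_psd_rejected(self):
        bad = np.eye(78)
        bad[0, 1] = bad[1, 0] = 1.5
        with pytest.raises(ValueError, match="positive semi-definite"):
            gen_fc_features(GeneratorSpec(n_subjects=10, fc_correlation=bad))


class TestOutcome:
    def test_baseline_rate_recovered(self):
        spec = GeneratorSpec(
            n_subjects=10**5, seed=8, effect_spec={},
            intercept_log_scale=np.log(1.452),
        )
        tab = gen_outcome(gen_demographics(spec), spec)
        se = np.sqrt(1.452 / 10**5)
        assert abs(tab["attention"].mean() - 1.452) < 3 * se

    def test_unit_poisson_moments(self):
        spec = GeneratorSpec(n_subjects=10**5, seed=9, effect_spec={},
                             intercept_log_scale=0.0)
        tab = gen_outcome(gen_demographics(spec), spec)
        y = tab["attention"]
        assert y.mean() == pytest.approx(1.0, abs=0.01)
        assert y.var() == pytest.approx(1.0, abs=0.02)

    def test_sex_multiplicative_ratio(self):
        eff = {"sex": centered_log_effects(
            {"Male": 1.17, "Female": 0.85}, DEFAULT_MARGINALS["sex"])}
        spec = GeneratorSpec(n_subjects=10**5, seed=10, effect_spec=eff)
        tab = gen_outcome(gen_demographics(spec), spec)
        m = tab.loc[tab["sex"] == "Male", "attention"].mean()
        f = tab.loc[tab["sex"] == "Female", "attention"].mean()
        assert m / f == pytest.approx(1.17 / 0.85, rel=0.03)

    def test_outcome_cap_truncates_by_redraw(self):
        spec = GeneratorSpec(n_subjects=5000, seed=11, effect_spec={},
                             intercept_log_scale=np.log(4.0), outcome_cap=6)
        tab = gen_outcome(gen_demographics(spec), spec)
        assert tab["attention"].max() <= 6
        assert tab["attention"].min() >= 0

    def test_unknown_effect_column_rejected(self):
        spec = GeneratorSpec(n_subjects=100, seed=12,
                             effect_spec={"nonexistent": {"a": 0.0}})
        with pytest.raises(ValueError, match="unknown column"):
            gen_outcome(gen_demographics(spec), spec)

    def test_right_skewed_counts(self):
        tab = generate_dataset(GeneratorSpec(n_subjects=20000, seed=13))
        y = tab["attention"]
        assert stats.skew(y) > 0.5
        assert (y == 0).mean() > 0.15


def test_fixed_seed_bit_identical():
    t1 = generate_dataset(GeneratorSpec(n_subjects=500, seed=42))
    t2 = generate_dataset(GeneratorSpec(n_subjects=500, seed=42))
    pd.testing.assert_frame_equal(t1, t2)
    t3 = generate_dataset(GeneratorSpec(n_subjects=500, seed=43))
    assert not t3["attention"].equals(t1["attention"])


def test_centered_log_effects_preserves_ratios():
    marg = DEFAULT_MARGINALS["drugs"]
    eff = centered_log_effects(
        {"None": 0.76, "Father Only": 0.93, "Mother Only": 1.12,
         "Both Parents": 1.27}, marg)
    assert sum(marg[k] * eff[k] for k in eff) == pytest.approx(0.0, abs=1e-12)
    assert np.exp(eff["Both Parents"] - eff["None"]) == pytest.approx(
        1.27 / 0.76)


class TestROITimeSeries:
    def test_pure_latent_gives_perfect_within_correlation(self):
        data, fd, labels = gen_roi_timeseries(T=200, seed=1, latent_share=1.0)
        labels = np.asarray(labels)
        for net in np.unique(labels):
            block = data[:, labels == net]
            corr = np.corrcoef(block, rowvar=False)
            assert np.allclose(corr, 1.0, atol=1e-10)

    def test_zero_spike_rate_keeps_fd_low(self):
        _, fd, _ = gen_roi_timeseries(T=2000, seed=2, fd_spike_rate=0.0)
        assert fd.max() < 0.2
        assert fd.min() >= 0.0

    def test_latent_share_sets_within_correlation(self):
        data, _, labels = gen_roi_timeseries(
            n_rois_per_network={"DT": 6, "DLA": 6}, T=1000, seed=3,
            latent_share=0.5,
        )
        labels = np.asarray(labels)
        vals = []
        for net in ("DT", "DLA"):
            corr = np.corrcoef(data[:, labels == net], rowvar=False)
            iu = np.triu_indices(corr.shape[0], k=1)
            vals.extend(corr[iu])
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_unknown_network_rejected(self):
        with pytest.raises(ValueError, match="unknown network"):
            gen_roi_timeseries(n_rois_per_network={"BOGUS": 3})
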