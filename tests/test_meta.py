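"""Random-effects pooling, heterogeneity and meta-analytic power."""

import numpy as np
import pytest
from scipy import stats

from specbias import (
    CorrelationEstimate,
    GroupContrast,
    MetaResult,
    PowerQuery,
    meta_power,
    pool,
    pool_correlations,
    pool_estimates,
    tau2_dl,
    tau2_reml,
)

Z975 = stats.norm.ppf(0.975)


def _contrast(d, var_d, model="m", attribute="a", g1="g1", g2="g2"):
    return GroupContrast(
        model=model, attribute=attribute, group1=g1, group2=g2, n1=10, n2=10, d=d, var_d=var_d
    )


def check_consistency(r: MetaResult):
    """Wald CI, Z and p must be mutually consistent in every MetaResult."""
    if r.scale == "d":
        assert r.ci_low == pytest.approx(r.estimate - Z975 * r.se)
        assert r.ci_high == pytest.approx(r.estimate + Z975 * r.se)
        assert r.z == pytest.approx(r.estimate / r.se)
    assert r.p == pytest.approx(2 * stats.norm.sf(abs(r.z)))
    assert 0.0 <= r.I2 <= 1.0
    assert r.tau2 >= 0.0
    assert r.Q >= 0.0


class TestTau2DL:
    def test_hand_worked_example(self):
        """y={0,2}, v={1,1}: Q=2, tau2 = (2-1)/(2-2/2) = 1."""
        assert tau2_dl([0, 2], [1, 1]) == pytest.approx(1.0)

    def test_homogeneous_estimates_give_zero(self):
        assert tau2_dl([0.7, 0.7, 0.7], [0.2, 0.3, 0.4]) == pytest.approx(0.0)

    def test_floor_at_zero_when_q_below_df(self):
        assert tau2_dl([0.50, 0.51, 0.49], [1.0, 1.0, 1.0]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            tau2_dl([1.0], [0.5])
        with pytest.raises(ValueError, match="positive"):
            tau2_dl([0, 1], [1.0, 0.0])


class TestPool:
    def test_single_study_passthrough(self):
        r = pool([_contrast(0.5, 0.04)])
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)
        assert r.ci_low == pytest.approx(0.108, abs=5e-4)
        assert r.ci_high == pytest.approx(0.892, abs=5e-4)
        assert r.tau2 == 0.0 and r.I2 == 0.0 and r.k == 1

    def test_hand_worked_two_study_example(self):
        r = pool([_contrast(0.0, 1.0), _contrast(2.0, 1.0)])
        assert r.estimate == pytest.approx(1.0)
        assert r.se == pytest.approx(1.0)
        assert r.tau2 == pytest.approx(1.0)
        assert r.Q == pytest.approx(2.0)
        assert r.I2 == pytest.approx(0.5)
        assert r.ci_low == pytest.approx(1.0 - Z975)
        check_consistency(r)

    def test_equal_weights_give_simple_mean(self):
        # Q <= df so tau2 floors at 0 and weights stay equal
        r = pool([_contrast(0.4, 1.0), _contrast(0.5, 1.0), _contrast(0.6, 1.0)])
        assert r.tau2 == 0.0
        assert r.estimate == pytest.approx(0.5)

    def test_tau2_zero_equals_fixed_effect_closed_form(self):
        y, v = [0.50, 0.52, 0.48], [0.04, 0.09, 0.16]  # homogeneous: Q < df
        r = pool_estimates(y, v, "DL")
        assert r.tau2 == 0.0
        w = 1 / np.asarray(v)
        assert r.estimate == pytest.approx(float(np.sum(w * y) / np.sum(w)))
        assert r.se == pytest.approx(float(np.sqrt(1 / np.sum(w))))

    def test_against_external_reference_values(self):
        """y={.2,.5,.9}, v={.04,.09,.16}: values frozen from an independent
        meta-analysis implementation (R metafor, method=DL)."""
        r = pool_estimates([0.2, 0.5, 0.9], [0.04, 0.09, 0.16], "DL")
        assert r.estimate == pytest.approx(0.4196154239, abs=1e-8)
        assert r.se == pytest.approx(0.1870672363, abs=1e-8)
        assert r.tau2 == pytest.approx(0.0277586207, abs=1e-8)
        assert r.Q == pytest.approx(2.6598360656, abs=1e-8)
        assert r.I2 == pytest.approx(0.248073959938, abs=1e-8)
        assert r.p == pytest.approx(0.0248886759, abs=1e-8)

    def test_mixed_contrast_pairs_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            pool([_contrast(0.1, 0.1, g1="a", g2="b"), _contrast(0.2, 0.1, g1="a", g2="c")])
        with pytest.raises(ValueError, match="no contrasts"):
            pool([])

    def test_se_decreases_with_k_for_identical_studies(self):
        ses = [
            pool([_contrast(0.5, 0.1)] * k).se
            for k in (1, 2, 4, 8)
        ]
        assert all(a > b for a, b in zip(ses, ses[1:]))


class TestREML:
    def test_against_external_reference_values(self):
        t2 = tau2_reml([0.2, 0.5, 0.9], [0.04, 0.09, 0.16])
        assert t2 == pytest.approx(0.0282351217, abs=1e-6)
        r = pool_estimates([0.2, 0.5, 0.9], [0.04, 0.09, 0.16], "REML")
        assert r.estimate == pytest.approx(0.4200870404, abs=1e-6)
        assert r.se == pytest.approx(0.1875626745, abs=1e-6)

    def test_agrees_with_dl_when_homogeneous_equal_variances(self):
        y, v = [0.50, 0.51, 0.49], [1.0, 1.0, 1.0]  # Q <= df
        assert abs(tau2_reml(y, v) - tau2_dl(y, v)) < 1e-6
        assert tau2_dl(y, v) == 0.0


class TestPoolCorrelations:
    def _corr(self, r, n, model="m"):
        return CorrelationEstimate(model=model, r=r, n=n)

    def test_equal_correlations_pool_to_themselves(self):
        r = pool_correlations([self._corr(0.5, 20), self._corr(0.5, 20), self._corr(0.5, 20)])
        assert r.estimate == pytest.approx(0.5)
        assert r.scale == "r"

    def test_single_correlation_passthrough(self):
        r = pool_correlations([self._corr(0.6, 28)])
        z = np.arctanh(0.6)
        se = 1 / np.sqrt(25)
        assert r.estimate == pytest.approx(0.6)
        assert r.ci_low == pytest.approx(np.tanh(z - Z975 * se))
        assert r.ci_high == pytest.approx(np.tanh(z + Z975 * se))

    def test_z_scale_hand_example(self):
        """z={0.2,0.6}, v={0.1,0.1}, tau2=0 floor -> pooled z=0.4, r=tanh(0.4)."""
        corrs = [self._corr(float(np.tanh(0.2)), 13), self._corr(float(np.tanh(0.6)), 13)]
        r = pool_correlations(corrs)
        assert r.estimate == pytest.approx(np.tanh(0.4), abs=1e-6)

    def test_ci_stays_inside_unit_interval(self):
        r = pool_correlations([self._corr(0.97, 10), self._corr(0.99, 10)])
        assert -1.0 < r.ci_low < r.ci_high < 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            pool_correlations([self._corr(0.5, 3)])


class TestMetaPower:
    def test_null_effect_power_equals_alpha(self):
        p = meta_power(PowerQuery(d=0.0, n1=10, n2=10, k=5, I2=0.2, alpha=0.05))
        assert p == pytest.approx(0.05)

    def test_design_level_power_exceeds_80_percent(self):
        """Smallest groups (n=8), k=7 models, I2=20%: d=0.95 is detectable."""
        p = meta_power(PowerQuery(d=0.95, n1=8, n2=8, k=7, I2=0.20))
        assert p > 0.80
        assert p == pytest.approx(0.99, abs=0.01)

    def test_monotone_in_d_k_n_and_decreasing_in_i2(self):
        base = PowerQuery(d=0.4, n1=10, n2=10, k=5, I2=0.2)
        p0 = meta_power(base)
        assert meta_power(PowerQuery(d=0.6, n1=10, n2=10, k=5, I2=0.2)) > p0
        assert meta_power(PowerQuery(d=0.4, n1=10, n2=10, k=10, I2=0.2)) > p0
        assert meta_power(PowerQuery(d=0.4, n1=30, n2=30, k=5, I2=0.2)) > p0
        assert meta_power(PowerQuery(d=0.4, n1=10, n2=10, k=5, I2=0.6)) < p0

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            meta_power(PowerQuery(d=0.5, n1=1, n2=10, k=5))
        with pytest.raises(ValueError):
            meta_power(PowerQuery(d=0.5, n1=10, n2=10, k=5, I2=1.0))
        with pytest.raises(ValueError):
            meta_power(PowerQuery(d=0.5, n1=10, n2=10, k=0))


class TestResultConsistency:
    @pytest.mark.parametrize("seed", range(4))
    def test_random_pools_are_internally_consistent(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 9)
        y = rng.normal(0.3, 0.5, k)
        v = rng.uniform(0.02, 0.3, k)
        for method in ("DL", "REML"):
            check_consistency(pool_estimates(y, v, method))
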