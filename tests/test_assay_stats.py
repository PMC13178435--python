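"""Assay statistics: enumeration oracles, calibration studies, power identities."""

import itertools

import numpy as np
import pytest
from scipy import stats

from orgaprint import assay_stats as ast
from orgaprint import synthetic
from orgaprint.datatypes import ConditionSample, PowerCurve, PowerSpec


def enumeration_mw_p(a, b):
    """Independent oracle: two-sided exact Mann-Whitney p by full enumeration."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(1.0 for x in a for y in b if x < y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        us.append(
            sum(1.0 for x in ga for y in gb if x < y)
            + 0.5 * sum(1 for x in ga for y in gb if x == y)
        )
    us = np.asarray(us)
    p = 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(p, 1.0)


class TestCoefficientOfVariation:
    def test_arithmetic(self):
        assert ast.coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)
        assert ast.coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            ast.coefficient_of_variation([-1.0, 1.0])

    def test_lognormal_monte_carlo(self, rng):
        mu, sig = synthetic.lognormal_params(100.0, 0.48)
        v = rng.lognormal(mu, sig, 100_000)
        assert 0.46 <= ast.coefficient_of_variation(v) <= 0.50


class TestMannWhitney:
    def test_complete_separation_examples(self):
        assert ast.mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert ast.mann_whitney_p([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == pytest.approx(2 / 252)

    def test_identical_samples_give_one(self):
        assert ast.mann_whitney_p([1, 2, 3], [1, 2, 3]) == 1.0
        assert ast.mann_whitney_p([5, 5, 5], [5, 5, 5]) == 1.0

    def test_matches_enumeration_on_random_small_samples(self, rng):
        for n1, n2 in [(2, 3), (3, 3), (4, 2), (4, 4), (5, 3)]:
            a = rng.normal(size=n1)
            b = rng.normal(0.8, size=n2)
            assert ast.mann_whitney_p(a, b) == pytest.approx(enumeration_mw_p(a, b))

    def test_large_sample_matches_scipy_asymptotic(self, rng):
        a = rng.lognormal(0.0, 0.6, 40)
        b = rng.lognormal(0.4, 0.6, 35)
        ours = ast.mann_whitney_p(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_tied_data_matches_scipy(self, rng):
        a = rng.integers(0, 5, 30).astype(float)
        b = rng.integers(1, 6, 25).astype(float)
        ours = ast.mann_whitney_p(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        a = rng.lognormal(0, 0.5, (5000, 20))
        b = rng.lognormal(0, 0.5, (5000, 20))
        rate = np.mean(ast._batch_mannwhitney(a, b) < 0.05)
        assert 0.04 <= rate <= 0.06


class TestDagostinoPearson:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ast.dagostino_pearson(np.arange(10.0))

    def test_normal_calibration(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(2000, 500))
        _, p = stats.normaltest(x, axis=1)
        # our scalar wrapper must agree with the vectorized reference
        k2_0, p_0 = ast.dagostino_pearson(x[0])
        assert p_0 == pytest.approx(p[0])
        assert 0.04 <= np.mean(p < 0.05) <= 0.065

    def test_heavy_lognormal_rejected(self, rng):
        mu, sig = synthetic.lognormal_params(1.0, 1.74)
        v = rng.lognormal(mu, sig, 300)
        _, p = ast.dagostino_pearson(v)
        assert p < 0.001


class TestBootstrapCurve:
    def test_null_mean_p_near_half(self, rng):
        x = rng.lognormal(0.0, 0.5, 100)
        curve = ast.bootstrap_power_curve(x, x.copy(), n_grid=[10], iterations=512, seed=3)
        assert 0.40 <= curve.mean_p[0] <= 0.60

    def test_separated_populations_exact_mean(self, rng):
        a = rng.uniform(10.0, 20.0, 30)
        b = rng.uniform(0.0, 1.0, 30)
        curve = ast.bootstrap_power_curve(a, b, n_grid=[3, 4, 5], iterations=256, seed=4)
        # every resample is fully separated: p is the exact minimum at each n
        np.testing.assert_allclose(curve.mean_p, [2 / 20, 2 / 70, 2 / 252])
        np.testing.assert_allclose(curve.sem_p, 0.0)
        assert ast.min_n_below_alpha(curve, 0.05) == 4

    def test_seeded_determinism(self, default_readouts):
        a = default_readouts[("printed", "treated")].values
        b = default_readouts[("printed", "untreated")].values
        c1 = ast.bootstrap_power_curve(a, b, n_grid=[5, 10], iterations=128, seed=9)
        c2 = ast.bootstrap_power_curve(a, b, n_grid=[5, 10], iterations=128, seed=9)
        np.testing.assert_array_equal(c1.mean_p, c2.mean_p)
        np.testing.assert_array_equal(c1.sem_p, c2.sem_p)

    def test_saturation_flagged_not_fatal(self, rng):
        a = rng.lognormal(0, 0.3, 5)
        b = rng.lognormal(1, 0.3, 5)
        curve = ast.bootstrap_power_curve(a, b, n_grid=[5, 60], iterations=32, seed=1)
        assert list(curve.saturated) == [False, True]

    def test_without_replacement_bounds(self, rng):
        a = rng.lognormal(0, 0.3, 20)
        b = rng.lognormal(1, 0.3, 20)
        curve = ast.bootstrap_power_curve(a, b, n_grid=[10], iterations=32, seed=1, replace=False)
        assert curve.mean_p[0] < 0.05
        with pytest.raises(ValueError):
            ast.bootstrap_power_curve(a, b, n_grid=[30], iterations=8, seed=1, replace=False)

    def test_mean_p_nonincreasing_for_shifted_populations(self, default_readouts):
        a = default_readouts[("printed", "treated")].values
        b = default_readouts[("printed", "untreated")].values
        curve = ast.bootstrap_power_curve(a, b, n_grid=[4, 8, 16, 32], iterations=512, seed=5)
        assert np.all(np.diff(curve.mean_p) < 0.02)  # Monte-Carlo slack


class TestMinN:
    def test_not_reached(self):
        curve = PowerCurve(
            n_grid=np.array([5, 10]), mean_p=np.array([0.4, 0.3]),
            sem_p=np.array([0.0, 0.0]), iterations=8, seed=0,
        )
        assert ast.min_n_below_alpha(curve, 0.05) is None
        assert ast.min_n_below_alpha(curve, 1.0) == 5


class TestRequiredSampleSize:
    def test_standard_effect_sizes(self):
        assert ast.required_sample_size(PowerSpec(mean_a=1, mean_b=0, sd_a=1, sd_b=1)) == 17
        assert ast.required_sample_size(PowerSpec(mean_a=0.5, mean_b=0, sd_a=1, sd_b=1)) == 64

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.power import TTestIndPower

        for d in (0.5, 0.8, 1.0):
            n_sm = int(np.ceil(TTestIndPower().solve_power(effect_size=d, alpha=0.05, power=0.8)))
            ours = ast.required_sample_size(PowerSpec(mean_a=d, mean_b=0, sd_a=1, sd_b=1))
            assert abs(ours - n_sm) <= 1

    def test_normal_approximation_closed_form(self):
        # n ~ 2 (z_{1-a/2} + z_{1-b})^2 / d^2, within +2 across d in [0.3, 1.5]
        z = stats.norm.ppf(0.975) + stats.norm.ppf(0.8)
        for d in np.arange(0.3, 1.51, 0.1):
            approx = 2.0 * z**2 / d**2
            ours = ast.required_sample_size(PowerSpec(mean_a=d, mean_b=0, sd_a=1, sd_b=1))
            assert approx <= ours <= approx + 2 + 1  # +1 for ceil of the approx

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="unachievable"):
            ast.required_sample_size(PowerSpec(mean_a=1.0, mean_b=1.0, sd_a=1, sd_b=1))

    def test_minimal_power_floor(self):
        assert ast.required_sample_size(
            PowerSpec(mean_a=100.0, mean_b=0.0, sd_a=1, sd_b=1, power=0.01)
        ) == 2


class TestEffectSummary:
    @staticmethod
    def _make(values_by_key):
        return {
            key: ConditionSample(modality=key[0], treatment=key[1], values=np.asarray(v, float))
            for key, v in values_by_key.items()
        }

    def test_zero_effect_flagged(self):
        same = [1.0, 2.0, 3.0]
        samples = self._make({
            ("printed", "treated"): same, ("printed", "untreated"): same,
            ("manual", "treated"): same, ("manual", "untreated"): same,
        })
        summary = ast.effect_summary(samples)
        assert summary["delta_printed"] == 0.0
        assert summary["delta_ratio"] is None and not summary["ratio_defined"]

    def test_ratio_arithmetic(self):
        samples = self._make({
            ("printed", "treated"): [4.7] * 3, ("printed", "untreated"): [1.0] * 3,
            ("manual", "treated"): [2.0] * 3, ("manual", "untreated"): [1.0] * 3,
        })
        assert ast.effect_summary(samples)["delta_ratio"] == pytest.approx(3.7)

    def test_missing_cell_rejected(self):
        samples = self._make({("printed", "treated"): [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing condition"):
            ast.effect_summary(samples)

    def test_calibrated_generator_ratio(self):
        spec = synthetic.default_assay_spec(n_per_condition=10_000, seed=31)
        samples = synthetic.gen_assay_readouts(spec)
        summary = ast.effect_summary(samples)
        assert summary["delta_ratio"] == pytest.approx(3.7, abs=0.2)
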