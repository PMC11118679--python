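"""Assay-quality statistics: Z', SSMD, pooled SDs, group comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import octscreen as oc
from octscreen import assay_stats as ast
from octscreen.errors import ParameterError, UndefinedStatisticError

# Published control-group stats of the thinning assay: day-10 negative
# controls 133.7 +/- 8.4 um against a 191.8 +/- 11.5 um baseline.
BASELINE = (191.8, 11.5)
DAY10_NEG = (133.7, 8.4)


def group(mu_p, sd_p, mu_n, sd_n, n=8):
    return oc.GroupStats(mu_p, sd_p, n, mu_n, sd_n, n)


finite = st.floats(-1e6, 1e6, allow_nan=False)
sds = st.floats(0, 1e4, allow_nan=False)


class TestZPrime:
    def test_zero_variance_limit(self):
        assert oc.zprime(group(10, 0, 5, 0)) == 1.0

    def test_printed_group_stats_hand_arithmetic(self):
        g = group(*BASELINE, *DAY10_NEG)
        expected = 1 - 3 * (11.5 + 8.4) / (191.8 - 133.7)
        assert oc.zprime(g) == pytest.approx(expected)
        assert oc.zprime(g) == pytest.approx(-0.02754, abs=1e-4)

    def test_scale_invariance(self):
        g1 = group(10, 1, 4, 2)
        g2 = group(30, 3, 12, 6)
        assert oc.zprime(g1) == pytest.approx(oc.zprime(g2))

    def test_label_order_cannot_flip_the_sign(self):
        assert oc.zprime(group(4, 1, 10, 2)) == oc.zprime(group(10, 2, 4, 1))

    def test_equal_means_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            oc.zprime(group(5, 1, 5, 1))

    @given(finite, sds, finite, sds)
    def test_never_exceeds_one(self, mu_p, sd_p, mu_n, sd_n):
        if mu_p == mu_n:
            return
        assert oc.zprime(group(mu_p, sd_p, mu_n, sd_n)) <= 1.0


class TestSSMD:
    def test_equal_means_give_zero(self):
        assert oc.ssmd(group(5, 1, 5, 1)) == 0.0

    def test_printed_group_stats_hand_arithmetic(self):
        g = group(*BASELINE, *DAY10_NEG)
        expected = (191.8 - 133.7) / np.sqrt(11.5**2 + 8.4**2)
        assert oc.ssmd(g) == pytest.approx(expected)
        assert oc.ssmd(g) == pytest.approx(4.080, abs=1e-3)

    def test_antisymmetry_under_group_swap(self):
        assert oc.ssmd(group(10, 1, 4, 2)) == pytest.approx(
            -oc.ssmd(group(4, 2, 10, 1)))

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            oc.ssmd(group(10, 0, 5, 0))


def test_zprime_ssmd_match_independent_formula_on_random_draws():
    """Both statistics agree with a from-scratch evaluation of their defining
    formulas to <= 1e-9 relative error over 1000 random group stats."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        mu_p, mu_n = rng.normal(0, 100, 2)
        sd_p, sd_n = rng.uniform(0.01, 50, 2)
        g = group(mu_p, sd_p, mu_n, sd_n)
        z_oracle = 1.0 - (3.0 * sd_p + 3.0 * sd_n) / abs(mu_p - mu_n)
        b_oracle = (mu_p - mu_n) / (sd_p * sd_p + sd_n * sd_n) ** 0.5
        assert abs(oc.zprime(g) - z_oracle) <= 1e-9 * max(1, abs(z_oracle))
        assert abs(oc.ssmd(g) - b_oracle) <= 1e-9 * max(1, abs(b_oracle))


class TestPooledSD:
    def test_identical_values_pool_to_zero(self):
        assert oc.pooled_sd([[3.0, 3.0, 3.0], [7.0, 7.0]]) == 0.0

    def test_single_set_reduces_to_its_own_sd(self):
        vals = [1.0, 4.0, 6.0, 9.0]
        assert oc.pooled_sd([vals]) == pytest.approx(np.std(vals, ddof=1))

    def test_two_set_hand_example(self):
        # s^2 = 2 and 8, one dof each -> sqrt((2+8)/2) = sqrt(5)
        assert oc.pooled_sd([[1, 3], [10, 14]]) == pytest.approx(np.sqrt(5))

    def test_matches_weighted_residual_brute_force(self):
        rng = np.random.default_rng(7)
        sets = [rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3),
                           rng.integers(2, 9)) for _ in range(20)]
        num = sum((len(s) - 1) * np.var(s, ddof=1) for s in sets)
        dof = sum(len(s) - 1 for s in sets)
        assert oc.pooled_sd(sets) == pytest.approx(np.sqrt(num / dof))

    def test_singleton_set_rejected(self):
        with pytest.raises(ParameterError):
            oc.pooled_sd([[1.0]])


class TestRepeatabilityReproducibility:
    def test_zero_repeat_noise_gives_zero_repeatability(self):
        df = oc.make_screen_dataset(5, 5, repeat_sd=0.0, seed=1)
        assert ast.repeatability(df, "thickness_um") == pytest.approx(
            0.0, abs=1e-9)

    def test_repeatability_recovers_configured_noise(self):
        df = oc.make_screen_dataset(20, 2, repeat_sd=0.4, n_repeats=5, seed=0)
        got = ast.repeatability(df[df.group == "negative"], "thickness_um")
        assert got == pytest.approx(0.4, rel=0.15)

    def test_reproducibility_recovers_between_sample_sd(self):
        df = oc.make_screen_dataset(50, 2, baseline_sd_um=12.1,
                                    repeat_sd=0.4, seed=0)
        got = ast.reproducibility(df, ("negative", "baseline"),
                                  "thickness_um")
        assert got == pytest.approx(12.1, rel=0.15)


class TestPercentChange:
    def test_no_change(self):
        assert oc.percent_change(191.8, 191.8) == 0.0

    def test_published_thinning_example(self):
        # 191.8 -> 133.7 um is the reported ~30% (60 um) reduction
        assert oc.percent_change(*[BASELINE[0], DAY10_NEG[0]]) == \
            pytest.approx(-30.29, abs=0.01)

    def test_simple_increase(self):
        assert oc.percent_change(100.0, 130.0) == pytest.approx(30.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ParameterError):
            oc.percent_change(0.0, 1.0)


class TestQualityFlags:
    @pytest.mark.parametrize("z, b, z_flag, b_flag", [
        (0.70, 8.8, "excellent", "excellent"),
        (0.55, 9.3, "excellent", "excellent"),
        (0.49, 1.9, "below-threshold", "below-threshold"),
        (0.50, -2.5, "excellent", "excellent"),  # boundary + sign of beta
    ])
    def test_flag_thresholds(self, z, b, z_flag, b_flag):
        q = oc.AssayQuality(readout="volume_mm3", zprime=z, ssmd=b)
        flags = oc.quality_flag(q)
        assert flags["zprime"] == z_flag
        assert flags["ssmd"] == b_flag


class TestGroupCompare:
    def test_identical_groups_are_indistinguishable(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        assert oc.group_compare(vals, vals) > 0.99

    def test_large_effect_detected_and_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 8)
        b = rng.normal(5, 1, 8)
        p = oc.group_compare(a, b)
        assert p < 0.001
        # permutation oracle on |mean difference|
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        perm_rng = np.random.default_rng(0)
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = perm_rng.permutation(pooled)
            hits += abs(perm[:8].mean() - perm[8:].mean()) >= obs
        assert hits / n_perm < 0.001 + 1e-9

    def test_symmetric_in_group_order(self):
        a = [1.0, 2.5, 3.0]
        b = [4.0, 5.5, 7.0]
        assert oc.group_compare(a, b) == pytest.approx(oc.group_compare(b, a))

    def test_tiny_group_rejected(self):
        with pytest.raises(ParameterError):
            oc.group_compare([1.0], [2.0, 3.0])
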