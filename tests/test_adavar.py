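"""Multinomial ratio moments, bias-constant estimation, and adaptive z-scores."""

import math

import numpy as np
import pytest
from scipy import stats

from adanipt import (
    AdavarModel,
    ChromCounts,
    DeviationProfile,
    ReferenceSelector,
    adavar_mean,
    adavar_sigma,
    adavar_train,
    adavar_zscore,
    build_deviation_profile,
    combine_sigma,
    estimate_bias_constant,
    estimate_proportions,
)
from adanipt.adavar import default_depth_grid
from adanipt.fixvar import ModelError
from adanipt.simulator import default_p_baseline


class TestProportionEstimation:
    def test_identical_proportions_recovered(self):
        x = np.arange(1.0, 23.0)
        train = [ChromCounts(f"s{i}", x * (i + 1)) for i in range(25)]
        p = estimate_proportions(train)
        np.testing.assert_allclose(p, x / x.sum(), rtol=1e-12)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_each_sample_weighted_equally_regardless_of_depth(self):
        # one deep and many shallow samples with different proportions:
        # the deep sample must not dominate
        a = np.full(22, 1.0)
        b = np.full(22, 1.0)
        b[0] = 2.0
        train = [ChromCounts("deep", a * 1e6)] + [ChromCounts(f"s{i}", b)
                                                  for i in range(19)]
        p = estimate_proportions(train)
        expected = (a / a.sum() + 19 * (b / b.sum())) / 20
        np.testing.assert_allclose(p, expected / expected.sum(), rtol=1e-12)

    def test_recovers_generating_proportions_within_sampling_error(self, make_cohort):
        train = make_cohort(200, 3_000_000, cnv_sd=0.0, seed=21)
        p = estimate_proportions(train)
        p_true = default_p_baseline()
        se = np.sqrt(p_true * (1 - p_true) / 3_000_000 / 200)
        assert np.all(np.abs(p - p_true) <= 5 * se)

    def test_zero_total_sample_is_error(self):
        train = [ChromCounts(f"s{i}", np.ones(22)) for i in range(20)]
        train[3] = ChromCounts("s3", np.zeros(22))
        with pytest.raises(ModelError, match="non-positive"):
            estimate_proportions(train)


class TestMomentFormulas:
    def test_mean_asymptote_and_inverse_n_scaling(self):
        q1, q2 = 0.013, 0.3
        assert adavar_mean(1e12, q1, q2) - q1 / q2 < 1e-9 * (q1 / q2)
        excess_n = adavar_mean(1e5, q1, q2) - q1 / q2
        excess_2n = adavar_mean(2e5, q1, q2) - q1 / q2
        assert excess_2n == pytest.approx(excess_n / 2, rel=1e-12)

    def test_sigma_inverse_sqrt_n_scaling(self):
        q1, q2 = 0.013, 0.3
        assert adavar_sigma(4e5, q1, q2) == pytest.approx(
            adavar_sigma(1e5, q1, q2) / 2, rel=1e-12)

    def test_moments_match_multinomial_monte_carlo(self):
        n, q1, q2 = 10**5, 0.05, 0.4
        rng = np.random.default_rng(7)
        draws = rng.multinomial(n, [q1, q2, 1 - q1 - q2], size=200_000)
        y = draws[:, 0] / draws[:, 1]
        se_mean = y.std(ddof=1) / math.sqrt(len(y))
        assert abs(y.mean() - adavar_mean(n, q1, q2)) <= 3 * se_mean
        assert y.std(ddof=1) == pytest.approx(adavar_sigma(n, q1, q2), rel=0.03)

    def test_sigma_equals_independent_delta_method_expression(self):
        # Var(U/V) via first-order expansion with Cov(U,V) = -n q1 q2
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = float(rng.integers(10**4, 10**8))
            q1 = rng.uniform(0.005, 0.1)
            q2 = rng.uniform(0.15, 0.6)
            var_u = n * q1 * (1 - q1)
            var_v = n * q2 * (1 - q2)
            cov_uv = -n * q1 * q2
            u, v = n * q1, n * q2
            delta = (u / v) * math.sqrt(var_u / u**2 + var_v / v**2
                                        - 2 * cov_uv / (u * v))
            # the printed formula drops the O(1/n) -(q1+q2) correction inside
            # the bracket; both agree to that order
            assert adavar_sigma(n, q1, q2) == pytest.approx(delta, rel=2 * (q1 + q2))
            simplified = (q1 / q2) * math.sqrt((1 / n) * (1 / q1 + 1 / q2))
            assert adavar_sigma(n, q1, q2) == pytest.approx(simplified, rel=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ModelError):
            adavar_mean(0, 0.1, 0.3)
        with pytest.raises(ModelError):
            adavar_sigma(100, 0.0, 0.3)


class TestDeviationProfile:
    def test_pure_multinomial_differences_are_small(self, make_cohort, t21_selector):
        train = make_cohort(500, 3_000_000, cnv_sd=0.0, seed=41)
        p = estimate_proportions(train)
        prof = build_deviation_profile(train, t21_selector, p,
                                       default_depth_grid(train), seed=41)
        assert np.all(np.abs(prof.differences) <= 0.1 * prof.theoretical_sd)

    def test_excess_noise_offset_is_depth_independent(self, make_cohort,
                                                      t21_selector):
        # CNV jitter adds ratio noise with no depth dependence; at this
        # profile resolution a linear fit must not resolve a depth trend
        covered = 0
        for seed in (51, 52, 53):
            train = make_cohort(100, 20_000_000, cnv_sd=0.001, seed=seed)
            p = estimate_proportions(train)
            prof = build_deviation_profile(train, t21_selector, p,
                                           default_depth_grid(train), seed=seed)
            res = stats.linregress(prof.depths, prof.differences)
            tcrit = stats.t.ppf(0.975, len(prof.depths) - 2)
            covered += int(abs(res.slope) <= tcrit * res.stderr)
        assert covered >= 2

    def test_single_depth_profile_supported(self, make_cohort, t21_selector):
        train = make_cohort(50, 1_000_000, seed=42)
        p = estimate_proportions(train)
        prof = build_deviation_profile(train, t21_selector, p, [500_000], seed=1)
        assert len(prof.depths) == 1
        assert np.isfinite(estimate_bias_constant(prof))

    def test_depth_exceeding_sample_names_the_sample(self, make_cohort,
                                                     t21_selector):
        train = make_cohort(50, 1_000_000, seed=43)
        p = estimate_proportions(train)
        with pytest.raises(ModelError, match=train[0].sample_id):
            build_deviation_profile(train, t21_selector, p, [2_000_000], seed=1)

    def test_profile_validation(self):
        with pytest.raises(ModelError, match="increasing"):
            DeviationProfile(depths=[2e6, 1e6], observed_sd=[1, 1],
                             theoretical_sd=[1, 1])


class TestBiasConstant:
    def test_constant_differences_recovered_exactly(self):
        prof = DeviationProfile(depths=[1e6, 2e6, 4e6],
                                observed_sd=[3e-4 + 5e-5, 2.2e-4 + 5e-5, 1.6e-4 + 5e-5],
                                theoretical_sd=[3e-4, 2.2e-4, 1.6e-4])
        assert estimate_bias_constant(prof) == pytest.approx(5e-5)

    def test_negative_average_floored_at_zero(self):
        prof = DeviationProfile(depths=[1e6], observed_sd=[1e-4],
                                theoretical_sd=[2e-4])
        assert estimate_bias_constant(prof) == 0.0

    def test_pure_multinomial_constant_is_negligible(self, make_cohort,
                                                     t21_selector):
        train = make_cohort(500, 3_000_000, cnv_sd=0.0, seed=44)
        p = estimate_proportions(train)
        prof = build_deviation_profile(train, t21_selector, p,
                                       default_depth_grid(train), seed=44)
        assert estimate_bias_constant(prof) <= 0.15 * prof.theoretical_sd.mean()


class TestCombineSigma:
    def test_zero_constant_is_identity_in_both_modes(self):
        assert combine_sigma(2e-4, 0.0, "linear") == 2e-4
        assert combine_sigma(2e-4, 0.0, "quadrature") == 2e-4

    def test_three_four_five(self):
        assert combine_sigma(3.0, 4.0, "linear") == 7.0
        assert combine_sigma(3.0, 4.0, "quadrature") == 5.0

    def test_quadrature_norm_inequality(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            s, c = rng.uniform(1e-6, 1.0, 2)
            q = combine_sigma(s, c, "quadrature")
            assert max(s, c) <= q <= s + c


class TestTraining:
    def test_deterministic_given_seed(self, make_cohort, t21_selector):
        train = make_cohort(60, 2_000_000, seed=61)
        m1 = adavar_train(train, t21_selector, seed=5)
        m2 = adavar_train(train, t21_selector, seed=5)
        assert m1.to_json() == m2.to_json()

    def test_empty_training_set_is_error(self, t21_selector):
        with pytest.raises(ModelError):
            adavar_train([], t21_selector)

    def test_q_parameters_depth_invariant(self, make_cohort, t21_selector):
        shallow = adavar_train(make_cohort(100, 3_000_000, seed=62),
                               t21_selector, seed=1)
        deep = adavar_train(make_cohort(100, 20_000_000, seed=63),
                            t21_selector, seed=1)
        assert deep.q1 == pytest.approx(shallow.q1, rel=0.01)
        assert deep.q2 == pytest.approx(shallow.q2, rel=0.01)

    def test_json_roundtrip(self, make_cohort, t21_selector):
        model = adavar_train(make_cohort(50, 1_000_000, seed=64), t21_selector,
                             seed=2)
        back = AdavarModel.from_json(model.to_json())
        assert back.selector == model.selector
        np.testing.assert_allclose(back.p, model.p, rtol=1e-15)
        assert back.c == model.c
        assert back.combine_mode == model.combine_mode
        assert back.depth_grid == model.depth_grid


class TestAdaptiveZscore:
    @pytest.fixture()
    def model(self, t21_selector):
        return AdavarModel(selector=t21_selector, p=default_p_baseline(), c=0.0)

    def test_ratio_at_model_mean_scores_zero(self, model):
        n = 2_000_000
        y = adavar_mean(n, model.q1, model.q2)
        x = np.zeros(22)
        # construct counts realizing ratio y at total n
        x[:] = default_p_baseline() * n
        x[20] = y * sum(x[c - 1] for c in model.selector.reference)
        sample = ChromCounts("s", x * (n / x.sum()))
        zc = adavar_zscore(sample, model)
        assert abs(zc.z) < 1e-6
        assert zc.call == "euploid"

    def test_z_scales_with_sqrt_depth_for_fixed_ratio(self, model):
        n = 4_000_000
        x = default_p_baseline() * n
        x[20] *= 1.001  # fixed relative ratio shift
        s1 = ChromCounts("a", x)
        s4 = ChromCounts("b", x * 4)
        z1 = adavar_zscore(s1, model).z
        z4 = adavar_zscore(s4, model).z
        assert abs(z4) == pytest.approx(2 * abs(z1), rel=1e-3)

    def test_trisomic_z_positive_and_increasing_in_depth(self, make_cohort,
                                                         t21_selector):
        model = adavar_train(make_cohort(100, 3_000_000, seed=71), t21_selector,
                             seed=3)
        means = []
        for depth in (1_000_000, 3_000_000, 10_000_000, 20_000_000):
            tri = make_cohort(200, depth, trisomy_chrom=21, fetal_fraction=0.1,
                              seed=72)
            z = np.array([adavar_zscore(s, model).z for s in tri])
            means.append(z.mean())
        assert means[0] > 0
        assert np.all(np.diff(means) > 0)

    def test_uses_sample_own_depth_not_training_depth(self, make_cohort,
                                                      t21_selector):
        model = adavar_train(make_cohort(100, 3_000_000, seed=73), t21_selector,
                             seed=4)
        x = default_p_baseline() * 12_345_678
        zc = adavar_zscore(ChromCounts("s", x), model)
        n = x.sum()
        sigma = combine_sigma(adavar_sigma(n, model.q1, model.q2), model.c,
                              model.combine_mode)
        from adanipt import chromosome_ratio

        expected = (chromosome_ratio(ChromCounts("s", x), model.selector)
                    - adavar_mean(n, model.q1, model.q2)) / sigma
        assert zc.z == pytest.approx(expected, rel=1e-12)
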