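"""Distribution-classification tests: decision rule, calibration, comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gelsig import (
    classify_distribution,
    compare_groups,
    decorrelated_subsample,
    degrade_map,
    elasticity_from_percolation,
    sample_exponent_field,
    summarize_map,
)
from gelsig.distributions import _ks_statistic_standardized, _lilliefors_null
from gelsig.errors import (
    DomainError,
    InsufficientSampleError,
    InsufficientVarianceError,
)


class TestClassifyDistribution:
    def test_lognormal_sample_classified_lognormal(self):
        rng = np.random.default_rng(42)
        sample = np.exp(rng.normal(5.7, 0.3, 500))
        verdict = classify_distribution(sample)
        assert verdict.classification == "log-normal"
        assert verdict.shapiro_p_linear < 0.05  # skewed on the linear scale

    def test_normal_sample_classified_normal(self):
        rng = np.random.default_rng(7)
        sample = rng.normal(300.0, 30.0, 500)
        sample = sample[sample > 0]
        assert classify_distribution(sample).classification == "normal"

    def test_bimodal_mixture_classified_neither(self):
        rng = np.random.default_rng(3)
        sample = np.concatenate(
            [np.exp(rng.normal(5.0, 0.1, 250)), np.exp(rng.normal(6.2, 0.1, 250))]
        )
        assert classify_distribution(sample).classification == "neither"

    def test_type_one_rate_on_true_lognormal(self):
        """On true log-normal data, the log-normal verdict holds at roughly
        1 - 2*alpha (two tests, each at level alpha)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sample = np.exp(rng.normal(5.7, 0.3, 500))
            hits += classify_distribution(sample, seed=seed).classification == "log-normal"
        assert 0.80 <= hits / 100 <= 0.99

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(1e-6, 1e6))
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(0)
        sample = np.exp(rng.normal(5.7, 0.3, 200))
        v1 = classify_distribution(sample, seed=1)
        v2 = classify_distribution(sample * scale, seed=1)
        assert v1.classification == v2.classification
        assert v2.ks_D_lognormal == pytest.approx(v1.ks_D_lognormal, abs=1e-12)
        assert v2.shapiro_p_log == pytest.approx(v1.shapiro_p_log, rel=1e-6)

    def test_ks_statistic_agrees_with_scipy(self):
        """Dual route: the internal vectorized KS D equals scipy's kstest
        against the fitted log-normal."""
        rng = np.random.default_rng(5)
        sample = np.exp(rng.normal(2.0, 0.5, 300))
        log_x = np.log(sample)
        mu, sd = log_x.mean(), log_x.std(ddof=1)
        d_internal = float(
            _ks_statistic_standardized(np.sort((log_x - mu) / sd))[0]
        )
        d_scipy = stats.kstest(
            sample, stats.lognorm(s=sd, scale=np.exp(mu)).cdf
        ).statistic
        assert d_internal == pytest.approx(d_scipy, abs=1e-12)

    def test_lilliefors_null_is_calibrated(self):
        """Rejection rate at alpha = 0.05 on true normal data in [0.03, 0.07]."""
        rejections = 0
        n_trials = 1000
        for seed in range(n_trials):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.normal(0.0, 1.0, 100)
            z = np.sort((x - x.mean()) / x.std(ddof=1))
            d = float(_ks_statistic_standardized(z)[0])
            null = _lilliefors_null(100, 500, np.random.default_rng(seed))
            p = (1 + np.sum(null >= d)) / 501
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_trials <= 0.07

    def test_naive_mode_is_conservative(self):
        """The naive KS p-value (parameters estimated, no correction) is
        stochastically larger than the Monte-Carlo one."""
        rng = np.random.default_rng(8)
        sample = np.exp(rng.normal(5.7, 0.3, 300))
        v_mc = classify_distribution(sample, ks_mode="monte_carlo", seed=0)
        v_naive = classify_distribution(sample, ks_mode="naive")
        assert v_naive.ks_p_lognormal > v_mc.ks_p_lognormal

    def test_domain_errors(self):
        with pytest.raises(InsufficientSampleError):
            classify_distribution(np.ones(10) + np.arange(10))
        with pytest.raises(DomainError):
            classify_distribution(np.linspace(-1.0, 1.0, 50))
        with pytest.raises(InsufficientVarianceError):
            classify_distribution(np.full(50, 3.0))


class TestCompareGroups:
    def test_identical_groups_give_maximal_p(self):
        rng = np.random.default_rng(0)
        sample = np.exp(rng.normal(5.7, 0.3, 100))
        assert compare_groups(sample, sample).p_value == pytest.approx(1.0)

    def test_null_p_values_are_uniform(self):
        """Two same-distribution samples, 300 repetitions: p-values uniform."""
        rng = np.random.default_rng(21)
        p_values = []
        for _ in range(300):
            a = np.exp(rng.normal(5.7, 0.3, 60))
            b = np.exp(rng.normal(5.7, 0.3, 60))
            p_values.append(compare_groups(a, b).p_value)
        assert stats.kstest(p_values, stats.uniform.cdf).pvalue > 0.01

    def test_shifted_lognormals_detected(self):
        """15% median shift at n = 500 per group: p < 0.001 in > 90% of seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = np.exp(rng.normal(5.7, 0.3, 500))
            b = np.exp(rng.normal(5.7 + np.log(1.15), 0.3, 500))
            hits += compare_groups(a, b).p_value < 1e-3
        assert hits / 50 > 0.9

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientSampleError):
            compare_groups(np.ones(5), np.ones(20))


class TestSummarizeMap:
    def test_constant_map_raises_insufficient_variance(self, baseline_map):
        from gelsig import ElasticityMap

        const = ElasticityMap(moduli_Pa=np.full((32, 32), 300.0))
        with pytest.raises(InsufficientVarianceError):
            summarize_map(const)

    def test_percolation_map_summary(self, baseline_map):
        summary = summarize_map(baseline_map, subsample_seed=3)
        assert summary.verdict.classification == "log-normal"
        assert summary.n == baseline_map.moduli_Pa.size
        assert summary.linear_counts.sum() == summary.n
        assert summary.log_counts.sum() == summary.n
        assert summary.mean_Pa > 0 and summary.sd_Pa > 0

    def test_degraded_map_classified_neither(self, baseline_map):
        degraded = degrade_map(baseline_map, fraction=0.3, severity=5.0, seed=2)
        summary = summarize_map(degraded, subsample_seed=3)
        assert summary.verdict.classification == "neither"

    def test_histogram_figure_written(self, tmp_path, baseline_map):
        from gelsig import plot_map_histograms

        summary = summarize_map(baseline_map, subsample_seed=3)
        out = tmp_path / "hist.png"
        plot_map_histograms(summary, out)
        assert out.stat().st_size > 0


class TestDegradationPower:
    def test_rejection_rate_monotone_in_severity(self):
        """Log-normality rejection is non-decreasing in degradation severity,
        with high power at severity 5 (the signature regime)."""
        rates = []
        for severity in (1.5, 3.0, 5.0):
            rejections = 0
            for seed in range(60):
                field = sample_exponent_field((48, 48), seed=seed)
                emap = elasticity_from_percolation(field)
                degraded = degrade_map(
                    emap, fraction=0.3, severity=severity, seed=seed + 999
                )
                sub = decorrelated_subsample(degraded.moduli_Pa, 1.5, seed=seed)
                verdict = classify_distribution(sub, seed=seed)
                rejections += verdict.classification != "log-normal"
            rates.append(rejections / 60)
        assert rates[0] <= rates[1] + 0.1
        assert rates[1] <= rates[2] + 0.1
        assert rates[2] >= 0.8
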