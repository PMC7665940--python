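"""Diagnostic metrics, tests of proportions and the PPV-prevalence relation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import erf
from statsmodels.stats.proportion import proportions_ztest

from lexemo.errors import (
    DegenerateTestError,
    UndefinedCorrelationError,
    UndefinedMetricError,
)
from lexemo.metrics import (
    ConfusionCounts,
    bonferroni,
    f_score,
    npv,
    pearson_correlation,
    ppv,
    ppv_from_prevalence,
    proportion_ci,
    sensitivity,
    specificity,
    two_proportion_test,
    two_proportion_z,
)


class TestProportionMetrics:
    def test_basic_arithmetic(self):
        c = ConfusionCounts("affect", tp=3, fp=0, fn=1, tn=6)
        assert sensitivity(c).value == pytest.approx(0.75)
        assert ppv(c).value == pytest.approx(1.0)
        assert specificity(c).value == pytest.approx(1.0)
        assert npv(c).value == pytest.approx(6 / 7)

    def test_operating_point_at_low_prevalence(self):
        # counts emulating a tagger with sens .858 on a 100k-word corpus
        # with ~1.8% emotion prevalence: precision collapses to ~0.33
        c = ConfusionCounts("affect", tp=858, fn=142, fp=1774, tn=97226)
        assert sensitivity(c).value == pytest.approx(0.858)
        assert ppv(c).value == pytest.approx(858 / 2632, abs=1e-12)
        assert round(ppv(c).value, 3) == 0.326

    def test_zero_denominator_raises(self):
        c = ConfusionCounts("x", tp=0, fp=0, fn=0, tn=5)
        with pytest.raises(UndefinedMetricError):
            sensitivity(c)
        with pytest.raises(UndefinedMetricError):
            ppv(c)

    def test_ci_brackets_value_for_both_methods(self):
        for method in ("wilson", "wald"):
            est = proportion_ci(3, 1000, method=method)
            assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0

    @pytest.mark.parametrize("p", [0.01, 0.3, 0.9])
    def test_wilson_ci_coverage(self, p):
        # 2000 binomial draws at n=500: the 95% Wilson interval should
        # cover the truth in 93-97% of draws
        rng = np.random.default_rng(17)
        n = 500
        xs = rng.binomial(n, p, size=2000)
        covered = 0
        for x in xs:
            est = proportion_ci(int(x), n, method="wilson")
            covered += est.covers(p)
        assert 0.93 <= covered / 2000 <= 0.97


class TestFScore:
    def test_harmonic_mean_of_equals_is_identity(self):
        for p in (0.1, 0.5, 0.9):
            assert f_score(p, p).value == pytest.approx(p)

    def test_known_operating_points(self):
        assert round(f_score(0.326, 0.858).value, 3) == 0.472
        assert round(f_score(0.640, 0.862).value, 3) == 0.735

    def test_between_min_and_max_and_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = rng.random(2)
            if a + b == 0:
                continue
            f = f_score(a, b).value
            assert min(a, b) - 1e-12 <= f <= max(a, b) + 1e-12
            assert f <= (a + b) / 2 + 1e-12  # harmonic ≤ arithmetic
            assert f_score(b, a).value == pytest.approx(f)

    def test_zero_when_either_input_zero(self):
        assert f_score(0.0, 0.5).value == 0.0
        with pytest.raises(UndefinedMetricError):
            f_score(0.0, 0.0)


class TestTwoProportionTest:
    def test_equal_proportions_give_z_zero(self):
        res = two_proportion_test(0.4, 500, 0.4, 500)
        assert res.z == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_matches_independent_erf_oracle(self):
        # direct pooled-z formula evaluated with scipy's erf only
        p1, n1, p2, n2 = 0.6, 1000, 0.5, 1000
        pooled = (600 + 500) / 2000
        z = (p1 - p2) / math.sqrt(
            pooled * (1 - pooled) * (1 / n1 + 1 / n2)
        )
        p_expect = 1.0 - erf(abs(z) / math.sqrt(2.0))
        res = two_proportion_test(p1, n1, p2, n2)
        assert res.z == pytest.approx(z, abs=1e-12)
        assert res.p_value == pytest.approx(p_expect, abs=1e-10)

    def test_matches_statsmodels(self):
        res = two_proportion_test(0.858, 3000, 0.896, 3000)
        z_sm, p_sm = proportions_ztest(
            [round(0.858 * 3000), round(0.896 * 3000)], [3000, 3000]
        )
        assert res.z == pytest.approx(z_sm)
        assert res.p_value == pytest.approx(p_sm)

    def test_swapping_sides_flips_z(self):
        a = two_proportion_test(0.3, 400, 0.35, 600)
        b = two_proportion_test(0.35, 600, 0.3, 400)
        assert a.z == pytest.approx(-b.z)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_pooled_proportion(self):
        with pytest.raises(DegenerateTestError):
            two_proportion_test(0.0, 100, 0.0, 100)
        with pytest.raises(DegenerateTestError):
            two_proportion_test(1.0, 100, 1.0, 100)

    def test_significance_flag_follows_threshold(self):
        res = two_proportion_test(0.6, 2000, 0.5, 2000,
                                  alpha_corrected=0.0021)
        assert res.significant == (res.p_value < 0.0021)
        assert res.significant


class TestBonferroni:
    def test_printed_thresholds(self):
        assert round(bonferroni(0.05, 6), 4) == 0.0083
        assert round(bonferroni(0.05, 24), 4) == 0.0021

    def test_identity_at_one_comparison(self):
        assert bonferroni(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni(1.5, 3)


class TestPearsonCorrelation:
    def _table(self, rng, n=30, cols=("a", "b", "c")):
        return pd.DataFrame(
            rng.random((n, len(cols))), columns=list(cols),
            index=[f"p{i}" for i in range(n)],
        )

    def test_self_correlation_diagonal_one(self):
        table = self._table(np.random.default_rng(0))
        r = pearson_correlation(table, table)
        assert np.allclose(np.diag(r.to_numpy()), 1.0)

    def test_anti_monotone_transform_gives_minus_one(self):
        table = self._table(np.random.default_rng(1))
        r = pearson_correlation(table, 10.0 - 3.0 * table)
        assert np.allclose(np.diag(r.to_numpy()), -1.0)

    def test_constant_column_raises(self):
        table = self._table(np.random.default_rng(2))
        bad = table.copy()
        bad["b"] = 5.0
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation(table, bad)

    def test_noisy_copy_attenuation(self):
        # corr(X, X+E) -> sigma_x / sqrt(sigma_x^2 + sigma_e^2) at large n
        rng = np.random.default_rng(4)
        n = 20000
        x = rng.normal(size=n)
        noise_sd = 0.5
        y = x + rng.normal(scale=noise_sd, size=n)
        a = pd.DataFrame({"c": x})
        b = pd.DataFrame({"c": y})
        expected = 1.0 / math.sqrt(1.0 + noise_sd**2)
        assert pearson_correlation(a, b).loc["c", "c"] == pytest.approx(
            expected, abs=0.01
        )


class TestPpvFromPrevalence:
    def test_perfect_specificity_gives_one(self):
        assert ppv_from_prevalence(0.8, 1.0, 0.1) == 1.0

    def test_zero_prevalence_gives_zero(self):
        assert ppv_from_prevalence(0.9, 0.95, 0.0) == 0.0
        assert ppv_from_prevalence(0.9, 1.0, 0.0) == 0.0

    def test_monte_carlo_confusion_oracle(self):
        # simulate 10^6 tokens at the published total-affect operating
        # point and 1.8% prevalence; empirical PPV must agree to ~3 dp
        sens, spec, prev = 0.858, 0.967, 0.018
        rng = np.random.default_rng(123)
        n = 1_000_000
        truth = rng.random(n) < prev
        flagged = np.where(
            truth, rng.random(n) < sens, rng.random(n) < (1 - spec)
        )
        empirical = (truth & flagged).sum() / flagged.sum()
        analytic = ppv_from_prevalence(sens, spec, prev)
        assert analytic == pytest.approx(empirical, abs=2e-3)
        assert round(analytic, 2) == 0.32

    def test_bayes_identity_with_confusion_counts(self):
        c = ConfusionCounts("x", tp=858, fn=142, fp=1774, tn=97226)
        lhs = ppv(c).value
        rhs = ppv_from_prevalence(
            sensitivity(c).value, specificity(c).value, c.prevalence
        )
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_increasing_in_prevalence(self):
        vals = [
            ppv_from_prevalence(0.858, 0.967, p)
            for p in (0.001, 0.018, 0.1, 0.5)
        ]
        assert vals == sorted(vals)


class TestVectorizedZ:
    def test_matches_scalar_path(self):
        z, p = two_proportion_z(
            np.array([60, 50]), np.array([100, 100]),
            np.array([50, 50]), np.array([100, 100]),
        )
        res = two_proportion_test(0.6, 100, 0.5, 100)
        assert z[0] == pytest.approx(res.z)
        assert p[0] == pytest.approx(res.p_value)
        assert z[1] == pytest.approx(0.0)

    def test_degenerate_cells_are_nan(self):
        z, p = two_proportion_z(0, 10, 0, 10)
        assert np.isnan(z) and np.isnan(p)
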