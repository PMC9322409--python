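import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from corrcompat import (
    correlation_test,
    fisher_interval,
    fisher_z_pvalue,
    pearson_r,
    sample_bivariate,
    substream,
)

# frozen oracle values computed independently (R) before the build
T_045_N30 = 2.6664054209
P_045_N30 = 0.0125910713
FISHER_045_N30 = (0.1070927825, 0.6972330058)


class TestPearsonR:
    def test_perfect_linear_relationships(self):
        x = np.arange(8.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # definitional formula applied by hand: r = 14.5 / 17.5 = 29/35
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([2, 1, 4, 3, 6, 5], dtype=float)
        assert pearson_r(x, y) == pytest.approx(29 / 35, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_agrees_with_scipy(self, rng):
        x, y = rng.standard_normal((2, 50))
        assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)


class TestCorrelationTest:
    def test_zero_correlation_gives_p_one(self):
        # orthogonal construction: r is exactly 0
        x = np.array([-1.5, -0.5, 0.5, 1.5])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        res = correlation_test(x, y)
        assert res.r_hat == pytest.approx(0.0)
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_frozen_t_distribution_oracle(self):
        # construct a sample with r almost exactly 0.45 via residual orthogonalisation
        rng = np.random.default_rng(42)
        n, target = 30, 0.45
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= (e @ x / (x @ x)) * x  # residualise e against x
        e /= e.std()
        y = target * x + math.sqrt(1 - target**2) * e
        res = correlation_test(x, y)
        assert res.r_hat == pytest.approx(0.45, abs=1e-12)
        assert res.df == 28
        assert res.t_stat == pytest.approx(T_045_N30, abs=1e-9)
        assert res.p_value == pytest.approx(P_045_N30, abs=1e-9)
        assert res.significant

    def test_perfect_correlation_degenerate_policy(self):
        x = np.arange(6.0)
        res = correlation_test(x, 3 * x)
        assert res.p_value == 0.0 and res.degenerate and res.t_stat == math.inf

    def test_p_uniform_under_null(self):
        # with rho = 0 the exact t test yields uniform p-values
        rng = substream(13, 0)
        ps = np.array(
            [correlation_test(sample_bivariate(12, 0.0, rng)).p_value for _ in range(2000)]
        )
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5), c=st.floats(0.1, 10), d=st.floats(-5, 5)
    )
    @settings(max_examples=25, deadline=None)
    def test_p_value_invariant_to_affine_rescaling(self, a, b, c, d):
        rng = np.random.default_rng(77)
        x, y = rng.standard_normal((2, 20))
        base = correlation_test(x, y)
        scaled = correlation_test(a * x + b, c * y + d)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_p_strictly_decreasing_in_n_for_fixed_r(self):
        ps = []
        for n in (10, 20, 40, 80):
            t = 0.45 * math.sqrt(n - 2) / math.sqrt(1 - 0.45**2)
            ps.append(2 * stats.t.sf(t, n - 2))
        r = np.array([0.45])
        from corrcompat.inference import _t_pvalues

        ours = [float(_t_pvalues(r, n)[0]) for n in (10, 20, 40, 80)]
        assert ours == pytest.approx(ps)
        assert all(b < a for a, b in zip(ours, ours[1:]))


class TestFisherInterval:
    def test_symmetric_about_zero_when_r_zero(self):
        iv = fisher_interval(0.0, 30, 0.95)
        assert iv.lower == pytest.approx(-iv.upper)

    def test_frozen_closed_form_oracle(self):
        iv = fisher_interval(0.45, 30, 0.95)
        assert iv.lower == pytest.approx(FISHER_045_N30[0], abs=1e-9)
        assert iv.upper == pytest.approx(FISHER_045_N30[1], abs=1e-9)
        assert iv.contains(0.45)

    def test_width_monotone_in_n_and_level(self):
        widths = [fisher_interval(0.45, n, 0.95).width for n in (10, 20, 40, 80)]
        assert all(b < a for a, b in zip(widths, widths[1:]))
        levels = [fisher_interval(0.45, 30, lv).width for lv in (0.5, 0.8, 0.95, 0.99)]
        assert all(b > a for a, b in zip(levels, levels[1:]))

    def test_coverage_at_nominal_level(self):
        # 95% interval should cover the true rho in about 95% of replicates
        rng = substream(17, 0)
        rho, n, reps = 0.45, 30, 10_000
        covered = 0
        from corrcompat.sampler import _sample_many

        x, y = _sample_many(n, rho, reps, rng)
        for i in range(reps):
            r = pearson_r(x[i], y[i])
            if fisher_interval(r, n, 0.95).contains(rho):
                covered += 1
        assert covered / reps == pytest.approx(0.95, abs=0.015)

    def test_degenerate_r_raises(self):
        with pytest.raises(ValueError):
            fisher_interval(1.0, 30)

    def test_z_test_interval_equivalence_exact_t_test_approximate(self):
        # the 95% Fisher interval excludes 0 iff the Fisher-z p < 0.05 (exact
        # duality, checked over random samples) ...
        rng = substream(19, 0)
        for _ in range(400):
            d = sample_bivariate(8, 0.3, rng)
            r = pearson_r(d.x, d.y)
            if abs(r) >= 1:
                continue
            excl = not fisher_interval(r, d.n, 0.95).contains(0.0)
            assert excl == (fisher_z_pvalue(r, d.n) < 0.05)
        # ... while the t test disagrees for r between the two critical
        # values at small n: at n = 8 the z cutoff is tanh(1.96/sqrt(5)) ~
        # 0.7045 and the t cutoff t*/sqrt(t*^2 + 6) ~ 0.7067
        n, r_gap = 8, 0.7055
        x = np.arange(float(n))
        x = (x - x.mean()) / x.std()
        e = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        e = e - e.mean()
        e -= (e @ x / (x @ x)) * x
        e /= e.std()
        y = r_gap * x + math.sqrt(1 - r_gap**2) * e
        res = correlation_test(x, y)
        assert res.r_hat == pytest.approx(r_gap, abs=1e-12)
        assert not fisher_interval(res.r_hat, n, 0.95).contains(0.0)  # z rejects
        assert res.p_value >= 0.05  # t does not
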