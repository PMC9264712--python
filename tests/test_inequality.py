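"""Concentration index, convenient regression, gaps, ratios, stars."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from equicost.inequality import (ci_inference, concentration_index,
                                 convenient_regression_slope, equity_gap,
                                 equity_ratio, equity_result, stars)
from equicost.wealth import RankedSample, ranked_sample

positive_samples = hnp.arrays(
    np.float64, st.integers(4, 60),
    elements=st.floats(0.0, 1e4, allow_nan=False, width=32),
).filter(lambda y: y.sum() > 0 and np.ptp(y) > 0)


def sample_on_grid(y):
    """Ranked sample with ranks (i - 1/2)/n in the given order of y."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return RankedSample(values=y, ranks=(np.arange(n) + 0.5) / n)


class TestConcentrationIndex:
    def test_linear_ascending_is_4_15(self):
        # brute force oracle: 2*sum(y R)/(n mu) - 1 with R = .1 ... .9
        y = np.arange(1.0, 6.0)
        oracle = 2 * np.sum(y * np.array([.1, .3, .5, .7, .9])) / (5 * 3.0) - 1
        assert oracle == pytest.approx(4 / 15)
        assert concentration_index(sample_on_grid(y)) == pytest.approx(4 / 15,
                                                                       abs=1e-14)

    def test_constant_outcome_is_zero(self):
        assert concentration_index(sample_on_grid(np.full(8, 3.3))) == \
            pytest.approx(0.0, abs=1e-15)

    def test_antisymmetric_under_rank_reversal(self):
        y = np.arange(1.0, 6.0)
        assert concentration_index(sample_on_grid(y[::-1])) == \
            pytest.approx(-4 / 15, abs=1e-14)

    @pytest.mark.parametrize("n", [2, 5, 40])
    def test_perfect_concentration_bound(self, n):
        """All of y on the richest individual gives exactly (n-1)/n."""
        y = np.zeros(n)
        y[-1] = 7.0
        assert concentration_index(sample_on_grid(y)) == \
            pytest.approx((n - 1) / n, abs=1e-12)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="mean is zero"):
            concentration_index(sample_on_grid(np.zeros(4)))
        with pytest.raises(ValueError, match="at least 2"):
            concentration_index(RankedSample(values=np.array([1.0]),
                                             ranks=np.array([0.5])))

    @given(positive_samples)
    def test_scale_invariance(self, y):
        s = sample_on_grid(y)
        ci = concentration_index(s)
        assert concentration_index(sample_on_grid(17.3 * y)) == \
            pytest.approx(ci, abs=1e-10)

    @given(positive_samples, st.floats(0.1, 100.0))
    def test_translation_shrinks_toward_zero(self, y, c):
        s = sample_on_grid(y)
        ci = concentration_index(s)
        mu = y.mean()
        shifted = concentration_index(sample_on_grid(y + c))
        assert shifted == pytest.approx(ci * mu / (mu + c), abs=1e-9)

    def test_transfer_from_poor_to_rich_increases_ci(self):
        rng = np.random.default_rng(21)
        y = rng.gamma(2, 10, 30)
        s = sample_on_grid(y)
        base = concentration_index(s)
        for lo, hi, amount in [(0, 29, 1.0), (5, 20, 3.0), (10, 11, 0.5)]:
            y2 = y.copy()
            y2[lo] -= amount
            y2[hi] += amount
            assert concentration_index(sample_on_grid(y2)) > base

    @given(positive_samples)
    def test_bounds(self, y):
        ci = concentration_index(sample_on_grid(y))
        n = y.size
        assert -(n - 1) / n - 1e-12 <= ci <= (n - 1) / n + 1e-12


class TestConvenientRegression:
    def test_slope_identity(self):
        s = sample_on_grid(np.arange(1.0, 6.0))
        assert convenient_regression_slope(s) == pytest.approx(4 / 15,
                                                               abs=1e-12)

    def test_constant_outcome_p_is_one(self):
        se, p = ci_inference(sample_on_grid(np.full(6, 2.0)))
        assert se == 0.0 and p == 1.0

    def test_needs_three_observations(self):
        with pytest.raises(ValueError, match="at least 3"):
            ci_inference(sample_on_grid(np.array([1.0, 2.0])))

    def test_robust_se_close_to_bootstrap(self):
        """HC1 SE within 15% of a 2000-resample bootstrap at n = 500."""
        rng = np.random.default_rng(42)
        y = rng.gamma(2.0, 15.0, 500)
        scores = rng.normal(size=500)
        s = ranked_sample(y, scores)
        se, _ = ci_inference(s)
        boots = np.empty(2000)
        for b in range(2000):
            idx = rng.integers(0, 500, 500)
            boots[b] = concentration_index(ranked_sample(y[idx], scores[idx]))
        assert abs(se - boots.std()) / boots.std() < 0.15

    def test_significant_gradient_detected(self):
        rng = np.random.default_rng(9)
        r = (np.arange(400) + 0.5) / 400
        y = 40 - 20 * r + rng.gamma(2, 2, 400)
        _, p = ci_inference(RankedSample(values=y, ranks=r))
        assert p < 0.01


class TestGapRatioStars:
    def test_toy_gap(self):
        a = np.array([35.0, 45.0, 40.0])
        b = np.array([20.0, 30.0, 25.0])
        gap, se, p = equity_gap(a, b)
        assert gap == pytest.approx(15.0)
        assert se > 0 and 0 <= p <= 1

    def test_identical_groups(self):
        x = np.array([3.0, 4.0, 5.0])
        gap, _, p = equity_gap(x, x.copy())
        assert gap == 0.0 and p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            equity_gap(np.array([]), np.array([1.0]))

    def test_welch_matches_permutation_oracle(self):
        """Welch p agrees with a full permutation test within MC error."""
        from itertools import combinations

        a = np.array([31.0, 44.0, 29.0, 52.0])
        b = np.array([18.0, 25.0, 21.0])
        _, _, p_welch = equity_gap(a, b)
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        idx = set(range(7))
        count = total = 0
        for pick in combinations(range(7), 4):
            ga = pooled[list(pick)]
            gb = pooled[list(idx - set(pick))]
            total += 1
            if abs(ga.mean() - gb.mean()) >= observed - 1e-12:
                count += 1
        p_perm = count / total
        assert abs(p_welch - p_perm) < 0.07

    def test_ratio(self):
        assert equity_ratio(40.0, 25.0) == pytest.approx(1.6)
        assert equity_ratio(7.0, 7.0) == pytest.approx(1.0)
        assert equity_ratio(5.0, 0.0) is None

    @pytest.mark.parametrize("p,expected", [
        (0.004, "***"), (0.01, "**"), (0.049, "**"), (0.05, "*"),
        (0.0999, "*"), (0.10, ""), (0.5, ""), (1.0, ""),
    ])
    def test_star_thresholds_strict(self, p, expected):
        assert stars(p) == expected

    def test_equity_result_sign_consistency(self):
        """sign(gap) == sign(ratio - 1) when both group means positive."""
        rng = np.random.default_rng(14)
        for _ in range(20):
            y = rng.gamma(2, 10, 60) + 0.1
            s = sample_on_grid(y)
            res = equity_result(s, s.quintile == 1, s.quintile == 5)
            assert res.ratio is not None
            assert np.sign(res.gap) == np.sign(res.ratio - 1) or res.gap == 0
            assert -1 < res.ci < 1
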