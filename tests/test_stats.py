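import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histodti.phantoms import CohortSpec, generate_cohort
from histodti.stats import (
    bca_ci, bh_fdr, cohens_d, effect_size_band, effect_size_table,
    permutation_t_test,
)


class TestCohensD:
    def test_hand_example(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)

    def test_identical_groups_give_zero(self):
        assert cohens_d([1, 2, 3, 4], [1, 2, 3, 4]) == 0.0

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.0], [4.0, 5.5, 7.0]
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([2, 2, 2], [5, 5, 5])

    @given(st.floats(-50, 50), st.floats(0.1, 20))
    @settings(max_examples=50, derandomize=True)
    def test_location_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 15)
        d0 = cohens_d(a, b)
        assert cohens_d(a + shift, b + shift) == pytest.approx(d0, rel=1e-9)
        assert cohens_d(a * scale, b * scale) == pytest.approx(d0, rel=1e-9)


class TestBcaCI:
    def test_zero_variance_gives_degenerate_interval(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_ci([1, 1, 1, 2], [1, 1, 1, 2], statistic=lambda c, t: 0.0,
                            n_boot=1000, seed=0)
        assert lo == hi == 0.0

    def test_close_to_percentile_for_symmetric_large_sample(self):
        """With negligible bias and skew, BCa collapses to the percentile CI."""
        rng = np.random.default_rng(1)
        c = rng.normal(0, 1, 300)
        t = rng.normal(0.4, 1, 300)
        lo, hi = bca_ci(c, t, n_boot=4000, seed=2)
        # percentile interval from an independent resampling pass
        boots = []
        rng2 = np.random.default_rng(3)
        for _ in range(4000):
            boots.append(cohens_d(rng2.choice(c, len(c)), rng2.choice(t, len(t))))
        plo, phi = np.quantile(boots, [0.025, 0.975])
        sd = np.std(boots)
        assert abs(lo - plo) < 0.05 * sd * 5  # same scale, generous sampling slack
        assert abs(hi - phi) < 0.05 * sd * 5

    def test_matches_scipy_bca_on_one_sample_mean(self):
        """Cross-check the BCa machinery against scipy's implementation."""
        from scipy.stats import bootstrap

        rng = np.random.default_rng(4)
        c = rng.exponential(1.0, 40)
        t = rng.exponential(1.5, 40)

        def diff_means(control, treated):
            return np.mean(treated) - np.mean(control)

        lo, hi = bca_ci(c, t, statistic=diff_means, n_boot=9999, seed=5)
        res = bootstrap((c, t), lambda c_, t_, axis=-1: np.mean(t_, axis=axis) - np.mean(c_, axis=axis),
                        n_resamples=9999, method="BCa", random_state=6, paired=False,
                        vectorized=True)
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.05)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.05)

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(7)
        c = rng.normal(0, 1, 15)
        t = rng.normal(1, 1.3, 18)
        d = cohens_d(c, t)
        lo, hi = bca_ci(c, t, n_boot=2000, seed=8)
        assert lo <= d <= hi


def _welch_t_oracle(c, t):
    c, t = np.asarray(c, float), np.asarray(t, float)
    se = math.sqrt(c.var(ddof=1) / len(c) + t.var(ddof=1) / len(t))
    return (t.mean() - c.mean()) / se


def _exhaustive_p_oracle(c, t):
    """Brute-force enumeration of all label splits, written independently."""
    pooled = list(c) + list(t)
    n1 = len(c)
    t_obs = abs(_welch_t_oracle(c, t))
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        cc = [pooled[i] for i in combo]
        tt = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(_welch_t_oracle(cc, tt)) >= t_obs - 1e-12:
            hits += 1
    return hits / total


class TestPermutationTest:
    @pytest.mark.parametrize("c, t", [
        ([1.0, 2.0], [10.0, 11.0]),
        ([0.5, 1.5, 2.5], [1.0, 2.0, 9.0]),
        ([3, 1, 4, 1, 5], [9, 2, 6, 5, 3]),
    ])
    def test_exhaustive_matches_brute_force(self, c, t):
        assert permutation_t_test(c, t, exhaustive=True) == pytest.approx(
            _exhaustive_p_oracle(c, t))

    def test_sampled_matches_exhaustive_within_error(self):
        c, t = [1.0, 2.0, 3.5, 0.5], [4.0, 5.5, 6.0, 3.0]
        p_ex = permutation_t_test(c, t, exhaustive=True)
        p_s = permutation_t_test(c, t, n_perm=40000, seed=1, exhaustive=False)
        assert p_s == pytest.approx(p_ex, abs=3 * math.sqrt(p_ex * (1 - p_ex) / 40000) + 1e-4)

    def test_identical_data_gives_p_one(self):
        assert permutation_t_test([5.0, 5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_add_one_floor(self):
        rng = np.random.default_rng(0)
        c = rng.normal(0, 0.1, 12)
        t = rng.normal(50, 0.1, 12)
        p = permutation_t_test(c, t, n_perm=5000, seed=1, exhaustive=False)
        assert p >= 1 / 5001

    def test_type_one_error_calibrated(self):
        """Under the null, rejections at alpha = 0.05 stay near 5%."""
        rng = np.random.default_rng(2)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            x = rng.normal(0, 1, 14)
            p = permutation_t_test(x[:7], x[7:], n_perm=400, seed=int(rng.integers(2**31)),
                                   exhaustive=False)
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_details_report_raw_proportion(self):
        res = permutation_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], n_perm=999,
                                 seed=0, exhaustive=False, return_details=True)
        assert res.p == pytest.approx((res.p_raw * 999 + 1) / 1000)


class TestBhFdr:
    def test_hand_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_passthrough(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 37)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_q_dominates_p_and_sorted_monotone(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestEffectSizeTable:
    def test_reporting_structure(self):
        table = generate_cohort(CohortSpec(seed=0))
        out = effect_size_table(table, ["FA", "CS"], n_boot=1000, n_perm=500, seed=0)
        assert list(out.columns) == ["parameter", "region", "d", "ci_low", "ci_high",
                                     "p", "q", "n_control", "n_treated", "band"]
        assert len(out) == 2 * 4  # parameters x regions
        assert np.all(out["q"] >= out["p"] - 1e-12)
        assert np.all(out["ci_low"] <= out["d"]) and np.all(out["d"] <= out["ci_high"])
        assert set(out["n_control"]) == {4} and set(out["n_treated"]) == {13}

    def test_bands(self):
        assert effect_size_band(1.0) == "large"
        assert effect_size_band(-0.6) == "medium"
        assert effect_size_band(0.3) == "small"
        assert effect_size_band(0.1) == "negligible"
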