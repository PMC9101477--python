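"""LOWESS wrapper and Chow structural-break machinery.

chow_f is cross-checked against a brute-force oracle that fits the three
simple regressions through explicit normal equations, independently of the
implementation's least-squares path.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elncut import chow_f, chow_scan, find_cutpoint, lowess_smooth
from elncut import default_config, generate_cohort


def oracle_chow(x, y, k):
    """Brute-force Chow F via explicit normal equations for each regression."""
    from scipy import stats

    def rss(xs, ys):
        n = len(xs)
        sx, sy = xs.sum(), ys.sum()
        sxx, sxy = (xs * xs).sum(), (xs * ys).sum()
        det = n * sxx - sx * sx
        b = (n * sxy - sx * sy) / det
        a = (sy - b * sx) / n
        r = ys - a - b * xs
        return float((r * r).sum())

    left, right = x <= k, x > k
    rp = rss(x, y)
    r1, r2 = rss(x[left], y[left]), rss(x[right], y[right])
    n = len(x)
    f = ((rp - r1 - r2) / 2.0) / ((r1 + r2) / (n - 4))
    return f, float(stats.f.sf(f, 2, n - 4)), rp, r1, r2


class TestChowF:
    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = np.sort(rng.uniform(0, 10, 20))
            x += np.arange(20) * 1e-6  # guard against exact ties in x
            y = rng.normal(0, 1, 20)
            k = x[rng.integers(4, 15)]
            t = chow_f(x, y, k)
            f, p, rp, r1, r2 = oracle_chow(x, y, k)
            assert np.isclose(t.f_stat, f, rtol=1e-8)
            assert np.isclose(t.p_value, p, rtol=1e-8)
            assert np.isclose(t.rss_pooled, rp, rtol=1e-8)

    def test_zero_on_exactly_linear_data(self):
        x = np.arange(1.0, 21.0)
        y = 3.0 * x - 2.0
        for k in (5.0, 10.0, 15.0):
            t = chow_f(x, y, k)
            assert t.f_stat == 0.0 and t.p_value == 1.0

    def test_infinite_on_exact_piecewise_data(self):
        x = np.arange(1.0, 31.0)
        y = np.where(x <= 16, 0.1 * x, 1.6)
        t = chow_f(x, y, 16.0)
        assert np.isinf(t.f_stat) and t.p_value == 0.0

    def test_rss_decomposition_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x = np.sort(rng.uniform(0, 5, 25))
            y = rng.normal(0, 1, 25)
            t = chow_f(x, y, x[12])
            assert t.rss_left + t.rss_right <= t.rss_pooled + 1e-10

    def test_undersized_segment_raises(self):
        x = np.arange(1.0, 11.0)
        with pytest.raises(ValueError):
            chow_f(x, x, 2.0)


class TestLowess:
    @pytest.mark.parametrize("fraction", [0.2, 2.0 / 3.0, 1.0])
    def test_exact_on_affine_input(self, fraction):
        x = np.arange(1.0, 41.0)
        y = 2.0 * x + 1.0
        sm = lowess_smooth(x, y, fraction=fraction)
        assert np.max(np.abs(sm.y_smooth - y)) < 1e-10

    def test_exact_on_constant_input(self):
        x = np.arange(1.0, 21.0)
        sm = lowess_smooth(x, np.full(20, 3.7))
        assert np.max(np.abs(sm.y_smooth - 3.7)) < 1e-10

    def test_small_bandwidth_recovers_piecewise_segments(self):
        # noiseless kink: local fits recover each linear piece away from it
        x = np.arange(1.0, 41.0)
        y = np.where(x <= 16, 0.1 * x, 1.6)
        sm = lowess_smooth(x, y, fraction=0.2)
        away = (x < 13) | (x > 19)
        assert np.max(np.abs(sm.y_smooth[away] - y[away])) < 0.02

    def test_input_validation(self):
        with pytest.raises(ValueError):
            lowess_smooth([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            lowess_smooth([1.0, 3.0, 2.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            lowess_smooth([1.0, 2.0, 3.0], [0.0, 1.0, 2.0], fraction=1.5)


class TestChowScan:
    def test_noiseless_break_found_with_infinite_f(self):
        x = np.arange(1.0, 41.0)
        y = np.where(x <= 16, 0.1 * x, 1.6)
        res = chow_scan((x, y))
        assert res.k_hat == 16.0
        assert np.isinf(res.f_stat)
        assert res.significant

    def test_k_hat_in_candidate_set_and_tie_break_low(self):
        x = np.arange(1.0, 13.0)
        y = 2.0 * x  # exactly linear: all F = 0, tie broken to smallest k
        res = chow_scan((x, y))
        assert res.k_hat == x[2]  # first candidate with min_segment=3
        assert not res.significant
        assert res.k_hat in set(res.candidates["k"])

    def test_noisy_break_recovery_median_within_one(self):
        rng = np.random.default_rng(7)
        x = np.arange(1.0, 41.0)
        truth = np.where(x <= 16, 0.1 * x, 1.6)
        khats = []
        for _ in range(200):
            y = truth + rng.normal(0, 0.16, len(x))  # 10% of dynamic range
            khats.append(chow_scan((x, y)).k_hat)
        assert abs(np.median(khats) - 16) <= 1

    def test_null_calibration_bonferroni(self):
        rng = np.random.default_rng(3)
        x = np.arange(1.0, 41.0)
        sig = sum(
            chow_scan((x, 0.05 * x + rng.normal(0, 0.1, len(x)))).significant
            for _ in range(300)
        )
        assert sig / 300 <= 0.10

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            chow_scan((np.arange(1.0, 6.0), np.arange(5.0)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_chow_f_oracle_property(seed):
    """chow_f equals the normal-equations oracle on random 20-point series."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0, 10, 20)) + np.arange(20) * 1e-6
    y = rng.normal(0, 1, 20)
    k = x[int(rng.integers(4, 15))]
    t = chow_f(x, y, k)
    f, p, *_ = oracle_chow(x, y, k)
    assert np.isclose(t.f_stat, f, rtol=1e-8)


class TestFindCutpoint:
    def test_recovers_planted_breakpoint(self, piecewise_cohort):
        res = find_cutpoint(piecewise_cohort, curve_source="migration", adjust=())
        assert abs(res.k_hat - 16) <= 2
        assert res.significant
        assert res.provenance["curve_source"] == "migration"
        assert res.provenance["scanned_series"] == "raw"

    def test_no_break_null_rarely_significant(self):
        # flat generating OR curve: beta1 = beta2 = 0
        hits = 0
        for seed in range(8):
            cfg = default_config(n_patients=20_000, seed=seed, mode="piecewise")
            cfg.piecewise.beta1 = 0.0
            cfg.piecewise.beta2 = 0.0
            df = generate_cohort(cfg)
            res = find_cutpoint(df, adjust=(), alpha=0.01)
            hits += res.significant
        assert hits <= 1

    def test_mechanistic_smooth_break_lands_early(self, default_cohort):
        # hypergeometric detection saturates smoothly; the break sits in the
        # single-digit-to-teens range rather than at a sharp planted value
        res = find_cutpoint(default_cohort, adjust=())
        assert 5 <= res.k_hat <= 20

    def test_permutation_invariance(self, piecewise_cohort):
        shuffled = piecewise_cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = find_cutpoint(piecewise_cohort, adjust=())
        b = find_cutpoint(shuffled, adjust=())
        assert a.k_hat == b.k_hat
        assert np.isclose(a.f_stat, b.f_stat)
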