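"""Survival estimators: KM reductions, log-rank calibration, Cox consistency."""

import numpy as np
import pandas as pd
import pytest

from elncut import (
    default_config,
    fit_cox_continuous,
    generate_cohort,
    km_compare_at_cutoff,
    km_estimate,
    logrank_test,
    per_count_hr_curve,
)
from conftest import make_survival_frame


def _exp_two_group(rng, n_per_arm, lam0, lam1, censor=None):
    t0 = rng.exponential(1.0 / lam0, n_per_arm)
    t1 = rng.exponential(1.0 / lam1, n_per_arm)
    df = pd.DataFrame(
        {
            "survival_months": np.concatenate([t0, t1]),
            "death_event": 1,
            "group": np.repeat([0, 1], n_per_arm),
        }
    )
    if censor is not None:
        c = rng.exponential(1.0 / censor, 2 * n_per_arm)
        df["death_event"] = (df["survival_months"] <= c).astype(int)
        df["survival_months"] = np.minimum(df["survival_months"], c)
    return df


class TestKaplanMeier:
    def test_product_limit_by_hand(self, toy_survival):
        s = km_estimate(toy_survival)
        lookup = dict(zip(s.curve["time"], s.curve["surv"]))
        assert np.isclose(lookup[1.0], 2 / 3)
        assert np.isclose(lookup[2.0], 1 / 3)
        assert np.isclose(lookup[3.0], 0.0)
        assert s.median_months == 2.0  # smallest t with S(t) <= 0.5

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        t = np.round(rng.exponential(30, 500), 1)
        df = make_survival_frame(t, np.ones(500))
        s = km_estimate(df)
        for ti, si in zip(s.curve["time"], s.curve["surv"]):
            if ti == 0:
                continue
            assert np.isclose(si, (t > ti).mean(), atol=1e-12)

    def test_all_censored_survival_stays_one_median_not_reached(self):
        df = make_survival_frame([5.0, 10.0, 15.0], [0, 0, 0])
        with pytest.raises(ValueError):
            logrank_test([df, df])
        s = km_estimate(df)
        assert (s.curve["surv"] == 1.0).all()
        assert np.isinf(s.median_months)
        assert s.to_dict()["median_months"] is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(make_survival_frame([], []))

    def test_five_year_readoff_is_step_value(self):
        df = make_survival_frame([10.0, 50.0, 70.0, 90.0], [1, 1, 1, 1])
        s = km_estimate(df)
        assert np.isclose(s.survival_at_60mo, 0.5)  # last step at t=50


class TestLogrank:
    def test_identical_groups_give_zero_chi_square(self, default_cohort):
        g = default_cohort.head(500)
        res = logrank_test([g, g])
        assert res.chi_square < 1e-10 and res.p_value > 0.999
        assert res.df == 1

    def test_gross_separation_detected(self):
        rng = np.random.default_rng(1)
        df = _exp_two_group(rng, 200, 0.02, 0.2)
        res = logrank_test([df[df.group == 0], df[df.group == 1]])
        assert res.p_value < 0.001

    def test_single_group_rejected(self, toy_survival):
        with pytest.raises(ValueError):
            logrank_test([toy_survival])

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 400
        for _ in range(reps):
            df = _exp_two_group(rng, 60, 0.05, 0.05)
            res = logrank_test([df[df.group == 0], df[df.group == 1]])
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestCox:
    def test_rate_ratio_two_consistency(self):
        rng = np.random.default_rng(3)
        df = _exp_two_group(rng, 4_000, 0.05, 0.10)
        df = df.assign(
            eln_count=df["group"] + 1,
            t_stage="T3",
            observed_n_stage="N0",
            histology="AC",
            positive_nodes_examined=0,
        )
        fit = fit_cox_continuous(df, adjust=())
        assert 1.85 <= fit.hr_per_eln <= 2.15

    def test_null_covariate_ci_covers_one(self):
        cfg = default_config(n_patients=10_000, seed=31, mode="piecewise")
        cfg.survival.log_hr_node_positive = 0.0
        cfg.survival.log_hr_residual_pos = 0.0
        cfg.survival.log_hr_t_stage = {t: 0.0 for t in cfg.survival.log_hr_t_stage}
        df = generate_cohort(cfg)
        fit = fit_cox_continuous(df, adjust=())
        lo, hi = fit.ci95
        assert lo <= 1.0 <= hi

    def test_time_scale_invariance(self, default_cohort):
        a = fit_cox_continuous(default_cohort, stratum="node-negative")
        scaled = default_cohort.assign(
            survival_months=default_cohort["survival_months"] * 7.3
        )
        b = fit_cox_continuous(scaled, stratum="node-negative")
        assert np.isclose(a.hr_per_eln, b.hr_per_eln, rtol=1e-6)

    def test_understaging_drives_protective_eln_effect(self, default_cohort):
        # mechanistic mode: low ELN counts hide positive nodes whose excess
        # hazard then contaminates the observed node-negative stratum
        fit = fit_cox_continuous(default_cohort, stratum="node-negative")
        assert fit.hr_per_eln < 1.0 and fit.p_value < 0.01

    def test_zero_events_rejected(self):
        df = pd.DataFrame(
            {
                "eln_count": [3, 4, 5, 6],
                "t_stage": "T3",
                "histology": "AC",
                "positive_nodes_examined": 0,
                "observed_n_stage": "N0",
                "survival_months": [5.0, 6.0, 7.0, 8.0],
                "death_event": 0,
            }
        )
        with pytest.raises(ValueError):
            fit_cox_continuous(df)


class TestHrCurve:
    def test_reference_hr_exactly_one_and_restriction(self, default_cohort):
        curve = per_count_hr_curve(default_cohort, reference_count=16, adjust=())
        assert curve.ratio[0] == 1.0 and curve.levels[0] == 16
        assert np.all(curve.levels >= 16)
        assert curve.scale == "hazard-ratio"

    def test_two_level_hr_matches_event_rate_ratio(self):
        rng = np.random.default_rng(5)
        df = _exp_two_group(rng, 3_000, 0.05, 0.05 * 1.6)
        df = df.assign(
            eln_count=np.where(df["group"] == 1, 20, 16),
            t_stage="T3",
            observed_n_stage="N0",
            histology="AC",
            positive_nodes_examined=0,
        )
        curve = per_count_hr_curve(df, reference_count=16, adjust=(), min_per_level=1)
        hr20 = curve.ratio[curve.levels == 20][0]
        # exponential data: HR consistent for the rate ratio 1.6
        assert 1.45 <= hr20 <= 1.75

    def test_flat_beyond_cutoff_when_survival_ignores_eln(self):
        # survival depends only on true stage, so beyond-cutoff HR trend is null
        cfg = default_config(n_patients=50_000, seed=17, mode="piecewise")
        cfg.survival.log_hr_residual_pos = 0.0
        df = generate_cohort(cfg)
        curve = per_count_hr_curve(df, stratum="node-negative", reference_count=16, adjust=())
        x, y = curve.levels[1:], curve.log_ratio[1:]
        w = 1.0 / np.maximum(curve.se_log[1:], 1e-6) ** 2
        slope, cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov=True)
        assert abs(slope[0]) < 2.5 * np.sqrt(cov[0, 0]) + 1e-3


class TestKmAtCutoff:
    def test_cutoff_below_minimum_is_one_sided(self, default_cohort):
        with pytest.raises(ValueError, match="one-sided"):
            km_compare_at_cutoff(default_cohort, cutoff=1)

    def test_understaged_low_eln_group_has_worse_survival(self, default_cohort):
        above, below, lr = km_compare_at_cutoff(
            default_cohort, cutoff=16, stratum="node-negative"
        )
        assert above.survival_at_60mo > below.survival_at_60mo
        assert lr.p_value < 0.05
        assert above.n + below.n == (default_cohort["observed_n_stage"] == "N0").sum()

    def test_null_split_p_value_roughly_uniform(self):
        # identical survival law on both sides of an arbitrary split
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(200):
            t = rng.exponential(30, 300)
            df = pd.DataFrame(
                {
                    "survival_months": t,
                    "death_event": 1,
                    "eln_count": rng.permutation(np.repeat([10, 20], 150)),
                    "observed_n_stage": "N0",
                    "t_stage": "T3",
                    "histology": "AC",
                    "positive_nodes_examined": 0,
                }
            )
            _, _, lr = km_compare_at_cutoff(df, cutoff=16)
            pvals.append(lr.p_value)
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01
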