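"""Metric contracts: concordance, bootstrap, deltas, stratification,
calibration, decision curves and fixed-FPR metrics."""

import numpy as np
import pytest
from lifelines.utils import concordance_index

from metastate.evaluation import (bootstrap_ci, c_delta, calibration_curve,
                                  decile_rate_ratio, decision_curve,
                                  event_rate_by_percentile, harrell_c,
                                  horizon_status, metrics_at_fpr)


def brute_force_c(times, events, scores):
    """O(n^2) pair enumeration of the concordance contract."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # comparable iff the earlier time is an event (i earlier here)
            if events[i] and (times[i] < times[j]
                              or (times[i] == times[j] and not events[j])):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_ranking_of_uncensored_times(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrell_c(t, [1, 1, 1, 1], [4.0, 3.0, 2.0, 1.0]) == 1.0

    def test_all_scores_tied_gives_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrell_c(t, [1, 1, 0, 1], [2.0, 2.0, 2.0, 2.0]) == 0.5

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = 50
            t = rng.integers(1, 20, size=n).astype(float)  # ties likely
            d = rng.random(n) < 0.7
            if d.sum() == 0:
                d[0] = True
            s = np.round(rng.normal(size=n), 1)  # score ties likely
            assert harrell_c(t, d, s) == pytest.approx(brute_force_c(t, d, s),
                                                       abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            t = rng.random(80) * 10
            d = rng.random(80) < 0.7
            s = rng.normal(size=80)
            # lifelines orders by predicted survival time (negated risk)
            assert harrell_c(t, d, s) == pytest.approx(
                concordance_index(t, -s, d), abs=1e-12)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            harrell_c([1.0, 2.0], [0, 0], [0.1, 0.2])


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        mid, (lo, hi) = bootstrap_ci(lambda x: 3.0, [np.arange(50)], 100, seed=0)
        assert mid == lo == hi == 3.0

    def test_same_seed_identical(self):
        data = [np.random.default_rng(2).normal(size=100)]
        a = bootstrap_ci(np.mean, data, 200, seed=5)
        b = bootstrap_ci(np.mean, data, 200, seed=5)
        assert a == b

    def test_mean_ci_coverage(self):
        rng = np.random.default_rng(3)
        covered = 0
        for rep in range(100):
            x = rng.normal(size=200)
            _, (lo, hi) = bootstrap_ci(np.mean, [x], 200, seed=rep)
            covered += lo <= 0.0 <= hi
        assert 91 <= covered <= 99


class TestCDelta:
    def test_identical_models_delta_zero_not_significant(self):
        rng = np.random.default_rng(4)
        t, d, s = rng.random(300) * 10, rng.random(300) < 0.5, rng.normal(size=300)
        res = c_delta(s, s, t, d, n_iterations=100, seed=0)
        assert res["delta"] == 0.0 and not res["significant"]

    def test_oracle_vs_noise_significant(self):
        rng = np.random.default_rng(5)
        n = 4000
        eta = rng.normal(size=n)
        t = -np.log(rng.random(n)) / (0.02 * np.exp(1.2 * eta))
        c = np.full(n, 12.0)
        d = t <= c
        t = np.minimum(t, c)
        noise = rng.normal(size=n)
        res = c_delta(eta, noise, t, d, n_iterations=200, seed=1)
        assert res["delta"] > 0 and res["significant"]

    def test_tiny_perturbation_not_significant(self):
        rng = np.random.default_rng(6)
        n = 800
        eta = rng.normal(size=n)
        t = -np.log(rng.random(n)) / (0.05 * np.exp(eta))
        d = t <= 10
        t = np.minimum(t, 10)
        res = c_delta(eta, eta + 1e-4 * rng.normal(size=n), t, d,
                      n_iterations=200, seed=2)
        assert not res["significant"]

    def test_unpaired_inputs_error(self):
        with pytest.raises(ValueError):
            c_delta([1.0], [1.0, 2.0], [1.0], [True])


class TestStratification:
    def test_constructed_decile_ratio_of_ten(self):
        scores = np.arange(1000, dtype=float)
        events = np.zeros(1000, dtype=bool)
        events[:100][:2] = True      # bottom decile: 2/100
        events[900:][:20] = True     # top decile: 20/100
        res = decile_rate_ratio(scores, events, n_iterations=50, seed=0)
        assert res["rate_ratio"] == pytest.approx(10.0)
        assert not res["lower_bound_flag"]

    def test_null_scores_ratio_ci_covers_one(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=20000)
        events = rng.random(20000) < 0.05
        res = decile_rate_ratio(scores, events, n_iterations=200, seed=1)
        lo, hi = res["ci"]
        assert lo <= 1.0 <= hi

    def test_percentile_curve_conserves_events(self):
        rng = np.random.default_rng(8)
        scores, events = rng.normal(size=5000), rng.random(5000) < 0.1
        curve = event_rate_by_percentile(scores, events)
        assert curve["events"].sum() == events.sum()
        assert curve["n"].sum() == 5000
        assert curve["mean_score"].is_monotonic_increasing


class TestCalibration:
    def test_constant_risk_no_censoring_on_diagonal(self):
        rng = np.random.default_rng(9)
        n = 2000
        events = rng.random(n) < 0.2
        times = np.where(events, 5.0, 15.0)
        risks = np.full(n, events.mean())
        cal = calibration_curve(risks, times, events, horizon=10, n_bins=1)
        row = cal.iloc[0]
        assert row["observed"] == pytest.approx(row["mean_predicted"], abs=1e-12)

    def test_mean_predicted_nondecreasing(self):
        rng = np.random.default_rng(10)
        risks = rng.random(3000)
        times = rng.random(3000) * 20
        events = rng.random(3000) < 0.3
        cal = calibration_curve(risks, times, events, horizon=10, n_bins=10)
        assert cal["mean_predicted"].is_monotonic_increasing

    def test_risks_outside_unit_interval_error(self):
        with pytest.raises(ValueError):
            calibration_curve([1.2], [1.0], [True], 10, 1)


class TestDecisionCurve:
    def test_constructed_confusion_table(self):
        # 30 flagged at risk 0.3 (10 events, 20 non); 70 at risk 0.1 with 5 events
        risks = np.r_[np.full(30, 0.3), np.full(70, 0.1)]
        events = np.r_[np.ones(10), np.zeros(20), np.ones(5), np.zeros(65)].astype(bool)
        times = np.where(events, 5.0, 20.0)
        dc = decision_curve(risks, times, events, [0.2], horizon=10)
        row = dc.iloc[0]
        assert row["net_benefit"] == pytest.approx(0.10 - 0.20 * 0.25)
        assert dc.attrs["prevalence"] == pytest.approx(0.15)
        assert row["snb"] == pytest.approx(1 / 3, abs=1e-12)
        assert row["treat_none"] == 0.0

    def test_treat_all_snb_limit_and_treat_none(self):
        rng = np.random.default_rng(11)
        events = rng.random(1000) < 0.1
        times = np.where(events, 4.0, 20.0)
        risks = rng.random(1000)
        dc = decision_curve(risks, times, events, [0.001, 0.2, 0.4], horizon=10)
        assert (dc["treat_none"] == 0).all()
        assert dc.iloc[0]["treat_all_snb"] > 0.98  # -> 1 as p_t -> 0

    def test_no_censoring_equals_naive_binary(self):
        rng = np.random.default_rng(12)
        n = 500
        events = rng.random(n) < 0.2
        times = np.where(events, 3.0, 11.0)  # nobody censored before horizon
        risks = rng.random(n)
        y, known = horizon_status(times, events, 10.0)
        assert known.all()
        dc = decision_curve(risks, times, events, [0.3], horizon=10)
        pos = risks >= 0.3
        tp, fp = (pos & events).sum() / n, (pos & ~events).sum() / n
        assert dc.iloc[0]["net_benefit"] == pytest.approx(tp - fp * 0.3 / 0.7)


class TestMetricsAtFPR:
    def test_perfect_separation(self):
        risks = np.r_[np.full(50, 0.9), np.full(200, 0.1)]
        y = np.r_[np.ones(50), np.zeros(200)].astype(bool)
        mf = metrics_at_fpr(risks, y, [0.05, 0.10, 0.20])
        assert (mf["sensitivity"] == 1.0).all()

    def test_lr_plus_definition(self):
        rng = np.random.default_rng(13)
        risks = rng.random(5000)
        y = rng.random(5000) < (0.1 + 0.3 * risks)
        mf = metrics_at_fpr(risks, y, [0.1])
        row = mf.iloc[0]
        assert row["lr_plus"] == pytest.approx(
            row["sensitivity"] / row["achieved_fpr"])

    def test_random_scores_sensitivity_tracks_fpr(self):
        rng = np.random.default_rng(14)
        risks = rng.random(20000)
        y = rng.random(20000) < 0.1
        mf = metrics_at_fpr(risks, y, [0.05, 0.10, 0.20])
        for _, row in mf.iterrows():
            assert abs(row["sensitivity"] - row["target_fpr"]) < 0.1
            assert abs(row["lr_plus"] - 1.0) < 0.35
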