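import math

import numpy as np
import pytest
from scipy.optimize import curve_fit

from restact._utils import circular_diff, circular_mean
from restact.cosinor import (OMEGA_12, OMEGA_24, aggregate_10min, cosinor_summary,
                             daily_cosinor_summary, fit_cosinor, fit_cosinor_values)
from restact.synth import CosinorTruth, generate_subject

from conftest import make_series

# published group-mean double-cosinor parameters, used as generator truth
TABLE_UE = dict(M=1569.3, A24=1875.2, p24=2.86, A12=550.2, p12=3.04)


def _double(t, M, A24, p24, A12, p12):
    return M + A24 * np.cos(OMEGA_24 * t + p24) + A12 * np.cos(OMEGA_12 * t + p12)


class TestAggregate10min:
    def test_sum_of_ten(self):
        s = make_series([3] * 10, start="2024-01-01 00:00")
        agg = aggregate_10min(s)
        assert agg.n == 1 and agg.counts[0] == 30
        assert agg.epoch_length == 10

    def test_trailing_epochs_dropped(self):
        s = make_series(np.ones(25), start="2024-01-01 00:00")
        agg = aggregate_10min(s)
        assert agg.n == 2
        assert list(agg.counts) == [10, 10]

    def test_unaligned_start_dropped(self):
        s = make_series(np.ones(23), start="2024-01-01 00:07")
        agg = aggregate_10min(s)
        assert agg.n == 2
        assert agg.start_time.minute == 10

    def test_zero_series(self):
        agg = aggregate_10min(make_series(np.zeros(30), start="2024-01-01 00:00"))
        assert np.all(agg.counts == 0)

    def test_bad_epoch_length(self):
        with pytest.raises(ValueError):
            aggregate_10min(make_series(np.ones(10), epoch_length=3))


class TestFitCosinor:
    def test_single_noiseless_exact(self):
        t = np.arange(0, 1440, 10, dtype=float)
        y = 100 + 50 * np.cos(OMEGA_24 * t + np.pi / 2)
        fit = fit_cosinor_values(t, y, "single")
        assert fit.mesor == pytest.approx(100, abs=1e-9)
        assert fit.amp24 == pytest.approx(50, abs=1e-9)
        assert fit.acro24 == pytest.approx(np.pi / 2, abs=1e-9)
        assert fit.rss == pytest.approx(0, abs=1e-12)

    def test_double_noiseless_published_values(self):
        t = np.arange(0, 1440, 10, dtype=float)
        y = _double(t, *TABLE_UE.values())
        fit = fit_cosinor_values(t, y, "double")
        assert fit.mesor == pytest.approx(TABLE_UE["M"], abs=1e-6)
        assert fit.amp24 == pytest.approx(TABLE_UE["A24"], abs=1e-6)
        assert fit.acro24 == pytest.approx(TABLE_UE["p24"], abs=1e-6)
        assert fit.amp12 == pytest.approx(TABLE_UE["A12"], abs=1e-6)
        assert fit.acro12 == pytest.approx(TABLE_UE["p12"], abs=1e-6)

    def test_constant_series(self):
        t = np.arange(0, 1440, 10, dtype=float)
        fit = fit_cosinor_values(t, np.full(t.size, 42.0), "single")
        assert fit.mesor == pytest.approx(42.0, abs=1e-9)
        assert fit.amp24 == pytest.approx(0.0, abs=1e-7)
        assert math.isnan(fit.acro24)

    def test_rank_deficient_time(self):
        with pytest.raises(ValueError):
            fit_cosinor_values(np.zeros(20), np.ones(20), "single")

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_cosinor_values(np.arange(5.0) * 200, np.ones(5), "single")

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 1440, 10, dtype=float)
        y = _double(t, 500, 200, 1.0, 80, 2.0) + rng.normal(0, 30, t.size)
        f1 = fit_cosinor_values(t, y, "double")
        f2 = fit_cosinor_values(t, y + 123.0, "double")
        assert f2.mesor == pytest.approx(f1.mesor + 123.0)
        assert f2.amp24 == pytest.approx(f1.amp24)
        assert f2.acro24 == pytest.approx(f1.acro24)
        assert f2.amp12 == pytest.approx(f1.amp12)

    def test_time_shift_covariance(self):
        t = np.arange(0, 1440, 10, dtype=float)
        y = _double(t, 500, 200, 1.0, 80, 2.0)
        delta = 130.0
        f1 = fit_cosinor_values(t, y, "double")
        f2 = fit_cosinor_values(t, _double(t + delta, 500, 200, 1.0, 80, 2.0), "double")
        assert f2.amp24 == pytest.approx(f1.amp24, abs=1e-9)
        assert circular_diff(f2.acro24, f1.acro24 + OMEGA_24 * delta) == pytest.approx(0, abs=1e-9)
        assert circular_diff(f2.acro12, f1.acro12 + OMEGA_12 * delta) == pytest.approx(0, abs=1e-9)

    def test_nested_rss(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 2880, 10, dtype=float)
        y = rng.normal(100, 20, t.size)
        single = fit_cosinor_values(t, y, "single")
        double = fit_cosinor_values(t, y, "double")
        assert double.rss <= single.rss + 1e-9

    def test_matches_nonlinear_least_squares(self):
        t = np.arange(0, 1440, 10, dtype=float)
        y = _double(t, 300, 120, 2.5, 45, 0.7)

        def model(t, M, A24, p24, A12, p12):
            return _double(t, M, A24, p24, A12, p12)

        popt, _ = curve_fit(model, t, y, p0=[250, 100, 2.0, 40, 1.0])
        fit = fit_cosinor_values(t, y, "double")
        assert fit.mesor == pytest.approx(popt[0], abs=1e-6)
        assert fit.amp24 == pytest.approx(abs(popt[1]), abs=1e-6)


class TestDailySummary:
    def test_identical_days_equal_single_fit(self):
        t = np.arange(0, 1440, dtype=float)
        day = np.round(_double(t, 300, 120, 2.5, 45, 0.7)).astype(int)
        s = make_series(np.tile(day, 3), start="2024-01-01 00:00")
        summ = daily_cosinor_summary(s, "double")
        one = fit_cosinor(aggregate_10min(s.day_slice(0)), "double")
        assert summ.n_days_fit == 3
        assert summ.mean_mesor == pytest.approx(one.mesor)
        assert summ.mean_amp24 == pytest.approx(one.amp24)
        assert summ.mean_acro24 == pytest.approx(one.acro24)

    def test_circular_mean_wraps(self):
        assert circular_mean([0.1, 2 * np.pi - 0.1]) == pytest.approx(0.0, abs=1e-12)
        assert circular_mean([np.pi - 0.1, np.pi + 0.1]) == pytest.approx(np.pi)

    def test_phase_averaging_across_wrapped_days(self):
        t = np.arange(0, 1440, dtype=float)
        d1 = np.round(_double(t, 300, 120, 0.1, 0, 0) + 200).astype(int)
        d2 = np.round(_double(t, 300, 120, 2 * np.pi - 0.1, 0, 0) + 200).astype(int)
        s = make_series(np.concatenate([d1, d2]), start="2024-01-01 00:00")
        summ = daily_cosinor_summary(s, "single")
        # circular mean lands near 0, not pi; the ~0.02 rad offset is the
        # known half-bin phase lag of 10-min aggregation (bins stamped at start)
        assert abs(circular_diff(summ.mean_acro24, 0.0)) < 0.03

    def test_no_complete_day_errors(self):
        s = make_series(np.ones(800), start="2024-01-01 07:00")
        with pytest.raises(ValueError):
            daily_cosinor_summary(s)

    def test_whole_series_mode(self):
        t = np.arange(0, 2880, dtype=float)
        y = np.round(_double(t, 300, 120, 2.5, 45, 0.7)).astype(int)
        s = make_series(y, start="2024-01-01 00:00")
        summ = cosinor_summary(s, "double", per_day=False)
        assert summ.n_days_fit == 1
        assert summ.mean_mesor == pytest.approx(3000, rel=0.01)  # 10-min scale


class TestCohortRecovery:
    def test_generator_truth_recovered(self, smooth_bout_config):
        cfg = smooth_bout_config
        truth = cfg.cosinor_truth["UE"]
        Ms, A24s, P24s, A12s, P12s = [], [], [], [], []
        for i in range(3):
            s = generate_subject(cfg, "UE", i)
            cs = daily_cosinor_summary(s, "double")
            Ms.append(cs.mean_mesor / 10)     # 10-min bins sum ten 1-min epochs
            A24s.append(cs.mean_amp24 / 10)
            P24s.append(cs.mean_acro24)
            A12s.append(cs.mean_amp12 / 10)
            P12s.append(cs.mean_acro12)
        assert np.mean(Ms) == pytest.approx(truth.mesor, rel=0.05)
        assert np.mean(A24s) == pytest.approx(truth.amp24, rel=0.10)
        assert np.mean(A12s) == pytest.approx(truth.amp12, rel=0.15)
        assert abs(circular_diff(circular_mean(P24s), truth.acro24)) < 0.10
        assert abs(circular_diff(circular_mean(P12s), truth.acro12)) < 0.20
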