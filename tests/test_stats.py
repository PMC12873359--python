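import math

import numpy as np
import pytest
from scipy import stats as sps

from restact.stats import (CorrelationResult, ThreeChamberTrial, group_hour_anova,
                           pearson_with_F, r_from_F, social_preference_index,
                           three_chamber_report, two_sample_t)
from restact.synth import generate_three_chamber


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_computed_example(self):
        res = two_sample_t([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        assert res.p == pytest.approx(0.2878, abs=1e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 6)
        res = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_zero_variance(self):
        same = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert same.degenerate and same.p == 1.0
        diff = two_sample_t([2.0, 2.0], [3.0, 3.0])
        assert diff.degenerate and diff.p == 0.0 and math.isinf(diff.t)

    def test_type_one_error_calibration_small(self):
        rng = np.random.default_rng(1)
        rejects = sum(
            two_sample_t(rng.normal(0, 1, 5), rng.normal(0, 1, 5)).p < 0.05
            for _ in range(2000)
        )
        assert rejects / 2000 == pytest.approx(0.05, abs=0.015)


class TestPearsonWithF:
    def test_perfect_linear(self):
        res = pearson_with_F([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == 1.0
        assert math.isinf(res.F)
        assert res.p == 0.0

    def test_published_F_inverts_to_r(self):
        assert r_from_F(7.6770, 7) == pytest.approx(0.7233, abs=1e-4)
        assert round(r_from_F(7.6770, 7), 2) == 0.72

    def test_matches_regression_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 9)
        y = 0.8 * x + rng.normal(0, 1, 9)
        res = pearson_with_F(x, y)
        reg = sps.linregress(x, y)
        assert res.r == pytest.approx(reg.rvalue, abs=1e-10)
        assert res.p == pytest.approx(reg.pvalue, abs=1e-10)  # F test == slope t test
        assert res.F == pytest.approx(reg.rvalue ** 2 * 7 / (1 - reg.rvalue ** 2), abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        a, b = pearson_with_F(x, y), pearson_with_F(y, x)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.F == pytest.approx(b.F, abs=1e-9)

    def test_internal_consistency_enforced(self):
        with pytest.raises(ValueError):
            CorrelationResult(r=0.5, F=99.0, df1=1, df2=7, p=0.01, n=9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_with_F([1, 1, 1], [1, 2, 3])


def _anova_oracle(labels, Y):
    """Definitional sums-of-squares decomposition by explicit loops."""
    labels = list(labels)
    groups = sorted(set(labels))
    N, h = Y.shape
    grand = Y.mean()
    ss = {}
    ss["between_subj"] = sum(h * (Y[i].mean() - grand) ** 2 for i in range(N))
    ss["group"] = 0.0
    for g in groups:
        rows = [i for i, l in enumerate(labels) if l == g]
        gm = Y[rows].mean()
        ss["group"] += len(rows) * h * (gm - grand) ** 2
    ss["subj_within"] = ss["between_subj"] - ss["group"]
    ss["hour"] = sum(N * (Y[:, j].mean() - grand) ** 2 for j in range(h))
    ss["inter"] = 0.0
    for g in groups:
        rows = [i for i, l in enumerate(labels) if l == g]
        gm = Y[rows].mean()
        for j in range(h):
            cell = Y[rows][:, j].mean()
            ss["inter"] += len(rows) * (cell - gm - Y[:, j].mean() + grand) ** 2
    ss["total"] = ((Y - grand) ** 2).sum()
    ss["err2"] = ss["total"] - ss["between_subj"] - ss["hour"] - ss["inter"]
    g = len(groups)
    F_group = (ss["group"] / (g - 1)) / (ss["subj_within"] / (N - g))
    F_hour = (ss["hour"] / (h - 1)) / (ss["err2"] / ((N - g) * (h - 1)))
    F_inter = (ss["inter"] / ((g - 1) * (h - 1))) / (ss["err2"] / ((N - g) * (h - 1)))
    return F_group, F_hour, F_inter


class TestGroupHourAnova:
    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(4)
        labels = ["UE"] * 3 + ["VPA"] * 3
        Y = rng.normal(10, 2, (6, 4))
        res = group_hour_anova(labels, Y, posthoc=False)
        Fg, Fh, Fi = _anova_oracle(labels, Y)
        assert res.group.F == pytest.approx(Fg, abs=1e-10)
        assert res.hour.F == pytest.approx(Fh, abs=1e-10)
        assert res.interaction.F == pytest.approx(Fi, abs=1e-10)
        assert (res.group.df_num, res.group.df_den) == (1, 4)
        assert (res.hour.df_num, res.hour.df_den) == (3, 12)

    def test_identical_profiles_null(self):
        Y = np.tile(np.arange(24, dtype=float), (6, 1))
        res = group_hour_anova(["UE"] * 3 + ["VPA"] * 3, Y, posthoc=False)
        assert res.group.F == 0.0 and res.group.p == 1.0
        assert res.interaction.p == 1.0

    def test_hour_effect_only(self):
        rng = np.random.default_rng(5)
        hits_hour = 0
        false_group = 0
        n_rep = 100
        for _ in range(n_rep):
            hour_effect = np.linspace(0, 5, 24)
            Y = hour_effect + rng.normal(0, 1, (10, 24))
            res = group_hour_anova(["UE"] * 5 + ["VPA"] * 5, Y, posthoc=False)
            hits_hour += res.hour.p < 0.05
            false_group += res.group.p < 0.05
        assert hits_hour >= 95
        assert false_group <= 15

    def test_posthoc_bonferroni_bounds(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(0, 1, (8, 24))
        res = group_hour_anova(["UE"] * 4 + ["VPA"] * 4, Y, posthoc=True)
        ph = res.posthoc
        assert (ph.p_bonferroni >= ph.p_raw - 1e-15).all()
        assert (ph.p_bonferroni <= 1.0).all()
        assert np.allclose(ph.p_bonferroni, np.minimum(1.0, ph.p_raw * 24))

    def test_missing_hours_error(self):
        Y = np.ones((4, 24))
        Y[0, 3] = np.nan
        with pytest.raises(ValueError, match="imputation"):
            group_hour_anova(["UE"] * 2 + ["VPA"] * 2, Y)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            group_hour_anova(["UE"] * 3 + ["VPA"] * 2, np.ones((5, 4)))


class TestThreeChamber:
    def _trial(self, sid, stranger, empty, trans=10, idx=1):
        return ThreeChamberTrial(sid, idx, stranger, empty,
                                 100 - stranger - empty, trans)

    def test_spi_formula(self):
        assert social_preference_index(self._trial("a", 60, 20)) == pytest.approx(0.4)
        assert social_preference_index(self._trial("a", 30, 30)) == 0.0
        assert social_preference_index(self._trial("a", 100, 0)) == 1.0

    def test_spi_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.dirichlet([1, 1, 1]) * 100
            spi = social_preference_index(
                ThreeChamberTrial("x", 1, p[0], p[1], p[2], 5))
            assert -1 <= spi <= 1

    def test_percentage_validation(self):
        with pytest.raises(ValueError):
            ThreeChamberTrial("x", 1, 80, 30, 20, 5)
        with pytest.raises(ValueError):
            ThreeChamberTrial("x", 1, 50, 20, 20, -1)

    def test_single_trial_subjects(self):
        trials = [self._trial("u1", 60, 20, 8), self._trial("u2", 55, 25, 9),
                  self._trial("v1", 35, 35, 20), self._trial("v2", 30, 30, 22)]
        groups = {"u1": "UE", "u2": "UE", "v1": "VPA", "v2": "VPA"}
        rep = three_chamber_report(trials, groups)
        row = rep.per_subject.set_index("subject_id").loc["u1"]
        assert row.spi == pytest.approx(0.4)
        assert row.transitions == 8

    def test_identical_groups_t_zero(self):
        trials = [self._trial(s, 50, 25, 10) for s in ("u1", "u2", "v1", "v2")]
        groups = {"u1": "UE", "u2": "UE", "v1": "VPA", "v2": "VPA"}
        rep = three_chamber_report(trials, groups)
        assert rep.spi_ttest.t == 0.0

    def test_negative_coupling_gives_negative_r(self):
        neg = 0
        n_seeds = 40
        for seed in range(n_seeds):
            trials = generate_three_chamber(5, n_trials=5, seed=seed,
                                            transition_coupling=-8.0)
            groups = {t.subject_id: t.subject_id.split("-")[0] for t in trials}
            rep = three_chamber_report(trials, groups)
            neg += rep.transitions_vs_stranger.r < 0
        assert neg >= int(0.95 * n_seeds) - 1
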