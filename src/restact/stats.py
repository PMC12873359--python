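"""Group comparisons, correlation reporting and three-chamber scoring.

Provides the pooled-variance two-tailed t-test, Pearson correlations reported
as (r, F(1, n-2), p), the mixed group x hour ANOVA (between-subject group,
within-subject hour) with Bonferroni-adjusted per-hour contrasts, and the
social-preference-index machinery of the three-chamber test.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import SubjectRecord


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    group_means: tuple
    group_sds: tuple
    degenerate: bool = False
    welch: bool = False


@dataclass
class CorrelationResult:
    """Pearson r with the equivalent regression F test.

    Invariant: F = r**2 * df2 / (1 - r**2), df1 = 1, df2 = n - 2.
    """

    r: float
    F: float
    df1: int
    df2: int
    p: float
    n: int

    def __post_init__(self):
        if self.df1 != 1:
            raise ValueError("df1 must be 1")
        if math.isfinite(self.F) and abs(self.r) < 1:
            expect = self.r ** 2 * self.df2 / (1 - self.r ** 2)
            if not math.isclose(self.F, expect, rel_tol=1e-6, abs_tol=1e-9):
                raise ValueError("inconsistent (r, F, df2) triple")


@dataclass
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class AnovaResult:
    group: AnovaEffect
    hour: AnovaEffect
    interaction: AnovaEffect
    posthoc: pd.DataFrame | None = None


@dataclass
class ThreeChamberTrial:
    subject_id: str
    trial_index: int
    pct_stranger: float
    pct_empty: float
    pct_center: float
    transitions: int

    def __post_init__(self):
        for name in ("pct_stranger", "pct_empty", "pct_center"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.pct_stranger + self.pct_empty + self.pct_center
        if total > 100.0 + 1e-6:
            raise ValueError(f"chamber percentages sum to {total} > 100")
        if self.transitions < 0 or int(self.transitions) != self.transitions:
            raise ValueError("transitions must be a non-negative integer")
        self.transitions = int(self.transitions)


@dataclass
class ThreeChamberReport:
    per_subject: pd.DataFrame
    spi_ttest: TTestResult
    transitions_ttest: TTestResult
    transitions_vs_stranger: CorrelationResult


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def two_sample_t(a, b, welch: bool = False) -> TTestResult:
    """Two-tailed Student t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    ma, mb = a.mean(), b.mean()
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    na, nb = a.size, b.size
    if welch:
        if sa == 0 and sb == 0:
            return _degenerate_t(ma, mb, sa, sb, float(na + nb - 2), welch=True)
        se = math.sqrt(sa ** 2 / na + sb ** 2 / nb)
        df = (sa ** 2 / na + sb ** 2 / nb) ** 2 / (
            (sa ** 2 / na) ** 2 / (na - 1) + (sb ** 2 / nb) ** 2 / (nb - 1)
        )
    else:
        sp2 = ((na - 1) * sa ** 2 + (nb - 1) * sb ** 2) / (na + nb - 2)
        if sp2 == 0:
            return _degenerate_t(ma, mb, sa, sb, float(na + nb - 2), welch=False)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
    t = (ma - mb) / se
    p = 2 * float(_sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, (float(ma), float(mb)),
                       (float(sa), float(sb)), welch=welch)


def _degenerate_t(ma, mb, sa, sb, df, welch):
    if ma == mb:
        return TTestResult(0.0, df, 1.0, (float(ma), float(mb)),
                           (float(sa), float(sb)), degenerate=True, welch=welch)
    return TTestResult(math.inf if ma > mb else -math.inf, df, 0.0,
                       (float(ma), float(mb)), (float(sa), float(sb)),
                       degenerate=True, welch=welch)


def r_from_F(F: float, df2: int) -> float:
    """Closed-form |r| implied by a simple-regression F with (1, df2) df."""
    if F < 0 or df2 <= 0:
        raise ValueError("F must be >= 0 and df2 > 0")
    return math.sqrt(F / (F + df2))


def pearson_with_F(x, y) -> CorrelationResult:
    """Pearson r reported with its regression F(1, n-2) and p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    n = int(x.size)
    df2 = n - 2
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationResult(float(np.sign(r)), math.inf, 1, df2, 0.0, n)
    F = r ** 2 * df2 / (1 - r ** 2)
    p = float(_sps.f.sf(F, 1, df2))
    return CorrelationResult(r, float(F), 1, df2, p, n)


# ---------------------------------------------------------------------------
# Mixed group x hour ANOVA (split-plot)
# ---------------------------------------------------------------------------

def group_hour_anova(group_labels, matrix, posthoc: bool = True,
                     n_comparisons: int | None = None) -> AnovaResult:
    """Two-factor mixed ANOVA: group between subjects, hour within.

    ``matrix`` is (n_subjects, n_hours) with complete rows (NaN is an error;
    missing hours are never imputed).  Group sizes must be equal.  The
    subject-within-group stratum is the error term for the group effect; the
    residual within-subject stratum serves hour and interaction.  Post hoc:
    per-hour pooled t-tests, Bonferroni-adjusted over the number of hours.
    """
    labels = np.asarray(group_labels)
    Y = np.asarray(matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != labels.size:
        raise ValueError("matrix must be (n_subjects, n_hours) matching group_labels")
    if np.isnan(Y).any():
        raise ValueError("missing cells in profile matrix; no imputation is performed")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    idx = [np.nonzero(labels == g)[0] for g in uniq]
    if any(len(i) < 2 for i in idx):
        raise ValueError("need >= 2 subjects per group")
    if len(idx[0]) != len(idx[1]):
        raise ValueError("groups must be balanced for this ANOVA")
    N, h = Y.shape
    g = 2
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([Y[i].mean() for i in idx])
    hour_means = Y.mean(axis=0)

    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = h * ((subj_means - grand) ** 2).sum()
    ss_group = h * sum(len(i) * (gm - grand) ** 2 for i, gm in zip(idx, group_means))
    ss_subj_within = ss_between_subj - ss_group
    ss_hour = N * ((hour_means - grand) ** 2).sum()
    ss_inter = 0.0
    for i, gm in zip(idx, group_means):
        cell = Y[i].mean(axis=0)
        ss_inter += len(i) * ((cell - gm - hour_means + grand) ** 2).sum()
    ss_err2 = ss_total - ss_between_subj - ss_hour - ss_inter

    df_group, df_s = g - 1, N - g
    df_hour = h - 1
    df_inter = (g - 1) * (h - 1)
    df_err2 = (N - g) * (h - 1)

    def _effect(ss, df_num, ms_err, df_den):
        if ms_err <= 0:
            if ss <= 1e-12:
                return AnovaEffect(0.0, df_num, df_den, 1.0)
            return AnovaEffect(math.inf, df_num, df_den, 0.0)
        F = (ss / df_num) / ms_err
        return AnovaEffect(float(F), df_num, df_den, float(_sps.f.sf(F, df_num, df_den)))

    ms_s = ss_subj_within / df_s if df_s else 0.0
    ms_e2 = ss_err2 / df_err2 if df_err2 else 0.0
    res = AnovaResult(
        group=_effect(ss_group, df_group, ms_s, df_s),
        hour=_effect(ss_hour, df_hour, ms_e2, df_err2),
        interaction=_effect(ss_inter, df_inter, ms_e2, df_err2),
    )
    if posthoc:
        k = n_comparisons if n_comparisons is not None else h
        rows = []
        for j in range(h):
            tt = two_sample_t(Y[idx[0], j], Y[idx[1], j])
            rows.append({
                "hour": j, "t": tt.t, "p_raw": tt.p,
                "p_bonferroni": min(1.0, tt.p * k),
                "significant_05": tt.p * k < 0.05,
                "tendency_10": tt.p * k < 0.10,
            })
        res.posthoc = pd.DataFrame(rows)
    return res


# ---------------------------------------------------------------------------
# Three-chamber scoring
# ---------------------------------------------------------------------------

def social_preference_index(trial: ThreeChamberTrial) -> float:
    """(percent stranger - percent empty) / 100, in [-1, 1]."""
    return (trial.pct_stranger - trial.pct_empty) / 100.0


def _group_of(subjects, sid: str) -> str:
    if isinstance(subjects, dict):
        return subjects[sid]
    for s in subjects:
        if s.subject_id == sid:
            return s.group
    raise KeyError(f"subject {sid} not found in metadata")


def three_chamber_report(trials, subjects) -> ThreeChamberReport:
    """Per-subject trial means, group t-tests on SPI/transitions, and the
    correlation between mean transitions and mean stranger-chamber time."""
    if not trials:
        raise ValueError("no trials")
    rows = []
    for t in trials:
        rows.append({
            "subject_id": t.subject_id,
            "group": _group_of(subjects, t.subject_id),
            "spi": social_preference_index(t),
            "pct_stranger": t.pct_stranger,
            "pct_empty": t.pct_empty,
            "pct_center": t.pct_center,
            "transitions": t.transitions,
        })
    df = pd.DataFrame(rows)
    per = df.groupby(["subject_id", "group"], sort=True, as_index=False).mean(numeric_only=True)
    a = per[per.group == "UE"]
    b = per[per.group == "VPA"]
    spi_tt = two_sample_t(a.spi, b.spi)
    tr_tt = two_sample_t(a.transitions, b.transitions)
    try:
        corr = pearson_with_F(per.transitions, per.pct_stranger)
    except ValueError:  # degenerate cohort (zero variance)
        n = len(per)
        corr = CorrelationResult(math.nan, math.nan, 1, max(n - 2, 1), math.nan, n)
    return ThreeChamberReport(per, spi_tt, tr_tt, corr)


def read_three_chamber_csv(path) -> list[ThreeChamberTrial]:
    df = pd.read_csv(path)
    req = ["animal_id", "trial", "pct_stranger", "pct_empty", "pct_center", "transitions"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        ThreeChamberTrial(str(r.animal_id), int(r.trial), float(r.pct_stranger),
                          float(r.pct_empty), float(r.pct_center), int(r.transitions))
        for r in df.itertuples()
    ]


def write_three_chamber_csv(trials, path) -> None:
    pd.DataFrame(
        [
            {"animal_id": t.subject_id, "trial": t.trial_index,
             "pct_stranger": t.pct_stranger, "pct_empty": t.pct_empty,
             "pct_center": t.pct_center, "transitions": t.transitions}
            for t in trials
        ]
    ).to_csv(path, index=False)
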