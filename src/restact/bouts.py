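"""Threshold-based rest/active bout extraction and duration-distribution fits.

An epoch is *resting* when its count is strictly below the threshold and
*active* otherwise; maximal runs of one state form bouts.  The empirical
survival curve P(x >= a) of bout durations is fitted with a power law for
resting bouts and a stretched exponential for active bouts, both by OLS on
the appropriate log transforms (matching the functional-form fitting the
analysis is defined with; a Hill-type MLE is provided as a cross-check).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .io import EpochSeries

DEFAULT_REST_RANGE = (3.0, 30.0)
DEFAULT_ACTIVE_RANGE = (10.0, 100.0)


@dataclass
class BoutSequence:
    threshold: float | np.ndarray
    rest_durations: np.ndarray
    active_durations: np.ndarray
    boundary_policy: str = "drop_censored"

    def __post_init__(self):
        self.rest_durations = np.asarray(self.rest_durations, dtype=float)
        self.active_durations = np.asarray(self.active_durations, dtype=float)
        for arr in (self.rest_durations, self.active_durations):
            if arr.size and arr.min() < 1:
                raise ValueError("bout durations must be >= 1 minute")
        if self.boundary_policy not in ("drop_censored", "keep_all"):
            raise ValueError("boundary_policy must be 'drop_censored' or 'keep_all'")


@dataclass
class SurvivalCurve:
    """Empirical P(x >= a) evaluated at each distinct observed duration."""

    durations_a: np.ndarray
    p_ge_a: np.ndarray
    n_bouts: int

    def __post_init__(self):
        self.durations_a = np.asarray(self.durations_a, dtype=float)
        self.p_ge_a = np.asarray(self.p_ge_a, dtype=float)
        if self.p_ge_a.size:
            if not np.isclose(self.p_ge_a[0], 1.0):
                raise ValueError("survival curve must start at 1")
            if (np.diff(self.p_ge_a) > 1e-12).any():
                raise ValueError("survival curve must be non-increasing")


@dataclass
class RestFit:
    """Power law P(x >= a) = A * a**(-gamma) fitted on log-log axes."""

    gamma: float
    prefactor_A: float
    fit_range: tuple
    r_squared: float
    n_points: int = 0


@dataclass
class ActiveFit:
    """Stretched exponential P(x >= a) = exp(-alpha * a**beta)."""

    alpha: float
    beta: float
    fit_range: tuple
    r_squared: float
    n_points: int = 0


def compute_threshold(series: EpochSeries, mode: str = "overall"):
    """Rest/active threshold: mean of the nonzero counts.

    ``mode='overall'`` (default) uses every nonzero count of the recording and
    returns a scalar.  ``mode='per_day'`` returns a per-epoch array in which
    each epoch carries the nonzero-mean of its own calendar day (days without
    nonzero counts fall back to the overall mean).
    """
    nz = series.counts[series.counts > 0]
    if nz.size == 0:
        raise ValueError("all counts are zero; threshold undefined")
    overall = float(nz.mean())
    if mode == "overall":
        return overall
    if mode == "per_day":
        out = np.full(series.n, overall, dtype=float)
        di = series.day_index
        for d in np.unique(di):
            sel = di == d
            nzd = series.counts[sel]
            nzd = nzd[nzd > 0]
            if nzd.size:
                out[sel] = float(nzd.mean())
        return out
    raise ValueError("mode must be 'overall' or 'per_day'")


def extract_bouts(series: EpochSeries, threshold,
                  boundary_policy: str = "drop_censored") -> BoutSequence:
    """Split the series into maximal rest (< threshold) / active (>= threshold)
    runs; durations are run length x epoch_length minutes.

    Under ``drop_censored`` the first and last runs are discarded because the
    recording window truncates them.
    """
    thr = np.asarray(threshold, dtype=float)
    if np.any(thr <= 0):
        raise ValueError("threshold must be positive")
    active = series.counts >= thr
    change = np.nonzero(np.diff(active))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [series.n]))
    states = active[starts]
    lengths = (ends - starts) * series.epoch_length
    if boundary_policy == "drop_censored" and lengths.size > 0:
        keep = np.ones(lengths.size, dtype=bool)
        keep[0] = keep[-1] = False
        states, lengths = states[keep], lengths[keep]
    elif boundary_policy != "keep_all":
        raise ValueError("boundary_policy must be 'drop_censored' or 'keep_all'")
    return BoutSequence(
        threshold=threshold,
        rest_durations=lengths[~states],
        active_durations=lengths[states],
        boundary_policy=boundary_policy,
    )


def survival_curve(durations) -> SurvivalCurve:
    """Empirical survival P(x >= a) = #(durations >= a) / n at distinct a."""
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no durations")
    uniq, counts = np.unique(d, return_counts=True)
    ge = counts[::-1].cumsum()[::-1]
    return SurvivalCurve(uniq, ge / d.size, int(d.size))


def _ols_loglog(x: np.ndarray, y: np.ndarray):
    res = _sps.linregress(x, y)
    return res.slope, res.intercept, res.rvalue ** 2


def fit_rest_powerlaw(curve: SurvivalCurve,
                      fit_range: tuple = DEFAULT_REST_RANGE) -> RestFit:
    """OLS of log P on log a over durations inside ``fit_range``."""
    lo, hi = fit_range
    mask = (curve.durations_a >= lo) & (curve.durations_a <= hi)
    a = curve.durations_a[mask]
    p = curve.p_ge_a[mask]
    if a.size < 3:
        raise ValueError(f"need >= 3 distinct durations in {fit_range}, got {a.size}")
    slope, intercept, r2 = _ols_loglog(np.log(a), np.log(p))
    return RestFit(gamma=-slope, prefactor_A=float(np.exp(intercept)),
                   fit_range=(lo, hi), r_squared=r2, n_points=int(a.size))


def fit_active_stretched_exp(curve: SurvivalCurve,
                             fit_range: tuple = DEFAULT_ACTIVE_RANGE) -> ActiveFit:
    """OLS of log(-log P) on log a; points with P = 1 are excluded
    (log(-log 1) is undefined)."""
    lo, hi = fit_range
    mask = (curve.durations_a >= lo) & (curve.durations_a <= hi) & (curve.p_ge_a < 1.0)
    a = curve.durations_a[mask]
    p = curve.p_ge_a[mask]
    if a.size < 3:
        raise ValueError(f"need >= 3 usable distinct durations in {fit_range}, got {a.size}")
    slope, intercept, r2 = _ols_loglog(np.log(a), np.log(-np.log(p)))
    return ActiveFit(alpha=float(np.exp(intercept)), beta=float(slope),
                     fit_range=(lo, hi), r_squared=r2, n_points=int(a.size))


def hill_exponent(durations, a_min: float) -> float:
    """Hill MLE of the survival exponent for the tail ``a >= a_min``.

    Cross-check utility for :func:`fit_rest_powerlaw`; assumes a continuous
    Pareto tail, so expect discretisation bias on whole-minute data.
    """
    d = np.asarray(durations, dtype=float)
    tail = d[d >= a_min]
    if tail.size < 2:
        raise ValueError("too few tail observations for Hill estimate")
    return float(tail.size / np.log(tail / a_min).sum())
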