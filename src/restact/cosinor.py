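"""Single- and double-component cosinor fitting of activity rhythms.

The model is ``y(t) = M + A24*cos(w24*t + phi24) [+ A12*cos(w12*t + phi12)]``
with fixed angular frequencies for the 24 h and 12 h periods.  Fitting is done
by linearising each component into cos/sin regressors and solving ordinary
least squares; time is measured in minutes from local midnight.  Fits are
performed per calendar day on 10-minute aggregated counts and the daily
parameters are then averaged (circularly for acrophases).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._utils import TWO_PI, circular_mean
from .io import MINUTES_PER_DAY, EpochSeries

logger = logging.getLogger(__name__)

OMEGA_24 = TWO_PI / MINUTES_PER_DAY   # rad per minute
OMEGA_12 = TWO_PI / (MINUTES_PER_DAY // 2)

_MIN_POINTS = {"single": 6, "double": 10}


@dataclass
class CosinorFit:
    """Parameters of one least-squares cosinor fit.

    Acrophases are the phase of ``cos(w*t + phi)`` in [0, 2*pi); when an
    amplitude is numerically zero the acrophase is NaN (undefined).
    """

    mesor: float
    amp24: float
    acro24: float
    rss: float
    n_points: int
    amp12: float | None = None
    acro12: float | None = None
    omega_24: float = OMEGA_24
    omega_12: float = OMEGA_12

    @property
    def components(self) -> str:
        return "single" if self.amp12 is None else "double"

    @property
    def peak_time_24(self) -> float:
        """Clock time of the 24 h component peak, minutes after midnight."""
        if math.isnan(self.acro24):
            return math.nan
        return ((TWO_PI - self.acro24) / OMEGA_24) % MINUTES_PER_DAY


@dataclass
class CosinorSummary:
    """Per-day fits plus their averages (circular mean for acrophases)."""

    per_day_fits: list
    mean_mesor: float
    mean_amp24: float
    mean_acro24: float
    mean_amp12: float | None = None
    mean_acro12: float | None = None
    n_days_fit: int = 0


def aggregate_10min(series: EpochSeries) -> EpochSeries:
    """Sum counts into clock-aligned, non-overlapping 10-minute bins.

    Leading epochs before the first 10-minute boundary and any trailing
    partial bin are dropped (logged, never imputed).
    """
    L = series.epoch_length
    if 10 % L != 0:
        raise ValueError(f"epoch_length {L} does not divide 10 minutes")
    if L == 10:
        return series
    k = 10 // L
    abs_min = series.abs_minutes
    aligned = np.nonzero(abs_min % 10 == 0)[0]
    if aligned.size == 0:
        raise ValueError("series too short to contain a clock-aligned 10-minute bin")
    i0 = int(aligned[0])
    n_bins = (series.n - i0) // k
    if n_bins < 1:
        raise ValueError("series too short to contain a complete 10-minute bin")
    dropped = i0 + (series.n - i0) - n_bins * k
    if dropped:
        logger.debug("aggregate_10min: dropped %d partial-bin epochs", dropped)
    binned = series.counts[i0:i0 + n_bins * k].reshape(n_bins, k).sum(axis=1)
    from datetime import timedelta

    start = series.start_time + timedelta(minutes=i0 * L)
    return EpochSeries(series.subject_id, start, binned, 10,
                      series.lights_on, series.lights_off)


def fit_cosinor_values(t, y, components: str = "double") -> CosinorFit:
    """Least-squares cosinor fit on raw (t, y) arrays; t in minutes."""
    if components not in _MIN_POINTS:
        raise ValueError("components must be 'single' or 'double'")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    n = t.size
    if n < _MIN_POINTS[components]:
        raise ValueError(f"need >= {_MIN_POINTS[components]} points for {components} cosinor")
    if t.max() - t.min() < MINUTES_PER_DAY / 2:
        raise ValueError("data must span at least half the 24 h period")
    cols = [np.ones(n), np.cos(OMEGA_24 * t), np.sin(OMEGA_24 * t)]
    if components == "double":
        cols += [np.cos(OMEGA_12 * t), np.sin(OMEGA_12 * t)]
    X = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient cosinor design (degenerate time axis)")
    resid = y - X @ coef
    rss = float(resid @ resid)

    def _polar(a: float, b: float) -> tuple[float, float]:
        amp = math.hypot(a, b)
        if amp <= 1e-9 * (1.0 + abs(coef[0])):
            return amp, math.nan
        return amp, math.atan2(-b, a) % TWO_PI

    amp24, acro24 = _polar(coef[1], coef[2])
    if components == "single":
        return CosinorFit(float(coef[0]), amp24, acro24, rss, n)
    amp12, acro12 = _polar(coef[3], coef[4])
    return CosinorFit(float(coef[0]), amp24, acro24, rss, n,
                      amp12=amp12, acro12=acro12)


def fit_cosinor(series: EpochSeries, components: str = "double") -> CosinorFit:
    """Cosinor fit of a whole series; t = epoch-start minutes from midnight
    of the first recording day."""
    return fit_cosinor_values(series.abs_minutes, series.counts.astype(float), components)


def daily_cosinor_summary(series: EpochSeries, components: str = "double") -> CosinorSummary:
    """Fit each complete calendar day on 10-min aggregates, then average.

    Days whose fit fails its preconditions are skipped with a log entry.
    Linear parameters are averaged arithmetically, acrophases circularly.
    """
    days = series.complete_days()
    if days.size == 0:
        raise ValueError("no complete calendar day in series")
    fits: list[CosinorFit] = []
    for d in days:
        try:
            sub = aggregate_10min(series.day_slice(int(d)))
            fits.append(fit_cosinor(sub, components))
        except ValueError as exc:  # pragma: no cover - defensive
            logger.warning("skipping day %d: %s", d, exc)
    if not fits:
        raise ValueError("no day could be fitted")
    mean_m = float(np.mean([f.mesor for f in fits]))
    mean_a24 = float(np.mean([f.amp24 for f in fits]))
    mean_p24 = circular_mean([f.acro24 for f in fits])
    if components == "double":
        mean_a12 = float(np.mean([f.amp12 for f in fits]))
        mean_p12 = circular_mean([f.acro12 for f in fits])
        return CosinorSummary(fits, mean_m, mean_a24, mean_p24,
                              mean_a12, mean_p12, n_days_fit=len(fits))
    return CosinorSummary(fits, mean_m, mean_a24, mean_p24, n_days_fit=len(fits))


def cosinor_summary(series: EpochSeries, components: str = "double",
                    per_day: bool = True) -> CosinorSummary:
    """Dispatch between the per-day-averaged (default) and whole-series modes."""
    if per_day:
        return daily_cosinor_summary(series, components)
    fit = fit_cosinor(aggregate_10min(series), components)
    return CosinorSummary([fit], fit.mesor, fit.amp24, fit.acro24,
                          fit.amp12, fit.acro12, n_days_fit=1)
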