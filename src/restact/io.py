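"""Data model and I/O for minute-epoch activity-count recordings.

An :class:`EpochSeries` holds equally spaced non-negative integer activity
counts together with the light schedule of the housing room.  Everything
downstream (cosinor fitting, bout extraction, entropy) consumes this type.
Module-level functions provide the CSV dialects, day/night partitioning and
the descriptive statistics reported per subject.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

GROUPS = ("UE", "VPA")
SEXES = ("M", "F")


class ParseError(ValueError):
    """A row of an epoch CSV could not be parsed."""


class SpacingError(ValueError):
    """Timestamps do not advance by exactly one epoch length."""


def _minute_of(t: time) -> int:
    return t.hour * 60 + t.minute


@dataclass
class EpochSeries:
    """Equally spaced activity counts for one subject.

    counts[i] covers the half-open interval starting at
    ``start_time + i * epoch_length`` minutes.  The series is contiguous by
    construction: gaps must be handled before building one.
    """

    subject_id: str
    start_time: datetime
    counts: np.ndarray
    epoch_length: int = 1
    lights_on: time = time(7, 0)
    lights_off: time = time(19, 0)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts).astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = int(np.argmax(self.counts < 0))
            raise ValueError(f"negative count at epoch {bad}")
        if not (isinstance(self.epoch_length, (int, np.integer)) and self.epoch_length >= 1):
            raise ValueError("epoch_length must be a positive integer (minutes)")
        self.epoch_length = int(self.epoch_length)
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")
        if self.start_time.second or self.start_time.microsecond:
            raise ValueError("start_time must be aligned to a whole minute")

    # ---- derived coordinates -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.counts.size)

    def __len__(self) -> int:
        return self.n

    @property
    def abs_minutes(self) -> np.ndarray:
        """Minutes of each epoch start since midnight of the first day."""
        off0 = self.start_time.hour * 60 + self.start_time.minute
        return off0 + np.arange(self.n, dtype=np.int64) * self.epoch_length

    @property
    def minute_of_day(self) -> np.ndarray:
        return self.abs_minutes % MINUTES_PER_DAY

    @property
    def day_index(self) -> np.ndarray:
        return self.abs_minutes // MINUTES_PER_DAY

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            start=self.start_time, periods=self.n, freq=f"{self.epoch_length}min"
        )

    def is_daytime(self) -> np.ndarray:
        """Boolean mask: epoch start falls in [lights_on, lights_off)."""
        on = _minute_of(self.lights_on)
        off = _minute_of(self.lights_off)
        mod = self.minute_of_day
        if on < off:
            return (mod >= on) & (mod < off)
        return (mod >= on) | (mod < off)

    def complete_days(self) -> np.ndarray:
        """Indices of calendar days (0-based from start date) fully covered."""
        if MINUTES_PER_DAY % self.epoch_length != 0:
            raise ValueError("epoch_length must divide 1440 for day-based operations")
        per_day = MINUTES_PER_DAY // self.epoch_length
        days, counts = np.unique(self.day_index, return_counts=True)
        return days[counts == per_day]

    def day_slice(self, day: int) -> "EpochSeries":
        """Sub-series covering calendar day ``day`` (must be complete)."""
        idx = np.nonzero(self.day_index == day)[0]
        if idx.size == 0:
            raise ValueError(f"no epochs on day {day}")
        i0, i1 = int(idx[0]), int(idx[-1]) + 1
        start = self.start_time + timedelta(minutes=i0 * self.epoch_length)
        return EpochSeries(
            self.subject_id, start, self.counts[i0:i1], self.epoch_length,
            self.lights_on, self.lights_off,
        )


@dataclass
class SeriesView:
    """Index-based view into an :class:`EpochSeries` (e.g. the daytime part)."""

    parent: EpochSeries
    indices: np.ndarray

    @property
    def counts(self) -> np.ndarray:
        return self.parent.counts[self.indices]

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    sex: str
    age_weeks: float
    weight_g: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.age_weeks > 0:
            raise ValueError("age_weeks must be positive")
        if not self.weight_g > 0:
            raise ValueError("weight_g must be positive")


@dataclass
class CortisolRecord:
    """Salivary cortisol samples (ug/dL) for one subject; mean is derived."""

    subject_id: str
    samples: list  # list of (label, value)
    subject_mean: float = field(init=False)

    def __post_init__(self):
        if not self.samples:
            raise ValueError("at least one cortisol sample required")
        vals = np.asarray([v for _, v in self.samples], dtype=float)
        if (vals < 0).any():
            raise ValueError("cortisol values must be non-negative")
        self.subject_mean = float(vals.mean())


@dataclass
class SummaryStats:
    """Descriptive statistics of epoch counts on a stated subset.

    ``kurtosis`` is excess kurtosis (normal distribution = 0), bias-corrected;
    ``sd``/``skewness`` use the sample (ddof=1) conventions.  ``degenerate`` is
    set when sd == 0, in which case skewness/kurtosis are NaN.
    """

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    includes_nocturnal: bool
    degenerate: bool = False
    kurtosis_convention: str = "excess"


@dataclass
class HourlyProfile:
    """Mean activity total per clock hour (T0..T23), averaged over days."""

    subject_id: str
    per_hour_mean: np.ndarray

    def __post_init__(self):
        self.per_hour_mean = np.asarray(self.per_hour_mean, dtype=float)
        if self.per_hour_mean.shape != (24,):
            raise ValueError("per_hour_mean must have exactly 24 entries")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.per_hour_mean) < 0:
                raise ValueError("hourly means must be non-negative")

    @property
    def overall_mean(self) -> float:
        return float(np.nanmean(self.per_hour_mean))


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_epoch_csv(
    path,
    epoch_length: int = 1,
    subject_id: str | None = None,
    lights_on: time = time(7, 0),
    lights_off: time = time(19, 0),
) -> EpochSeries:
    """Read a ``timestamp,count`` CSV into an :class:`EpochSeries`.

    Timestamps must be ISO-8601 and strictly increasing at exactly
    ``epoch_length`` minutes; gaps are an error, never silently filled.
    Row numbers in error messages are 1-based file lines (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["timestamp", "count"]:
        raise ParseError(f"{path}: expected columns 'timestamp,count', got {list(df.columns)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(np.argmax(ts.isna().to_numpy())) + 2
        raise ParseError(f"{path}: unparseable timestamp at line {row}")
    cnt = pd.to_numeric(df["count"], errors="coerce")
    if cnt.isna().any():
        row = int(np.argmax(cnt.isna().to_numpy())) + 2
        raise ParseError(f"{path}: unparseable count at line {row}")
    vals = cnt.to_numpy()
    if not np.array_equal(vals, np.floor(vals)):
        row = int(np.argmax(vals != np.floor(vals))) + 2
        raise ParseError(f"{path}: non-integer count at line {row}")
    if (vals < 0).any():
        row = int(np.argmax(vals < 0)) + 2
        raise ValueError(f"{path}: negative count at line {row}")
    tsv = ts.to_numpy()
    if len(tsv) > 1:
        deltas = np.diff(tsv) / np.timedelta64(60, "s")
        bad = deltas != epoch_length
        if bad.any():
            row = int(np.argmax(bad)) + 3  # line of the second row in the bad pair
            raise SpacingError(
                f"{path}: expected {epoch_length}-minute spacing, violated at line {row}"
            )
    start = ts.iloc[0].to_pydatetime()
    return EpochSeries(
        subject_id=subject_id or path.stem,
        start_time=start,
        counts=vals.astype(np.int64),
        epoch_length=epoch_length,
        lights_on=lights_on,
        lights_off=lights_off,
    )


def write_epoch_csv(series: EpochSeries, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stamps = series.timestamps().strftime("%Y-%m-%dT%H:%M:%S")
    pd.DataFrame({"timestamp": stamps, "count": series.counts}).to_csv(path, index=False)


def read_subjects_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    req = ["animal_id", "group", "sex", "age_weeks", "weight_g"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return [
        SubjectRecord(str(r.animal_id), str(r.group), str(r.sex),
                      float(r.age_weeks), float(r.weight_g))
        for r in df.itertuples()
    ]


def write_subjects_csv(subjects: list[SubjectRecord], path) -> None:
    pd.DataFrame(
        [
            {"animal_id": s.subject_id, "group": s.group, "sex": s.sex,
             "age_weeks": s.age_weeks, "weight_g": s.weight_g}
            for s in subjects
        ]
    ).to_csv(path, index=False)


def read_cortisol_csv(path) -> list[CortisolRecord]:
    df = pd.read_csv(path)
    req = ["animal_id", "label", "value_ugdl"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out = []
    for sid, grp in df.groupby("animal_id", sort=False):
        out.append(CortisolRecord(str(sid), list(zip(grp["label"].astype(str), grp["value_ugdl"].astype(float)))))
    return out


def write_cortisol_csv(records: list[CortisolRecord], path) -> None:
    rows = [
        {"animal_id": r.subject_id, "label": lab, "value_ugdl": val}
        for r in records
        for lab, val in r.samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Partitioning and descriptive statistics
# ---------------------------------------------------------------------------

def split_day_night(series: EpochSeries) -> tuple[SeriesView, SeriesView]:
    """Partition into the lights-on view and its complement.

    The two views are disjoint and together cover every epoch.
    """
    day_mask = series.is_daytime()
    idx = np.arange(series.n)
    return SeriesView(series, idx[day_mask]), SeriesView(series, idx[~day_mask])


def summary_stats(series: EpochSeries, include_nocturnal: bool = True) -> SummaryStats:
    """Mean / sample SD / sample skewness / excess kurtosis of the counts.

    With ``include_nocturnal=False`` only lights-on epochs enter.
    """
    if include_nocturnal:
        values = series.counts
    else:
        values = split_day_night(series)[0].counts
    if values.size == 0:
        raise ValueError("selected subset is empty")
    if values.size < 2:
        raise ValueError("at least 2 epochs required for sd")
    x = values.astype(float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return SummaryStats(mean, 0.0, float("nan"), float("nan"),
                            include_nocturnal, degenerate=True)
    skew = float(_sps.skew(x, bias=False))
    kurt = float(_sps.kurtosis(x, fisher=True, bias=False))
    return SummaryStats(mean, sd, skew, kurt, include_nocturnal)


def hourly_profile(series: EpochSeries, complete_days_only: bool = True) -> HourlyProfile:
    """Per-clock-hour mean of the per-day hourly activity totals.

    By default only complete calendar days contribute (avoids edge bias from
    partial first/last days).  With ``complete_days_only=False`` every fully
    covered hour occurrence contributes instead.  Hours with no data are NaN.
    """
    L = series.epoch_length
    if 60 % L != 0:
        raise ValueError("epoch_length must divide 60 for hourly profiles")
    per_hour = 60 // L
    abs_hour = series.abs_minutes // 60
    totals: dict[int, list[float]] = {h: [] for h in range(24)}
    if complete_days_only:
        days = set(series.complete_days().tolist())
        if not days:
            raise ValueError("no complete day in series")
        keep = np.isin(series.day_index, list(days))
    else:
        occ, occ_counts = np.unique(abs_hour, return_counts=True)
        complete_occ = set(occ[occ_counts == per_hour].tolist())
        if not complete_occ:
            raise ValueError("no complete hour in series")
        keep = np.isin(abs_hour, list(complete_occ))
    kept_hours = abs_hour[keep]
    kept_counts = series.counts[keep]
    for h in np.unique(kept_hours):
        total = kept_counts[kept_hours == h].sum()
        totals[int(h) % 24].append(float(total))
    means = np.array(
        [np.mean(totals[h]) if totals[h] else np.nan for h in range(24)], dtype=float
    )
    return HourlyProfile(series.subject_id, means)


def daily_totals(series: EpochSeries) -> np.ndarray:
    """Total counts for each complete calendar day, in day order."""
    days = series.complete_days()
    if days.size == 0:
        raise ValueError("no complete day in series")
    di = series.day_index
    return np.array([series.counts[di == d].sum() for d in days], dtype=float)


def mean_daily_activity(series: EpochSeries, per: str = "epoch") -> float:
    """Average daily activity over complete days.

    ``per='epoch'`` (default) returns the mean per-epoch count; ``per='total'``
    returns the mean per-day total.  The default keeps the value on the same
    scale as the whole-series mean.
    """
    totals = daily_totals(series)
    if per == "total":
        return float(totals.mean())
    if per == "epoch":
        per_day = MINUTES_PER_DAY // series.epoch_length
        return float(totals.mean() / per_day)
    raise ValueError("per must be 'epoch' or 'total'")
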