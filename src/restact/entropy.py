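"""Sample Entropy of z-normalised daytime activity.

SampEn(m, r) = -ln(A/B) where B counts ordered template pairs (i != j) of
length m whose Chebyshev distance is <= r, and A the same for length m + 1.
Both counts use the N - m templates of the Richman-Moorman convention so the
ratio is a proper conditional probability; self-matches are excluded.  The
tolerance r is in SD units, i.e. exactly r after z-scoring.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import EpochSeries, split_day_night

_BLOCK = 512  # row-block size for the pairwise distance computation


@dataclass
class EntropyConfig:
    m: int = 2
    r: float = 0.2
    normalize: bool = True

    def __post_init__(self):
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError("m must be an integer >= 1")
        if not self.r > 0:
            raise ValueError("r must be positive")


@dataclass
class EntropyResult:
    per_day_values: list
    mean_sampen: float
    n_days: int
    config: EntropyConfig
    n_undefined: int = 0


def zscore(x) -> np.ndarray:
    """(x - mean) / sample SD (ddof=1).  Constant input is an error."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sequence has no z-score (zero variance)")
    return (x - x.mean()) / sd


def _pair_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Ordered-pair match counts (A, B) for template lengths m+1 and m."""
    n = x.size
    nt = n - m
    B = 0
    A = 0
    for s in range(0, nt, _BLOCK):
        e = min(s + _BLOCK, nt)
        D = np.abs(x[s:e, None] - x[None, :nt])
        for k in range(1, m):
            np.maximum(D, np.abs(x[s + k:e + k, None] - x[None, k:k + nt]), out=D)
        B += int((D <= r).sum()) - (e - s)  # subtract self-matches
        np.maximum(D, np.abs(x[s + m:e + m, None] - x[None, m:m + nt]), out=D)
        A += int((D <= r).sum()) - (e - s)
    return A, B


def sample_entropy(x, config: EntropyConfig | None = None) -> float:
    """SampEn of a sequence; NaN (undefined) when no matches exist."""
    cfg = config or EntropyConfig()
    x = np.asarray(x, dtype=float)
    if x.size < cfg.m + 2:
        raise ValueError(f"need at least m + 2 = {cfg.m + 2} points")
    if cfg.normalize:
        x = zscore(x)
    A, B = _pair_counts(x, cfg.m, cfg.r)
    if A == 0 or B == 0:
        return math.nan
    return -math.log(A / B)


def daytime_sampen(series: EpochSeries, config: EntropyConfig | None = None,
                   scope: str = "per-day") -> EntropyResult:
    """SampEn of the z-normalised daytime counts.

    ``scope='per-day'`` (default): one value per complete daytime segment
    (lights_on to lights_off), averaged over days where it is defined.
    ``scope='concatenated'``: all daytime epochs joined into one sequence.
    Days with constant counts (z-score undefined) or without matches are
    excluded from the mean and counted in ``n_undefined``.
    """
    cfg = config or EntropyConfig()
    on = series.lights_on.hour * 60 + series.lights_on.minute
    off = series.lights_off.hour * 60 + series.lights_off.minute
    seg_len = ((off - on) % 1440) // series.epoch_length
    day_mask = series.is_daytime()
    di = series.day_index

    segments = []
    for d in np.unique(di):
        sel = (di == d) & day_mask
        if int(sel.sum()) == seg_len and seg_len >= cfg.m + 2:
            segments.append(series.counts[sel].astype(float))
    if not segments:
        raise ValueError("no complete daytime segment of sufficient length")

    if scope == "concatenated":
        seq = np.concatenate(segments)
        try:
            val = sample_entropy(seq, cfg)
        except ValueError:
            val = math.nan
        undefined = int(math.isnan(val))
        mean = val if not undefined else math.nan
        return EntropyResult([val], mean, 1 - undefined, cfg, undefined)
    if scope != "per-day":
        raise ValueError("scope must be 'per-day' or 'concatenated'")

    values = []
    for seg in segments:
        try:
            values.append(sample_entropy(seg, cfg))
        except ValueError:  # constant daytime segment
            values.append(math.nan)
    arr = np.asarray(values, dtype=float)
    defined = arr[~np.isnan(arr)]
    if defined.size == 0:
        raise ValueError("sample entropy undefined on every day")
    return EntropyResult(values, float(defined.mean()), int(defined.size),
                         cfg, int(arr.size - defined.size))
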