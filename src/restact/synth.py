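"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Each subject is an alternating rest/active renewal process on a 1-minute grid:
rest-bout durations follow a truncated discrete power law (survival exponent
``rest_gamma``), active-bout durations a stretched-exponential (Weibull) law
with (``active_alpha``, ``active_beta``).  Counts inside active bouts are
negative-binomial with a mean tracking a double-cosinor envelope (clipped at
zero and rescaled by the analytic duty cycle so the unconditional expectation
equals the envelope); rest epochs carry small Poisson noise well below the
eventual threshold.  Night epochs are binomially thinned by
``night_suppression``.  Cortisol is linearly coupled to each subject's mean
hourly activity, with the noise SD optionally calibrated to hit a target
population correlation.  One RNG stream per subject, derived from
``(seed, subject_seed)``, keeps cohorts extensible without perturbing
existing subjects.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from datetime import datetime

import numpy as np

from .io import MINUTES_PER_DAY, CortisolRecord, EpochSeries, SubjectRecord
from .stats import ThreeChamberTrial

_START = datetime(2024, 1, 1, 7, 0)  # lights-on of day 0


@dataclass
class CosinorTruth:
    """Per-minute generative envelope parameters for one group."""

    mesor: float
    amp24: float
    acro24: float
    amp12: float
    acro12: float


def _default_truth():
    return {
        "UE": CosinorTruth(160.0, 120.0, 2.86, 50.0, 3.04),
        "VPA": CosinorTruth(200.0, 140.0, 2.88, 70.0, 2.84),
    }


def _default_gamma():
    return {"UE": 1.10, "VPA": 1.38}


@dataclass
class SynthConfig:
    n_subjects_per_group: int = 5
    n_days: int = 22
    epoch_length: int = 1
    cosinor_truth: dict = field(default_factory=_default_truth)
    rest_gamma: dict = field(default_factory=_default_gamma)
    rest_min: int = 2
    rest_max: int = 480
    active_alpha: float = 0.86
    active_beta: float = 0.60
    count_intensity: float = 1.0
    night_suppression: float = 0.2
    count_dispersion: float = 20.0
    rest_mean_count: float = 1.0
    cortisol_intercept: float = 3.0
    cortisol_slope: float = 0.0005
    cortisol_noise_sd: float = 1.0
    cortisol_target_r: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.epoch_length != 1:
            raise ValueError("generation is defined on the 1-minute grid only")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2 (at least one complete day)")
        if not (1 <= self.rest_min <= self.rest_max):
            raise ValueError("need 1 <= rest_min <= rest_max")
        if not (0.0 <= self.night_suppression <= 1.0):
            raise ValueError("night_suppression must be in [0, 1]")
        if any(g <= 0 for g in self.rest_gamma.values()):
            raise ValueError("rest_gamma must be positive")
        if self.active_alpha <= 0 or self.active_beta <= 0:
            raise ValueError("active_alpha and active_beta must be positive")
        if self.count_dispersion <= 0 or self.rest_mean_count < 0:
            raise ValueError("invalid count-noise parameters")
        for g in self.rest_gamma:
            if g not in self.cosinor_truth:
                raise ValueError(f"missing cosinor truth for group {g}")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "cosinor_truth" in d:
            d["cosinor_truth"] = {
                g: v if isinstance(v, CosinorTruth) else CosinorTruth(**v)
                for g, v in d["cosinor_truth"].items()
            }
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    series: list
    subjects: list
    cortisol: list


# ---------------------------------------------------------------------------
# Duration samplers (also used directly by recovery tests)
# ---------------------------------------------------------------------------

def sample_truncated_pareto(rng, gamma: float, lo: float, hi: float, size) -> np.ndarray:
    """Continuous samples with survival P(X >= a) proportional to
    a**-gamma - hi**-gamma on [lo, hi]."""
    u = rng.random(size)
    lo_g, hi_g = lo ** -gamma, hi ** -gamma
    return (lo_g - u * (lo_g - hi_g)) ** (-1.0 / gamma)


def sample_rest_durations(rng, gamma: float, lo: int, hi: int, size) -> np.ndarray:
    """Whole-minute rest durations with an exact integer power-law survival.

    Flooring a continuous truncated Pareto drawn on [lo, hi + 1) gives
    P(X >= a) proportional to a**-gamma - (hi+1)**-gamma at every integer a,
    so log-log fits recover gamma without rounding bias.
    """
    return np.floor(sample_truncated_pareto(rng, gamma, lo, hi + 1, size)).astype(np.int64)


def sample_active_durations(rng, alpha: float, beta: float, size) -> np.ndarray:
    """Whole-minute active durations from P(X >= a) = exp(-alpha * a**beta)."""
    w = rng.weibull(beta, size) * alpha ** (-1.0 / beta)
    return np.maximum(1, np.rint(w)).astype(np.int64)


def mean_rest_duration(gamma: float, lo: int, hi: int) -> float:
    a = np.arange(lo, hi + 1, dtype=float)
    B = (hi + 1.0) ** -gamma
    S = (a ** -gamma - B) / (lo ** -gamma - B)
    return float(lo - 1 + S.sum())


def mean_active_duration(alpha: float, beta: float) -> float:
    cap = int(min(max((35.0 / alpha) ** (1.0 / beta), 1000), 2_000_000))
    a = np.arange(1, cap + 1, dtype=float)
    S = np.exp(-alpha * np.maximum(a - 0.5, 0.0) ** beta)
    S[0] = 1.0
    return float(S.sum())


# ---------------------------------------------------------------------------
# Subject / cohort generation
# ---------------------------------------------------------------------------

def _envelope(truth: CosinorTruth, t: np.ndarray) -> np.ndarray:
    w24 = 2 * math.pi / MINUTES_PER_DAY
    w12 = 2 * math.pi / (MINUTES_PER_DAY // 2)
    env = (truth.mesor
           + truth.amp24 * np.cos(w24 * t + truth.acro24)
           + truth.amp12 * np.cos(w12 * t + truth.acro12))
    return np.clip(env, 0.0, None)


def generate_subject(config: SynthConfig, group: str, subject_seed: int) -> EpochSeries:
    """One subject's minute-epoch series; bit-identical under (seed, subject_seed)."""
    if group not in config.rest_gamma:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng([config.seed, subject_seed])
    truth = config.cosinor_truth[group]
    gamma = config.rest_gamma[group]
    n_min = config.n_days * MINUTES_PER_DAY

    mr = mean_rest_duration(gamma, config.rest_min, config.rest_max)
    ma = mean_active_duration(config.active_alpha, config.active_beta)
    rho = ma / (ma + mr)  # stationary duty cycle of the renewal alternation

    need = int(n_min / (mr + ma) * 1.3) + 32
    while True:
        rests = sample_rest_durations(rng, gamma, config.rest_min, config.rest_max, need)
        acts = sample_active_durations(rng, config.active_alpha, config.active_beta, need)
        if int(rests.sum() + acts.sum()) >= n_min:
            break
        need *= 2
    lengths = np.empty(2 * need, dtype=np.int64)
    lengths[0::2] = rests
    lengths[1::2] = acts
    states = np.zeros(2 * need, dtype=bool)
    states[1::2] = True
    active = np.repeat(states, lengths)[:n_min]

    t = (7 * 60) + np.arange(n_min, dtype=np.int64)  # minutes from midnight of day 0
    env = _envelope(truth, t) * config.count_intensity
    mu_active = np.maximum((env - (1 - rho) * config.rest_mean_count) / rho, 1e-9)

    counts = np.zeros(n_min, dtype=np.int64)
    k = config.count_dispersion
    mu = mu_active[active]
    counts[active] = rng.negative_binomial(k, k / (k + mu))
    n_rest = int((~active).sum())
    if config.rest_mean_count > 0:
        counts[~active] = rng.poisson(config.rest_mean_count, n_rest)

    mod = t % MINUTES_PER_DAY
    night = ~((mod >= 7 * 60) & (mod < 19 * 60))
    if config.night_suppression < 1.0:
        counts[night] = rng.binomial(counts[night], config.night_suppression)

    return EpochSeries(f"{group}-{subject_seed:04d}", _START, counts, 1)


def calibrate_noise_sd(x, slope: float, target_r: float) -> float:
    """Noise SD so that cortisol = a + slope*x + noise has population
    correlation ``target_r`` given the empirical spread of x."""
    if not 0 < abs(target_r) < 1:
        raise ValueError("target_r must be in (0, 1) in magnitude")
    sd_x = float(np.std(np.asarray(x, dtype=float), ddof=1))
    return abs(slope) * sd_x * math.sqrt(1.0 / target_r ** 2 - 1.0)


def attach_cortisol(x, intercept: float, slope: float, noise_sd: float, rng,
                    n_samples: int = 3) -> list:
    """Cortisol records linearly coupled to activity summaries ``x``.

    Each subject gets ``n_samples`` collections whose mean has SD exactly
    ``noise_sd`` around the linear predictor (values clipped at 0).
    """
    x = np.asarray(x, dtype=float)
    out = []
    for i, xi in enumerate(x):
        base = intercept + slope * xi
        samples = base + rng.normal(0.0, noise_sd * math.sqrt(n_samples), n_samples)
        samples = np.clip(samples, 0.0, None)
        out.append([(f"m{j + 1}", float(v)) for j, v in enumerate(samples)])
    return out


def generate_cohort(config: SynthConfig) -> Cohort:
    """Full cohort: epoch series, metadata and coupled cortisol records."""
    from .io import hourly_profile  # deferred to avoid import-time cost

    series, subjects = [], []
    for gi, group in enumerate(sorted(config.rest_gamma)):
        for i in range(config.n_subjects_per_group):
            sseed = gi * 1000 + i
            s = generate_subject(config, group, sseed)
            meta_rng = np.random.default_rng([config.seed, 777_000 + sseed])
            subjects.append(SubjectRecord(
                s.subject_id, group, "M",
                age_weeks=float(meta_rng.integers(104, 253)),
                weight_g=float(np.round(meta_rng.uniform(350, 550), 1)),
            ))
            series.append(s)

    x = np.array([hourly_profile(s).overall_mean for s in series])
    noise_sd = config.cortisol_noise_sd
    if config.cortisol_target_r is not None:
        noise_sd = calibrate_noise_sd(x, config.cortisol_slope, config.cortisol_target_r)
    crng = np.random.default_rng([config.seed, 888_001])
    sample_sets = attach_cortisol(x, config.cortisol_intercept, config.cortisol_slope,
                                  noise_sd, crng)
    cortisol = [CortisolRecord(s.subject_id, samples)
                for s, samples in zip(series, sample_sets)]
    return Cohort(series, subjects, cortisol)


# ---------------------------------------------------------------------------
# Three-chamber trials
# ---------------------------------------------------------------------------

def _default_preference():
    return {"UE": (0.55, 0.20, 0.25), "VPA": (0.34, 0.33, 0.33)}


def _default_transition_rate():
    return {"UE": 40.0, "VPA": 60.0}


def generate_three_chamber(n_per_group: int, n_trials: int = 5,
                           preference_truth: dict | None = None,
                           transition_rate: dict | None = None,
                           seed: int = 0,
                           concentration: float = 200.0,
                           trial_concentration: float = 300.0,
                           transition_coupling: float = 0.0) -> list:
    """Three-chamber trials with Dirichlet dwell noise around group propensities.

    ``concentration`` controls subject-level spread, ``trial_concentration``
    trial-level spread (``math.inf`` for either means no noise at that level).
    ``transition_coupling`` < 0 makes high-stranger-propensity subjects
    transition less, producing a negative transitions-vs-stranger correlation.
    """
    prefs = preference_truth or _default_preference()
    rates = transition_rate or _default_transition_rate()
    for g, p in prefs.items():
        if not math.isclose(sum(p), 1.0, abs_tol=1e-9):
            raise ValueError(f"propensities for {g} must sum to 1")
    trials = []
    for gi, group in enumerate(sorted(prefs)):
        props = np.asarray(prefs[group], dtype=float)
        for i in range(n_per_group):
            rng = np.random.default_rng([seed, 555_000 + gi * 1000 + i])
            if math.isinf(concentration):
                subj = props.copy()
            else:
                subj = rng.dirichlet(concentration * props)
            rel = subj[0] / props[0] - 1.0
            rate = rates[group] * math.exp(transition_coupling * rel)
            sid = f"{group}-J{i:02d}"
            for trial in range(1, n_trials + 1):
                if math.isinf(trial_concentration):
                    dwell = subj * 100.0
                else:
                    dwell = rng.dirichlet(trial_concentration * subj) * 100.0
                trials.append(ThreeChamberTrial(
                    sid, trial,
                    pct_stranger=float(dwell[0]),
                    pct_empty=float(dwell[1]),
                    pct_center=float(dwell[2]),
                    transitions=int(rng.poisson(rate)),
                ))
    return trials
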