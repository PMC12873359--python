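"""End-to-end orchestration: synthesize or ingest, analyse, summarise, report.

`analyze_subject` computes the full per-subject parameter row (basic
statistics with and without the nocturnal subset, single/double cosinor
summaries, bout-distribution fits, daytime sample entropy).  `run_pipeline`
applies it to a cohort, writes per-subject and group-level CSV tables plus a
correlations table and a machine-readable JSON manifest; identical config and
seed produce byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bouts import (DEFAULT_ACTIVE_RANGE, DEFAULT_REST_RANGE, compute_threshold,
                    extract_bouts, fit_active_stretched_exp, fit_rest_powerlaw,
                    survival_curve)
from .cosinor import cosinor_summary
from .entropy import EntropyConfig, daytime_sampen
from .io import (EpochSeries, hourly_profile, mean_daily_activity, read_cortisol_csv,
                 read_epoch_csv, read_subjects_csv, split_day_night, summary_stats,
                 write_cortisol_csv, write_epoch_csv, write_subjects_csv)
from .stats import group_hour_anova, pearson_with_F, two_sample_t
from .synth import SynthConfig, generate_cohort

logger = logging.getLogger(__name__)

#: per-subject columns mirroring the published group-comparison table
TABLE_PARAMETERS = [
    "mean_all", "sd_all", "skewness_all", "kurtosis_all",
    "mean_day", "sd_day", "skewness_day", "kurtosis_day",
    "single_mesor", "single_amp24", "single_acro24",
    "mesor", "amp24", "acro24", "amp12", "acro12",
    "gamma", "alpha", "beta", "sampen",
]


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and subject id."""


@dataclass
class RunConfig:
    input_mode: str = "synthetic"          # "synthetic" | "csv_dir"
    synth: SynthConfig = field(default_factory=SynthConfig)
    csv_dir: str | None = None
    cosinor_components: str = "double"
    cosinor_per_day: bool = True
    rest_range: tuple = DEFAULT_REST_RANGE
    active_range: tuple = DEFAULT_ACTIVE_RANGE
    threshold_mode: str = "overall"
    boundary_policy: str = "drop_censored"
    entropy_m: int = 2
    entropy_r: float = 0.2
    entropy_scope: str = "per-day"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.input_mode not in ("synthetic", "csv_dir"):
            raise ValueError("input_mode must be 'synthetic' or 'csv_dir'")
        if self.input_mode == "csv_dir" and not self.csv_dir:
            raise ValueError("csv_dir required when input_mode='csv_dir'")
        self.rest_range = tuple(self.rest_range)
        self.active_range = tuple(self.active_range)
        # a single run seed fans out into the synthetic substreams
        self.synth.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw:
            raw["synth"] = SynthConfig.from_dict(raw["synth"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rest_range"] = list(self.rest_range)
        d["active_range"] = list(self.active_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def analyze_subject(series: EpochSeries, *, components: str = "double",
                    rest_range=DEFAULT_REST_RANGE, active_range=DEFAULT_ACTIVE_RANGE,
                    threshold_mode: str = "overall",
                    boundary_policy: str = "drop_censored",
                    entropy_config: EntropyConfig | None = None,
                    entropy_scope: str = "per-day") -> dict:
    """Compute the full parameter row for one subject."""
    row: dict = {"subject_id": series.subject_id, "n_epochs": series.n}

    st_all = summary_stats(series, include_nocturnal=True)
    st_day = summary_stats(series, include_nocturnal=False)
    row.update(mean_all=st_all.mean, sd_all=st_all.sd, skewness_all=st_all.skewness,
               kurtosis_all=st_all.kurtosis, mean_day=st_day.mean, sd_day=st_day.sd,
               skewness_day=st_day.skewness, kurtosis_day=st_day.kurtosis)
    row["mean_daily_activity"] = mean_daily_activity(series)
    night = split_day_night(series)[1]
    row["mean_night"] = float(night.counts.mean()) if len(night) else float("nan")
    hp = hourly_profile(series)
    row["mean_hourly"] = hp.overall_mean

    single = cosinor_summary(series, "single")
    row.update(single_mesor=single.mean_mesor, single_amp24=single.mean_amp24,
               single_acro24=single.mean_acro24)
    if components == "double":
        double = cosinor_summary(series, "double")
        row.update(mesor=double.mean_mesor, amp24=double.mean_amp24,
                   acro24=double.mean_acro24, amp12=double.mean_amp12,
                   acro12=double.mean_acro12)
    else:
        row.update(mesor=single.mean_mesor, amp24=single.mean_amp24,
                   acro24=single.mean_acro24, amp12=float("nan"),
                   acro12=float("nan"))

    thr = compute_threshold(series, mode="per_day" if threshold_mode == "per-day" else "overall")
    row["threshold"] = float(np.mean(thr))
    seq = extract_bouts(series, thr, boundary_policy)
    rest_fit = fit_rest_powerlaw(survival_curve(seq.rest_durations), rest_range)
    act_fit = fit_active_stretched_exp(survival_curve(seq.active_durations), active_range)
    row.update(gamma=rest_fit.gamma, rest_prefactor=rest_fit.prefactor_A,
               rest_r2=rest_fit.r_squared, alpha=act_fit.alpha, beta=act_fit.beta,
               active_r2=act_fit.r_squared)

    ent = daytime_sampen(series, entropy_config or EntropyConfig(), scope=entropy_scope)
    row.update(sampen=ent.mean_sampen, sampen_n_days=ent.n_days,
               sampen_n_undefined=ent.n_undefined)
    return row


def analyze_cohort(series_list, config: RunConfig) -> pd.DataFrame:
    """Per-subject parameter table; failures abort naming stage and subject."""
    rows = []
    for s in series_list:
        try:
            rows.append(analyze_subject(
                s, components=config.cosinor_components,
                rest_range=config.rest_range, active_range=config.active_range,
                threshold_mode=config.threshold_mode,
                boundary_policy=config.boundary_policy,
                entropy_config=EntropyConfig(config.entropy_m, config.entropy_r),
                entropy_scope=config.entropy_scope,
            ))
        except Exception as exc:
            raise PipelineError(
                f"stage 'analyze_subject' failed for subject {s.subject_id}: {exc}"
            ) from exc
    return pd.DataFrame(rows)


def group_summary(per_subject: pd.DataFrame, subjects) -> pd.DataFrame:
    """Per-parameter group means +/- SD and pooled-t p values."""
    gmap = {s.subject_id: s.group for s in subjects}
    df = per_subject.copy()
    df["group"] = df.subject_id.map(gmap)
    rows = []
    for param in TABLE_PARAMETERS:
        a = df.loc[df.group == "UE", param].dropna()
        b = df.loc[df.group == "VPA", param].dropna()
        row = {"parameter": param,
               "UE_mean": a.mean(), "UE_sd": a.std(ddof=1),
               "VPA_mean": b.mean(), "VPA_sd": b.std(ddof=1)}
        if len(a) >= 2 and len(b) >= 2:
            row["p_value"] = two_sample_t(a, b).p
        else:
            row["p_value"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(per_subject: pd.DataFrame, cortisol) -> pd.DataFrame:
    """Cortisol vs mean hourly activity / sample entropy / rest exponent.

    Subjects without a cortisol record are dropped (mirrors the exclusion of
    untrainable subjects from saliva collection).
    """
    cmap = {c.subject_id: c.subject_mean for c in cortisol}
    df = per_subject[per_subject.subject_id.isin(cmap)].copy()
    df["cortisol"] = df.subject_id.map(cmap)
    rows = []
    for param in ("mean_hourly", "sampen", "gamma"):
        res = pearson_with_F(df["cortisol"], df[param])
        rows.append({"x": "cortisol", "y": param, "r": res.r, "F": res.F,
                     "df1": res.df1, "df2": res.df2, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def _load_csv_dir(root: Path):
    epochs_dir = root / "epochs"
    files = sorted(epochs_dir.glob("*.csv"))
    if not files:
        raise PipelineError(f"stage 'ingest': no epoch CSVs under {epochs_dir}")
    series = []
    for f in files:
        try:
            series.append(read_epoch_csv(f))
        except Exception as exc:
            raise PipelineError(f"stage 'ingest' failed for file {f.name}: {exc}") from exc
    subjects = read_subjects_csv(root / "subjects.csv")
    cort_path = root / "cortisol.csv"
    cortisol = read_cortisol_csv(cort_path) if cort_path.exists() else []
    return series, subjects, cortisol


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_mode == "synthetic":
        cohort = generate_cohort(config.synth)
        series, subjects, cortisol = cohort.series, cohort.subjects, cohort.cortisol
        epochs_dir = out / "epochs"
        for s in series:
            write_epoch_csv(s, epochs_dir / f"{s.subject_id}.csv")
        write_subjects_csv(subjects, out / "subjects.csv")
        write_cortisol_csv(cortisol, out / "cortisol.csv")
    else:
        series, subjects, cortisol = _load_csv_dir(Path(config.csv_dir))

    per_subject = analyze_cohort(series, config)
    per_subject.to_csv(out / "per_subject.csv", index=False)

    summary = group_summary(per_subject, subjects)
    summary.to_csv(out / "group_summary.csv", index=False)

    profiles = pd.DataFrame(
        {s.subject_id: hourly_profile(s).per_hour_mean for s in series}
    ).T
    profiles.columns = [f"T{h}" for h in range(24)]
    profiles.index.name = "subject_id"
    profiles.to_csv(out / "hourly_profiles.csv")

    gmap = {s.subject_id: s.group for s in subjects}
    labels = np.array([gmap[sid] for sid in profiles.index])
    anova_block = None
    counts = pd.Series(labels).value_counts()
    if len(counts) == 2 and counts.nunique() == 1 and counts.iloc[0] >= 2:
        anova = group_hour_anova(labels, profiles.to_numpy())
        anova.posthoc.to_csv(out / "hourly_posthoc.csv", index=False)
        anova_block = {
            eff: {"F": getattr(anova, eff).F, "df": [getattr(anova, eff).df_num,
                                                     getattr(anova, eff).df_den],
                  "p": getattr(anova, eff).p}
            for eff in ("group", "hour", "interaction")
        }

    if cortisol:
        correlation_table(per_subject, cortisol).to_csv(out / "correlations.csv", index=False)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_subjects": len(series),
        "anova": anova_block,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
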