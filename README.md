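# restact

Rest–activity rhythm analysis for minute-epoch actigraphy count data, with a
seeded synthetic-cohort generator so every stage is verifiable by parameter
recovery. The pipeline covers:

- **I/O & descriptives** (`restact.io`) — validated epoch-count series with a
  12:12 light schedule, day/night partitioning, hourly activity profiles,
  basic statistics with/without the nocturnal subset.
- **Cosinor fitting** (`restact.cosinor`) — single (24 h) and double
  (24 h + 12 h) cosinor models on 10-minute aggregates, fitted per calendar
  day and averaged (circular mean for acrophases).
- **Behavioral organization** (`restact.bouts`) — threshold-based rest/active
  bout extraction (threshold = mean of the nonzero counts), empirical survival
  curves, power-law fit of rest durations (exponent γ, default range 3–30 min)
  and stretched-exponential fit of active durations (α, β, default 10–100 min).
- **Complexity** (`restact.entropy`) — Sample Entropy (m = 2, r = 0.2) of
  z-normalised daytime counts, per day with averaging or concatenated.
- **Statistics** (`restact.stats`) — pooled two-tailed t-tests, Pearson r
  reported with its regression F(1, n−2), mixed group×hour ANOVA with
  Bonferroni post hoc, and three-chamber social-preference scoring
  (SPI = (%stranger − %empty)/100, transition counts).
- **Synthetic data** (`restact.synth`) — alternating rest/active renewal
  process (truncated discrete power-law rests, Weibull active bouts),
  negative-binomial counts tracking a double-cosinor envelope, night
  suppression, cortisol linearly coupled to activity with a calibratable
  target correlation, and Dirichlet three-chamber trials.
- **Pipeline** (`restact.pipeline`, `restact.cli`) — end-to-end orchestration
  with per-subject tables, group summaries, correlation tables and a
  reproducibility manifest.

## CLI

```bash
# synthesize a cohort (writes epochs/*.csv, subjects.csv, cortisol.csv, three_chamber.csv)
restact synth --config examples/synth.yaml --seed 1 --out cohort/

# per-subject analyses on a timestamp,count CSV
restact cosinor --input cohort/epochs/UE-0000.csv --components double --out cos.json
restact bouts   --input cohort/epochs/UE-0000.csv --rest-range 3:30 --active-range 10:100 --out bouts.csv
restact entropy --input cohort/epochs/UE-0000.csv --m 2 --r 0.2 --out ent.csv

# full pipeline (synthetic or csv_dir input), reproducible under --seed
restact run --config run.yaml --seed 1 --out report/

# group tables from per-subject outputs
restact stats --per-subject report/per_subject.csv --subjects report/subjects.csv \
              --cortisol report/cortisol.csv --out tables/
```

Epoch CSVs use `timestamp,count` with ISO-8601 timestamps at a fixed spacing;
gaps are rejected, never imputed.

## Conventions worth knowing

- Kurtosis is reported as *excess* kurtosis (normal = 0); SD/skewness use
  sample (ddof = 1) conventions, as does the z-score used before entropy.
- Acrophases are the phase φ of `cos(ωt + φ)` in radians `[0, 2π)`; the peak
  clock time is exposed separately.
- "Average daily activity" defaults to the mean per-epoch count over complete
  days; per-day totals are also available.
- Rest epochs are counts strictly below the threshold; ties count as active.
  Boundary-truncated bouts are dropped by default.
- Undefined values (zero-amplitude acrophase, matchless entropy) propagate as
  NaN markers and are excluded from averages with a logged count.
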