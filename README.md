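# activemon

A reusable analysis pipeline for remote digital monitoring with
smartphone/smartwatch *active tests* in Huntington's disease: synthetic raw
data generation, per-session feature extraction, quality control, 2-week
median aggregation with adherence accounting, and cross-sectional validation
statistics (test–retest reliability, convergent validity, known-groups
validity).

## What it does

Eight active tests are each reduced to one scalar feature per session:

| Test            | Feature                        | Units    |
| --------------- | ------------------------------ | -------- |
| SDMT            | number of correct answers      | count    |
| Stroop word reading | number of correctly read words | count |
| Speeded Tapping | mean intertap (in-air) interval | ms      |
| Draw-A-Shape    | spiral drawing-speed CV        | unitless |
| Chorea, Balance | sway path (Σ‖Δa‖)              | m/s²     |
| U-Turn          | median turn speed              | rad/s    |
| Walking         | step frequency variance        | Hz²      |

Sessions failing quality control (placement in the pocket instead of the
waist pouch for the three ambulatory tests, short recordings, incomplete
spiral traces, too few taps/turns/steps) are excluded. Passing values are
median-aggregated over the two 2-week intervals of a 4-week schedule; an
interval is missing when fewer than n passing observations are available
(n = 1 for the weekly cognitive tests, 3 otherwise). The validation layer
computes ICC(2,1) with F-based confidence bounds between the two interval
medians, Pearson/Spearman correlations against in-clinic scores, and
Kruskal–Wallis plus all pairwise Mann–Whitney U tests on age- and
study-adjusted residuals (mixed linear model with a random study intercept)
across five study/cohort groups.

Because no participant-level study data are public, the `synthetic` module
generates cohorts in which a single latent severity scalar drives both the
in-clinic scores and every sensor signature, giving the downstream
statistics a recoverable ground truth.

## CLI

```bash
# full chain in memory, artifacts to ./activemon_run
activemon all --seed 7 --outdir run7

# or staged, exchanging plain-text artifacts
activemon simulate  --config config.yaml
activemon extract   --config config.yaml
activemon qc        --config config.yaml
activemon aggregate --config config.yaml
activemon validate  --config config.yaml
```

Outputs: `features.csv` (long per-session features with QC status),
`qc_strata.csv` / `exclusions.csv`, `aggregated.csv` (interval medians),
`adherence.json`, `icc.csv`, `convergent.csv`, `known_groups.json`. A run
is reproducible from config + seed alone; see `activemon.config.PipelineConfig`
for every generator, QC, and reporting knob.

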