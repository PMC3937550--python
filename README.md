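# reprotime

Analysis toolkit for duration-reproduction experiments built around a
leaky-integrator ("water clock") model of interval timing.

Two inflow–outflow units, each obeying `dx/dt = inflow − κ·x`, represent an
encoded and a reproduced interval: the first fills during stimulus
presentation (relative inflow η), decays through the pause `w`, and the
reproduction ends when the second unit — filling at unit inflow — catches up
with it. The closed-form response function

```
r = (1/κ) · ln(1 + η · exp(−κw) · (1 − exp(−κs)))
```

predicts the ubiquitous "progressive shortening" of reproductions (`r/s`
decreasing in `s`) via the leak rate κ, while condition-specific effects
(e.g., emotional arousal) live in the inflow ratio η. The closed form is
validated against an independent dynamical oracle (fixed-step RK4 integration
plus root bracketing/bisection) to < 1e-5 s over the parameter grid.

## What's inside

| Module | Purpose |
|---|---|
| `reprotime.model` | Reproduction function, exact η-inversion, numeric integrator, dynamical oracle |
| `reprotime.estimation` | Three-step per-subject fits (κ with η≡1, then η per condition, then ratios η_P/η_E, η_N/η_E) and subject screening |
| `reprotime.indices` | Model-free cell means and aggregate ratio indices a_P, a_N |
| `reprotime.stats` | t-tests, two-way repeated-measures ANOVA with Greenhouse–Geisser correction, Pearson correlation, fixed-bandwidth Gaussian KDE |
| `reprotime.synthetic` | Seeded cohort generator (3 valences × 3 durations × 5 trials, lognormal κ population, injectable anomalous subjects) |
| `reprotime.pipeline` / `reprotime.cli` | Trial-table validation, end-to-end analysis, report bundle, CLI |
| `reprotime.datasets` | Packaged fixtures: stimulus metadata (sub-group valence/arousal ratings) and a reference grand-mean summary table |

## CLI

```bash
# generate a synthetic cohort (trial + truth CSVs)
reprotime simulate --out scratch/sim --seed 9 --n-subjects 31 \
    --eta-pe 1.08 --eta-ne 1.04 --over-reproducers 4 --non-responders 1

# per-subject parameter estimates only
reprotime fit --input scratch/sim/trials.csv --out scratch/fits.csv

# full pipeline: indices, fits, screening, group statistics, report bundle
reprotime analyze --input scratch/sim/trials.csv --out scratch/report --seed 1

# re-render an existing report at display precision
reprotime report --input scratch/report/report.json
```

Trial CSVs use the schema
`subject_id, trial_index, valence (P|N|E), stimulus_id, s_sec, w_sec, r_sec`.
`analyze` accepts a YAML config (`--config`) overriding any default in
`reprotime.pipeline.AnalysisConfig` (screening thresholds, KDE bandwidth,
η-estimation method `lsq` or `invert-mean`, …) and writes `report.json`,
`per_subject.csv`, `kde_curves.csv` and `summary.json`.

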