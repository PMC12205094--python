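# coldtrial

Reusable analysis engine for a single-arm Bayesian adaptive phase-II
trial and its companion translational readouts:

- **`coldtrial.design`** — beta-binomial monitoring: conjugate posterior
  summaries with equal-tailed (or HPD) credible intervals, futility /
  efficacy stopping decisions under both a posterior-probability and a
  predictive-probability reading of the rule, interim schedules, trial
  simulation and operating characteristics.
- **`coldtrial.survival`** — Kaplan–Meier product-limit estimation with
  Greenwood variance, medians and milestone rates with log(−log)
  confidence bands, best-overall-response tallies, duration of response,
  and the growth-modulation index (current-line / prior-line PFS, with
  the conventional ≥ 1.33 benefit threshold).
- **`coldtrial.spatial`** — paired pre-/on-treatment statistics on
  phenotyped cell maps: densities per mm², radius-based colocalization
  (closed ball, default 10 µm), marker-positive fractions, and exact
  paired Wilcoxon signed-rank tests (full enumeration up to 25
  informative pairs).
- **`coldtrial.synth`** — synthetic cohorts (exponential PFS, calibrated
  OS, log-normal prior-line PFS, administrative censoring) and paired
  Poisson / Thomas-process cell maps, so every stage runs without
  external data.
- **`coldtrial.io` / `coldtrial.cli`** — CSV schema readers/writers,
  YAML config, JSON reporting, and the `coldtrial` command-line tool.

## CLI examples

```sh
# posterior summary + interim decision at 4 responders of 43 evaluable
coldtrial design interim --n 43 --responders 4

# operating characteristics over a true-ORR grid
coldtrial design oc --orr 0.05,0.10,0.25 --sims 10000 --seed 1 --out oc.csv

# synthetic data
coldtrial simulate cohort --preset paper --seed 7 --out patients.csv
coldtrial simulate cells --preset paper --seed 7 \
    --out-cells cells.csv --out-samples samples.csv

# analyses
coldtrial analyze survival --patients patients.csv --endpoint pfs --milestones 6,12
coldtrial analyze gmi --patients patients.csv
coldtrial analyze spatial --cells cells.csv --samples samples.csv \
    --radius 10 --phenotypes CD8,CD4,CD20,CD163

# everything in one JSON report
coldtrial report --patients patients.csv --cells cells.csv \
    --samples samples.csv --seed 7 --out report.json
```

## Data schemas

Patient CSV: `patient_id, evaluable_efficacy, bor (CR|PR|SD|PD|NE),
response_onset_months, pfs_months, pfs_event, os_months, os_event,
prior_pfs_months` (missing values empty; months are the canonical unit).

Cells CSV: `sample_id, patient_id, timepoint (baseline|C2D1), x_um,
y_um` plus one 0/1 column per phenotype flag
(`CD8, CD4, CD20, CD163, CD3, PD1, CD23`); a companion samples CSV
carries `area_mm2` per sample.

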