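# ornrbe

Empirical proton RBE estimation for mandible osteoradionecrosis (ORN),
implemented as a tested, end-to-end pipeline:

1. **synthetic cohort** — head-and-neck cohort generator with configurable
   covariate marginals, confounded photon/proton assignment, voxelized
   mandible dose/LET fields, and a logistic outcome mechanism driven by a
   known (configurable) LET-dependent ground-truth RBE;
2. **dosimetry** — cumulative DVHs, exact DVH indices (V40–V75 in cc,
   D0.01cc, Dmean) and joint dose–LET volume histograms with DLx% contours;
3. **matching** — deterministic IRLS propensity model and greedy 1:1
   nearest-neighbor matching without replacement, with balance diagnostics;
4. **inference** — Mann-Whitney / chi-square / Welch tests, ROC curves with
   optimal operating points (closest to TPR 1 / FPR 0), and a stratified
   percentile bootstrap engine;
5. **rbe** — volume tolerance curves (with isotonic repair), equivalent
   constraint doses by piecewise-linear interpolation, and empirical RBE
   (equivalent photon dose over proton physical dose = nominal / 1.1) with
   joint bootstrap confidence intervals;
6. **pipeline / CLI** — orchestration, provenance (seed + config hash) and
   report rendering.

## CLI

```bash
orn-rbe synth --n 1266 --seed 7 --out cohort/          # generate a cohort
orn-rbe dvh   --cohort cohort/ --out indices.csv       # DVH index table
orn-rbe match --cohort cohort/ --out pairs.csv         # propensity matching
orn-rbe derive-dvc --indices indices.csv --reps 1000 --seed 1 --out dvc/
orn-rbe rbe   --indices indices.csv --levels 40,50,60 --reps 1000 --seed 1 --out rbe/
orn-rbe run   --seed 7 --out run/                      # full pipeline
```

Cohorts are plain CSV (a cohort table, a manifest, and one voxel-sample
file per patient). A YAML config mirroring the generator/bootstrap settings
can be passed with `--config`; exit codes are 0 (ok), 1 (validation error),
2 (runtime failure).

`run/report.json` carries the cohort summary, incidence rates, balance and
significance tables, ROC-derived critical volumes with bootstrap CIs, and
the per-dose-level equivalent constraint doses and RBE estimates.

## Notes on the generator

The proton nominal-dose field is, by default, the photon-shaped field
passed through the inverse of the generator's mean biological dose map
(`proton_field: bio_matched`), i.e. both modalities plan toward the same
biological objective. This makes the configured effective RBE recoverable
by the constraint-equivalence analysis and collapses to identical fields
when the LET effect is disabled. An independent parametric proton shape is
available with `proton_field: shape`.
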