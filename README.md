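# vmquant

Quantification of vasculogenic mimicry (VM) from two-channel histology
images, plus the companion expression-cohort statistics: a keratinocyte-
contamination sample filter, expression-range stratification, survival
comparison and a negative-binomial differential-expression test. Ground-
truthed synthetic data generators stand in for patient images and cohort
downloads so the whole pipeline is testable end to end.

## What it does

**Imaging** (`vmquant.vm_imaging`): basement-membrane (PAS-fluorescence)
channels are filtered with a multi-scale Hessian ridge ("tubeness")
detector — per scale σ the response is `σ²·|λ₂|` where the larger-magnitude
Hessian eigenvalue is negative, maximized over scales. The segmented PAS
network, minus the (dilated) endothelial CD31 network, within the detected
tissue extent, gives the VM mask; the VM score is its area as a percent of
tissue. Images are also categorized PAS-neg / PAS-low / PAS-high (low =
under 10 % of area or no branching skeleton component).

**Expression** (`vmquant.expression`): counts-per-million normalization; a
contamination filter removing samples whose keratinocyte markers (IVL,
KRT14, BNC1) are all above 5 CPM or any two above 20 CPM (strict
inequalities); low/mid/high stratification by cut-points a fixed fraction
(default 10 %) into the expression range of one gene (quantile mode
available); an exact conditional NB test with moment-estimated common
dispersion and BH-FDR for high-vs-low differential expression; Mann-Whitney
and Kruskal-Wallis rank comparisons.

**Survival & categorical statistics** (`vmquant.survival`): from-scratch
Kaplan-Meier product-limit curves with medians, Mantel-Haenszel log-rank
test with an observed/expected hazard-ratio estimate, two-sided Fisher's
exact test by enumeration, Benjamini-Hochberg adjustment, and matched-pair
concordance summaries.

**Synthetic data** (`vmquant.synthetic_data`): seeded generators for
branching tubular networks with partially overlapping vessel networks
(exact truth masks and VM fraction) and for NB count cohorts with planted
contaminated samples, a stratification-gene gradient, planted DE genes and
exponential survival with a group-dependent hazard. Also ships small
transcribed fixture tables used by the worked-example checks.

## CLI

All stages are exposed through one entry point (exit codes: 0 ok, 2 input
error, 3 stage failure):

```bash
vmquant simulate-image  --seed 1 --out out/img          # image + truth sidecar
vmquant simulate-cohort --seed 1 --out out/cohort       # counts.tsv, clinical.tsv, truth.json
vmquant vm-score --pas out/img/image.tif --out report.json
vmquant filter-samples --counts counts.tsv --out filter.json
vmquant stratify --counts counts.tsv --gene DSG2 --fraction 0.1 --mode range --out strat.json
vmquant de --counts counts.tsv --groups groups.json --fdr 0.005 --min-fold 2 --out de.csv
vmquant survival --clinical clinical.tsv --groups groups.json --out surv.json
vmquant fisher --table 18,28,6,19
vmquant report --counts counts.tsv --clinical clinical.tsv --out run.json   # full cohort pipeline
vmquant accept                                           # built-in worked-example checks
```

`--config` accepts a flat YAML file (unknown keys are rejected); see
`vmquant.pipeline.PipelineConfig` for the keys and defaults.

## Layout

```
src/vmquant/
  synthetic_data.py   seeded image & cohort generators, fixture tables
  vm_imaging.py       tubeness filter, segmentation, VM scoring
  expression.py       CPM, contamination filter, stratification, DE, rank tests
  survival.py         KM, log-rank, Fisher, BH, concordance
  pipeline.py         config, cohort/image orchestration, acceptance suite
  io.py               TSV / TIFF / PNG / JSON readers and writers
  cli.py              click entry point
tests/                pytest suite incl. test_acceptance.py
scripts/acceptance.py acceptance report
```
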