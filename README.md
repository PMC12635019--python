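# clockaudit

Audit toolkit for linear DNA-methylation (DNAm) age clocks. Given a clock's
coefficient table and a beta-value matrix with sample ages, `clockaudit`
quantifies three failure modes of elastic-net clocks:

- **Coefficient-sign coherence** — the share of clock CpGs (and of total
  absolute model weight) whose coefficient sign opposes the CpG's univariate
  Pearson correlation with age, plus rectification (dropping or
  sign-constraining misaligned features) and the accuracy-vs-separation
  trade-off it induces on healthy-vs-disease residuals.
- **Leukocyte-fraction collinearity** — constrained-least-squares cell-type
  deconvolution over 12 immune cell types, per-CpG Spearman correlations
  with each fraction, and the change in variance inflation factor (VIF) when
  each fraction is added to the per-model CpG regression, binned into
  small/moderate/large/very-large categories.
- **Noise barometer** — per-CpG mean/SD/CV over sliding age windows,
  detection of stable-mean/rising-SD loci, and a continuous piecewise-linear
  fit of the aggregate noise trajectory with free breakpoints.

A fully parameterized synthetic cohort generator (`clockaudit.synthetic`)
produces beta matrices with known ground truth — age-linear CpGs with slope
0.008/year, exactly or noisily collinear CpGs, age-independent fillers,
mixture CpGs driven by a 12-cell-type leukocyte composition with
age-declining naive T cells and a disease myeloid shift, homeostatic CpGs
with a piecewise rising noise SD, and confounded CpG pairs whose shared
nuisance term carries the disease signal — so every audit is testable
against planted parameters without any external download.

## CLI

```sh
clockaudit simulate  --config config.yaml --seed 1 --out cohort/
clockaudit train     --beta cohort/beta.tsv --meta cohort/metadata.tsv \
                     --model en --alpha 0.05 --repeats 5 --out train/
clockaudit audit     --clock clock.tsv --beta cohort/beta.tsv \
                     --meta cohort/metadata.tsv --out audit/
clockaudit cellaudit --clock clock.tsv --beta cohort/beta.tsv \
                     --reference cohort/reference_profiles.tsv --out cell/
clockaudit noise     --beta cohort/beta.tsv --meta cohort/metadata.tsv \
                     --breakpoints 3 --out noise/
clockaudit demo      --config config.yaml --seed 1 --out demo/
```

`demo` runs every stage on one seeded synthetic cohort and writes a
manifest with a content hash per output file; reruns with the same seed and
config are byte-identical. The YAML config is key-per-field (see
`clockaudit.pipeline.DEFAULTS`); a minimal config is just `seed: 1`.

File formats are plain delimited text: clock tables are `cpg,coefficient`
with an optional `(Intercept)` row; beta matrices have sample ids in the
header row and CpG ids in the first column (series-matrix convention, the
transpose is accepted via `orientation`); metadata is
`sample_id,age,status[,disease_name]`.

## Package layout

| module | contents |
| --- | --- |
| `clockaudit.io` | clock tables, beta matrices, metadata, `apply_clock` |
| `clockaudit.synthetic` | cohort specs and the synthetic generator |
| `clockaudit.models` | OLS, coordinate-descent elastic net, split eval |
| `clockaudit.coherence` | sign-coherence audit, rectification, trade-off |
| `clockaudit.cellfractions` | deconvolution, Spearman and VIF audits |
| `clockaudit.noise` | windowed noise metrics and trajectory fitting |
| `clockaudit.pipeline` / `clockaudit.cli` | config, orchestration, CLI |
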