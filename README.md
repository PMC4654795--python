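# methexpress

Integration of DNA methylation and gene expression for a two-group
(fetal vs adult tissue) design, built around Illumina 450K-style beta
values and log2 expression arrays.

Developmental tissue comparisons typically find that *most* CpGs shift
their methylation a little, while only a specific subset — CpGs near
the transcription start site or in the first exon of a gene — carries a
regulatory signal: a fetal-to-adult methylation *decrease* there
predicts adult *overexpression* of the gene. `methexpress` provides the
full analysis chain needed to quantify that pattern, plus a synthetic
data generator with known ground truth so every step can be validated
for calibration and power.

## What it computes

Given a CpG × sample beta matrix **B** (βᵢⱼ ∈ [0,1]), a detection
p-value matrix, a gene × sample log2 expression matrix, a 450K-style
probe annotation and a sample→group design:

1. **Filtering** — keep probes with detection p < 0.05 in all samples;
   drop chrX/chrY probes.
2. **Differential testing** (shared by methylation and expression) —
   per-feature two-group OLS on M-values M = log₂((β+ε)/(1−β+ε)) (or
   log2 expression), then empirical-Bayes variance moderation: the
   per-feature variances s²_g are assumed to follow a scaled-F model
   s²_g ~ s₀²·F(d, d₀); (d₀, s₀²) are estimated by method of moments on
   log s²_g (digamma/trigamma matching) and each feature's variance is
   shrunk to the posterior s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d). The
   moderated t = effect/√(s̃²·leverage) has d + d₀ degrees of freedom.
   Benjamini–Hochberg q-values control the FDR. Effects are reported as
   delta-beta dβ = adult − fetal on the beta scale, and as a signed
   fold change (+r fetal-higher / −r adult-higher, |r| ≥ 1) for
   expression.
3. **Gene-region aggregation** — RefGene labels collapse into TSS/Ex1
   (TSS200, TSS1500, 1stExon) vs UTR/GB (5'UTR, Body, 3'UTR); per-gene
   mean methylation is the unweighted mean over its CpGs.
4. **Integration** — expression classes (q ≤ 0.05 & ≥5-fold
   overexpressed, or "similar": non-significant & <1.1-fold);
   methylation levels hypo [0,0.3) / intermediate [0.3,0.7) / hyper
   [0.7,1]; contingency tables with Pearson chi-square; and the
   prediction probability P(gene q-significantly ≥k-fold overexpressed
   in the opposite direction | CpG has a q-significant dβ beyond ±0.2
   or ±0.5, by region class).
5. **Calibrated enrichment** — hypergeometric over-representation where
   the significance threshold is the minimum p achieved by 5 random
   size-matched control gene sets drawn from similarly expressed genes.

## Worked example

```python
import methexpress as mx
from methexpress.regions import RegionClass

ds = mx.simulate_dataset(mx.SimulationConfig(seed=19))   # 20,000 CpGs, 3v3
beta, _ = mx.filter_detection(ds.beta, ds.detection_p)
beta, _ = mx.filter_sex_chromosomes(beta, ds.annotation)
dm = mx.differential_methylation(beta, ds.design)
de = mx.differential_expression(ds.expression, ds.design)
records = mx.build_integration_records(dm, mx.build_links(ds.annotation), de)
print(mx.prediction_table(records))
```

prints (abridged):

```
direction  dbeta_cut region_class  n_cpgs  p_ge2fold  p_ge5fold
 decrease      0.200      TSS_EX1     373      0.643      0.638
 decrease      0.200       UTR_GB     610      0.048      0.048
 increase      0.200      TSS_EX1     403      0.067      0.067
 increase      0.200       UTR_GB     439      0.046      0.043
```

Read: of the 373 TSS/Ex1 CpGs with a q-significant fetal-to-adult
methylation decrease ≥ 0.2, 64% sit on genes with a q-significant
≥2-fold adult overexpression; gene-body/UTR decreases (4.8%) and
methylation increases in either region (~5–7%) carry almost no signal.
That asymmetry — promoter demethylation predicts induction, promoter
*gain* of methylation predicts nothing — is the analysis' central
readout, and here it matches the generator's built-in coupling.

The `examples/` directory has one short narrative script per
capability (simulation, differential methylation, region hierarchy,
prediction probabilities, calibrated enrichment). The `methexpress`
CLI wraps the same library functions:

```sh
methexpress simulate --n-cpgs 5000 --n-genes 400 --seed 7 --out fix/
methexpress run --beta fix/beta.tsv --detection-p fix/detection_p.tsv \
    --expression fix/expression.tsv --annotation fix/annotation.tsv \
    --design fix/design.tsv --out-dir out/ --seed 7
```

`run` emits every stage's TSV plus `manifest.json` (version, seed,
thresholds, input checksums, per-stage record counts); reruns with the
same config are byte-identical.

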