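# Methods

## Data model

A study is a two-group design (labelled `fetal` and `adult`, ≥2 samples
each; the canonical configuration is 3 vs 3) observed on two platforms:

* **Methylation**: CpG × sample beta values β ∈ [0,1], the proportion
  of methylated signal at a probe; missing entries (`NA`) are excluded
  pairwise. A detection p-value accompanies every entry.
* **Expression**: gene × sample normalized log2 intensities.

Probes map to genes through a 450K-manifest-style annotation whose
RefGene labels (TSS200, TSS1500, 1stExon, 5'UTR, Body, 3'UTR) collapse
into two aggregate classes: **TSS/Ex1** (promoter-proximal: TSS200,
TSS1500, 1stExon) and **UTR/GB** (5'UTR, Body, 3'UTR). A probe carrying
both classes for the same gene counts as TSS/Ex1 — promoter-proximal
membership is what the downstream filters select on, so membership
priority is the natural resolution; the rule is explicit and
configurable. A probe linked to several genes contributes one record
per gene.

## Differential testing

Group comparison is ordinary least squares per feature — on M-values
M = log₂((β+ε)/(1−β+ε)) with offset ε = 10⁻⁶ for methylation (the
logit stabilizes the variance near the β boundaries; effects are still
*reported* on the beta scale as dβ = adult − fetal), on log2
intensities for expression. Numeric covariates in the design table are
supported and absorbed by the per-feature linear model.

Variance moderation follows the hierarchical scaled-F model: if
s²_g | σ²_g ~ σ²_g χ²_d/d and 1/σ²_g ~ χ²_{d₀}/(d₀ s₀²), then
s²_g ~ s₀² F(d, d₀) and

    E[log s²] = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2)
    Var[log s²] = ψ′(d/2) + ψ′(d₀/2)

Method-of-moments on log s²_g therefore gives d₀ by inverting the
trigamma function (Newton iteration) and s₀² from the mean. The
posterior variance (d₀s₀² + d·s²_g)/(d₀+d) replaces s²_g in the
t-statistic, which gains d₀ degrees of freedom. Degenerate cases:

* spread of log variances at or below the χ² sampling floor → d₀ = ∞
  and s₀² is the geometric mean of the variances, so all-equal
  variances return exactly the common variance (we prefer this
  fixed-point behaviour over the bias-corrected moment estimate in the
  zero-spread branch);
* zero-variance features are excluded from the fit and assigned
  posterior s₀²;
* d₀ = 0 (moderation off) reduces exactly to the ordinary pooled
  two-sample t — the test suite enforces this to 1e-10 against an
  independent implementation.

BH q-values use the cumulative-minimum step-up formulation
q_(i) = min_{j≥i} m·p_(j)/j capped at 1, which is tie-safe and
order-preserving; it is tested for exact agreement with the
definitional oracle. q-values are computed within each platform
separately. Expression fold changes are reported signed: +r when the
fetal mean is higher (r = 2^{fetal−adult}), −1/r when adult is higher,
so |fold| ≥ 1 always.

## Integration statistics

* **Expression classes**: overexpressed = q ≤ 0.05 and |fold| ≥ 5 (by
  sign); similar = q > 0.05 and |fold| < 1.1; everything else "other".
  The classes partition all genes.
* **Methylation levels**: hypo [0, 0.3), intermediate [0.3, 0.7),
  hyper [0.7, 1]. The prose convention "0 to 0.3, 0.3 to 0.7, 0.7 to
  1.0" shares endpoints; a total partition needs half-open bins, and
  ours are declared in every output.
* **Filtering hierarchy**: per-gene mean methylation vs expression
  ratio under four nested CpG filters — (a) methylation q ≤ 0.05, (b)
  plus |dβ| > 0.2, (c) plus TSS/Ex1 restriction, (d) all three. The
  |dβ| filter is absolute by default with a directional flag. Filter
  monotonicity (a ⊇ b ⊇ d, a ⊇ c ⊇ d) is asserted in tests.
* **Category tables**: CpG counts by methylation level per (expression
  context, tissue, region class); percentages rounded half-up to
  integers with raw counts retained; empty rows are flagged, never
  divided. Counts are per (CpG, gene) link by default with a
  deduplication flag. Association is tested with the Pearson
  chi-square statistic Σ(O−E)²/E, df = (r−1)(c−1); a zero marginal is
  an error and expected counts < 5 raise a warning flag.
* **Prediction probabilities**: qualifying CpGs have methylation
  q ≤ 0.05, the stated region class, and dβ beyond ∓0.2 or ∓0.5 in the
  stated direction; the probability is the fraction whose gene shows
  an opposite-direction expression change of ≥2- or ≥5-fold. By
  default the expression change must also be q-significant
  (`require_expr_q`); the fold-only reading is available as a flag. A
  CpG linked to several genes qualifies if any linked gene meets the
  criterion. Probabilities for nested fold cuts are monotone by
  construction.

## Calibrated enrichment

Over-representation of a query gene list in a named collection is
scored by the upper-tail hypergeometric p (the scorer is pluggable).
Significance is calibrated, not thresholded: k = 5 control gene lists,
each query-sized, are sampled without replacement from the similarly
expressed pool (controls need not be mutually disjoint), scored
against every collection, and the threshold is the global minimum p
over all control scores; a query set is significant only when its p is
*strictly* below that. The strictest (global, strict-inequality)
reading is used because calibration exists to absorb multiplicity
across the whole collection. The pool must be at least query-sized;
since controls are drawn independently, k·|query| pool members are not
required.

## Synthetic data generator

The generator is the package's reference instrument: it produces data
with the structure the analysis assumes, plus complete ground truth
(per-CpG true means and differential flags; per-gene true log2 effects
and coupling flags). Defaults define the standard study conditions:

| parameter | default | rationale |
|---|---|---|
| samples per group | 3 | canonical triplicate design |
| beta noise | Beta(μκ, (1−μ)κ), κ = 100 | per-CpG variance μ(1−μ)/(1+κ); averaged over the baseline mixture ≈ 1e-3, matching the tight replication of real arrays (mean within-group variance ~0.001, ~96% < 0.01) |
| baseline modes | hypo μ~U(0.01,0.12), intermediate μ~U(0.3,0.7), hyper μ~U(0.88,0.99); weights 0.65/0.15/0.20 for TSS/Ex1 probes, 0.30/0.20/0.50 for UTR/GB, 0.40/0.20/0.40 unannotated | bimodal marginal with promoter-proximal hypomethylation |
| frac_diff_cpgs | 0.42 | near half of CpGs genuinely differ between the groups |
| effect law | \|dβ\| ~ Exp(0.15) truncated [0.01, 0.8]; P(adult higher) = 0.72 | small-effect-dominated spectrum (~74% < 0.2, ~4% > 0.5) with the adult-hypermethylation excess |
| region label weights | 0.12/0.15/0.12/0.08/0.43/0.10 | gene-body-dominated manifest composition |
| unannotated probes | 25% | matches typical RefGene coverage (~75%) |
| regulatory feature | 21% annotated, 92% of those Promoter_Associated | sparse regulatory-feature coverage |
| sex-chromosome probes | 2.5% | ~X+Y share of a 450K manifest |
| detection failures | 0.1% uniform at random | sporadic probe failure; no structure assumed |
| coupling | 5% of genes adult-over (fetal TSS/Ex1 mean ~U(0.7,1), adult ~U(0.3, min(0.7, fetal−0.25)); log2 effect ~U(2.5,4) to adult), 5% fetal-over (expression only) | the inverse promoter-methylation/expression pattern; the −0.25 floor guarantees every coupled gene owns a TSS/Ex1 CpG with \|dβ\| > 0.2 |
| expression | baseline ~U(4,12) log2, N(0, 0.25) noise | array-scale intensities |

Effects are applied on the mean scale and clipped to [0.01, 0.99] (so
Beta parameters stay positive); when clipping would shrink a drawn
magnitude the sign is flipped if the opposite direction preserves it.
Truth records the *realized* means, and `is_differential` ⇔ true
dβ ≠ 0. Each CpG is assigned to exactly one gene — multi-gene parsing
is exercised by hand-written annotation fixtures instead — and all
draws come from a single seeded RNG, so identical configs are
byte-identical.

What the generator does **not** emulate: Infinium I/II probe-type
chemistry, batch effects, cell-type mixture, spatial/CpG-island
correlation between neighbouring probes, and annotation ambiguity
(multi-gene probes). Passing tests therefore demonstrate calibration
and power under idealized independence, not robustness to those
artifacts; the detection-p and normalization steps that would address
them upstream are out of scope by design (the pipeline consumes
already-normalized matrices).

## Problem sizes and numerical choices

The test suite and the acceptance script run at sizes chosen to make
the statistical checks tight yet quick: 50,000 CpGs for
null-calibration (binomial SE of the p<0.05 fraction ≈ 0.001), 20,000
CpGs for power/FDR and the end-to-end coupled run, 10,000 features for
variance-prior recovery. The trigamma inversion iterates Newton steps
to relative tolerance 1e-10. TSV output uses `%.12g` floats
(round-trips well below the declared 1e-9 read-back tolerance).
Percentages in category tables round half-up; all raw counts are kept.

The pipeline manifest intentionally excludes wall-clock information so
reruns with identical config and seed are byte-identical; timings are
logged to stderr.

## Known limitations

* With 3 samples per group the per-feature variance carries only 4
  residual df; inference leans heavily on moderation, and the null
  calibration checks hold for the generator's noise law (logit-Beta),
  not arbitrary heavy-tailed noise.
* The detection-p filter treats the supplied matrix as-is (any
  adjustment is the caller's choice); the all-samples-must-pass rule is
  the strictest reading and is configurable.
* The control-set calibration's strictness grows with the number of
  collections scored; with very many collections it approaches a
  min-p permutation bound and becomes conservative.
* Surrogate-variable / latent-confounder estimation is not
  implemented; known covariates can be supplied in the design table
  instead.
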