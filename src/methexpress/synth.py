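"""Two-group methylation + expression simulator with known ground truth.

The generator emulates the statistical structure a fetal-vs-adult
450K/expression integration analysis assumes:

* bimodal marginal beta distribution (most CpGs near 0 or near 1),
  with promoter-proximal (TSS/Ex1) probes shifted toward
  hypomethylation relative to gene-body/UTR probes;
* tight within-group replication — per-CpG Beta(μκ, (1−μ)κ) noise with
  concentration κ tuned so the mean per-CpG sample variance is ~1e-3;
* a configurable fraction of differential CpGs whose |dβ| spectrum is
  peaked near small values (exponential law) with a configurable
  probability that the adult group is the hypermethylated one;
* gene-linked annotation with manifest-style region labels, a sex-
  chromosome fraction, partial annotation coverage, and sporadic
  detection-p failures;
* a coupled gene subset: "adult-overexpressed" genes whose TSS/Ex1
  CpGs transition from fetal hypermethylation to adult low/intermediate
  methylation (the inverse methylation-expression pattern), plus a
  "fetal-overexpressed" subset with no methylation coupling.

Everything is drawn from a single seeded RNG stream, so identical
configs produce byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .errors import ConfigurationError

AUTOSOMES = [str(i) for i in range(1, 23)]
REGION_LABELS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")
TSS_EX1_LABELS = frozenset({"TSS200", "TSS1500", "1stExon"})


@dataclass
class EffectSpec:
    """Signed delta-beta effect law for ordinary differential CpGs.

    kind 'exponential': |dβ| ~ Exp(scale) truncated to [min_effect,
    max_effect]. kind 'fixed': |dβ| = value for every differential CpG.
    The sign is adult-hypermethylated with probability
    ``prob_adult_higher``; when clipping the adult mean into
    [clip_lo, clip_hi] would shrink the magnitude, the opposite sign is
    used instead so the realized |dβ| matches the drawn one whenever
    either direction fits.
    """

    kind: str = "exponential"
    scale: float = 0.15
    value: float = 0.3
    min_effect: float = 0.01
    max_effect: float = 0.8
    prob_adult_higher: float = 0.72


@dataclass
class CouplingSpec:
    """Methylation-expression coupling for a gene subset.

    ``frac_adult_over`` of genes (among those owning >=1 autosomal
    TSS/Ex1 CpG) become adult-overexpressed with fetal TSS/Ex1
    hypermethylation: fetal mean ~ U(0.7, 1.0), adult mean ~
    U(0.3, min(0.7, fetal − 0.25)) — every coupled TSS/Ex1 CpG has a
    true fetal-to-adult decrease of at least 0.25. ``frac_fetal_over``
    of the remaining genes are fetal-overexpressed with no methylation
    coupling. Expression effects are log2 units ~ U(lo, hi).
    """

    frac_adult_over: float = 0.05
    frac_fetal_over: float = 0.05
    log2_effect_lo: float = 2.5
    log2_effect_hi: float = 4.0


@dataclass
class SimulationConfig:
    n_cpgs: int = 20_000
    n_genes: int = 1_500
    samples_per_group: int = 3
    #: baseline-mode weights (hypo, intermediate, hyper) for unannotated CpGs
    beta_mixture_weights: tuple = (0.40, 0.20, 0.40)
    #: TSS/Ex1-labelled CpGs lean hypomethylated
    tss_mixture_weights: tuple = (0.65, 0.15, 0.20)
    #: gene-body/UTR CpGs carry more hypermethylation
    utr_gb_mixture_weights: tuple = (0.30, 0.20, 0.50)
    #: Beta-noise concentration κ; per-CpG variance = μ(1−μ)/(1+κ)
    within_group_precision: float = 100.0
    frac_diff_cpgs: float = 0.42
    dbeta_effect: EffectSpec = field(default_factory=EffectSpec)
    region_label_weights: tuple = (0.12, 0.15, 0.12, 0.08, 0.43, 0.10)
    frac_sex_chrom: float = 0.025
    frac_unannotated: float = 0.25
    frac_regulatory_feature: float = 0.21
    frac_promoter_associated: float = 0.92  # of regulatory-feature probes
    detection_fail_rate: float = 0.001
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    expression_noise_sd: float = 0.25
    expression_baseline: tuple = (4.0, 12.0)
    clip: tuple = (0.01, 0.99)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cpgs", "n_genes", "samples_per_group"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.samples_per_group < 2:
            raise ConfigurationError("need >=2 samples per group")
        for name in ("beta_mixture_weights", "tss_mixture_weights",
                     "utr_gb_mixture_weights", "region_label_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if (w < 0).any() or (w > 1).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{name} must be proportions summing to 1, got {tuple(w)}"
                )
        for name in ("frac_diff_cpgs", "frac_sex_chrom", "frac_unannotated",
                     "frac_regulatory_feature", "frac_promoter_associated",
                     "detection_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.within_group_precision <= 0:
            raise ConfigurationError("within_group_precision must be positive")
        c = self.coupling
        if not (0 <= c.frac_adult_over <= 1 and 0 <= c.frac_fetal_over <= 1
                and c.frac_adult_over + c.frac_fetal_over <= 1):
            raise ConfigurationError("coupling fractions must be proportions "
                                     "with sum <= 1")
        if self.dbeta_effect.kind not in ("exponential", "fixed"):
            raise ConfigurationError(
                f"unknown effect law {self.dbeta_effect.kind!r}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``cpgs``: per-CpG true group means, differential flag, region
    label, gene, chromosome (true_delta_beta = adult − fetal).
    ``genes``: per-gene true log2 difference (fetal − adult), class
    label in {adult_over, fetal_over, background} and coupling flag.
    """

    cpgs: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class SyntheticDataset:
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    expression: pd.DataFrame
    annotation: pd.DataFrame
    design: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig


def _sample_baseline_means(rng, modes):
    """Baseline mean per CpG given its mode index (0 hypo, 1 inter, 2 hyper)."""
    n = len(modes)
    mu = np.empty(n)
    mu[modes == 0] = rng.uniform(0.01, 0.12, size=(modes == 0).sum())
    mu[modes == 1] = rng.uniform(0.30, 0.70, size=(modes == 1).sum())
    mu[modes == 2] = rng.uniform(0.88, 0.99, size=(modes == 2).sum())
    return mu


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one complete two-group dataset; see the module docstring."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g, spg = config.n_cpgs, config.n_genes, config.samples_per_group
    clip_lo, clip_hi = config.clip

    cpg_ids = np.array([f"cg{i:08d}" for i in range(n)])
    gene_ids = np.array([f"GENE{i:05d}" for i in range(g)])
    fetal_samples = [f"F{i + 1}" for i in range(spg)]
    adult_samples = [f"A{i + 1}" for i in range(spg)]

    # --- annotation structure -------------------------------------------
    is_sex = rng.random(n) < config.frac_sex_chrom
    chrom = rng.choice(AUTOSOMES, size=n)
    chrom[is_sex] = rng.choice(["X", "Y"], size=is_sex.sum())
    position = rng.integers(10_000, 200_000_000, size=n)
    region = rng.choice(REGION_LABELS, size=n, p=config.region_label_weights)
    annotated = rng.random(n) >= config.frac_unannotated
    gene_of = np.where(annotated, rng.choice(gene_ids, size=n), "")
    has_regfeat = rng.random(n) < config.frac_regulatory_feature
    promoter = rng.random(n) < config.frac_promoter_associated
    regfeat = np.where(
        has_regfeat, np.where(promoter, "Promoter_Associated", "Gene_Associated"), ""
    )

    is_tss = np.isin(region, list(TSS_EX1_LABELS)) & annotated

    # --- baseline methylation means -------------------------------------
    modes = np.empty(n, dtype=int)
    for mask, weights in (
        (is_tss, config.tss_mixture_weights),
        (~is_tss & annotated, config.utr_gb_mixture_weights),
        (~annotated, config.beta_mixture_weights),
    ):
        modes[mask] = rng.choice(3, size=mask.sum(), p=np.asarray(weights))
    fetal_mean = np.clip(_sample_baseline_means(rng, modes), clip_lo, clip_hi)
    adult_mean = fetal_mean.copy()

    # --- ordinary differential effects ----------------------------------
    is_diff = rng.random(n) < config.frac_diff_cpgs
    n_diff = int(is_diff.sum())
    eff = config.dbeta_effect
    if eff.kind == "fixed":
        mag = np.full(n_diff, float(eff.value))
    else:
        mag = rng.exponential(eff.scale, size=n_diff)
        mag = np.clip(mag, eff.min_effect, eff.max_effect)
    sign = np.where(rng.random(n_diff) < eff.prob_adult_higher, 1.0, -1.0)
    base = fetal_mean[is_diff]
    proposed = np.clip(base + sign * mag, clip_lo, clip_hi)
    # flip the sign when clipping shrank the magnitude and the opposite
    # direction preserves it better
    flipped = np.clip(base - sign * mag, clip_lo, clip_hi)
    use_flip = np.abs(flipped - base) > np.abs(proposed - base)
    adult_diff = np.where(use_flip, flipped, proposed)
    adult_mean[is_diff] = adult_diff

    # --- coupled genes ---------------------------------------------------
    coup = config.coupling
    tss_genes = np.unique(gene_of[is_tss & ~is_sex])
    rng.shuffle(tss_genes)
    n_adult_over = int(round(coup.frac_adult_over * g))
    n_fetal_over = int(round(coup.frac_fetal_over * g))
    adult_over_genes = set(tss_genes[:n_adult_over])
    remaining = np.array([gg for gg in gene_ids if gg not in adult_over_genes])
    fetal_over_genes = set(rng.choice(remaining, size=n_fetal_over,
                                      replace=False)) if n_fetal_over else set()

    coupled_cpg = is_tss & np.isin(gene_of, list(adult_over_genes))
    n_coup = int(coupled_cpg.sum())
    f_c = rng.uniform(0.70, 1.00, size=n_coup)
    f_c = np.clip(f_c, clip_lo, clip_hi)
    a_hi = np.minimum(0.70, f_c - 0.25)
    a_c = rng.uniform(0.30, a_hi)
    fetal_mean[coupled_cpg] = f_c
    adult_mean[coupled_cpg] = a_c
    is_diff = is_diff | coupled_cpg

    true_delta = adult_mean - fetal_mean
    is_diff = is_diff & (true_delta != 0.0)

    # --- beta draws -------------------------------------------------------
    kappa = config.within_group_precision
    beta_vals = np.empty((n, 2 * spg))
    for j in range(spg):
        beta_vals[:, j] = rng.beta(fetal_mean * kappa, (1 - fetal_mean) * kappa)
    for j in range(spg):
        beta_vals[:, spg + j] = rng.beta(adult_mean * kappa,
                                         (1 - adult_mean) * kappa)
    samples = fetal_samples + adult_samples
    beta = pd.DataFrame(beta_vals, index=cpg_ids, columns=samples)

    detp_vals = rng.uniform(0.0, 0.01, size=(n, 2 * spg))
    fails = rng.random((n, 2 * spg)) < config.detection_fail_rate
    detp_vals[fails] = rng.uniform(0.06, 1.0, size=int(fails.sum()))
    detection_p = pd.DataFrame(detp_vals, index=cpg_ids, columns=samples)

    # --- expression -------------------------------------------------------
    base_expr = rng.uniform(*config.expression_baseline, size=g)
    gene_fetal = base_expr.copy()
    gene_adult = base_expr.copy()
    effects = rng.uniform(coup.log2_effect_lo, coup.log2_effect_hi, size=g)
    in_adult_over = np.isin(gene_ids, list(adult_over_genes))
    in_fetal_over = np.isin(gene_ids, list(fetal_over_genes))
    gene_adult[in_adult_over] += effects[in_adult_over]
    gene_fetal[in_fetal_over] += effects[in_fetal_over]
    expr_vals = np.column_stack(
        [gene_fetal + rng.normal(0, config.expression_noise_sd, size=g)
         for _ in range(spg)]
        + [gene_adult + rng.normal(0, config.expression_noise_sd, size=g)
           for _ in range(spg)]
    )
    expression = pd.DataFrame(expr_vals, index=gene_ids, columns=samples)

    # --- tables -----------------------------------------------------------
    annotation = pd.DataFrame(
        {
            "IlmnID": cpg_ids,
            "CHR": chrom,
            "MAPINFO": position,
            "UCSC_RefGene_Name": gene_of,
            "UCSC_RefGene_Group": np.where(gene_of != "", region, ""),
            "Regulatory_Feature_Group": regfeat,
        }
    )
    annotation = io_formats.validate_annotation(annotation)

    design = io_formats.validate_design(
        pd.DataFrame(
            {"sample_id": samples,
             "group": ["fetal"] * spg + ["adult"] * spg}
        )
    )

    truth_cpgs = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "true_fetal_mean": fetal_mean,
            "true_adult_mean": adult_mean,
            "is_differential": is_diff,
            "region": np.where(gene_of != "", region, ""),
            "gene": gene_of,
            "chromosome": chrom,
        }
    )
    gene_class = np.full(g, "background", dtype=object)
    gene_class[in_adult_over] = "adult_over"
    gene_class[in_fetal_over] = "fetal_over"
    truth_genes = pd.DataFrame(
        {
            "gene": gene_ids,
            "true_log2_diff": gene_fetal - gene_adult,
            "expr_class": gene_class,
            "coupled": in_adult_over,
        }
    )
    truth = SyntheticTruth(cpgs=truth_cpgs, genes=truth_genes)
    return SyntheticDataset(
        beta=io_formats.validate_matrix(beta, "beta"),
        detection_p=io_formats.validate_matrix(detection_p, "detection_p"),
        expression=io_formats.validate_matrix(expression, "expression"),
        annotation=annotation,
        design=design,
        truth=truth,
        config=config,
    )


FIXTURE_FILES = {
    "beta": "beta.tsv",
    "detection_p": "detection_p.tsv",
    "expression": "expression.tsv",
    "annotation": "annotation.tsv",
    "design": "design.tsv",
    "truth_cpgs": "truth_cpgs.tsv",
    "truth_genes": "truth_genes.tsv",
}


def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, Path]:
    """Write the dataset as the standard TSV file set; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}
    io_formats.write_matrix(dataset.beta, paths["beta"])
    io_formats.write_matrix(dataset.detection_p, paths["detection_p"])
    io_formats.write_matrix(dataset.expression, paths["expression"])
    io_formats.write_annotation(dataset.annotation, paths["annotation"])
    io_formats.write_design(dataset.design, paths["design"])
    io_formats.write_table(dataset.truth.cpgs, paths["truth_cpgs"])
    io_formats.write_table(dataset.truth.genes, paths["truth_genes"])
    return paths


def read_fixture(directory):
    """Read a fixture directory back; returns a dict of frames."""
    directory = Path(directory)
    return {
        "beta": io_formats.read_matrix(directory / FIXTURE_FILES["beta"], "beta"),
        "detection_p": io_formats.read_matrix(
            directory / FIXTURE_FILES["detection_p"], "detection_p"),
        "expression": io_formats.read_matrix(
            directory / FIXTURE_FILES["expression"], "expression"),
        "annotation": io_formats.read_annotation(
            directory / FIXTURE_FILES["annotation"]),
        "design": io_formats.read_design(directory / FIXTURE_FILES["design"]),
        "truth_cpgs": pd.read_csv(directory / FIXTURE_FILES["truth_cpgs"],
                                  sep="\t", keep_default_na=False,
                                  na_values=[]),
        "truth_genes": pd.read_csv(directory / FIXTURE_FILES["truth_genes"],
                                   sep="\t", keep_default_na=False,
                                   na_values=[]),
    }


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
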