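"""End-to-end pipeline: filter → transform/test → regions → integrate →
enrich, with a machine-readable run manifest.

The manifest records the package version, seed, every threshold, the
SHA-256 of each input file and per-stage record counts — enough to
reproduce a run bit-exactly — and deliberately contains no timestamps,
so reruns with the same config are byte-identical. Timing goes to the
stderr log instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diffstats, enrich, integrate, io_formats, regions
from .errors import PipelineError
from .regions import RegionClass

log = logging.getLogger("methexpress")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run. Defaults are the analysis'
    canonical values: detection p < 0.05, FDR q <= 0.05, dβ cuts
    0.2/0.5, 5-fold overexpression, 1.1-fold similarity, methylation
    bins at 0.3/0.7, 0.05 histogram bins, logit offset 1e-6, 5 control
    sets."""

    beta_path: str = ""
    detection_p_path: str = ""
    expression_path: str = ""
    annotation_path: str = ""
    design_path: str = ""
    gene_sets_path: str | None = None  # GMT; default: per-chromosome sets
    out_dir: str = "methexpress_out"
    detection_threshold: float = 0.05
    q_cut: float = 0.05
    dbeta_cuts: tuple = (0.2, 0.5)
    over_fold: float = 5.0
    similar_fold: float = 1.1
    fold_cuts: tuple = (2.0, 5.0)
    meth_bins: tuple = (0.3, 0.7)
    hist_bin_width: float = 0.05
    logit_offset: float = 1e-6
    moderation: bool = True
    require_expr_q: bool = True
    k_controls: int = 5
    seed: int = 0


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunBundle:
    """In-memory results of a completed run plus the manifest."""

    config: PipelineConfig
    manifest: dict
    dm: pd.DataFrame
    de: pd.DataFrame
    links: pd.DataFrame
    records: pd.DataFrame
    category: pd.DataFrame
    prediction: pd.DataFrame
    relationship: dict = field(default_factory=dict)
    chi_square: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)


def _default_gene_sets(links: pd.DataFrame, annot: pd.DataFrame):
    """Positional gene sets: genes grouped by the chromosome of their
    probes (the in-repo analog of a positional pathway collection)."""
    annotated = links[links["gene"] != ""]
    chrom = annot.loc[annotated["cpg_id"], "CHR"].map(
        io_formats.normalize_chromosome
    ).to_numpy()
    frame = pd.DataFrame({"gene": annotated["gene"].to_numpy(), "chrom": chrom})
    sets = {
        f"chr{c}": set(sub["gene"])
        for c, sub in frame.groupby("chrom")
        if len(set(sub["gene"])) >= 5
    }
    return sets


def run_pipeline(config: PipelineConfig) -> RunBundle:
    """Run all stages in order, writing each stage's TSVs plus
    ``manifest.json`` under ``config.out_dir``.

    Any stage failure writes a FAILED marker naming the stage and
    re-raises as PipelineError; earlier outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "methexpress",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "stages": [],
    }
    state: dict = {}

    stages = [
        ("validate", _stage_validate),
        ("filter", _stage_filter),
        ("dm", _stage_dm),
        ("de", _stage_de),
        ("regions", _stage_regions),
        ("integrate", _stage_integrate),
        ("enrich", _stage_enrich),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            n_records, outputs = fn(config, state, out, manifest)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage: {name}\nerror: {exc}\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"name": name, "n_records": n_records, "outputs": outputs}
        )
        log.info("stage %-10s %8d records  %.2fs", name, n_records,
                 time.perf_counter() - t0)

    counts = summarize_counts(state, config)
    state["counts"] = counts
    with open(out / "summary.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return RunBundle(
        config=config, manifest=manifest, dm=state["dm"], de=state["de"],
        links=state["links"], records=state["records"],
        category=state["category"], prediction=state["prediction"],
        relationship=state["relationship"], chi_square=state["chi_square"],
        enrichment=state["enrichment"], counts=counts,
    )


def _stage_validate(config, state, out, manifest):
    paths = {
        "beta": config.beta_path,
        "detection_p": config.detection_p_path,
        "expression": config.expression_path,
        "annotation": config.annotation_path,
        "design": config.design_path,
    }
    state["beta"] = io_formats.read_matrix(paths["beta"], "beta")
    state["detection_p"] = io_formats.read_matrix(paths["detection_p"],
                                                  "detection_p")
    state["expression"] = io_formats.read_matrix(paths["expression"],
                                                 "expression")
    state["annotation"] = io_formats.read_annotation(paths["annotation"])
    state["design"] = io_formats.read_design(paths["design"])
    io_formats.check_design_covers(state["beta"], state["design"], paths["beta"])
    io_formats.check_design_covers(state["expression"], state["design"],
                                   paths["expression"])
    for key, p in paths.items():
        manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
    return len(state["beta"]), []


def _stage_filter(config, state, out, manifest):
    beta, n_detp = diffstats.filter_detection(
        state["beta"], state["detection_p"], config.detection_threshold
    )
    beta, n_sex = diffstats.filter_sex_chromosomes(beta, state["annotation"])
    state["beta_filtered"] = beta
    state["n_removed_detection"] = n_detp
    state["n_removed_sex"] = n_sex
    io_formats.write_matrix(beta, out / "beta_filtered.tsv")
    return len(beta), ["beta_filtered.tsv"]


def _stage_dm(config, state, out, manifest):
    dm = diffstats.differential_methylation(
        state["beta_filtered"], state["design"],
        offset=config.logit_offset, moderation=config.moderation,
    )
    state["dm"] = dm
    io_formats.write_table(dm.rename_axis("cpg_id"), out / "dm.tsv", index=True)
    return len(dm), ["dm.tsv"]


def _stage_de(config, state, out, manifest):
    de = diffstats.differential_expression(
        state["expression"], state["design"], moderation=config.moderation
    )
    state["de"] = de
    io_formats.write_table(de.rename_axis("gene"), out / "de.tsv", index=True)
    return len(de), ["de.tsv"]


def _stage_regions(config, state, out, manifest):
    links = regions.build_links(state["annotation"])
    links = links[links["cpg_id"].isin(state["beta_filtered"].index)
                  | (links["gene"] == "")]
    state["links"] = links
    gene_means = regions.gene_mean_methylation(
        state["beta_filtered"], links, state["design"]
    )
    state["coverage"] = regions.annotation_coverage_summary(state["annotation"])
    io_formats.write_table(links, out / "links.tsv")
    io_formats.write_table(gene_means.rename_axis("gene"),
                           out / "gene_mean_methylation.tsv", index=True)
    return len(links), ["links.tsv", "gene_mean_methylation.tsv"]


def _stage_integrate(config, state, out, manifest):
    dm, de, links = state["dm"], state["de"], state["links"]
    records = integrate.build_integration_records(
        dm, links, de, over_fold=config.over_fold,
        similar_fold=config.similar_fold, q_cut=config.q_cut,
        meth_bins=config.meth_bins,
    )
    state["records"] = records

    dbeta_cut = config.dbeta_cuts[0]
    panels = {
        "a": dict(q_cut=config.q_cut),
        "b": dict(q_cut=config.q_cut, min_abs_dbeta=dbeta_cut),
        "c": dict(q_cut=config.q_cut, region=RegionClass.TSS_EX1),
        "d": dict(q_cut=config.q_cut, min_abs_dbeta=dbeta_cut,
                  region=RegionClass.TSS_EX1),
    }
    relationship = {
        k: integrate.relationship_table(dm, links, de, **kw)
        for k, kw in panels.items()
    }
    state["relationship"] = relationship
    for k, tbl in relationship.items():
        io_formats.write_table(tbl, out / f"relationship_{k}.tsv")

    category = integrate.category_table(records)
    state["category"] = category
    io_formats.write_table(category, out / "category.tsv")

    chi = {}
    for region in (RegionClass.TSS_EX1, RegionClass.UTR_GB):
        for tissue in ("fetal", "adult"):
            sub = category[(category["region_class"] == region.value)
                           & (category["tissue"] == tissue)]
            counts = sub[["n_hypo", "n_intermediate", "n_hyper"]].to_numpy()
            nonzero_rows = counts.sum(axis=1) > 0
            counts = counts[nonzero_rows]
            key = f"{tissue}_{region.value}"
            if counts.shape[0] >= 2 and (counts.sum(axis=0) > 0).all():
                r = integrate.chi_square(counts)
                chi[key] = {
                    "statistic": r.statistic, "df": r.df, "p": r.p,
                    "low_expected": r.low_expected,
                    "contexts": sub.loc[nonzero_rows, "context"].tolist(),
                }
    state["chi_square"] = chi
    with open(out / "chi_square.json", "w") as fh:
        json.dump(chi, fh, indent=2, sort_keys=True)

    prediction = integrate.prediction_table(
        records, dbeta_cuts=config.dbeta_cuts, fold_cuts=config.fold_cuts,
        q_cut=config.q_cut, require_expr_q=config.require_expr_q,
    )
    state["prediction"] = prediction
    io_formats.write_table(prediction, out / "prediction.tsv")

    fine_records = integrate.build_integration_records(
        dm, links, de, over_fold=config.over_fold,
        similar_fold=config.similar_fold, q_cut=config.q_cut, collapse=False,
    )
    filt = fine_records[(fine_records["meth_q"] <= config.q_cut)
                        & (fine_records["delta_beta"].abs() > dbeta_cut)]
    density = integrate.density_summary(filt, stratify_by="fine_region",
                                        bin_width=config.hist_bin_width)
    io_formats.write_table(density, out / "density.tsv")
    return len(records), ["relationship_a.tsv", "relationship_b.tsv",
                          "relationship_c.tsv", "relationship_d.tsv",
                          "category.tsv", "chi_square.json",
                          "prediction.tsv", "density.tsv"]


def _stage_enrich(config, state, out, manifest):
    dm, de, records = state["dm"], state["de"], state["records"]
    dbeta_cut = config.dbeta_cuts[0]
    # query: over-expressed genes (either direction) with a q-significant
    # TSS/Ex1 methylation change beyond the dβ cut
    over = records["expr_class"].isin(["FETAL_OVER", "ADULT_OVER"])
    meth_hit = (records["meth_q"] <= config.q_cut) \
        & (records["delta_beta"].abs() > dbeta_cut) \
        & (records["region_class"] == RegionClass.TSS_EX1.value)
    query = sorted(set(records.loc[over & meth_hit, "gene"]))
    similar_pool = sorted(set(records.loc[records["expr_class"] == "SIMILAR",
                                          "gene"]))
    universe = sorted(set(de.index))
    if config.gene_sets_path:
        collections = enrich.read_gmt(config.gene_sets_path)
    else:
        collections = _default_gene_sets(state["links"], state["annotation"])
    report = None
    if query and collections and len(similar_pool) >= len(query):
        report = enrich.control_calibrated_enrichment(
            query, collections, similar_pool, universe,
            k_controls=config.k_controls, seed=config.seed,
        )
        rows = [
            {"set_name": r.set_name, "overlap": r.overlap, "p": r.p,
             "threshold": r.threshold, "significant": r.significant}
            for r in report.results
        ]
        io_formats.write_table(pd.DataFrame(rows), out / "enrichment.tsv")
    state["enrichment"] = {
        "n_query_genes": len(query),
        "n_similar_pool": len(similar_pool),
        "threshold": report.threshold if report else None,
        "n_significant": (sum(r.significant for r in report.results)
                          if report else None),
    }
    with open(out / "enrichment_summary.json", "w") as fh:
        json.dump(state["enrichment"], fh, indent=2, sort_keys=True)
    return len(query), ["enrichment.tsv", "enrichment_summary.json"] \
        if report else ["enrichment_summary.json"]


def summarize_counts(state: dict, config: PipelineConfig) -> dict:
    """Headline statistics of a completed run.

    Percentages are None (not 0) when their denominator is empty.
    dβ here is adult − fetal, so 'adult hypermethylated' means dβ > 0.
    """
    dm, de = state["dm"], state["de"]
    q_cut = config.q_cut
    small_cut, large_cut = config.dbeta_cuts

    n_input = int(state.get("n_removed_detection", 0)
                  + state.get("n_removed_sex", 0) + len(dm))
    sig = dm[dm["q"] <= q_cut]
    n_sig = len(sig)
    small = sig[sig["delta_beta"].abs() <= small_cut]
    large = sig[sig["delta_beta"].abs() > large_cut]

    def pct(num, den):
        return 100.0 * num / den if den else None

    de_sig = de[de["q"] <= q_cut]
    de_5fold = de_sig[de_sig["fold_change"].abs() >= config.over_fold]
    return {
        "n_probes_input": n_input,
        "n_removed_detection": int(state.get("n_removed_detection", 0)),
        "n_removed_sex_chrom": int(state.get("n_removed_sex", 0)),
        "n_probes_analyzed": int(len(dm)),
        "n_significant_cpgs": int(n_sig),
        "pct_significant_cpgs": pct(n_sig, len(dm)),
        "n_significant_small_dbeta": int(len(small)),
        "pct_significant_small_dbeta": pct(len(small), n_sig),
        "n_significant_large_dbeta": int(len(large)),
        "pct_significant_large_dbeta": pct(len(large), n_sig),
        "pct_adult_hyper_small_dbeta": pct(
            int((small["delta_beta"] > 0).sum()), len(small)),
        "n_genes": int(len(de)),
        "n_de_genes": int(len(de_sig)),
        "n_5fold_genes": int(len(de_5fold)),
        "n_5fold_fetal_over": int((de_5fold["fold_change"] > 0).sum()),
        "n_5fold_adult_over": int((de_5fold["fold_change"] < 0).sum()),
    }


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
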