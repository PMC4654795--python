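"""CpG-to-gene mapping and gene-region aggregation.

The six manifest RefGene labels collapse into two aggregate classes:
TSS/Ex1 (TSS200, TSS1500, 1stExon — promoter-proximal, where
methylation is expected to repress transcription) and UTR/GB (5'UTR,
Body, 3'UTR). A probe annotated to both classes for the same gene
counts as TSS/Ex1 (promoter-proximal membership takes priority); the
rule is configurable via ``cpg_region_class``.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import group_samples


class RegionClass(str, Enum):
    TSS_EX1 = "TSS_EX1"
    UTR_GB = "UTR_GB"
    UNANNOTATED = "UNANNOTATED"


#: fine manifest label -> aggregate class
FINE_TO_CLASS = {
    "TSS200": RegionClass.TSS_EX1,
    "TSS1500": RegionClass.TSS_EX1,
    "1stExon": RegionClass.TSS_EX1,
    "5'UTR": RegionClass.UTR_GB,
    "Body": RegionClass.UTR_GB,
    "3'UTR": RegionClass.UTR_GB,
}


def build_links(annot: pd.DataFrame) -> pd.DataFrame:
    """One row per deduplicated (CpG, gene, fine region) triple.

    Probes with an empty gene list yield a single UNANNOTATED link with
    an empty gene. Columns: cpg_id, gene, fine_region, region_class.
    """
    cpgs, genes, fines, classes = [], [], [], []
    for probe, pairs in zip(annot["IlmnID"], annot["pairs"]):
        if not pairs:
            cpgs.append(probe)
            genes.append("")
            fines.append("")
            classes.append(RegionClass.UNANNOTATED.value)
            continue
        for gene, fine in pairs:
            cpgs.append(probe)
            genes.append(gene)
            fines.append(fine)
            classes.append(FINE_TO_CLASS[fine].value)
    return pd.DataFrame(
        {"cpg_id": cpgs, "gene": genes, "fine_region": fines,
         "region_class": classes}
    )


def cpg_region_class(links: pd.DataFrame,
                     priority: RegionClass = RegionClass.TSS_EX1) -> str:
    """Resolve the aggregate class of one (CpG, gene)'s links: the
    ``priority`` class wins if any link carries it."""
    if len(links) == 0:
        raise ValidationError("no links for this (CpG, gene)")
    classes = set(links["region_class"])
    if priority.value in classes:
        return priority.value
    if RegionClass.UTR_GB.value in classes:
        return RegionClass.UTR_GB.value
    return RegionClass.UNANNOTATED.value


def collapse_links(links: pd.DataFrame,
                   priority: RegionClass = RegionClass.TSS_EX1) -> pd.DataFrame:
    """One row per (CpG, gene) with the resolved aggregate class."""
    annotated = links[links["gene"] != ""]
    if len(annotated) == 0:
        return pd.DataFrame(columns=["cpg_id", "gene", "region_class"])
    is_priority = annotated["region_class"] == priority.value
    agg = (
        annotated.assign(_prio=is_priority)
        .groupby(["cpg_id", "gene"], sort=False)["_prio"]
        .any()
        .reset_index()
    )
    agg["region_class"] = np.where(
        agg["_prio"], priority.value,
        RegionClass.UTR_GB.value if priority == RegionClass.TSS_EX1
        else RegionClass.TSS_EX1.value,
    )
    return agg.drop(columns="_prio")


def gene_mean_methylation(beta: pd.DataFrame, links: pd.DataFrame,
                          design: pd.DataFrame,
                          restrict: RegionClass | None = None) -> pd.DataFrame:
    """Per-(gene, group) mean beta: the unweighted mean over qualifying
    CpGs of each CpG's within-group mean.

    ``restrict`` keeps only CpGs whose resolved (CpG, gene) class equals
    it; genes with no qualifying CpG are omitted. Returns a frame
    indexed by gene with columns mean_fetal, mean_adult, n_cpgs.
    """
    collapsed = collapse_links(links)
    if restrict is not None:
        collapsed = collapsed[collapsed["region_class"] == restrict.value]
    collapsed = collapsed[collapsed["cpg_id"].isin(beta.index)]
    if len(collapsed) == 0:
        return pd.DataFrame(columns=["mean_fetal", "mean_adult", "n_cpgs"])
    groups = group_samples(design)
    cpg_means = pd.DataFrame(
        {
            "mean_fetal": beta[groups["fetal"]].mean(axis=1),
            "mean_adult": beta[groups["adult"]].mean(axis=1),
        }
    )
    joined = collapsed.join(cpg_means, on="cpg_id")
    out = joined.groupby("gene").agg(
        mean_fetal=("mean_fetal", "mean"),
        mean_adult=("mean_adult", "mean"),
        n_cpgs=("cpg_id", "size"),
    )
    return out


def annotation_coverage_summary(annot: pd.DataFrame) -> dict:
    """Counts of probes with/without a regulatory-feature annotation and
    with/without a RefGene (gene-region) annotation, plus the
    promoter-associated subset size."""
    has_reg = annot["Regulatory_Feature_Group"].str.strip() != ""
    has_refgene = annot["pairs"].map(len) > 0
    promoter = annot["Regulatory_Feature_Group"].str.contains(
        "Promoter_Associated", case=False, regex=False
    )
    n = len(annot)
    return {
        "n_probes": n,
        "n_with_regulatory_feature": int(has_reg.sum()),
        "n_without_regulatory_feature": int((~has_reg).sum()),
        "n_with_refgene_group": int(has_refgene.sum()),
        "n_without_refgene_group": int((~has_refgene).sum()),
        "n_promoter_associated": int(promoter.sum()),
    }
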