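"""Joint methylation-expression analysis.

Genes are classified from the expression differential table
(overexpressed at a q-significant >=5-fold difference; "similar" when
non-significant and within 1.1-fold), CpG methylation levels fall into
hypo [0, 0.3), intermediate [0.3, 0.7) and hyper [0.7, 1.0] bins, and
the two views are joined per (CpG, gene) link into integration records
that feed the filtering hierarchy, the category contingency tables with
a Pearson chi-square test, the methylation-to-expression prediction
probabilities, and region-stratified density summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .regions import RegionClass, collapse_links


class ExpressionClass(str, Enum):
    FETAL_OVER = "FETAL_OVER"
    ADULT_OVER = "ADULT_OVER"
    SIMILAR = "SIMILAR"
    OTHER = "OTHER"


class MethLevel(str, Enum):
    HYPO = "HYPO"
    INTERMEDIATE = "INTERMEDIATE"
    HYPER = "HYPER"


METH_LEVEL_ORDER = [MethLevel.HYPO.value, MethLevel.INTERMEDIATE.value,
                    MethLevel.HYPER.value]


def classify_meth_level(beta, hypo_cut: float = 0.3, hyper_cut: float = 0.7):
    """Categorical methylation level: hypo [0, hypo_cut), intermediate
    [hypo_cut, hyper_cut), hyper [hyper_cut, 1]. Vectorized; beta
    outside [0,1] raises."""
    arr = np.asarray(beta, dtype=float)
    if ((arr < 0) | (arr > 1) | np.isnan(arr)).any():
        bad = arr[(arr < 0) | (arr > 1) | np.isnan(arr)][:3]
        raise ValidationError(f"beta outside [0,1]: {bad}")
    out = np.where(
        arr < hypo_cut, MethLevel.HYPO.value,
        np.where(arr < hyper_cut, MethLevel.INTERMEDIATE.value,
                 MethLevel.HYPER.value),
    )
    return out if arr.shape else out.item()


def classify_expression(expr_diff: pd.DataFrame, over_fold: float = 5.0,
                        similar_fold: float = 1.1,
                        q_cut: float = 0.05) -> pd.Series:
    """Total partition of genes into expression classes.

    FETAL_OVER / ADULT_OVER: q <= q_cut and |fold change| >= over_fold
    with the corresponding sign. SIMILAR: q > q_cut and |fold change| <
    similar_fold. Everything else is OTHER.
    """
    fc = expr_diff["fold_change"].to_numpy()
    q = expr_diff["q"].to_numpy()
    sig = q <= q_cut
    cls = np.full(len(expr_diff), ExpressionClass.OTHER.value, dtype=object)
    cls[sig & (fc >= over_fold)] = ExpressionClass.FETAL_OVER.value
    cls[sig & (fc <= -over_fold)] = ExpressionClass.ADULT_OVER.value
    cls[~sig & (np.abs(fc) < similar_fold)] = ExpressionClass.SIMILAR.value
    return pd.Series(cls, index=expr_diff.index, name="expr_class")


def build_integration_records(meth_diff: pd.DataFrame, links: pd.DataFrame,
                              expr_diff: pd.DataFrame,
                              over_fold: float = 5.0,
                              similar_fold: float = 1.1,
                              q_cut: float = 0.05,
                              collapse: bool = True,
                              meth_bins: tuple = (0.3, 0.7)) -> pd.DataFrame:
    """Join the differential tables into one record per (CpG, gene) link.

    Columns: cpg_id, gene, region_class, beta_fetal, beta_adult,
    fetal_level, adult_level, delta_beta, meth_q, expr_class,
    fold_change, expr_q. Links to genes absent from the expression
    table are dropped (no expression context exists for them), as are
    unannotated links. With ``collapse`` off, one record per (CpG,
    gene, fine region) is kept instead (carrying a ``fine_region``
    column) for fine-region density stratification.
    """
    if collapse:
        collapsed = collapse_links(links)
    else:
        collapsed = links[links["gene"] != ""][
            ["cpg_id", "gene", "fine_region", "region_class"]
        ].copy()
    collapsed = collapsed[collapsed["cpg_id"].isin(meth_diff.index)]
    collapsed = collapsed[collapsed["gene"].isin(expr_diff.index)]
    expr_class = classify_expression(expr_diff, over_fold, similar_fold, q_cut)
    rec = collapsed.copy()
    rec["beta_fetal"] = meth_diff.loc[rec["cpg_id"], "mean_fetal"].to_numpy()
    rec["beta_adult"] = meth_diff.loc[rec["cpg_id"], "mean_adult"].to_numpy()
    rec["delta_beta"] = meth_diff.loc[rec["cpg_id"], "delta_beta"].to_numpy()
    rec["meth_q"] = meth_diff.loc[rec["cpg_id"], "q"].to_numpy()
    rec["fetal_level"] = classify_meth_level(rec["beta_fetal"].to_numpy(),
                                             *meth_bins)
    rec["adult_level"] = classify_meth_level(rec["beta_adult"].to_numpy(),
                                             *meth_bins)
    rec["expr_class"] = expr_class.loc[rec["gene"]].to_numpy()
    rec["fold_change"] = expr_diff.loc[rec["gene"], "fold_change"].to_numpy()
    rec["expr_q"] = expr_diff.loc[rec["gene"], "q"].to_numpy()
    return rec.reset_index(drop=True)


# ---------------------------------------------------------------------------
# filtering hierarchy (gene-level methylation vs expression)


def relationship_table(meth_diff: pd.DataFrame, links: pd.DataFrame,
                       expr_diff: pd.DataFrame, q_cut: float = 0.05,
                       min_abs_dbeta: float | None = None,
                       region: RegionClass | None = None,
                       directional: bool = False) -> pd.DataFrame:
    """Per-gene mean methylation versus expression under a CpG filter.

    Qualifying CpGs have methylation q <= q_cut, optionally |dβ| (or
    signed dβ <= −cut when ``directional``) beyond ``min_abs_dbeta``,
    and optionally a region-class restriction. Each gene with >=1
    qualifying CpG contributes one row: the unweighted mean fetal and
    adult beta over its qualifying CpGs and its signed expression
    ratio. The four combinations of (min_abs_dbeta, region) reproduce
    the filtering-hierarchy panels.
    """
    collapsed = collapse_links(links)
    collapsed = collapsed[collapsed["cpg_id"].isin(meth_diff.index)]
    md = meth_diff.loc[collapsed["cpg_id"]]
    keep = (md["q"].to_numpy() <= q_cut)
    if min_abs_dbeta is not None:
        db = md["delta_beta"].to_numpy()
        if directional:
            keep &= db <= -min_abs_dbeta
        else:
            keep &= np.abs(db) > min_abs_dbeta
    if region is not None:
        keep &= (collapsed["region_class"] == region.value).to_numpy()
    qual = collapsed[keep].copy()
    qual["beta_fetal"] = meth_diff.loc[qual["cpg_id"], "mean_fetal"].to_numpy()
    qual["beta_adult"] = meth_diff.loc[qual["cpg_id"], "mean_adult"].to_numpy()
    per_gene = qual.groupby("gene").agg(
        mean_beta_fetal=("beta_fetal", "mean"),
        mean_beta_adult=("beta_adult", "mean"),
        n_cpgs=("cpg_id", "size"),
    )
    per_gene = per_gene[per_gene.index.isin(expr_diff.index)]
    per_gene["fold_change"] = expr_diff.loc[per_gene.index, "fold_change"]
    return per_gene.reset_index()


# ---------------------------------------------------------------------------
# category (contingency) tables


def _round_half_up(x):
    return int(np.floor(x + 0.5))


def category_table(records: pd.DataFrame,
                   contexts=(ExpressionClass.FETAL_OVER,
                             ExpressionClass.ADULT_OVER,
                             ExpressionClass.SIMILAR),
                   dedup_cpgs: bool = False) -> pd.DataFrame:
    """CpG counts and percentages by methylation level, per
    (expression context, tissue, region class).

    Each row carries the raw counts (n_hypo, n_intermediate, n_hyper),
    the row total, and half-up integer-rounded percentages. Empty rows
    keep zero counts and NA percentages (no division by zero). With
    ``dedup_cpgs`` a CpG linked to several qualifying genes counts
    once per (context, region) instead of once per link.
    """
    rows = []
    for ctx in contexts:
        ctx = ExpressionClass(ctx)
        sub_ctx = records[records["expr_class"] == ctx.value]
        for region in (RegionClass.TSS_EX1, RegionClass.UTR_GB):
            sub = sub_ctx[sub_ctx["region_class"] == region.value]
            if dedup_cpgs:
                sub = sub.drop_duplicates(subset="cpg_id")
            for tissue, col in (("fetal", "fetal_level"),
                                ("adult", "adult_level")):
                counts = sub[col].value_counts()
                n = int(len(sub))
                row = {
                    "context": ctx.value,
                    "tissue": tissue,
                    "region_class": region.value,
                    "n_cpgs": n,
                }
                for level in METH_LEVEL_ORDER:
                    c = int(counts.get(level, 0))
                    row[f"n_{level.lower()}"] = c
                    row[f"pct_{level.lower()}"] = (
                        _round_half_up(100.0 * c / n) if n else np.nan
                    )
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    min_expected: float
    low_expected: bool  # any expected cell count < 5


def chi_square(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    statistic = sum (O−E)²/E with E from the product of the marginals;
    df = (r−1)(c−1); p is the upper tail of the chi-square
    distribution. A zero row or column marginal raises (E undefined).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError(f"need an r x c table with r,c >= 2, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValidationError("negative counts in contingency table")
    total = obs.sum()
    row_m = obs.sum(axis=1)
    col_m = obs.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        raise ValidationError("zero marginal: expected counts undefined")
    expected = np.outer(row_m, col_m) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return ChiSquareResult(statistic=stat, df=df, p=p,
                           min_expected=float(expected.min()),
                           low_expected=bool((expected < 5).any()))


# ---------------------------------------------------------------------------
# prediction probabilities


@dataclass
class PredictionRow:
    """Probability that a qualifying methylation change predicts an
    opposite-direction expression change.

    direction 'decrease' = fetal-to-adult methylation loss (dβ <= −cut),
    whose opposite-direction expression event is adult overexpression;
    'increase' (dβ >= +cut) pairs with fetal overexpression."""

    direction: str
    dbeta_cut: float
    region: str
    n_cpgs: int
    p_ge2fold: float | None
    p_ge5fold: float | None
    empty: bool


def prediction_probability(records: pd.DataFrame, direction: str,
                           dbeta_cut: float, region: RegionClass,
                           fold_cuts=(2.0, 5.0), q_cut: float = 0.05,
                           require_expr_q: bool = True) -> PredictionRow:
    """Fraction of qualifying CpGs whose gene shows an opposite-direction
    expression change of at least each fold cut.

    Qualifying: methylation q <= q_cut, region class matches, and dβ
    beyond ``dbeta_cut`` in the stated direction. The expression event
    additionally requires expression q <= q_cut unless
    ``require_expr_q`` is off. A CpG linked to several genes qualifies
    if ANY linked gene meets the expression event (records are
    per-link; duplicate CpG ids collapse to 'any gene hit').
    """
    if direction not in ("decrease", "increase"):
        raise ValidationError(f"direction must be decrease/increase, got {direction!r}")
    db = records["delta_beta"].to_numpy()
    qual = (records["meth_q"].to_numpy() <= q_cut)
    qual &= (records["region_class"] == region.value).to_numpy()
    if direction == "decrease":
        qual &= db <= -dbeta_cut
    else:
        qual &= db >= dbeta_cut
    sub = records[qual]
    n = int(sub["cpg_id"].nunique())
    if n == 0:
        return PredictionRow(direction, dbeta_cut, region.value, 0,
                             None, None, empty=True)
    fc = sub["fold_change"].to_numpy()
    expr_ok = np.ones(len(sub), dtype=bool)
    if require_expr_q:
        expr_ok &= sub["expr_q"].to_numpy() <= q_cut
    probs = []
    for cut in fold_cuts:
        if direction == "decrease":       # expect adult overexpression
            hit = expr_ok & (fc <= -cut)
        else:                             # expect fetal overexpression
            hit = expr_ok & (fc >= cut)
        n_hit = int(sub.loc[hit, "cpg_id"].nunique())
        probs.append(n_hit / n)
    return PredictionRow(direction, dbeta_cut, region.value, n,
                         probs[0], probs[1], empty=False)


def prediction_table(records: pd.DataFrame, dbeta_cuts=(0.2, 0.5),
                     fold_cuts=(2.0, 5.0), q_cut: float = 0.05,
                     require_expr_q: bool = True) -> pd.DataFrame:
    """The full prediction-probability layout: both directions, both dβ
    cuts, both region classes (8 rows)."""
    rows = []
    for direction in ("decrease", "increase"):
        for cut in dbeta_cuts:
            for region in (RegionClass.TSS_EX1, RegionClass.UTR_GB):
                r = prediction_probability(records, direction, cut, region,
                                           fold_cuts, q_cut, require_expr_q)
                rows.append(
                    {
                        "direction": r.direction,
                        "dbeta_cut": r.dbeta_cut,
                        "region_class": r.region,
                        "n_cpgs": r.n_cpgs,
                        "p_ge2fold": r.p_ge2fold,
                        "p_ge5fold": r.p_ge5fold,
                        "empty": r.empty,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# density summaries


def density_summary(records: pd.DataFrame, stratify_by: str = "region_class",
                    contexts=(ExpressionClass.FETAL_OVER,
                              ExpressionClass.ADULT_OVER,
                              ExpressionClass.SIMILAR),
                    bin_width: float = 0.05) -> pd.DataFrame:
    """Normalized beta densities per (tissue, context, stratum).

    ``stratify_by`` is 'region_class' or 'fine_region' (the latter
    requires records built from uncollapsed links carrying a
    fine_region column). Densities integrate to 1 over [0,1]; empty
    strata are omitted. Returns tidy rows (tissue, context, stratum,
    bin_left, bin_right, density, n).
    """
    if stratify_by not in records.columns:
        raise ValidationError(f"no column {stratify_by!r} in records")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    edges[-1] = 1.0
    rows = []
    for ctx in contexts:
        ctx = ExpressionClass(ctx)
        sub_ctx = records[records["expr_class"] == ctx.value]
        for stratum, sub in sub_ctx.groupby(stratify_by):
            for tissue, col in (("fetal", "beta_fetal"),
                                ("adult", "beta_adult")):
                vals = sub[col].to_numpy()
                if len(vals) == 0:
                    continue
                dens, _ = np.histogram(vals, bins=edges, density=True)
                for i in range(len(dens)):
                    rows.append(
                        {
                            "tissue": tissue,
                            "context": ctx.value,
                            "stratum": stratum,
                            "bin_left": edges[i],
                            "bin_right": edges[i + 1],
                            "density": dens[i],
                            "n": len(vals),
                        }
                    )
    return pd.DataFrame(rows)
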