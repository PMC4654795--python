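"""Readers and writers for the tables the pipeline touches.

All files are tab-delimited UTF-8 with a header row. Matrices carry
feature ids in the first column and sample ids in the header. Missing
beta values are encoded as ``NA`` and propagated as NaN; downstream
statistics exclude them pairwise.

The CpG annotation follows the Illumina 450K manifest column naming
(``IlmnID``, ``CHR``, ``MAPINFO``, ``UCSC_RefGene_Name``,
``UCSC_RefGene_Group``, ``Regulatory_Feature_Group``) so that a real
manifest extract drops in unchanged. Gene and gene-region lists are
semicolon-separated parallel lists, deduplicated on read.
"""

from __future__ import annotations

import io
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: The six RefGene region labels the 450K manifest uses.
REFGENE_GROUPS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")

#: Recognised sample group labels (the two-group design).
GROUP_LABELS = ("fetal", "adult")

ANNOTATION_COLUMNS = (
    "IlmnID",
    "CHR",
    "MAPINFO",
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "Regulatory_Feature_Group",
)

MATRIX_KINDS = ("beta", "detection_p", "expression")

#: float format used by every writer; round-trips doubles to <1e-10 relative.
FLOAT_FORMAT = "%.12g"


def normalize_chromosome(label: str) -> str:
    """Strip an optional ``chr`` prefix and uppercase, so the manifest's
    ``X`` and UCSC's ``chrX`` compare equal."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()


def _check_unique(ids: Iterable[str], what: str, path) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate {what} id(s): {dups[:5]}")


def validate_matrix(df: pd.DataFrame, kind: str, path="<memory>") -> pd.DataFrame:
    """Validate a feature-by-sample matrix against its type invariants.

    kind='beta': values in [0,1] or NaN. kind='detection_p': values in
    [0,1], no NaN. kind='expression': finite values, no NaN.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    _check_unique(df.index, "feature", path)
    _check_unique(df.columns, "sample", path)
    values = df.to_numpy(dtype=float)
    if kind in ("beta", "detection_p"):
        bad = (values < 0) | (values > 1)
        if kind == "detection_p":
            bad |= np.isnan(values)
        else:
            bad &= ~np.isnan(values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"{path}: {kind} value {values[r, c]!r} out of [0,1] at "
                f"feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )
    else:  # expression
        bad = ~np.isfinite(values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"{path}: non-finite expression value at feature "
                f"{df.index[r]!r}, sample {df.columns[c]!r}"
            )
    out = df.astype(float)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    return out


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read a TSV matrix (first column feature ids, header sample ids)."""
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
        )
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse matrix TSV: {exc}") from exc
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry: {exc}") from exc
    return validate_matrix(df, kind, path)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA",
              index_label="id")


def _split_list(text) -> list[str]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    return [t.strip() for t in text.split(";")]


def parse_annotation_row(probe: str, genes: str, groups: str):
    """Split the parallel semicolon lists into deduplicated (gene, group)
    pairs, preserving first-seen order."""
    gene_list = _split_list(genes)
    group_list = _split_list(groups)
    if len(gene_list) != len(group_list):
        raise ValidationError(
            f"probe {probe!r}: gene list ({len(gene_list)}) and RefGene group "
            f"list ({len(group_list)}) have unequal lengths"
        )
    for g in group_list:
        if g not in REFGENE_GROUPS:
            raise ValidationError(
                f"probe {probe!r}: unknown RefGene group {g!r} "
                f"(allowed: {REFGENE_GROUPS})"
            )
    pairs: list[tuple[str, str]] = []
    for pair in zip(gene_list, group_list):
        if pair not in pairs:
            pairs.append(pair)
    return pairs


def validate_annotation(df: pd.DataFrame, path="<memory>") -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing column(s) {missing}")
    _check_unique(df["IlmnID"], "probe", path)
    out = df.loc[:, list(ANNOTATION_COLUMNS)].copy()
    out["IlmnID"] = out["IlmnID"].astype(str)
    out["CHR"] = out["CHR"].astype(str)
    out["pairs"] = [
        parse_annotation_row(p, g, r)
        for p, g, r in zip(out["IlmnID"], out["UCSC_RefGene_Name"],
                           out["UCSC_RefGene_Group"])
    ]
    out["Regulatory_Feature_Group"] = (
        out["Regulatory_Feature_Group"].fillna("").astype(str)
    )
    return out.set_index("IlmnID", drop=False)


def read_annotation(path) -> pd.DataFrame:
    """Read a 450K-manifest-style annotation TSV.

    Returns a frame indexed by probe id with the manifest columns plus a
    ``pairs`` column of deduplicated (gene, RefGene group) tuples.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=[""],
                         keep_default_na=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse annotation TSV: {exc}") from exc
    return validate_annotation(df, path)


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def validate_design(df: pd.DataFrame, path="<memory>") -> pd.DataFrame:
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: design missing column {col!r}")
    _check_unique(df["sample_id"], "sample", path)
    bad = df.loc[~df["group"].isin(GROUP_LABELS), "group"]
    if len(bad):
        raise ValidationError(
            f"{path}: unknown group label(s) {sorted(bad.unique())} "
            f"(allowed: {GROUP_LABELS})"
        )
    counts = df["group"].value_counts()
    for grp in GROUP_LABELS:
        if counts.get(grp, 0) < 2:
            raise ValidationError(
                f"{path}: group {grp!r} has {counts.get(grp, 0)} sample(s); "
                f"need at least 2 per group"
            )
    out = df.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    covars = [c for c in out.columns if c not in ("sample_id", "group")]
    for c in covars:
        try:
            out[c] = out[c].astype(float)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: covariate column {c!r} is not numeric: {exc}"
            ) from exc
    return out.set_index("sample_id", drop=False)


def read_design(path) -> pd.DataFrame:
    """Read the sample design table (sample_id, group[, covariates...])."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse design TSV: {exc}") from exc
    return validate_design(df, path)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def check_design_covers(matrix: pd.DataFrame, design: pd.DataFrame,
                        path="<memory>") -> None:
    """Ensure every matrix column appears in the design."""
    missing = [c for c in matrix.columns if c not in design.index]
    if missing:
        raise ValidationError(
            f"{path}: sample(s) {missing} absent from the design table"
        )


def group_samples(design: pd.DataFrame) -> dict[str, list[str]]:
    """Map group label -> ordered list of sample ids."""
    return {
        grp: design.loc[design["group"] == grp, "sample_id"].tolist()
        for grp in GROUP_LABELS
    }


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a generic result table with the package's float format."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA",
              index=index)
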