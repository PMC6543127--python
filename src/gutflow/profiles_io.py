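"""Readers/writers for tabular profiles plus normalisation, annotation
aggregation and the abundance/prevalence feature filter.

All on-disk tables are plain TSV: tab-delimited, UTF-8, '.' decimal, no
quoting. Matrices carry a header row of sample ids and feature ids in the
first column.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, validate_metadata

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_annotation_map",
    "relative_abundance",
    "aggregate_by_annotation",
    "filter_features",
]


def read_matrix(path, kind: str = "depth") -> AbundanceMatrix:
    """Read a features x samples TSV into an :class:`AbundanceMatrix`.

    Rejects ragged rows, missing cells, negative values and duplicate ids,
    naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return AbundanceMatrix(df, kind=kind)


def write_matrix(m: AbundanceMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, header=0)
    meta.index = meta.index.astype(str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation_map(path) -> pd.DataFrame:
    """Read a gene->feature annotation TSV with columns gene_id, feature_id, level."""
    amap = pd.read_csv(path, sep="\t", header=0, dtype=str)
    required = {"gene_id", "feature_id"}
    if not required.issubset(amap.columns):
        raise ValueError(f"annotation map must have columns {sorted(required)}")
    return amap


def relative_abundance(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample column by its total. Idempotent on relative input."""
    if m.kind == "relative":
        return m
    values = m.values()
    totals = values.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        bad = m.data.columns[np.argmax(zero)]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    rel = pd.DataFrame(values / totals, index=m.data.index, columns=m.data.columns)
    return AbundanceMatrix(rel, kind="relative")


def aggregate_by_annotation(
    genes: AbundanceMatrix, annotation: pd.DataFrame
) -> tuple[AbundanceMatrix, pd.Series]:
    """Sum gene abundances over genes annotated to the same feature.

    Returns the aggregated matrix plus the per-sample total abundance of
    genes absent from the annotation map (the unmapped share). Per sample,
    aggregated totals + unmapped share equal the input total exactly.
    """
    if annotation.empty:
        raise ValueError("annotation map is empty")
    mapping = annotation.set_index("gene_id")["feature_id"]
    present = mapping.index.intersection(genes.data.index)
    if len(present) == 0:
        warnings.warn("no annotated gene overlaps the matrix; result is empty")
    sub = genes.data.loc[present]
    agg = sub.groupby(mapping.loc[present]).sum()
    agg = agg.sort_index()
    unmapped_ids = genes.data.index.difference(mapping.index)
    unmapped_share = genes.data.loc[unmapped_ids].sum(axis=0)
    unmapped_share.name = "unmapped"
    return AbundanceMatrix(agg, kind=genes.kind), unmapped_share


def filter_features(
    m: AbundanceMatrix, min_mean: float = 1e-4, min_prevalence: int = 6
) -> AbundanceMatrix:
    """Keep features with mean relative abundance >= ``min_mean`` across all
    samples and strictly positive abundance in >= ``min_prevalence`` samples.

    The thresholds follow the common metagenomic inclusion criterion (mean
    relative abundance at least 1e-4, detected in at least 6 samples),
    evaluated on the pooled cohort. Feature order is preserved.
    """
    if m.kind != "relative":
        raise ValueError("filter_features expects a relative abundance matrix")
    values = m.values()
    keep = (values.mean(axis=1) >= min_mean) & ((values > 0).sum(axis=1) >= min_prevalence)
    return AbundanceMatrix.unchecked(m.data.loc[keep], m.kind)
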