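"""Expression-matrix handling: I/O, filtering, normalization, probe collapse.

The pipeline consumes a pre-summarized probe x sample intensity matrix
(e.g. an Affymetrix series matrix exported as TSV). Preprocessing follows
the usual microarray sequence: drop unexpressed rows, quantile-normalize
across samples, log2-transform, collapse probes to gene symbols by mean,
and split the gene-level matrix into mRNA and lncRNA partitions using a
probe annotation table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats  # noqa: F401  (rankdata alternative kept for reference)

logger = logging.getLogger(__name__)

#: Columns every probe annotation table must provide.
ANNOTATION_COLUMNS = ("probe_id", "gene_symbol", "biotype", "chromosome_band", "start", "end")

VALID_BIOTYPES = frozenset({"mRNA", "lncRNA"})


@dataclass
class ExpressionMatrix:
    """A probe- or gene-level expression matrix with sample group labels.

    Parameters
    ----------
    values
        DataFrame of intensities, rows indexed by probe/gene identifiers,
        columns by sample identifiers.
    sample_groups
        Mapping of every sample column to its group label (e.g. ``day0`` /
        ``day8``).
    scale
        ``"linear"`` for raw intensities, ``"log2"`` after log transform.
    level
        ``"probe"`` or ``"gene"``.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str] = field(repr=False)
    scale: str = "linear"
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        if self.level == "gene" and self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers at gene level: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        """Sample columns belonging to ``group``, in column order."""
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="id", float_format="%.6g")


def read_group_map(path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>group`` TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"group map {path} needs columns (sample, group)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression_matrix(path, group_map_path, scale: str = "linear") -> ExpressionMatrix:
    """Read a probe x sample TSV matrix plus a sample->group map.

    The first column holds probe identifiers; the header row holds sample
    identifiers. Every sample column must be assigned a group in the map.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric values in columns {non_numeric}")
    df.columns = [str(c) for c in df.columns]
    groups = read_group_map(group_map_path)
    unassigned = [s for s in df.columns if s not in groups]
    if unassigned:
        raise ValueError(f"samples missing from group map: {unassigned}")
    return ExpressionMatrix(values=df.astype(float), sample_groups=groups, scale=scale, level="probe")


def read_probe_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV (probe_id, gene_symbol, biotype, chromosome_band, start, end).

    Returns a DataFrame indexed by ``probe_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} missing columns {missing}")
    df = df.set_index("probe_id")
    validate_annotation(df)
    return df


def validate_annotation(annot: pd.DataFrame) -> None:
    if annot.index.has_duplicates:
        dups = annot.index[annot.index.duplicated()].unique().tolist()
        raise ValueError(f"probes annotated more than once: {dups}")
    bad_biotype = sorted(set(annot["biotype"]) - VALID_BIOTYPES)
    if bad_biotype:
        raise ValueError(f"unknown biotypes {bad_biotype}; expected one of {sorted(VALID_BIOTYPES)}")
    if (annot["start"] >= annot["end"]).any():
        offenders = annot.index[annot["start"] >= annot["end"]].tolist()
        raise ValueError(f"start >= end for probes {offenders}")


def filter_unexpressed(
    mat: ExpressionMatrix, min_value: float = 0.0, min_fraction: float = 1.0
) -> ExpressionMatrix:
    """Drop rows not expressed above ``min_value`` in at least ``min_fraction`` of samples.

    With the defaults (0, 1.0) this removes rows that are <= 0 everywhere,
    i.e. the zero-expression filter. Row order is preserved.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    frac_above = (mat.values > min_value).mean(axis=1)
    keep = frac_above >= min_fraction
    kept = mat.values.loc[keep]
    logger.info("filter_unexpressed: kept %d of %d rows", kept.shape[0], mat.values.shape[0])
    return replace(mat, values=kept)


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common distribution of mean order statistics.

    After the operation every column holds the identical multiset of values:
    the across-column mean of the k-th smallest values becomes the k-th
    smallest value of every column. Ties within a column receive the mean of
    the target values their positions span, which makes the operation
    deterministic and idempotent.
    """
    if mat.values.shape[1] < 2:
        warnings.warn("quantile_normalize: single-column matrix returned unchanged")
        return mat
    arr = mat.values.to_numpy(dtype=float)
    mean_order_stats = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = mean_order_stats
        # average target values over tied input positions
        out[:, j] = pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)
    return replace(mat, values=values)


def log2_transform(mat: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset); flips the scale flag and guards against double logging."""
    if mat.scale == "log2":
        raise ValueError("matrix is already on the log2 scale (double-log guard)")
    if offset < 0:
        raise ValueError(f"offset must be >= 0, got {offset}")
    shifted = mat.values + offset
    if (shifted.to_numpy() <= 0).any():
        raise ValueError("non-positive value under log; increase offset")
    return replace(mat, values=np.log2(shifted), scale="log2")


def collapse_probes(mat: ExpressionMatrix, annot: pd.DataFrame) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by per-sample arithmetic mean.

    Probes absent from the annotation are dropped (count logged). Gene rows
    come out sorted by symbol for reproducible output.
    """
    if mat.level != "probe":
        raise ValueError("collapse_probes expects a probe-level matrix")
    annotated = mat.values.index.intersection(annot.index)
    if len(annotated) == 0:
        raise ValueError("no probe of the matrix is present in the annotation")
    n_dropped = mat.values.shape[0] - len(annotated)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unannotated probes", n_dropped)
    sub = mat.values.loc[annotated]
    genes = annot.loc[annotated, "gene_symbol"]
    collapsed = sub.groupby(genes).mean()
    collapsed.index.name = None
    return replace(mat, values=collapsed, level="gene")


def gene_biotypes(annot: pd.DataFrame) -> pd.Series:
    """Map gene symbol -> biotype; error if a gene's probes disagree."""
    per_gene = annot.groupby("gene_symbol")["biotype"].agg(set)
    conflicts = per_gene[per_gene.map(len) > 1]
    if len(conflicts):
        raise ValueError(f"genes with conflicting biotypes across probes: {sorted(conflicts.index)}")
    return per_gene.map(lambda s: next(iter(s)))


def split_by_biotype(
    mat: ExpressionMatrix, annot: pd.DataFrame
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition a gene-level matrix into (mRNA, lncRNA) matrices."""
    if mat.level != "gene":
        raise ValueError("split_by_biotype expects a gene-level matrix")
    biotype = gene_biotypes(annot)
    unknown = mat.values.index.difference(biotype.index)
    if len(unknown):
        raise ValueError(f"genes without biotype annotation: {sorted(unknown)}")
    bt = biotype.loc[mat.values.index]
    mrna = replace(mat, values=mat.values.loc[bt == "mRNA"])
    lncrna = replace(mat, values=mat.values.loc[bt == "lncRNA"])
    return mrna, lncrna
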