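"""Readers and writers for the pipeline's tabular artifacts.

Matrices travel as TSV (UTF-8, ``.`` decimal, plain integers for counts);
sample metadata and phenotype records as CSV.  Readers validate strictly and
round-trip with the writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import CLUSTERS, ClusterMembership, cluster_subtypes
from .design import DesignError, DesignSpec, Sample

log = logging.getLogger(__name__)


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its invariants."""


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample matrix."""

    data: pd.DataFrame  # index gene_id, columns sample_id, integer dtype

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate gene IDs: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate sample IDs: {dup}")
        if not all(np.issubdtype(t, np.integer) for t in df.dtypes):
            raise CountMatrixError("counts must be integers")
        if (df.to_numpy() < 0).any():
            bad = df.columns[(df < 0).any(axis=0)].tolist()
            raise CountMatrixError(f"negative counts in samples {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def library_sizes(self) -> pd.Series:
        """Total counts per sample over the supplied gene universe."""
        return self.data.sum(axis=0)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column gene IDs, header row sample IDs)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.ParserError as e:  # ragged rows: pandas reports the line
        raise CountMatrixError(f"{path}: malformed TSV: {e}") from e
    except pd.errors.EmptyDataError as e:
        raise CountMatrixError(f"{path}: empty file") from e
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise CountMatrixError(f"{path}: missing values in rows {rows[:5]}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise CountMatrixError(f"{path}: non-numeric cells present")
    if not np.allclose(arr, np.round(arr)):
        raise CountMatrixError(f"{path}: non-integer counts present")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> DesignSpec:
    """Read a CSV sample sheet (sample_id, species, sex, tissue, replicate)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise DesignError(f"{path}: empty sample sheet") from e
    required = ["sample_id", "species", "sex", "tissue", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DesignError(f"{path}: missing columns {missing}")
    if df.empty:
        raise DesignError(f"{path}: sample sheet has no rows")
    samples = [
        Sample(str(r.sample_id), str(r.species), str(r.sex), str(r.tissue), int(r.replicate))
        for r in df.itertuples()
    ]
    return DesignSpec(samples)


def write_sample_sheet(design: DesignSpec, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def check_samples_match(cm: CountMatrix, design: DesignSpec) -> None:
    """Require identical sample sets in the count matrix and the sheet."""
    in_counts = set(cm.sample_ids)
    in_sheet = set(design.sample_ids)
    only_counts = sorted(in_counts - in_sheet)
    only_sheet = sorted(in_sheet - in_counts)
    if only_counts or only_sheet:
        raise DesignError(
            f"sample mismatch: only in counts {only_counts}; only in sheet {only_sheet}"
        )


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, length_bp) -> Series of lengths."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, length_bp)")
    s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    if (s <= 0).any():
        bad = s.index[s <= 0].tolist()
        raise ValueError(f"{path}: non-positive lengths for {bad[:5]}")
    s.name = "length_bp"
    s.index.name = "gene_id"
    return s


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": lengths.index, "length_bp": lengths.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def match_lengths(cm: CountMatrix, lengths: pd.Series) -> tuple[CountMatrix, pd.Series]:
    """Subset the matrix to genes with a known length.

    Genes missing from the length table are dropped with a warning rather
    than given a default, since a silently-defaulted length corrupts FPKM.
    """
    have = cm.gene_ids.intersection(lengths.index)
    dropped = cm.gene_ids.difference(lengths.index)
    if len(dropped):
        log.warning("dropping %d genes with no length entry (e.g. %s)",
                    len(dropped), list(dropped[:3]))
    if not len(have):
        raise ValueError("no genes left after matching the length table")
    return CountMatrix(cm.data.loc[have]), lengths.loc[have].astype(float)


def gene_lengths_from_gtf(path: str | Path, attribute: str = "gene_id") -> pd.Series:
    """Reduce a GTF/GFF annotation to per-gene summed exon length.

    Overlapping exons of one gene are merged before summing, so the result is
    the length of the exonic footprint.  The attribute key naming the gene is
    configurable (default ``gene_id``).
    """
    import re

    pat = re.compile(rf'{attribute}[ =]+"?([^";]+)"?')
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            m = pat.search(f[8])
            if not m:
                continue
            exons.setdefault(m.group(1), []).append((int(f[3]), int(f[4])))
    out = {}
    for gene, ivs in exons.items():
        ivs.sort()
        total, cur_s, cur_e = 0, *ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        out[gene] = total
    if not out:
        raise ValueError(f"{path}: no exon features with attribute {attribute!r}")
    s = pd.Series(out, name="length_bp", dtype=float).sort_index()
    s.index.name = "gene_id"
    return s


# --- DE tables --------------------------------------------------------------

DE_COLUMNS = ["log2fc", "pvalue", "fdr", "mean_fpkm_a", "mean_fpkm_b"]


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    """DE table TSV: gene_id, log2fc, pvalue, fdr, mean FPKMs, comparison_id.

    Group orientation (B over A) is carried in the ``group_a`` / ``group_b``
    attrs and echoed into columns for self-description on disk.
    """
    df = de[DE_COLUMNS].copy()
    df.insert(0, "gene_id", de.index)
    df["comparison_id"] = de.attrs.get("comparison_id", "")
    df["group_a"] = de.attrs.get("group_a", "")
    df["group_b"] = de.attrs.get("group_b", "")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_de_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a DE table; ``column_map`` renames externally-produced columns
    onto the canonical schema (e.g. ``{"logFC": "log2fc", "FDR": "fdr"}``)."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ["gene_id", *DE_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: DE table missing columns {missing}")
    out = df.set_index(df["gene_id"].astype(str))[DE_COLUMNS].astype(float)
    out.index.name = "gene_id"
    for key in ("comparison_id", "group_a", "group_b"):
        if key in df.columns and len(df):
            out.attrs[key] = str(df[key].iloc[0])
    bad = out.index[(out["fdr"] < 0) | (out["fdr"] > 1) | (out["pvalue"] < 0) | (out["pvalue"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: p/FDR outside [0,1] for {bad[:5].tolist()}")
    return out


# --- cluster membership -----------------------------------------------------


def write_membership(m: ClusterMembership, path: str | Path) -> None:
    """Serialize membership in the presence/absence convention: a 0/1 column
    per (cluster, subtype) plus a label column per cluster."""
    df = m.indicator_frame()
    df.insert(0, "gene_id", df.index)
    df.to_csv(path, sep="\t", index=False)


def read_membership(path: str | Path) -> ClusterMembership:
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    df.index = df.index.astype(str)
    cols = {}
    for c in CLUSTERS:
        label_col = f"{c}__label"
        if label_col not in df.columns:
            raise ValueError(f"{path}: missing column {label_col}")
        cols[c] = df[label_col].astype(str)
        # cross-check the indicator columns against the labels
        for st in cluster_subtypes(c):
            if st == "none":
                continue
            ind_col = f"{c}__{st}"
            if ind_col in df.columns:
                expect = (cols[c] == st).astype(int)
                if not (df[ind_col].astype(int) == expect).all():
                    raise ValueError(f"{path}: indicator column {ind_col} contradicts labels")
    return ClusterMembership(pd.DataFrame(cols, index=df.index))


def write_fpkm(fpkm: pd.DataFrame, path: str | Path) -> None:
    df = fpkm.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_fpkm(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)
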