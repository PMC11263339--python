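"""Threshold-based expression categories and the five expression clusters.

Each pairwise comparison of group-mean FPKMs is assigned one of four
categories with a fixed decision tree:

1. *low* — mean FPKM below 1 in both groups;
2. *unbiased* — not low, and either FDR > 0.05 or \\|log2FC\\| <= 2;
3. *specific* — significant with \\|log2FC\\| > 2 and the losing group's mean
   FPKM below 1;
4. *biased* — significant with \\|log2FC\\| > 2 and both means >= 1.

Per-comparison categories are then combined, using pure-species samples only,
into five clusters: sex within reproductive organs (REPRODUCTIVE_SEX), sex
within carcass (CARCASS_SEX), species within each tissue
(REPRODUCTIVE_SPECIES / CARCASS_SPECIES), and tissue within every
(species, sex) pair (TISSUE).  A gene joins a cluster as ``X_specific`` when
every constituent comparison is specific toward the same factor level, and
as ``X_biased`` when every comparison is specific or biased toward that
level with at least one biased call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import group_key

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds: low-expression FPKM cutoff, log2 fold-change
    cutoff, and BH-adjusted significance level."""

    fpkm_low: float = 1.0
    lfc: float = 2.0
    fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.fpkm_low <= 0 or self.lfc <= 0 or self.fdr <= 0:
            raise ValueError("all thresholds must be > 0")


LABELS = ("low", "unbiased", "biased", "specific")
DIRECTIONS = ("A_high", "B_high", "none")


@dataclass(frozen=True)
class PairCategory:
    label: str
    direction: str = "none"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if (self.direction == "none") != (self.label in ("low", "unbiased")):
            raise ValueError(
                f"direction {self.direction!r} inconsistent with label {self.label!r}"
            )


def categorize_pair(
    mean_fpkm_a: float,
    mean_fpkm_b: float,
    log2fc: float,
    fdr: float | None,
    t: Thresholds = Thresholds(),
) -> PairCategory:
    """Assign one comparison row to low / unbiased / specific / biased.

    ``log2fc`` is oriented B over A; the returned direction names the group
    with the higher mean.  ``fdr`` may be None only when the fold change is
    inside the unbiased band.
    """
    if mean_fpkm_a < t.fpkm_low and mean_fpkm_b < t.fpkm_low:
        return PairCategory("low")
    if math.isnan(log2fc):
        raise ValueError("log2FC is NaN; cannot categorize")
    if abs(log2fc) <= t.lfc:
        return PairCategory("unbiased")
    if fdr is None or math.isnan(fdr):
        raise ValueError("significant-sized fold change but no FDR available")
    if fdr > t.fdr:
        return PairCategory("unbiased")
    direction = "B_high" if log2fc > 0 else "A_high"
    low_side = mean_fpkm_a if direction == "B_high" else mean_fpkm_b
    if low_side < t.fpkm_low:
        return PairCategory("specific", direction)
    return PairCategory("biased", direction)


# --- cluster definitions ----------------------------------------------------

CLUSTERS = (
    "REPRODUCTIVE_SEX",
    "REPRODUCTIVE_SPECIES",
    "CARCASS_SEX",
    "CARCASS_SPECIES",
    "TISSUE",
)

#: factor levels a cluster's subtypes are named after
CLUSTER_LEVELS = {
    "REPRODUCTIVE_SEX": ("male", "female"),
    "CARCASS_SEX": ("male", "female"),
    "REPRODUCTIVE_SPECIES": ("U", "M"),
    "CARCASS_SPECIES": ("U", "M"),
    "TISSUE": ("reproductive", "carcass"),
}


def cluster_subtypes(cluster: str) -> tuple[str, ...]:
    a, b = CLUSTER_LEVELS[cluster]
    return (
        f"{a}_specific",
        f"{a}_biased",
        f"{b}_specific",
        f"{b}_biased",
        "low",
        "none",
    )


def cluster_comparisons(cluster: str) -> list[tuple[str, str, str]]:
    """Pure-species comparisons defining a cluster.

    Each entry is ``(comparison_id, group_A, group_B)``; log2FC is oriented
    B over A, and group_A / group_B carry the first / second factor level of
    :data:`CLUSTER_LEVELS` so that direction maps onto subtype names.
    """
    out = []
    if cluster in ("REPRODUCTIVE_SEX", "CARCASS_SEX"):
        tissue = "reproductive" if cluster == "REPRODUCTIVE_SEX" else "carcass"
        for sp in ("U", "M"):
            out.append(
                (
                    f"{cluster}:{sp}",
                    group_key(sp, "male", tissue),
                    group_key(sp, "female", tissue),
                )
            )
    elif cluster in ("REPRODUCTIVE_SPECIES", "CARCASS_SPECIES"):
        tissue = "reproductive" if cluster == "REPRODUCTIVE_SPECIES" else "carcass"
        for sex in ("male", "female"):
            out.append(
                (
                    f"{cluster}:{sex}",
                    group_key("U", sex, tissue),
                    group_key("M", sex, tissue),
                )
            )
    elif cluster == "TISSUE":
        for sp in ("U", "M"):
            for sex in ("male", "female"):
                out.append(
                    (
                        f"TISSUE:{sp}_{sex}",
                        group_key(sp, sex, "reproductive"),
                        group_key(sp, sex, "carcass"),
                    )
                )
    else:
        raise ValueError(f"unknown cluster {cluster!r}")
    return out


def build_cluster(
    cluster: str,
    pair_categories: dict[str, pd.DataFrame],
    rule: str = "any",
) -> pd.Series:
    """Combine per-comparison categories into one cluster's subtype column.

    ``pair_categories`` maps comparison_id -> DataFrame indexed by gene with
    columns ``label`` and ``direction``.  The default ``rule="any"`` treats
    low and unbiased comparisons as uninformative: a gene joins the cluster
    when at least one comparison is directed (specific or biased) and no
    comparison is directed the other way — ``<level>_specific`` when all
    directed calls are specific, ``<level>_biased`` otherwise.  This is the
    rule that lets a gene be, say, both female-specific and
    reproductive-specific (such a gene is unavoidably low in the male-side
    tissue comparisons).  The strict ``rule="all"`` variant demands every
    constituent comparison be directed and consistent.  Genes low in every
    comparison get subtype ``low``; any other mixture gets ``none``.
    """
    if rule not in ("all", "any"):
        raise ValueError(f"unknown combine rule {rule!r}")
    comps = cluster_comparisons(cluster)
    missing = [c[0] for c in comps if c[0] not in pair_categories]
    if missing:
        raise KeyError(f"cluster {cluster}: missing comparison tables {missing}")
    frames = [pair_categories[c[0]] for c in comps]
    genes = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(genes):
            raise ValueError(f"cluster {cluster}: comparison tables disagree on gene set")

    labels = np.stack([f["label"].to_numpy() for f in frames])  # (ncomp, ngene)
    a_level, b_level = CLUSTER_LEVELS[cluster]
    level = np.where(
        np.stack([f["direction"].to_numpy() for f in frames]) == "B_high", b_level, a_level
    )
    directed = (labels == "specific") | (labels == "biased")

    out = np.full(len(genes), "none", dtype=object)

    all_low = (labels == "low").all(axis=0)
    out[all_low] = "low"

    # consistent direction among directed calls
    n_directed = directed.sum(axis=0)
    first_level = np.take_along_axis(
        level, np.argmax(directed, axis=0)[None, :], axis=0
    )[0]
    consistent = np.ones(len(genes), dtype=bool)
    for i in range(labels.shape[0]):
        consistent &= ~directed[i] | (level[i] == first_level)

    if rule == "all":
        eligible = directed.all(axis=0) & consistent
    else:
        eligible = (n_directed >= 1) & consistent
    any_biased = (labels == "biased").any(axis=0)
    all_specific = (labels == "specific").all(axis=0) if rule == "all" else ~any_biased
    member_specific = eligible & all_specific
    member_biased = eligible & ~all_specific & any_biased
    for lev in (a_level, b_level):
        sel = first_level == lev
        out[member_specific & sel] = f"{lev}_specific"
        out[member_biased & sel] = f"{lev}_biased"

    n_conflict = int((n_directed >= 2).sum() - (consistent & (n_directed >= 2)).sum())
    if n_conflict:
        log.info("cluster %s: %d genes with conflicting directions set to none", cluster, n_conflict)
    return pd.Series(out, index=genes, name=cluster)


@dataclass
class ClusterMembership:
    """Gene x cluster table of subtype labels (one subtype per gene per cluster)."""

    table: pd.DataFrame  # index gene_id, columns CLUSTERS, values subtype strings

    def __post_init__(self) -> None:
        missing = [c for c in CLUSTERS if c not in self.table.columns]
        if missing:
            raise ValueError(f"membership table missing cluster columns {missing}")
        for c in CLUSTERS:
            bad = set(self.table[c]) - set(cluster_subtypes(c))
            if bad:
                raise ValueError(f"cluster {c}: unknown subtypes {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def members(self, cluster: str, subtype: str) -> pd.Index:
        if subtype not in cluster_subtypes(cluster):
            raise ValueError(f"{subtype!r} is not a subtype of {cluster}")
        return self.table.index[self.table[cluster] == subtype]

    def indicator_frame(self) -> pd.DataFrame:
        """Presence/absence view: one 0/1 column per (cluster, subtype) pair
        (the 'none' placeholder is not a column), plus a label column per
        cluster."""
        cols: dict[str, object] = {}
        for c in CLUSTERS:
            for st in cluster_subtypes(c):
                if st == "none":
                    continue
                cols[f"{c}__{st}"] = (self.table[c] == st).astype(int)
            cols[f"{c}__label"] = self.table[c]
        return pd.DataFrame(cols, index=self.table.index)


def build_all_clusters(
    de_tables: dict[str, pd.DataFrame],
    thresholds: Thresholds = Thresholds(),
    rule: str = "any",
) -> ClusterMembership:
    """Run the decision tree on every constituent comparison and combine.

    ``de_tables`` maps comparison_id -> DE table (columns ``mean_fpkm_a``,
    ``mean_fpkm_b``, ``log2fc``, ``fdr``, indexed by gene) for all 12
    pure-species comparisons named by :func:`cluster_comparisons`.
    """
    columns = {}
    for cluster in CLUSTERS:
        cats: dict[str, pd.DataFrame] = {}
        for comp_id, _ga, _gb in cluster_comparisons(cluster):
            if comp_id not in de_tables:
                raise KeyError(f"missing DE table for comparison {comp_id!r}")
            cats[comp_id] = categorize_table(de_tables[comp_id], thresholds)
        columns[cluster] = build_cluster(cluster, cats, rule=rule)
    return ClusterMembership(pd.DataFrame(columns))


def categorize_table(de: pd.DataFrame, t: Thresholds = Thresholds()) -> pd.DataFrame:
    """Vectorized :func:`categorize_pair` over a DE table; returns a DataFrame
    with ``label`` and ``direction`` columns indexed like ``de``."""
    a = de["mean_fpkm_a"].to_numpy(float)
    b = de["mean_fpkm_b"].to_numpy(float)
    lfc = de["log2fc"].to_numpy(float)
    fdr = de["fdr"].to_numpy(float)

    low = (a < t.fpkm_low) & (b < t.fpkm_low)
    big = np.abs(lfc) > t.lfc
    if np.isnan(lfc[~low]).any():
        raise ValueError("log2FC is NaN for a non-low gene; cannot categorize")
    if np.isnan(fdr[~low & big]).any():
        raise ValueError("significant-sized fold change but no FDR available")
    sig = big & ~np.isnan(fdr) & (fdr <= t.fdr)
    direction = np.where(lfc > 0, "B_high", "A_high")
    low_side = np.where(lfc > 0, a, b)

    label = np.full(len(de), "unbiased", dtype=object)
    label[low] = "low"
    label[~low & sig & (low_side < t.fpkm_low)] = "specific"
    label[~low & sig & (low_side >= t.fpkm_low)] = "biased"
    direction = np.where(np.isin(label, ("specific", "biased")), direction, "none")
    return pd.DataFrame({"label": label, "direction": direction}, index=de.index)
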