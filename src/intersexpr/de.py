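"""Two-group negative-binomial differential expression.

The test is an exact conditional test in the spirit of the classic NB exact
test for replicated count data: libraries are equalized by total-count
scaling to the geometric-mean library size, replicate sums within each group
are treated as NB (a sum of n iid NB(mean mu, dispersion phi) variables is
NB with mean n*mu and dispersion phi/n), and the two-sided p-value for a
gene is the total conditional probability — given the gene's grand total —
of all splits between the groups that are as likely or less likely than the
observed one.  Dispersions are per-gene method-of-moments estimates shrunk
toward the common value.

Fold changes are reported on mean FPKMs with a small prior count, and FDR is
Benjamini–Hochberg within each comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .design import DesignSpec
from .io import CountMatrix
from .quantify import compute_fpkm, group_mean_fpkm

log = logging.getLogger(__name__)

#: prior count (FPKM units) added to both group means before the log-ratio
LOG2FC_PRIOR = 0.25

#: shrinkage weight of the common dispersion in the per-gene estimate
DISPERSION_SHRINKAGE = 0.7

#: below this dispersion the conditional distribution is binomial (Poisson limit)
_PHI_POISSON = 1e-8


@dataclass
class DispersionEstimate:
    """Per-gene and common NB dispersions with a shrinkage weight."""

    per_gene: pd.Series  # floored moment estimates, >= 0
    common: float
    weight: float = DISPERSION_SHRINKAGE

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError("shrinkage weight must be in [0, 1]")
        if not np.isfinite(self.per_gene).all():
            raise ValueError("non-finite per-gene dispersion")

    @property
    def shrunk(self) -> pd.Series:
        """phi* = w * common + (1 - w) * per-gene."""
        return self.weight * self.common + (1 - self.weight) * self.per_gene


def equalize_libraries(
    counts: CountMatrix, samples: list[str] | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Rescale each sample's counts to the geometric-mean library size and round.

    Library sizes default to column sums over the full matrix; rounding keeps
    the pseudo-counts integral so the conditional test can enumerate splits.
    """
    if samples is None:
        samples = list(counts.sample_ids)
    sub = counts.data[samples]
    if library_sizes is None:
        n = counts.library_sizes()[samples].astype(float)
    else:
        n = library_sizes.reindex(samples).astype(float)
    if (n <= 0).any():
        raise ValueError(f"zero library size for {n.index[n <= 0].tolist()}")
    target = float(np.exp(np.mean(np.log(n))))
    return (sub * (target / n)).round().astype(np.int64)


def _group_moments(pseudo: pd.DataFrame, ids: list[str]) -> tuple[np.ndarray, np.ndarray, int]:
    x = pseudo[ids].to_numpy(float)
    return x.mean(axis=1), x.var(axis=1, ddof=1), len(ids)


def estimate_dispersion(
    counts: CountMatrix,
    design: DesignSpec,
    group_a: str,
    group_b: str,
    weight: float = DISPERSION_SHRINKAGE,
) -> DispersionEstimate:
    """Method-of-moments dispersion on equalized counts, shrunk to the common value.

    For each group with >= 2 replicates the raw estimate is
    ``(s^2 - m) / m^2``; group estimates are combined with weights
    ``n_k - 1`` and floored at zero.  The common value is the mean of the raw
    (unfloored) per-gene estimates, floored at zero.
    """
    ids_a = design.group_samples(group_a)
    ids_b = design.group_samples(group_b)
    if len(ids_a) < 2 and len(ids_b) < 2:
        raise ValueError(
            "dispersion cannot be estimated with a single replicate per group; "
            "supply a fixed dispersion instead"
        )
    pseudo = equalize_libraries(counts, ids_a + ids_b)
    num = np.zeros(len(counts.gene_ids))
    wsum = np.zeros(len(counts.gene_ids))
    for ids in (ids_a, ids_b):
        if len(ids) < 2:
            continue
        m, v, n = _group_moments(pseudo, ids)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(m > 0, (v - m) / np.square(m), np.nan)
        ok = ~np.isnan(raw)
        num[ok] += raw[ok] * (n - 1)
        wsum[ok] += n - 1
    with np.errstate(invalid="ignore"):
        raw_combined = np.where(wsum > 0, num / np.maximum(wsum, 1e-300), np.nan)
    informative = ~np.isnan(raw_combined)
    common = float(max(0.0, np.mean(raw_combined[informative]))) if informative.any() else 0.0
    per_gene = pd.Series(
        np.maximum(0.0, np.where(np.isfinite(raw_combined), raw_combined, 0.0)),
        index=counts.gene_ids,
    )
    return DispersionEstimate(per_gene=per_gene, common=common, weight=weight)


def exact_nb_pvalue(a_obs: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional p-value for one gene.

    Conditional on ``total`` (grand sum of equalized counts), the group-A sum
    follows a beta-binomial-type law with NB size parameters n_a/phi and
    n_b/phi; the p-value sums the probabilities of every split as or less
    likely than the observed one.  At phi -> 0 this is the conditional
    binomial of the Poisson model.
    """
    if total == 0:
        return 1.0
    if not 0 <= a_obs <= total:
        raise ValueError("observed group sum outside [0, total]")
    a = np.arange(total + 1)
    if phi < _PHI_POISSON:
        p_a = n_a / (n_a + n_b)
        logpmf = (
            gammaln(total + 1) - gammaln(a + 1) - gammaln(total - a + 1)
            + a * np.log(p_a) + (total - a) * np.log1p(-p_a)
        )
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        logpmf = (
            gammaln(a + r_a) - gammaln(a + 1)
            + gammaln(total - a + r_b) - gammaln(total - a + 1)
        )
    logpmf = logpmf - logsumexp(logpmf)
    keep = logpmf <= logpmf[a_obs] + 1e-10
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))


def nb_exact_test(
    counts: CountMatrix,
    design: DesignSpec,
    group_a: str,
    group_b: str,
    dispersion: DispersionEstimate | pd.Series | float | None = None,
) -> pd.Series:
    """Per-gene two-sided exact test p-values for group B vs group A.

    ``dispersion`` may be a :class:`DispersionEstimate` (its shrunk values are
    used), a per-gene Series, a scalar, or None (estimated from the data).
    All-zero genes get p = 1 by convention and are counted in a log message.
    """
    ids_a = design.group_samples(group_a)
    ids_b = design.group_samples(group_b)
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"groups overlap on samples {sorted(overlap)}")
    if dispersion is None:
        dispersion = estimate_dispersion(counts, design, group_a, group_b)
    if isinstance(dispersion, DispersionEstimate):
        phi = dispersion.shrunk.reindex(counts.gene_ids).to_numpy(float)
    elif isinstance(dispersion, pd.Series):
        phi = dispersion.reindex(counts.gene_ids).to_numpy(float)
    else:
        phi = np.full(len(counts.gene_ids), float(dispersion))
    if np.isnan(phi).any() or (phi < 0).any():
        raise ValueError("dispersion must be finite and >= 0 for every gene")

    pseudo = equalize_libraries(counts, ids_a + ids_b)
    sum_a = pseudo[ids_a].sum(axis=1).to_numpy()
    total = sum_a + pseudo[ids_b].sum(axis=1).to_numpy()
    n_zero = int((total == 0).sum())
    if n_zero:
        log.info("%d all-zero genes assigned p = 1 by convention", n_zero)
    pvals = np.ones(len(total))
    for i in range(len(total)):
        if total[i] > 0:
            pvals[i] = exact_nb_pvalue(
                int(sum_a[i]), int(total[i]), len(ids_a), len(ids_b), float(phi[i])
            )
    return pd.Series(pvals, index=counts.gene_ids, name="pvalue")


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjusted values over one comparison."""
    arr = np.asarray(pvalues, dtype=float)
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(adj, index=pvalues.index, name="fdr")
    return adj


def compare_groups(
    counts: CountMatrix,
    design: DesignSpec,
    group_a: str,
    group_b: str,
    lengths: pd.Series | None = None,
    dispersion: DispersionEstimate | pd.Series | float | None = None,
    comparison_id: str | None = None,
    prior_fpkm: float = LOG2FC_PRIOR,
) -> pd.DataFrame:
    """Full two-group DE table: log2FC (B over A), exact-test p, BH FDR, and
    group-mean FPKMs.

    Gene lengths default to 1 kb (FPKM then coincides with counts per million
    up to a constant).
    """
    if lengths is None:
        lengths = pd.Series(1000.0, index=counts.gene_ids)
    fpkm = compute_fpkm(counts, lengths)
    means = group_mean_fpkm(fpkm, design)
    if group_a not in means.columns or group_b not in means.columns:
        missing = [g for g in (group_a, group_b) if g not in means.columns]
        raise ValueError(f"groups missing from design: {missing}")
    mean_a = means[group_a]
    mean_b = means[group_b]
    log2fc = np.log2((mean_b + prior_fpkm) / (mean_a + prior_fpkm))
    pvalues = nb_exact_test(counts, design, group_a, group_b, dispersion=dispersion)
    de = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalues,
            "fdr": bh_adjust(pvalues),
            "mean_fpkm_a": mean_a,
            "mean_fpkm_b": mean_b,
        },
        index=counts.gene_ids,
    )
    de.attrs["group_a"] = group_a
    de.attrs["group_b"] = group_b
    de.attrs["comparison_id"] = comparison_id or f"{group_b}_over_{group_a}"
    return de
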