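"""FPKM quantification.

FPKM_gs = c_gs * 1e9 / (L_g * N_s), with L_g the gene length in bp and N_s
the library size.  By default N_s is the column sum of the count matrix over
the supplied gene universe, which keeps the unit self-contained; an explicit
library-size vector (e.g. the nominal depth a simulation targeted) may be
passed instead.
"""

from __future__ import annotations

import pandas as pd

from .design import DesignSpec
from .io import CountMatrix


def compute_fpkm(
    counts: CountMatrix,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Elementwise FPKM for every gene and sample.

    Parameters
    ----------
    counts
        Gene x sample integer matrix.
    lengths
        Per-gene length in bp, indexed like the matrix genes; must be > 0.
    library_sizes
        Optional per-sample N_s; defaults to the matrix column sums.
    """
    lengths = lengths.reindex(counts.gene_ids)
    if lengths.isna().any():
        missing = counts.gene_ids[lengths.isna()].tolist()
        raise ValueError(f"no length for genes {missing[:5]}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive lengths for {bad[:5]}")
    if library_sizes is None:
        library_sizes = counts.library_sizes()
    else:
        library_sizes = library_sizes.reindex(counts.sample_ids)
        if library_sizes.isna().any():
            raise ValueError("library_sizes missing entries for some samples")
    zero = library_sizes.index[library_sizes <= 0].tolist()
    if zero:
        raise ValueError(f"zero library size for samples {zero}")
    fpkm = counts.data.div(library_sizes, axis=1).div(lengths, axis=0) * 1e9
    return fpkm


def group_mean_fpkm(fpkm: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Arithmetic mean FPKM over replicates, one column per design group.

    Every FPKM column must be assigned to a group; single-replicate groups
    pass through unchanged.
    """
    groups = design.groups()
    assigned = {s for ids in groups.values() for s in ids}
    unassigned = [s for s in fpkm.columns if s not in assigned]
    if unassigned:
        raise ValueError(f"samples not assigned to any group: {unassigned}")
    cols = {}
    for g, ids in groups.items():
        present = [s for s in ids if s in fpkm.columns]
        if not present:
            raise ValueError(f"group {g!r} has no samples in the FPKM matrix")
        cols[g] = fpkm[present].mean(axis=1)
    return pd.DataFrame(cols, index=fpkm.index)
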