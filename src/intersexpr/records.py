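"""Observed phenotype tallies for the UUM and RRM backcrosses.

The reported per-pupa-type margins for adults emerging from abnormal male
pupae are reconstructed here as per-individual records:

UUM (Uganda backcross):
  Type I:   21 adults,  5 intersex (germline classes 3-5), 16 with two MAGs,
            16 with no spermathecae
  Type II:  23 adults, 18 intersex,  5 with two MAGs,  3 with no spermathecae
  Type III: 16 adults, 15 intersex,  1 with two MAGs,  1 with no spermathecae

RRM (RED backcross):
  Type I:   17 adults,  7 intersex
  Type II:  26 adults, 20 intersex
  Type III: 34 adults, 29 intersex

Only those margins are reported; the joint assignment of attributes to
individual records below is synthetic (each attribute filled in record
order), which leaves every row margin — and hence every proportion computed
from it — exact.
"""

from __future__ import annotations

from .phenotype import INTERSEX_CLASSES, ContingencyTable, PhenotypeRecord, build_contingency

#: (pupa_type, n_adults, n_intersex, n_two_mags, n_no_spermathecae)
UUM_MARGINS = (
    ("I", 21, 5, 16, 16),
    ("II", 23, 18, 5, 3),
    ("III", 16, 15, 1, 1),
)

#: (pupa_type, n_adults, n_intersex)
RRM_MARGINS = (
    ("I", 17, 7),
    ("II", 26, 20),
    ("III", 34, 29),
)


def _records(prefix, ptype, n, n_intersex, n_two_mags=None, n_no_sperm=None):
    out = []
    for i in range(n):
        cls = 3 if i < n_intersex else 1
        mag = None
        if n_two_mags is not None:
            mag = 2 if i < n_two_mags else 1
        sperm = None
        if n_no_sperm is not None:
            sperm = 0 if i < n_no_sperm else 3
        out.append(
            PhenotypeRecord(
                individual_id=f"{prefix}_{ptype}_{i:03d}",
                pupa_type=ptype,
                adult_class=cls,
                mag_count=mag,
                spermatheca_count=sperm,
                rotation_24h="no",
                rotation_48h="n/a",
            )
        )
    return out


def uum_backcross_records() -> list[PhenotypeRecord]:
    """Per-individual records matching the UUM abnormal-pupae margins."""
    out = []
    for ptype, n, n_ix, n_mag2, n_sp0 in UUM_MARGINS:
        out.extend(_records("UUM", ptype, n, n_ix, n_mag2, n_sp0))
    return out


def rrm_backcross_records() -> list[PhenotypeRecord]:
    """Per-individual records matching the RRM abnormal-pupae margins."""
    out = []
    for ptype, n, n_ix in RRM_MARGINS:
        out.extend(_records("RRM", ptype, n, n_ix))
    return out


def intersex_by_pupa_table(records: list[PhenotypeRecord]) -> ContingencyTable:
    """Pupa type x {intersex, non_intersex} table (classes 3-5 collapsed)."""
    collapse = {c: "intersex" for c in INTERSEX_CLASSES}
    collapse.update({1: "non_intersex", 2: "non_intersex"})
    return build_contingency(
        records, "pupa_type", "adult_class",
        row_subset=["I", "II", "III"], col_collapse=collapse,
    )


def mag_by_pupa_table(records: list[PhenotypeRecord]) -> ContingencyTable:
    """Pupa type x MAG-count table."""
    return build_contingency(
        records, "pupa_type", "mag_count", row_subset=["I", "II", "III"]
    )
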