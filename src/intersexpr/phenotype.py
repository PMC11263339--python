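"""Contingency tables and association statistics for backcross phenotypes.

Each backcross individual is scored at the pupal stage (normal, or abnormal
Type I/II/III by genital-lobe morphology) and, if it ecloses, at the adult
stage: germline class 1-5 (classes 3-5 have ovarian tissue and are
intersex), number of male accessory glands (0-2), number of spermathecae
(0-4), and whether the VIIIth abdominal segment rotated by 24 h / 48 h.

Association between ordinal phenotypes is tested with the Pearson chi-square
statistic X^2 = sum (O-E)^2 / E and the likelihood-ratio G statistic
G = 2 sum O ln(O/E), both referred to the chi-square distribution with
(rows-1)(cols-1) degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

log = logging.getLogger(__name__)

PUPA_TYPES = ("normal", "I", "II", "III")
ADULT_CLASSES = (1, 2, 3, 4, 5)
#: germline classes with ovarian tissue — the intersex super-category
INTERSEX_CLASSES = (3, 4, 5)


@dataclass(frozen=True)
class PhenotypeRecord:
    individual_id: str
    pupa_type: str
    adult_class: int | None = None  # None = died before eclosion
    mag_count: int | None = None
    spermatheca_count: int | None = None
    rotation_24h: str | None = None  # yes / no
    rotation_48h: str | None = None  # yes / no / n/a

    def __post_init__(self) -> None:
        if self.pupa_type not in PUPA_TYPES:
            raise ValueError(f"{self.individual_id}: unknown pupa type {self.pupa_type!r}")
        if self.adult_class is not None and self.adult_class not in ADULT_CLASSES:
            raise ValueError(f"{self.individual_id}: adult class must be 1-5")
        if self.mag_count is not None and self.mag_count not in (0, 1, 2):
            raise ValueError(f"{self.individual_id}: MAG count must be 0-2")
        if self.spermatheca_count is not None and not 0 <= self.spermatheca_count <= 4:
            raise ValueError(f"{self.individual_id}: spermatheca count must be 0-4")
        eclosed = self.adult_class is not None
        if not eclosed and (self.mag_count is not None or self.spermatheca_count is not None):
            raise ValueError(
                f"{self.individual_id}: adult-derived fields present without an adult class"
            )


@dataclass
class ContingencyTable:
    """Observed counts with row/column labels; expected counts are derived
    from the margins."""

    observed: pd.DataFrame  # integer counts

    def __post_init__(self) -> None:
        if self.observed.size == 0 or self.observed.to_numpy().sum() == 0:
            raise ValueError("empty contingency table")
        if (self.observed.to_numpy() < 0).any():
            raise ValueError("negative cell counts")

    @property
    def n(self) -> int:
        return int(self.observed.to_numpy().sum())

    @property
    def expected(self) -> pd.DataFrame:
        o = self.observed.to_numpy(float)
        e = np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()
        return pd.DataFrame(e, index=self.observed.index, columns=self.observed.columns)


def build_contingency(
    records: list[PhenotypeRecord],
    row_var: str,
    col_var: str,
    row_subset: list | None = None,
    col_collapse: dict | None = None,
) -> ContingencyTable:
    """Cross-tabulate two record attributes over individuals with both present.

    ``col_collapse`` maps raw column values onto super-categories before
    counting (e.g. ``{3: "intersex", 4: "intersex", 5: "intersex"}``);
    unmapped values pass through unchanged.  ``row_subset`` restricts and
    orders the rows.
    """
    if not records:
        raise ValueError("no records to tabulate")
    pairs = []
    for r in records:
        rv = getattr(r, row_var)
        cv = getattr(r, col_var)
        if rv is None or cv is None:
            continue
        if col_collapse is not None:
            cv = col_collapse.get(cv, cv)
        pairs.append((rv, cv))
    if not pairs:
        raise ValueError(f"no records with both {row_var!r} and {col_var!r}")
    df = pd.DataFrame(pairs, columns=[row_var, col_var])
    table = pd.crosstab(df[row_var], df[col_var])
    if row_subset is not None:
        keep = [r for r in row_subset if r in table.index]
        if not keep:
            raise ValueError(f"row subset {row_subset} not present in data")
        table = table.loc[keep]
    return ContingencyTable(table.astype(int))


def _check_testable(t: ContingencyTable) -> tuple[np.ndarray, np.ndarray, int]:
    o = t.observed.to_numpy(float)
    if min(o.shape) < 2:
        raise ValueError("association tests need at least a 2x2 table (df would be 0)")
    if (o.sum(axis=1) == 0).any() or (o.sum(axis=0) == 0).any():
        raise ValueError("all margins must be > 0")
    e = t.expected.to_numpy(float)
    df = (o.shape[0] - 1) * (o.shape[1] - 1)
    return o, e, df


def pearson_chi2(t: ContingencyTable) -> tuple[float, int, float]:
    """Pearson X^2 = sum (O-E)^2 / E with upper-tail chi-square p-value.

    Cells with E = 0 are excluded from the sum with a warning (they cannot
    arise when both margins are positive, but collapsed tables passed in
    directly may contain them).
    """
    o, e, df = _check_testable(t)
    mask = e > 0
    if not mask.all():
        log.warning("excluding %d cells with expected count 0", int((~mask).sum()))
    stat = float(np.sum(np.square(o[mask] - e[mask]) / e[mask]))
    return stat, df, float(chi2.sf(stat, df))


def g_test(t: ContingencyTable) -> tuple[float, int, float]:
    """Likelihood-ratio G = 2 sum O ln(O/E) over O > 0 cells, chi-square p-value."""
    o, e, df = _check_testable(t)
    mask = o > 0
    stat = float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))
    return stat, df, float(chi2.sf(stat, df))


def proportion(t: ContingencyTable, row, cols: list) -> float:
    """Percentage of a row's total falling in the selected columns, to 2 dp."""
    if row not in t.observed.index:
        raise KeyError(f"row {row!r} not in table")
    r = t.observed.loc[row]
    total = int(r.sum())
    if total == 0:
        raise ValueError(f"row {row!r} has zero total")
    sel = [c for c in cols if c in t.observed.columns]
    return round(100.0 * float(r[sel].sum()) / total, 2)


# --- record I/O -------------------------------------------------------------

_CSV_COLUMNS = [
    "individual_id", "pupa_type", "adult_class", "mag_count",
    "spermatheca_count", "rotation_24h", "rotation_48h",
]


def write_records(records: list[PhenotypeRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in _CSV_COLUMNS})
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_records(path: str | Path) -> list[PhenotypeRecord]:
    # keep literal "n/a" rotation values; only empty cells are missing
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    def opt_int(v):
        return None if (v is None or (isinstance(v, float) and math.isnan(v))) else int(v)

    def opt_str(v):
        return None if (v is None or (isinstance(v, float) and math.isnan(v))) else str(v)

    return [
        PhenotypeRecord(
            individual_id=str(r.individual_id),
            pupa_type=str(r.pupa_type),
            adult_class=opt_int(r.adult_class),
            mag_count=opt_int(r.mag_count),
            spermatheca_count=opt_int(r.spermatheca_count),
            rotation_24h=opt_str(r.rotation_24h),
            rotation_48h=opt_str(r.rotation_48h),
        )
        for r in df.itertuples()
    ]
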