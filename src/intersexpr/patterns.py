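"""Expression-pattern classification across the five normal-vs-intersex comparisons.

For one tissue and one reference sex the five comparisons are, in order:

    1. U   vs UUM     (pure species vs normal backcross, reference sex)
    2. M   vs UUM
    3. UUM vs UUMix   (normal backcross vs intersex backcross)
    4. U   vs UUMix
    5. M   vs UUMix

with log2FC oriented second-over-first, so the last three are
intersex-over-reference and "downregulation" means lower in intersexes.
A gene is *No change* when all five comparisons show no change;
*Upregulation*/*Downregulation* when the first two show no change and the
last three are unanimously up/down; anything else is *Other*.

The elementary call uses the same thresholds as clustering: no change when
-2 < log2FC < 2 (any FDR) or |log2FC| >= 2 with FDR > 0.05; up when
log2FC >= 2 with FDR <= 0.05; down when log2FC <= -2 with FDR <= 0.05.
"""

from __future__ import annotations

import logging
import math
from collections import Counter

import pandas as pd

from .clusters import Thresholds
from .design import group_key
from .groups import GeneGroup

log = logging.getLogger(__name__)

COMPARISON_ORDER = ("U_vs_UUM", "M_vs_UUM", "UUM_vs_UUMix", "U_vs_UUMix", "M_vs_UUMix")
PATTERNS = ("no_change", "upregulation", "downregulation", "other")
CALLS = ("no_change", "up", "down")


def comparison_groups(tissue: str, reference_sex: str) -> dict[str, tuple[str, str]]:
    """Map each of the five comparison IDs to its (group_A, group_B) pair.

    ``reference_sex`` selects which normal samples the intersexes are
    compared against (female for female-associated gene groups, male for
    male-associated ones).
    """
    if reference_sex not in ("male", "female"):
        raise ValueError(f"reference_sex must be male or female, got {reference_sex!r}")
    ix = group_key("UUM", "intersex", tissue)
    ref = {sp: group_key(sp, reference_sex, tissue) for sp in ("U", "M", "UUM")}
    return {
        "U_vs_UUM": (ref["U"], ref["UUM"]),
        "M_vs_UUM": (ref["M"], ref["UUM"]),
        "UUM_vs_UUMix": (ref["UUM"], ix),
        "U_vs_UUMix": (ref["U"], ix),
        "M_vs_UUMix": (ref["M"], ix),
    }


def classify_single(log2fc: float, fdr: float, t: Thresholds = Thresholds()) -> str:
    """Elementary call for one comparison: no_change / up / down."""
    if math.isnan(log2fc) or math.isnan(fdr):
        raise ValueError("NaN log2FC or FDR cannot be classified")
    if -t.lfc < log2fc < t.lfc:
        return "no_change"
    if fdr > t.fdr:
        return "no_change"
    return "up" if log2fc >= t.lfc else "down"


def classify_pattern(calls: list[str] | tuple[str, ...]) -> str:
    """Combine the five ordered elementary calls into the final label."""
    if len(calls) != 5:
        raise ValueError(f"expected 5 calls in comparison order, got {len(calls)}")
    bad = [c for c in calls if c not in CALLS]
    if bad:
        raise ValueError(f"unknown elementary calls {bad}")
    first_two, last_three = calls[:2], calls[2:]
    if any(c != "no_change" for c in first_two):
        return "other"
    if all(c == "no_change" for c in last_three):
        return "no_change"
    if all(c == "up" for c in last_three):
        return "upregulation"
    if all(c == "down" for c in last_three):
        return "downregulation"
    return "other"


def classify_genes(
    comparison_set: dict[str, pd.DataFrame],
    genes: list[str],
    t: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-gene call table over the five comparisons plus the final pattern.

    ``comparison_set`` maps the five comparison IDs to DE tables; genes
    missing from any table are excluded with a logged warning.
    """
    missing_tables = [c for c in COMPARISON_ORDER if c not in comparison_set]
    if missing_tables:
        raise KeyError(f"comparison set is missing {missing_tables}")
    usable = []
    skipped = []
    for g in genes:
        if all(g in comparison_set[c].index for c in COMPARISON_ORDER):
            usable.append(g)
        else:
            skipped.append(g)
    if skipped:
        log.warning(
            "%d group genes absent from at least one DE table were excluded (e.g. %s)",
            len(skipped), skipped[:3],
        )
    rows = {}
    for g in usable:
        calls = []
        for c in COMPARISON_ORDER:
            row = comparison_set[c].loc[g]
            calls.append(classify_single(float(row["log2fc"]), float(row["fdr"]), t))
        rows[g] = [*calls, classify_pattern(calls)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[*COMPARISON_ORDER, "pattern"]
    ).rename_axis("gene_id")


def summarize_patterns(
    group: GeneGroup,
    comparison_set: dict[str, pd.DataFrame],
    t: Thresholds = Thresholds(),
) -> dict[str, int]:
    """Counts of the four pattern labels over one gene group's classifiable members."""
    table = classify_genes(comparison_set, group.members, t)
    counts = Counter(table["pattern"])
    return {p: int(counts.get(p, 0)) for p in PATTERNS}
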