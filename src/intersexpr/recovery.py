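"""Planted-truth recovery metrics for simulated runs.

Given a simulated count matrix and the truth it was drawn from, run the full
classification pipeline and score it against the planted expectation — the
labels the same rules produce on the noiseless planted group means
(:func:`intersexpr.simulate.planted_de_tables`).  Agreement is reported over
genes whose planted label is informative (a directed cluster subtype, or
membership in a sex x tissue group), which is the recovery rate a simulation
study quotes.
"""

from __future__ import annotations

import pandas as pd

from .clusters import CLUSTERS, Thresholds, build_all_clusters, cluster_comparisons
from .de import compare_groups
from .design import DesignSpec
from .groups import intersect_groups
from .io import CountMatrix
from .patterns import classify_genes, comparison_groups
from .simulate import TruthTable, planted_de_tables

DEFAULT_ANALYSES = (("female", "reproductive"), ("male", "reproductive"))


def comparison_plan(
    analyses: tuple[tuple[str, str], ...] = DEFAULT_ANALYSES,
) -> dict[str, tuple[str, str]]:
    """Cluster comparisons plus the five intersex comparisons per analysis."""
    plan: dict[str, tuple[str, str]] = {}
    for cluster in CLUSTERS:
        for comp_id, ga, gb in cluster_comparisons(cluster):
            plan[comp_id] = (ga, gb)
    for sex, tissue in analyses:
        for comp_id, pair in comparison_groups(tissue, sex).items():
            plan[f"{tissue}:{sex}:{comp_id}"] = pair
    return plan


def evaluate_recovery(
    counts: CountMatrix,
    design: DesignSpec,
    truth: TruthTable,
    thresholds: Thresholds = Thresholds(),
    rule: str = "any",
    analyses: tuple[tuple[str, str], ...] = DEFAULT_ANALYSES,
) -> dict:
    """Run the pipeline on simulated counts and score it against the plant.

    Returns a dict with, per cluster, the percentage of planted directed
    subtypes recovered exactly; per analysis, the percentage of planted
    group members whose intersex pattern matches the planted one; and the
    overall cluster/pattern recovery percentages.
    """
    plan = comparison_plan(analyses)
    observed_tables = {
        cid: compare_groups(counts, design, ga, gb, comparison_id=cid)
        for cid, (ga, gb) in plan.items()
    }
    planted_tables = planted_de_tables(truth, plan)

    observed = build_all_clusters(observed_tables, thresholds, rule=rule)
    planted = build_all_clusters(planted_tables, thresholds, rule=rule)

    out: dict = {"clusters": {}, "patterns": {}}
    agree_total = n_total = 0
    for cluster in CLUSTERS:
        exp = planted.table[cluster]
        directed = exp.index[(exp != "none") & (exp != "low")]
        if len(directed) == 0:
            continue
        agree = int((observed.table.loc[directed, cluster] == exp.loc[directed]).sum())
        out["clusters"][cluster] = {
            "n_planted": int(len(directed)),
            "recovered_pct": 100.0 * agree / len(directed),
        }
        agree_total += agree
        n_total += len(directed)
    out["cluster_recovery_pct"] = 100.0 * agree_total / n_total if n_total else float("nan")

    agree_total = n_total = 0
    for sex, tissue in analyses:
        planted_groups = intersect_groups(planted, sex, tissue)
        members = sorted({g for grp in planted_groups.values() for g in grp.members})
        if not members:
            continue
        obs_set = {
            base: observed_tables[f"{tissue}:{sex}:{base}"]
            for base in comparison_groups(tissue, sex)
        }
        exp_set = {
            base: planted_tables[f"{tissue}:{sex}:{base}"]
            for base in comparison_groups(tissue, sex)
        }
        got = classify_genes(obs_set, members, thresholds)
        exp = classify_genes(exp_set, members, thresholds)
        agree = int((got["pattern"] == exp["pattern"]).sum())
        out["patterns"][f"{sex}_{tissue}"] = {
            "n_planted": int(len(members)),
            "recovered_pct": 100.0 * agree / len(members),
        }
        agree_total += agree
        n_total += len(members)
    out["pattern_recovery_pct"] = 100.0 * agree_total / n_total if n_total else float("nan")
    return out
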