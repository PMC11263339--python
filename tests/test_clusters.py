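"""Threshold decision tree and cluster combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intersexpr.clusters import (
    CLUSTERS,
    Thresholds,
    build_all_clusters,
    build_cluster,
    categorize_pair,
    categorize_table,
    cluster_comparisons,
)
from intersexpr.simulate import planted_de_tables


def _comparison_plan():
    plan = {}
    for cl in CLUSTERS:
        for cid, ga, gb in cluster_comparisons(cl):
            plan[cid] = (ga, gb)
    return plan


class TestCategorizePair:
    @pytest.mark.parametrize(
        "a,b,lfc,fdr,label,direction",
        [
            (0.5, 0.8, 4.0, 0.001, "low", "none"),          # both means below 1
            (10, 28, 1.49, 0.001, "unbiased", "none"),      # |lfc| <= 2
            (12, 0.3, -5.0, 1e-6, "specific", "A_high"),    # losing side below 1
            (40, 5, -3.0, 0.001, "biased", "A_high"),       # both sides expressed
            (5, 40, 3.0, 0.2, "unbiased", "none"),          # not significant
            (0.3, 50, 7.0, 1e-9, "specific", "B_high"),
        ],
    )
    def test_decision_tree(self, a, b, lfc, fdr, label, direction):
        cat = categorize_pair(a, b, lfc, fdr)
        assert (cat.label, cat.direction) == (label, direction)

    def test_threshold_boundaries_use_printed_operators(self):
        # |log2FC| exactly 2 is unbiased (rule is log2FC <= 2); FDR exactly
        # 0.05 is significant (rule is FDR > 0.05 for unbiased)
        assert categorize_pair(2, 32, 2.0, 0.001).label == "unbiased"
        assert categorize_pair(2, 32, 2.01, 0.05).label == "biased"
        # mean exactly 1 is not low ("below 1")
        assert categorize_pair(1.0, 1.0, 0.0, 0.9).label == "unbiased"

    def test_missing_fdr_with_large_fold_is_an_error(self):
        with pytest.raises(ValueError, match="FDR"):
            categorize_pair(2, 40, 4.0, float("nan"))

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.floats(min_value=0, max_value=1e4),
        ratio=st.floats(min_value=-12, max_value=12),
        fdr=st.floats(min_value=0, max_value=1),
    )
    def test_outcomes_partition_all_inputs(self, a, ratio, fdr):
        """Every classifiable row gets exactly one of the four labels, and
        flipping the orientation flips the direction but never the label."""
        b = a * 2.0**ratio if a > 0 else (2.0**ratio if ratio > 0 else 0.0)
        lfc = np.log2((b + 0.25) / (a + 0.25))
        cat = categorize_pair(a, b, lfc, fdr)
        assert cat.label in ("low", "unbiased", "biased", "specific")
        flipped = categorize_pair(b, a, -lfc, fdr)
        assert flipped.label == cat.label
        if cat.direction != "none":
            assert {cat.direction, flipped.direction} == {"A_high", "B_high"}

    def test_raising_low_threshold_is_monotone(self):
        """A gene low at threshold 1 stays low (never becomes specific or
        biased) when the threshold is raised."""
        for t2 in (2.0, 5.0):
            for a, b, lfc in [(0.5, 0.9, 0.6), (0.2, 0.9, 1.8)]:
                c1 = categorize_pair(a, b, lfc, 0.01, Thresholds())
                c2 = categorize_pair(a, b, lfc, 0.01, Thresholds(fpkm_low=t2))
                if c1.label == "low":
                    assert c2.label == "low"


def _cat_frame(rows):
    genes = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=genes, columns=["label", "direction"])


class TestBuildCluster:
    def test_specific_in_both_species_joins_as_specific(self):
        cats = {
            "REPRODUCTIVE_SEX:U": _cat_frame([("specific", "B_high")]),
            "REPRODUCTIVE_SEX:M": _cat_frame([("specific", "B_high")]),
        }
        col = build_cluster("REPRODUCTIVE_SEX", cats)
        assert col.iloc[0] == "female_specific"

    def test_specific_plus_unbiased_joins_under_default_rule(self):
        """One informative species comparison with no contradiction is
        enough under the default rule; the strict rule demands both."""
        cats = {
            "REPRODUCTIVE_SEX:U": _cat_frame([("specific", "B_high")]),
            "REPRODUCTIVE_SEX:M": _cat_frame([("unbiased", "none")]),
        }
        assert build_cluster("REPRODUCTIVE_SEX", cats).iloc[0] == "female_specific"
        assert build_cluster("REPRODUCTIVE_SEX", cats, rule="all").iloc[0] == "none"

    def test_conflicting_directions_give_none(self):
        cats = {
            "REPRODUCTIVE_SEX:U": _cat_frame([("specific", "B_high")]),
            "REPRODUCTIVE_SEX:M": _cat_frame([("biased", "A_high")]),
        }
        assert build_cluster("REPRODUCTIVE_SEX", cats).iloc[0] == "none"

    def test_all_biased_tissue_gene(self):
        cats = {
            cid: _cat_frame([("biased", "A_high")])
            for cid, _, _ in cluster_comparisons("TISSUE")
        }
        assert build_cluster("TISSUE", cats).iloc[0] == "reproductive_biased"

    def test_mixed_specific_and_biased_is_biased(self):
        cats = {
            "CARCASS_SEX:U": _cat_frame([("specific", "A_high")]),
            "CARCASS_SEX:M": _cat_frame([("biased", "A_high")]),
        }
        assert build_cluster("CARCASS_SEX", cats).iloc[0] == "male_biased"

    def test_all_low_is_low(self):
        cats = {
            "CARCASS_SPECIES:male": _cat_frame([("low", "none")]),
            "CARCASS_SPECIES:female": _cat_frame([("low", "none")]),
        }
        assert build_cluster("CARCASS_SPECIES", cats).iloc[0] == "low"

    def test_missing_comparison_is_an_error(self):
        with pytest.raises(KeyError, match="REPRODUCTIVE_SEX"):
            build_cluster("REPRODUCTIVE_SEX",
                          {"REPRODUCTIVE_SEX:U": _cat_frame([("low", "none")])})


class TestBuildAllClusters:
    def test_planted_oracle_labels_recovered_exactly_on_noiseless_tables(self, strong_truth):
        """Running the rules on the planted (noiseless) DE quantities must
        reproduce directed subtypes for every planted effect gene."""
        plan = _comparison_plan()
        membership = build_all_clusters(planted_de_tables(strong_truth, plan))
        tt = strong_truth.table
        sex_r = tt[(tt.sex_class != "none")
                   & ((tt.tissue_class == "none") | (tt.tissue_high == "reproductive"))]
        for gene, row in sex_r.iterrows():
            want = f"{row.sex_high}_{row.sex_class}"
            assert membership.table.loc[gene, "REPRODUCTIVE_SEX"] == want

    def test_all_null_simulation_yields_almost_no_members(self, full_design):
        from intersexpr.de import compare_groups
        from intersexpr.simulate import simulate_counts
        from .conftest import flat_truth

        truth = flat_truth(400, baseline=50.0, dispersion=0.05)
        cm = simulate_counts(full_design, truth, seed=33)
        plan = _comparison_plan()
        tables = {cid: compare_groups(cm, full_design, ga, gb) for cid, (ga, gb) in plan.items()}
        membership = build_all_clusters(tables)
        directed = (membership.table != "none") & (membership.table != "low")
        assert directed.to_numpy().mean() < 0.01

    def test_missing_table_error_names_comparison(self, strong_truth):
        plan = _comparison_plan()
        tables = planted_de_tables(strong_truth, plan)
        tables.pop("TISSUE:U_male")
        with pytest.raises(KeyError, match="TISSUE:U_male"):
            build_all_clusters(tables)


class TestCategorizeTable:
    def test_vectorized_agrees_with_scalar(self, rng):
        n = 300
        a = rng.uniform(0, 30, n)
        b = rng.uniform(0, 30, n)
        lfc = np.log2((b + 0.25) / (a + 0.25))
        fdr = rng.uniform(0, 1, n)
        de = pd.DataFrame(
            {"mean_fpkm_a": a, "mean_fpkm_b": b, "log2fc": lfc, "fdr": fdr},
            index=[f"g{i}" for i in range(n)],
        )
        vec = categorize_table(de)
        for g in de.index[:50]:
            row = de.loc[g]
            cat = categorize_pair(row.mean_fpkm_a, row.mean_fpkm_b, row.log2fc, row.fdr)
            assert vec.loc[g, "label"] == cat.label
            assert vec.loc[g, "direction"] == cat.direction
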