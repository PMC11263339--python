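"""Expression clusters and the six sex x tissue gene groups.

Runs all 12 pure-species comparisons, assigns every gene a subtype in each
of the five clusters (REPRODUCTIVE_SEX, REPRODUCTIVE_SPECIES, CARCASS_SEX,
CARCASS_SPECIES, TISSUE), and intersects the female-side subtypes with the
TISSUE cluster into the six female x reproductive groups.
"""

from intersexpr import (
    build_all_clusters,
    compare_groups,
    default_design,
    default_truth,
    intersect_groups,
    simulate_counts,
)
from intersexpr.clusters import CLUSTERS, cluster_comparisons

design = default_design()
truth = default_truth(n_genes=500, seed=3)
counts = simulate_counts(design, truth, seed=3)

tables = {}
for cluster in CLUSTERS:
    for comp_id, ga, gb in cluster_comparisons(cluster):
        tables[comp_id] = compare_groups(counts, design, ga, gb, comparison_id=comp_id)

membership = build_all_clusters(tables)
for cluster in CLUSTERS:
    counts_by_subtype = membership.table[cluster].value_counts().to_dict()
    counts_by_subtype.pop("none", None)
    print(cluster, counts_by_subtype)

print()
groups = intersect_groups(membership, "female", "reproductive")
for kind, grp in groups.items():
    print(f"{grp.name}: {len(grp)} genes")
# Each subtype tally reflects the planted composition; the joint groups are
# the gene sets whose intersex behaviour the pattern analysis profiles.
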