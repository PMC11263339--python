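"""Sex x tissue gene groups.

For a chosen sex (male/female) and tissue (reproductive/carcass) the six
groups intersect the tissue-matched sex cluster with the TISSUE cluster:

    sex-specific/tissue-specific   sex-biased/tissue-specific
    sex-specific/tissue-biased     sex-biased/tissue-biased
    sex-specific/tissue-unbiased   sex-biased/tissue-unbiased

"tissue-unbiased" means the gene carries no TISSUE subtype (neither specific
nor biased toward either tissue) while not being low in the TISSUE
comparisons — the only reading under which the six groups exhaust the
non-low sex-associated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clusters import ClusterMembership

GROUP_KINDS = (
    "sex_specific_tissue_specific",
    "sex_specific_tissue_biased",
    "sex_specific_tissue_unbiased",
    "sex_biased_tissue_specific",
    "sex_biased_tissue_biased",
    "sex_biased_tissue_unbiased",
)


@dataclass
class GeneGroup:
    name: str
    sex: str
    tissue: str
    members: list[str] = field(default_factory=list)
    defining_clusters: tuple[str, str] = ("", "")

    def __len__(self) -> int:
        return len(self.members)


def intersect_groups(
    membership: ClusterMembership, sex: str, tissue: str
) -> dict[str, GeneGroup]:
    """Build the six sex x tissue groups from cluster membership alone."""
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be male or female, got {sex!r}")
    if tissue not in ("reproductive", "carcass"):
        raise ValueError(f"tissue must be reproductive or carcass, got {tissue!r}")
    sex_cluster = "REPRODUCTIVE_SEX" if tissue == "reproductive" else "CARCASS_SEX"
    t = membership.table

    sex_sets = {
        "sex_specific": set(membership.members(sex_cluster, f"{sex}_specific")),
        "sex_biased": set(membership.members(sex_cluster, f"{sex}_biased")),
    }
    tissue_sets = {
        "tissue_specific": set(membership.members("TISSUE", f"{tissue}_specific")),
        "tissue_biased": set(membership.members("TISSUE", f"{tissue}_biased")),
        # no TISSUE subtype at all, but expressed (not low) in those comparisons
        "tissue_unbiased": set(t.index[t["TISSUE"] == "none"]),
    }

    out: dict[str, GeneGroup] = {}
    for kind in GROUP_KINDS:
        sex_part = "sex_specific" if "sex_specific" in kind else "sex_biased"
        tissue_part = kind[kind.index("tissue_"):]
        members = sorted(sex_sets[sex_part] & tissue_sets[tissue_part])
        pretty = kind.replace("sex", sex, 1).replace("tissue", tissue, 1)
        out[kind] = GeneGroup(
            name=pretty,
            sex=sex,
            tissue=tissue,
            members=members,
            defining_clusters=(sex_cluster, "TISSUE"),
        )
    return out


def write_group(group: GeneGroup, path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": group.members,
            "group": group.name,
            "sex_cluster": group.defining_clusters[0],
            "tissue_cluster": group.defining_clusters[1],
        }
    )
    df.to_csv(path, sep="\t", index=False)
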