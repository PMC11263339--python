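"""Synthetic count matrices and phenotype records with planted ground truth.

Counts are drawn per gene and sample from a negative binomial with
``var = mu + phi * mu^2``, the same mean/dispersion parameterization the
differential-expression stage assumes.  Planted truth is expressed per gene
as one (class, high-side) pair per factor — sex, species, tissue — where the
class is ``none``, ``biased`` (high side = baseline FPKM, low side =
baseline / fold) or ``specific`` (low side pinned at a near-zero FPKM), plus
an intersex behaviour describing how the backcross intersex group relates to
its reference sex: ``no_change`` copies the reference mean, ``down``/``up``
divide/multiply it by the fold change, and ``other`` shifts the *normal
backcross* reference group away from the pure species so the first two of
the five intersex comparisons deviate and the gene must classify as Other.

Backcross (UUM) samples take the U side of any species effect, since the
backcross is to *Ae. aegypti* females.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SEXES, SPECIES, TISSUES, DesignSpec, default_design, group_key
from .io import CountMatrix

SEX_CLASSES = SPECIES_CLASSES = TISSUE_CLASSES = ("none", "biased", "specific")
INTERSEX_BEHAVIORS = ("no_change", "down", "up", "other")

TRUTH_COLUMNS = [
    "sex_class", "sex_high", "species_class", "species_high",
    "tissue_class", "tissue_high", "baseline_fpkm", "specific_fpkm",
    "fold_change", "dispersion", "intersex_behavior", "intersex_reference",
]


class TruthError(ValueError):
    """Raised when a truth table violates a planted-class invariant."""


#: fold applied to the normal-backcross reference group for 'other' genes —
#: large enough to clear the |log2FC| = 2 call threshold decisively, small
#: enough not to distort the library composition
OTHER_SHIFT = 8.0


@dataclass
class TruthTable:
    """Per-gene planted expression truth.

    ``table`` is indexed by gene_id with the columns in
    :data:`TRUTH_COLUMNS`.  ``baseline_fpkm`` is the high-side expected FPKM,
    ``specific_fpkm`` the pinned low side of specific classes (< 1),
    ``fold_change`` the linear fold (>= 1) for biased classes and intersex
    shifts, ``dispersion`` the NB dispersion phi (>= 0).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in TRUTH_COLUMNS if c not in t.columns]
        if missing:
            raise TruthError(f"truth table missing columns {missing}")
        if t.index.has_duplicates:
            raise TruthError("duplicate gene IDs in truth table")
        for gene, row in t.iterrows():
            for axis, levels in (
                ("sex", ("male", "female")),
                ("species", ("U", "M")),
                ("tissue", TISSUES),
            ):
                cls = row[f"{axis}_class"]
                if cls not in ("none", "biased", "specific"):
                    raise TruthError(f"gene {gene}: unknown {axis}_class {cls!r}")
                if cls != "none" and row[f"{axis}_high"] not in levels:
                    raise TruthError(
                        f"gene {gene}: {axis} direction references unknown group "
                        f"level {row[f'{axis}_high']!r} (expected one of {levels})"
                    )
                if cls == "specific" and not row["specific_fpkm"] < 1:
                    raise TruthError(
                        f"gene {gene}: specific class requires low-side FPKM < 1"
                    )
                if cls == "biased":
                    if not np.log2(row["fold_change"]) > 2:
                        raise TruthError(
                            f"gene {gene}: biased class requires log2(fold) > 2"
                        )
                    if row["baseline_fpkm"] / row["fold_change"] < 1:
                        raise TruthError(
                            f"gene {gene}: biased class requires both sides >= 1 FPKM"
                        )
            if row["fold_change"] < 1:
                raise TruthError(f"gene {gene}: fold change must be >= 1")
            if row["dispersion"] < 0 or row["baseline_fpkm"] < 0:
                raise TruthError(f"gene {gene}: negative dispersion or baseline")
            if row["intersex_behavior"] not in INTERSEX_BEHAVIORS:
                raise TruthError(
                    f"gene {gene}: unknown intersex behavior {row['intersex_behavior']!r}"
                )
            if row["intersex_reference"] not in ("male", "female"):
                raise TruthError(
                    f"gene {gene}: intersex reference must be male or female"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def planted_class(self) -> pd.Series:
        """Summary label per gene: low / unbiased / <axis>_<class> combinations."""
        out = []
        for gene, row in self.table.iterrows():
            parts = [
                f"{axis}_{row[f'{axis}_class']}"
                for axis in ("sex", "species", "tissue")
                if row[f"{axis}_class"] != "none"
            ]
            if parts:
                out.append("+".join(parts))
            elif row["baseline_fpkm"] < 1:
                out.append("low")
            else:
                out.append("unbiased")
        return pd.Series(out, index=self.table.index, name="planted_class")

    def group_mean_fpkm(self, groups: list[str] | None = None) -> pd.DataFrame:
        """Expected FPKM per gene for each (species, sex, tissue) group label."""
        if groups is None:
            groups = sorted({s.group for s in default_design().samples})
        parsed = []
        for g in groups:
            species, sex, tissue = g.split("_")
            if species not in SPECIES or sex not in SEXES or tissue not in TISSUES:
                raise TruthError(f"unparseable group label {g!r}")
            parsed.append((g, species, sex, tissue))
        t = self.table
        base = t["baseline_fpkm"].to_numpy(float)
        spec = t["specific_fpkm"].to_numpy(float)
        fold = t["fold_change"].to_numpy(float)

        def axis_factor(axis: str, level: np.ndarray | str) -> np.ndarray:
            cls = t[f"{axis}_class"].to_numpy()
            high = t[f"{axis}_high"].to_numpy()
            on_high = high == level
            f = np.ones(len(t))
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where((cls == "biased") & ~on_high, 1.0 / fold, f)
                f = np.where(
                    (cls == "specific") & ~on_high,
                    np.where(base > 0, spec / base, 0.0),
                    f,
                )
            return f

        normal: dict[str, np.ndarray] = {}
        for g, species, sex, tissue in parsed:
            if sex == "intersex":
                continue
            species_side = "U" if species in ("U", "UUM") else "M"
            mean = base * axis_factor("sex", sex) * axis_factor("species", species_side)
            mean = mean * axis_factor("tissue", tissue)
            normal[g] = mean

        # 'other' behaviour: shift the normal-backcross reference group away
        # from the pure species so the first two comparisons deviate
        behavior = t["intersex_behavior"].to_numpy()
        ref_sex = t["intersex_reference"].to_numpy()
        cols: dict[str, np.ndarray] = {}
        for g, species, sex, tissue in parsed:
            if sex == "intersex":
                continue
            mean = normal[g].copy()
            if species == "UUM":
                shift = (behavior == "other") & (ref_sex == sex)
                mean = np.where(shift, mean * OTHER_SHIFT, mean)
            cols[g] = mean
        for g, species, sex, tissue in parsed:
            if sex != "intersex":
                continue
            ix = np.empty(len(t))
            for rs in ("male", "female"):
                ref_group = group_key("UUM", rs, tissue)
                ref = normal.get(ref_group)
                if ref is None:
                    # reference group not in the requested set: recompute it
                    mean = base * axis_factor("sex", rs) * axis_factor("species", "U")
                    ref = mean * axis_factor("tissue", tissue)
                sel = ref_sex == rs
                vals = np.where(behavior == "down", ref / fold, ref)
                vals = np.where(behavior == "up", ref * fold, vals)
                # 'other' and 'no_change' both copy the unshifted reference
                ix[sel] = vals[sel]
            cols[g] = ix
        return pd.DataFrame(cols, index=t.index, columns=[p[0] for p in parsed])


def simulate_counts(
    design: DesignSpec,
    truth: TruthTable,
    gene_lengths: pd.Series | None = None,
    target_library_size: int = 1_000_000,
    seed: int = 0,
) -> CountMatrix:
    """Draw a gene x sample NB count matrix from the planted truth.

    The NB mean for gene g in sample s is
    ``fpkm_g(group(s)) * L_g * target_library_size / 1e9``, so the expected
    FPKM recomputed against the nominal library size equals the planted
    value.  One RNG stream (``numpy.random.default_rng(seed)``) drives the
    whole matrix; identical (design, truth, seed) give identical output.
    """
    if target_library_size <= 0:
        raise ValueError("target_library_size must be > 0")
    genes = truth.gene_ids
    if gene_lengths is None:
        gene_lengths = pd.Series(1000.0, index=genes)
    else:
        gene_lengths = gene_lengths.reindex(genes)
        if gene_lengths.isna().any() or (gene_lengths <= 0).any():
            raise ValueError("all genes need a positive length")
    groups = sorted({s.group for s in design.samples})
    fpkm = truth.group_mean_fpkm(groups)
    scale = gene_lengths.to_numpy(float) * target_library_size / 1e9
    sample_groups = [s.group for s in design.samples]
    mean = fpkm[sample_groups].to_numpy(float) * scale[:, None]

    phi = truth.table["dispersion"].to_numpy(float)
    rng = np.random.default_rng(seed)
    out = np.zeros(mean.shape, dtype=np.int64)

    nb = phi > 0
    if nb.any():
        r = 1.0 / phi[nb]
        m = mean[nb]
        p = np.where(m > 0, r[:, None] / (r[:, None] + m), 1.0)
        out[nb] = rng.negative_binomial(np.broadcast_to(r[:, None], m.shape), p)
    if (~nb).any():
        out[~nb] = rng.poisson(mean[~nb])
    out[mean == 0] = 0

    df = pd.DataFrame(out, index=genes, columns=design.sample_ids)
    df.index.name = "gene_id"
    cm = CountMatrix(df)
    cm.data.attrs["target_library_size"] = int(target_library_size)
    return cm


def write_truth(truth: TruthTable, path) -> None:
    df = truth.table.copy()
    df.insert(0, "gene_id", df.index)
    df["planted_class"] = truth.planted_class
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    df.index = df.index.astype(str)
    for axis in ("sex", "species", "tissue"):
        df[f"{axis}_high"] = df[f"{axis}_high"].fillna("").astype(str)
    return TruthTable(df[TRUTH_COLUMNS])


# --- default planted composition -------------------------------------------

#: fraction of genes per planted class in the default truth
DEFAULT_CLASS_MIX: dict[tuple[str, str], float] = {
    ("none", "none"): 0.46,        # unbiased
    ("low", "none"): 0.08,
    ("specific", "none"): 0.06,    # (sex_class, tissue_class)
    ("biased", "none"): 0.06,
    ("none", "specific"): 0.06,
    ("none", "biased"): 0.06,
    ("specific", "specific"): 0.05,
    ("specific", "biased"): 0.03,
    ("biased", "specific"): 0.03,
    ("biased", "biased"): 0.03,
    ("species_specific", "none"): 0.04,
    ("species_biased", "none"): 0.04,
}

#: intersex behaviour mix for sex-associated genes
DEFAULT_BEHAVIOR_MIX = {"no_change": 0.6, "down": 0.2, "other": 0.2}


def default_truth(
    n_genes: int = 2000,
    seed: int = 0,
    baseline_fpkm: float = 200.0,
    fold_change: float = 64.0,
    dispersion: float = 0.05,
    specific_fpkm: float = 0.05,
    low_fpkm: float = 0.2,
    class_mix: dict[tuple[str, str], float] | None = None,
    behavior_mix: dict[str, float] | None = None,
    normalize_library: bool = True,
) -> TruthTable:
    """Planted truth with the default class composition and strong effects.

    Defaults encode the strong-effect regime the recovery analyses assume:
    high-side FPKM 200, fold change 64 (log2 = 6), dispersion 0.05,
    specific-side FPKM 0.05.  With ``normalize_library`` the whole abundance
    profile is rescaled by one global constant so each sample's expected
    FPKM composition is self-consistent (sums to ~1e6 per kb), making
    count-derived FPKM agree with the plant; the constant is shared by all
    groups, so fold changes and class boundaries are preserved exactly.
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    bmix = dict(DEFAULT_BEHAVIOR_MIX if behavior_mix is None else behavior_mix)
    if abs(sum(mix.values()) - 1) > 1e-9:
        raise ValueError("class mix fractions must sum to 1")
    if abs(sum(bmix.values()) - 1) > 1e-9:
        raise ValueError("behavior mix fractions must sum to 1")
    rng = np.random.default_rng(seed)

    counts = {k: int(round(v * n_genes)) for k, v in mix.items()}
    # absorb rounding drift into the unbiased class
    counts[("none", "none")] += n_genes - sum(counts.values())

    rows = []
    gid = 0
    for (kind, tissue_cls), n in counts.items():
        for _ in range(n):
            gene = f"g{gid:05d}"
            gid += 1
            row = {
                "sex_class": "none", "sex_high": "",
                "species_class": "none", "species_high": "",
                "tissue_class": "none", "tissue_high": "",
                "baseline_fpkm": baseline_fpkm,
                "specific_fpkm": specific_fpkm,
                "fold_change": fold_change,
                "dispersion": dispersion,
                "intersex_behavior": "no_change",
                "intersex_reference": "female",
            }
            if kind == "low":
                row["baseline_fpkm"] = low_fpkm
            elif kind == "none":
                pass
            elif kind in ("specific", "biased"):
                row["sex_class"] = kind
                row["sex_high"] = str(rng.choice(["male", "female"]))
            elif kind in ("species_specific", "species_biased"):
                row["species_class"] = kind.split("_")[1]
                row["species_high"] = str(rng.choice(["U", "M"]))
            else:
                raise ValueError(f"unknown class kind {kind!r}")
            if tissue_cls != "none":
                row["tissue_class"] = tissue_cls
                row["tissue_high"] = str(rng.choice(TISSUES))
            if kind in ("low", "none") and tissue_cls == "none":
                row["fold_change"] = 1.0  # fold is meaningless without an effect
            if row["sex_class"] != "none":
                row["intersex_reference"] = row["sex_high"]
                row["intersex_behavior"] = str(
                    rng.choice(list(bmix), p=list(bmix.values()))
                )
            rows.append((gene, row))
    table = pd.DataFrame({g: r for g, r in rows}).T[TRUTH_COLUMNS]
    table.index.name = "gene_id"
    for c in ("baseline_fpkm", "specific_fpkm", "fold_change", "dispersion"):
        table[c] = table[c].astype(float)
    truth = TruthTable(table)

    if normalize_library:
        # expected fraction of the library each pure-species sample's
        # composition explains, at the default 1 kb length (pure-species
        # groups are the ones the cluster thresholds are applied to)
        pure_groups = [
            f"{sp}_{sex}_{tissue}"
            for sp in ("U", "M") for sex in ("male", "female") for tissue in TISSUES
        ]
        means = truth.group_mean_fpkm(pure_groups)
        s = float((means.to_numpy().sum(axis=0) * 1000 / 1e9).mean())
        if s > 0:
            # rescale expressed genes only: planted-low baselines and the
            # pinned specific-side FPKM keep their absolute (sub-threshold)
            # values, and their library contribution is negligible
            table = table.copy()
            expressed = table["baseline_fpkm"] >= 1.0
            table.loc[expressed, "baseline_fpkm"] /= s
            truth = TruthTable(table)
    return truth


# --- planted-label oracle ---------------------------------------------------


def planted_de_tables(
    truth: TruthTable, comparisons: dict[str, tuple[str, str]], prior_fpkm: float = 0.25
) -> dict[str, pd.DataFrame]:
    """Noiseless DE tables computed from the planted group means.

    For each comparison the planted means stand in for the estimated ones,
    the log2 fold change uses the same prior count as the estimator, and the
    FDR is 0 where the planted means differ and 1 where they are equal.  The
    expected (planted) cluster subtype or intersex pattern of a gene is then
    whatever the classification rules produce on these tables — the label
    the pipeline would recover with unlimited replication.
    """
    groups = sorted({g for pair in comparisons.values() for g in pair})
    means = truth.group_mean_fpkm(groups)
    out = {}
    for comp_id, (ga, gb) in comparisons.items():
        a = means[ga]
        b = means[gb]
        log2fc = np.log2((b + prior_fpkm) / (a + prior_fpkm))
        sig = np.where(np.isclose(a, b, rtol=1e-9), 1.0, 0.0)
        de = pd.DataFrame(
            {
                "log2fc": log2fc,
                "pvalue": sig,
                "fdr": sig,
                "mean_fpkm_a": a,
                "mean_fpkm_b": b,
            },
            index=truth.gene_ids,
        )
        de.attrs["comparison_id"] = comp_id
        de.attrs["group_a"] = ga
        de.attrs["group_b"] = gb
        out[comp_id] = de
    return out


# --- phenotype simulation ---------------------------------------------------


@dataclass
class PhenotypeGenerator:
    """Categorical phenotype model per pupa type.

    For each pupa type: the number of individuals, a distribution over adult
    germline classes 1-5, and distributions over MAG counts {0,1,2} and
    spermatheca counts {0..4}.
    """

    counts: dict[str, int]
    class_probs: dict[str, dict[int, float]]
    mag_probs: dict[str, dict[int, float]] = field(default_factory=dict)
    spermatheca_probs: dict[str, dict[int, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for ptype, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative individual count for pupa type {ptype!r}")
        for name, dists in (
            ("class", self.class_probs),
            ("mag", self.mag_probs),
            ("spermatheca", self.spermatheca_probs),
        ):
            for ptype, dist in dists.items():
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{name} probabilities for pupa type {ptype!r} sum to {total}, not 1"
                    )
                if any(p < 0 for p in dist.values()):
                    raise ValueError(f"negative {name} probability for {ptype!r}")


def simulate_phenotypes(gen: PhenotypeGenerator) -> list:
    """Draw per-individual records; counts per pupa type are exact, category
    frequencies converge to the requested probabilities."""
    from .phenotype import PhenotypeRecord

    rng = np.random.default_rng(gen.seed)
    records = []
    for ptype in sorted(gen.counts):
        n = gen.counts[ptype]
        cdist = gen.class_probs.get(ptype)
        mdist = gen.mag_probs.get(ptype)
        sdist = gen.spermatheca_probs.get(ptype)
        for i in range(n):
            cls = (
                int(rng.choice(list(cdist), p=list(cdist.values())))
                if cdist else None
            )
            mag = int(rng.choice(list(mdist), p=list(mdist.values()))) if mdist else None
            sp = int(rng.choice(list(sdist), p=list(sdist.values()))) if sdist else None
            records.append(
                PhenotypeRecord(
                    individual_id=f"{ptype}_{i:04d}",
                    pupa_type=ptype,
                    adult_class=cls,
                    mag_count=mag if cls is not None else None,
                    spermatheca_count=sp if cls is not None else None,
                    rotation_24h="yes" if ptype == "normal" else "no",
                    rotation_48h="n/a",
                )
            )
    return records
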