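# Methods

## Design and data model

The experimental design is a 14-group layout: species ∈ {U (*Ae. aegypti*
Uganda), M (*Ae. mascarensis*), UUM (backcross)} × sex × tissue
(reproductive organs vs. carcass), where intersex individuals exist only in
the backcross, giving 2·2·2 + 3·2 = 14 (species, sex, tissue) groups with
three biological replicates each (42 samples). All containers are pandas
structures: counts are a gene × sample integer DataFrame, DE results are
per-comparison DataFrames with `log2fc`, `pvalue`, `fdr` and both
group-mean FPKMs, and cluster membership is a gene × 5 table of subtype
labels serialized to the presence/absence (0/1) convention.

## Quantification

FPKM_gs = c_gs · 10⁹ / (L_g · N_s). The library size N_s is the column sum
over the supplied gene universe — there is no external "mapped reads"
figure, which keeps the quantity self-contained and reproducible.
Thresholding ("FPKM below 1") is applied to arithmetic group means over
replicates, the only summary that supports a single per-gene decision per
comparison. Genes without a length entry are dropped with a warning rather
than defaulted; a silently defaulted length would corrupt FPKM. Gene
lengths default to 1,000 bp in simulation and examples so that FPKM and
counts-per-million coincide up to a constant, which keeps hand oracles
simple.

## Differential expression

The paper-trail analyses in this field delegate two-group testing to an
external package; here the test is self-contained so that the pipeline has
no statistical dependency beyond scipy/statsmodels, and no claim of exact
numerical agreement with any external tool is made — agreement is asserted
at the level of downstream classification on strong planted effects.

- **Normalization.** Total-count scaling to the geometric-mean library
  size, with rounding so pseudo-counts stay integral. Trimmed-mean
  normalization is deliberately out of scope; the hook for alternatives is
  the `library_sizes` argument.
- **Dispersion.** Per gene, the method-of-moments estimate
  φ̂ = (s² − m)/m² within each group with ≥ 2 replicates, combined with
  n−1 weights and floored at 0; the common value is the mean of the raw
  per-gene estimates. The delivered estimate is the shrunk
  φ* = 0.7·φ̄ + 0.3·φ̂_g. The 0.7 weight reflects how little information
  three replicates carry about a second moment; at 50 replicates the shrunk
  estimates land within 25% of a planted φ = 0.2 for ≥ 90% of genes, and on
  Poisson data they collapse toward 0.
- **Exact test.** A sum of n iid NB(μ, φ) variables is NB(nμ, φ/n), so
  conditional on the grand total the group-A sum follows a
  beta-binomial-type law with size parameters n_A/φ and n_B/φ that is free
  of μ. The two-sided p-value sums the conditional probabilities of every
  split as or less likely than the observed one (log-space, with a 1e-10
  tie tolerance); at φ < 1e-8 the conditional law is the binomial of the
  Poisson model. All-zero genes get p = 1 by convention. This construction
  is validated against a brute-force oracle that enumerates per-sample
  count compositions (never using the sum-closure shortcut) to 1e-12, and
  its type-I error on 5,000 simulated null genes at 3 vs 3 replicates stays
  within [α/2, 2α] for α ∈ {0.01, 0.05}.
- **Fold change.** log2((mean_B + 0.25)/(mean_A + 0.25)) on group-mean
  FPKMs; the 0.25 prior keeps specific genes finite and deterministic at
  boundaries. FDR is Benjamini–Hochberg applied per comparison, not pooled
  across comparisons.

## Cluster assignment

Each comparison row is categorized by a fixed decision tree — low (both
means < 1), unbiased (|log2FC| ≤ 2 or FDR > 0.05), specific (losing mean
< 1), biased (otherwise) — with the comparison operators taken literally,
so |log2FC| = 2 exactly is unbiased and FDR = 0.05 exactly is significant.
"More than 1 FPKM" in the unbiased rule is read as "not low" (at least one
group mean ≥ 1); otherwise genes with one mean just below 1 would be
unclassifiable.

Five clusters combine pure-species comparisons: sex within each tissue
(2 comparisons each), species within each tissue (2 each), and tissue
within each species × sex (4). The default combine rule treats low and
unbiased comparisons as uninformative: a gene joins when at least one
comparison is directed and none is directed the other way, as `_specific`
if all directed calls are specific and `_biased` otherwise. The strict
variant (every comparison directed and consistent) is available as
`rule="all"`, but it cannot be the default: a gene that is both
female-specific and reproductive-specific is necessarily in the low
category for the male-side tissue comparisons, so under the strict rule
every joint sex × tissue group would be empty by construction — in
contradiction with such genes demonstrably existing. A gene low in *every*
constituent comparison gets the `low` subtype and is excluded from the
cluster and from "unbiased" group definitions alike.

## Gene groups and intersex patterns

For a sex and tissue, six groups intersect the tissue-matched sex cluster
(`female_specific` etc.) with the TISSUE cluster; "tissue-unbiased" means
no TISSUE subtype while not tissue-low, the only reading that makes the six
groups exhaustive over non-low sex-associated genes.

Pattern classification uses five comparisons per tissue with a
reference sex — female references for female-associated groups, male for
male-associated ones (configurable), log2FC oriented intersex-over-reference
in the last three comparisons so "Downregulation" means lower in
intersexes. Elementary calls: no change when −2 < log2FC < 2 (any FDR) or
|log2FC| ≥ 2 with FDR > 0.05; up when log2FC ≥ 2 with FDR ≤ 0.05; down when
log2FC ≤ −2 with FDR ≤ 0.05. The down rule's sign is the symmetric
counterpart of the up rule (the band −2 < log2FC < 2 leaves no other
consistent reading). The final label is No change only if all five calls
are no change; Up/Downregulation only if the first two calls (pure species
vs. normal backcross) are no change and the last three are unanimous;
everything else is Other.

## Phenotype association

Contingency tables are built from per-individual records by cross-
tabulating any two attributes, with an optional collapse map applied first
(the canonical one folds germline classes 3–5, i.e. any ovarian tissue,
into "intersex"). X² excludes expected-zero cells with a warning; G sums
over observed-positive cells; both use the upper χ² tail with
(rows−1)(cols−1) df and no continuity correction. Both implementations are
hand-rolled from the O/E formulas and cross-checked in the tests against
scipy's independent implementation to 1e-8. The published association
P-values for the full type × class tables are not reproduced here because
the underlying per-individual tables ship only as supplementary downloads;
the reconstructed records match the *printed* margins, which is sufficient
for the proportion checks and for demonstrating the same qualitative
association on the collapsed tables.

## Synthetic data: what it emulates and what it does not

Truth is specified per gene as one (class, high side) pair per factor —
sex, species, tissue; class ∈ {none, biased, specific} — plus a baseline
(high-side) FPKM, a linear fold change, an NB dispersion φ, and an intersex
behaviour. Group means compose multiplicatively: the low side of a biased
axis divides by the fold, the low side of a specific axis is pinned at a
near-zero FPKM (default 0.05). Backcross samples take the U side of
species effects (the backcross is to *Ae. aegypti* females). Intersex
groups derive from the backcross mean of the gene's reference sex:
`no_change` copies it, `down`/`up` divide/multiply by the fold, and
`other` instead shifts the *normal backcross* reference group ×8 away from
the pure species, which forces the first two comparisons to deviate and
the gene to classify as Other deterministically.

Defaults encode the strong-effect regime the recovery analyses assume:
baseline 200 FPKM, fold 64 (log2 = 6), φ = 0.05, specific side 0.05 FPKM,
3 replicates, 1e6-fragment libraries; behaviour mix for sex-associated
genes 60% no_change / 20% down / 20% other (no upregulation, matching the
intuition that a gene copying the reference mean cannot rise above it).
Counts are drawn NB with mean FPKM·L·N/10⁹ from a single
`numpy.random.default_rng(seed)` stream, so identical inputs give
byte-identical matrices. Because FPKM re-derived from counts uses the
realized library size, the default truth constructor rescales expressed
genes by one global constant so each pure-species sample's planted
composition sums to ~10⁶ FPKM·kb — planted and recomputed FPKM then agree
up to NB noise while every fold change and threshold relationship is
preserved exactly. Planted-low and specific-side values are left at their
absolute sub-threshold FPKMs (their library contribution is negligible).

The generator does not emulate: batch or lane effects, GC/length bias,
per-group variance heterogeneity between intersexes and normals (φ is a
per-gene column; nothing is known about intersex-specific variance, so it
is exposed rather than guessed), isoform structure, or correlated genes.
A passing recovery test therefore demonstrates that the classification
rules invert the planted model under its own assumptions — not that real
libraries satisfy those assumptions.

## Recovery scoring

The planted "expected" label of a gene is defined by running the identical
classification rules on the *noiseless* planted group means (FDR set to 0
where means differ, 1 where they are equal). Recovery is the percentage of
genes with an informative expected label (a directed cluster subtype; group
membership for patterns) whose pipeline label matches. At the default
strong-effect regime the end-to-end rates are ≈ 99% for cluster subtypes
and ≈ 100% for intersex patterns; the acceptance gate is ≥ 90%.

## Problem sizes

The shipped analyses use 1,000–1,200 genes for end-to-end recovery, 5,000
genes for null calibration, 10,000 draws for NB moment checks, and totals
≤ 30 for the enumeration oracle — sizes at which every Monte-Carlo bound in
the tests has comfortable margin while the whole suite stays fast.

## Known limitations

- The exact test conditions on totals with an estimated dispersion; no
  uncertainty in φ* is propagated (a quasi-likelihood extension is the
  natural upgrade path).
- Normalization is total-count only; composition-robust alternatives
  (e.g. trimmed-mean) must be supplied via explicit library sizes.
- BH is applied per comparison; genes appearing in several comparisons are
  not jointly corrected.
- The five-comparison reference-sex convention is configurable but the
  pipeline runs one reference sex per analysis; mosaic designs mixing
  references within one group are not supported.
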