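"""Simulate a backcross RNA-seq experiment with planted truth.

Builds the 14-group x 3-replicate design (two pure species, the backcross
with normal males/females and intersexes, two tissues), plants gene classes
(low, unbiased, sex/species/tissue-specific and -biased, plus joint
sex x tissue classes), and draws a negative-binomial count matrix.
"""

from intersexpr import default_design, default_truth, simulate_counts

design = default_design()
truth = default_truth(n_genes=500, seed=1)
counts = simulate_counts(design, truth, target_library_size=1_000_000, seed=1)

print(f"design: {len(design)} samples in {len(design.groups())} groups")
print("planted classes:")
print(truth.planted_class.value_counts().to_string())
print(f"\ncount matrix: {counts.data.shape[0]} genes x {counts.data.shape[1]} samples")
print(f"mean library size: {counts.library_sizes().mean():,.0f} fragments")
# The class counts are the ground truth every downstream stage is scored
# against; library sizes land near the 1e6 target because the planted FPKM
# composition is normalized to be self-consistent.
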