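"""Cross-species chromosome homology from ortholog placement.

When two genomes are too diverged for collinear blocks, homology is read
from where one-to-one orthologs land: per (focal, target) chromosome pair a
one-sided binomial test (BH-corrected across the grid) asks whether the
focal chromosome carries more target-chromosome orthologs than the target's
genome-wide share predicts.
"""

from macrosyn import homology
from macrosyn.simulate import SimulationConfig, simulate_pair

cfg = SimulationConfig(seed=14, n_translocations=8, n_fissions=2, n_fusions=1)
genome_a, genome_b, orthologs, truth = simulate_pair(cfg)

chrom_map = homology.build_chromosome_map(orthologs, genome_a, genome_b)
grid = homology.chromosome_enrichment(chrom_map)
significant = grid[grid["q"] < 0.05]
print(f"{len(chrom_map)} mapped ortholog pairs; "
      f"{len(significant)}/{len(grid)} chromosome pairs BH-significant:")
print(significant[["focal_chrom", "target_chrom", "observed", "trials",
                   "odds_ratio", "q"]].to_string(index=False))

conserved = homology.x_conservation(chrom_map, "chr1", truth.x_label)
print(f"X ortholog conservation: {conserved:.0f}% of focal-X orthologs "
      f"remain on the target X")
res = homology.x_vs_autosome_or_test(grid, "chr1")
print(f"X vs autosome |log2 odds ratio|: W = {res.statistic:.0f}, "
      f"p = {res.p_value:.3g}")
# With the X protected, focal-X orthologs map almost exclusively to the
# target X, giving near-100% conservation and extreme X odds ratios.
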