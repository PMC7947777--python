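"""Morph-biased expression, X expression and dosage compensation.

The simulated expression matrix covers four morphs (FA unwinged asexual
female, FW winged asexual female, M winged male, N nymph) with six
replicates each: X-linked genes are expressed lower, and 5% of genes are
male-biased with 70% of them on the X — the aphid pattern.
"""

from macrosyn import expression
from macrosyn.io import morphs_from_columns
from macrosyn.simulate import SimulationConfig, simulate_ancestor, simulate_expression

cfg = SimulationConfig(seed=44, n_chrom=4, genes_per_chrom=500)
genome = simulate_ancestor(cfg)
gene_chrom = {g.gene_id: g.chrom for g in genome.genes}
tpm, counts, de, true_male_biased = simulate_expression(genome, cfg, seed=45)
morphs = morphs_from_columns(tpm.columns)

expressed = expression.expressed_filter(counts)  # count > 4 in >= 12/24
labels = expression.classify_morph_bias(de)  # q < 0.05, |beta| > 0.5
n_biased = int(labels["morph_biased"].sum())
n_male = int(labels["male_specific"].sum())
print(f"expressed genes: {int(expressed.sum())}/{len(counts)}")
print(f"morph-biased: {n_biased}; male-specific: {n_male} "
      f"({expression.male_biased_fraction(n_male, n_biased):.1f}%); "
      f"planted: {len(true_male_biased)}")

enrich = expression.scaffold_enrichment(
    set(labels.index[labels["male_specific"]]),
    set(counts.index[expressed]),
    gene_chrom,
)
print(enrich.to_string(index=False))

x_test = expression.x_expression_test(tpm, morphs, gene_chrom, "chr1")
print(f"X vs autosome FA expression: W = {x_test.statistic:.0f}, "
      f"p = {x_test.p_value:.3g} (X is expressed lower)")

dosage, table = expression.dosage_compensation_test(tpm, morphs, gene_chrom, "chr1")
x_median = table.loc[table.is_x & ~table.extreme, "log2_m_fa"].median()
print(f"dosage compensation: X median log2 M:FA = {x_median:.3f} "
      f"(0 = fully compensated, -1 = uncompensated single-copy X)")
# The per-chromosome binomial enrichment should flag only chr1 (the X),
# mirroring the X-enrichment of male-biased genes planted by the simulator.
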