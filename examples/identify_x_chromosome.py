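"""Identify the X chromosome from male vs female read depth.

Aphid males are X0, so male sequencing depth on the X is half the asexual
female depth while autosomes match. The caller normalizes the per-window
male:female ratio with a coverage correction factor and calls a chromosome
X when most windows sit near ratio 0.5.
"""

from macrosyn import coverage
from macrosyn.simulate import SimulationConfig, simulate_coverage, simulate_pair

cfg = SimulationConfig(seed=33, depth_m=50.0, depth_f=50.0)
_, genome_b, _, truth = simulate_pair(cfg)
depth_m, depth_f = simulate_coverage(genome_b, cfg, seed=34)

windows = coverage.window_depth_ratio(depth_m, depth_f, window=100_000)
factor = coverage.normalization_factor(windows, excluded_chroms=[truth.x_label])
calls, windows = coverage.call_x(windows)

print(f"coverage correction factor (reported 1 dp): {round(factor, 1)}")
for chrom, grp in windows.groupby("chrom"):
    print(f"  {chrom}: median normalized M:FA ratio "
          f"{grp['ratio_norm'].median():.2f} over {len(grp)} windows "
          f"-> {calls[chrom]}")
print(f"true X: {truth.x_label}")
# A median ratio near 0.5 marks the single-copy male X; near 1.0 marks a
# diploid autosome; chromosomes with <20 windows stay ambiguous.
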