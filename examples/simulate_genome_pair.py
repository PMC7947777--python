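"""Simulate a genome pair with known ground truth and write standard files.

Builds an ancestor genome and a descendant rearranged by inversions,
reciprocal translocations, a fission and a fusion (the X is protected),
then writes GFF3 gene annotations, a TE BED and the ortholog table the
analysis stages consume.
"""

import tempfile
from pathlib import Path

from macrosyn.io import write_bed, write_gff3
from macrosyn.simulate import SimulationConfig, plant_tes, simulate_pair

cfg = SimulationConfig(seed=7)
genome_a, genome_b, orthologs, truth = simulate_pair(cfg)
tes = plant_tes(genome_b, cfg, seed=8, truth=truth)

out = Path(tempfile.mkdtemp(prefix="macrosyn_"))
write_gff3(genome_a, out / "genomeA.gff3")
write_gff3(genome_b, out / "genomeB.gff3")
write_bed(tes, out / "tes_B.bed")
(out / "orthologs.tsv").write_text(
    "".join(f"{a}\t{b}\n" for a, b in orthologs)
)

print(f"ancestor: {len(genome_a.genes)} genes on "
      f"{len(genome_a.chromosomes.lengths)} chromosomes")
print(f"descendant chromosomes: {dict(genome_b.chromosomes.lengths)}")
print(f"rearrangement events: "
      f"{[(e.kind, e.chroms) for e in truth.events]}")
print(f"true junctions (descendant coordinates): {len(truth.junctions)}")
print(f"TEs planted: {len(tes)}")
print(f"files written to {out}")
# The junction list is the ground truth that downstream breakpoint-recovery
# checks score against; the ortholog table is the identity map of gene ids.
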