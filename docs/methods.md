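# Methods

`macrosyn` implements the chromosome-evolution analyses used to compare
chromosome-scale genome assemblies of rapidly rearranging insect genomes
(the motivating system is aphids: holocentric chromosomes, X0 sex
determination, extensive autosomal rearrangement with a conserved X). This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not establish.

## Synteny blocks

Anchors are one-to-one ortholog pairs carrying dense gene-order ranks
(assigned per chromosome by gene midpoint; ties by start then id). Per
chromosome pair and orientation, the block finder runs
longest-increasing-subsequence dynamic programming over anchors sorted by
focal rank, subject to a gap constraint: between consecutive chain members,
`rank difference − 1 ≤ max_gap` on *both* genomes. Chains are extracted
greedily by descending anchor count (anchor-disjoint), and chains below
`min_genes` anchors are discarded. Defaults `min_genes=10`, `max_gap=25`
are the standard MCScanX-style parameterization for insect comparisons;
`min_genes` counts anchors (ortholog pairs), not gap genes.

Determinism: among equal-count chains the selection order is (count
descending, rank-A tuple ascending lexicographically, `+` before `−`). A
region-multiplicity cap (default 2) drops blocks whose rank interval on
either genome already overlaps two accepted blocks. Gene strand is stored
but ignored; block orientation comes from the anchor rank trend.

Anchors come from a provided ortholog table rather than an internal
all-vs-all BLAST stage. This is a deliberate deviation from the classic
MCScanX input: it matches the orthology-restricted variant of the analysis
and removes a heavyweight alignment dependency; tandem-array collapsing is
unnecessary because inputs are one-to-one.

**Known blind spots** (inherent to the gap-25 chaining, verified on
synthetic genomes): an insertion of ≤ `max_gap` foreign genes inside an
otherwise collinear run is absorbed into the spanning block, and repeated
reciprocal translocations on the same chromosome pair can re-join
near-adjacent ancestral material invisibly. Both depress breakpoint-recall
slightly below 1 (mean ≈ 0.92 on the default synthetic world).

## Breakpoint regions

Block spans on the focal genome (first member gene start to last member
gene end) are restricted to autosomes, merged where they overlap, and
complemented per chromosome. Only interior gaps count: segments before the
first and after the last block are excluded because chromosome ends may be
subtelomeric repeat rather than rearrangement junctions. Gaps of length ≤ 0
are dropped; no further minimum-length filter is applied. Recovery against
simulator truth scores recall (junctions within a slack of a region;
default 50 kb) and precision (regions containing ≥ 1 junction).

## TE enrichment permutation test

A TE counts once per region it overlaps by ≥ 1 bp; span contributions are
clipped to the region; classes (DNA, LINE, LTR, RC, SINE, Unknown) are
summed independently. The null shuffles the observed region set `n_perm`
times (default 10,000), preserving each region's length; for each placement
the chromosome is drawn among autosomes long enough to hold the region with
probability proportional to length, and the start uniformly. Random regions
within one set may overlap each other: the null is uniform genomic
position, and rejection sampling would bias long-region placement on short
chromosomes (this inflates within-set variance slightly, making the test
marginally conservative).

The permutation statistic is the per-class count. Two empirical
p estimators are reported: `p_empirical` = #(null ≥ observed)/N (may be exactly
0) and the add-one `p_conservative` = (#+1)/(N+1) for downstream use.
Span-based fold enrichment is reported alongside: expected span = class
autosomal span × (region bp / autosomal bp), fold = observed/expected —
algebraically the class's fraction-in-regions over the regions' fraction of
the autosomes.

Window densities (fraction of bp covered per 100-kb or 1-Mb fixed window,
same-class intervals merged first) and the telomere-gradient statistic
(Pearson r of window density against distance from the window midpoint to
the nearest chromosome end) complete the module.

## X identification from coverage

With X0 males, male depth on the X is half the female depth. Per 100-kb
window the raw male:female ratio is computed (windows with zero female
depth are excluded; trailing windows shorter than half the window size are
dropped). The coverage correction factor is mean male depth over mean
female depth outside putative X chromosomes — equivalently the factor that
scales female depth so autosomal ratios center on 1; it is reported rounded
to one decimal but applied unrounded. Calling is two-pass: (1) candidate X
= chromosomes whose median raw ratio is below 0.75× the genome-wide median;
(2) recompute the factor excluding candidates, then call X if ≥ 80% of a
chromosome's normalized ratios lie in [0.35, 0.65], autosome if ≥ 80% lie
in [0.8, 1.2], else ambiguous; chromosomes with < 20 usable windows are
always ambiguous. These thresholds are not biology — they separate Poisson
sampling noise at ≥ 20× depth — and are all configurable.

## Chromosome homology by ortholog enrichment

For genomes too diverged for collinear blocks, each (focal, target)
chromosome pair gets a one-sided binomial test: successes = focal-chromosome
orthologs from the target chromosome, trials = all orthologs on the focal
chromosome, success probability = the target chromosome's share of all
chromosome-anchored orthologs (pairs with an unplaced gene are excluded and
logged). BH correction is applied across the whole focal×target grid as one
family. Depletion is read from odds ratios (observed/expected) below 1
rather than a second test; the X-vs-autosome comparison ranks |log2 OR|
values of focal-X pairs against focal-autosome pairs (two-sided rank-sum).
A pair with zero observed orthologs gets |log2 OR| = ∞, which ranks
correctly. X conservation is the percentage of focal-X orthologs whose
partner is on the target X.

## Expression and dosage compensation

Morphs: FA (unwinged asexual female), FW (winged asexual female), M (winged
male), N (nymph). Expressed = estimated count > 4 in ≥ half the samples.
Morph-biased = q < 0.05 and |beta| > 0.5 in any contrast against FA;
male-specific additionally requires beta_M > 0.5 with beta_FW and beta_N
below 0.5. The DE model producing q and beta is an input contract (an
external likelihood-ratio fit); it is not recomputed here. Per-chromosome
enrichment of male-specific genes uses a one-sided binomial test with
trials = expressed genes on the chromosome and probability = the overall
male-specific fraction among placed expressed genes.

Morph means are arithmetic means of replicate TPM ("average expression"
is unspecified upstream; geometric means would down-weight outlier
replicates but arithmetic is the common reading). The dosage test takes
log2(mean M / mean FA) for genes with mean TPM ≥ 1 in both morphs
(interpreted per-morph-mean, not per-replicate) and rank-sums X against
autosomes; genes with |ratio| > 2.5 are flagged extreme and excluded only
from exported figure tables, never from the test. Full compensation
predicts an X median ratio near 0; no compensation predicts ≈ −1.

## TE age landscapes

K2P distance d = −½·ln((1 − 2P − Q)·√(1 − 2Q)) from transition (P) and
transversion (Q) fractions; saturated inputs raise an error and such
records are excluded from landscapes (counted separately). From alignments,
gap/N columns are skipped; the CpG adjustment excludes transition columns
at consensus CpG dinucleotides from both the transition count and the
scored-column total — the exact upstream reweighting is undocumented, so
exclusion is used as a defensible, togglable approximation. Divergence
values present in input annotations take precedence over alignment-based
computation. Landscapes bin TE bp by percent divergence (1-point bins over
[0, 50)) split into autosomal and X sets; the recency threshold is half the
median synonymous-site divergence between the species' orthologs (same
units as the divergence column), and bp below it is "recent". The X-size
attribution report turns the recent-X TE span into integer percentages of
the X-size and genome-size differences.

## Statistics

Binomial tails and Pearson r come from scipy; BH from statsmodels. The 2×2
chi-square uses no continuity correction (the genome-scale counts it serves
make Yates irrelevant). The Wilcoxon rank-sum is implemented here because
the required contract — midranks with exact enumeration for n1+n2 ≤ 20
including ties, otherwise the normal approximation with tie and 0.5
continuity corrections — matches R's `wilcox.test` behaviour, which scipy's
exact method (no ties allowed) does not provide. The reported statistic is
the Mann-Whitney U of the first sample (R's W). Sidedness defaults: binomial
one-greater (enrichment), rank-sum two-sided. Note that BH adjustment is
*not* idempotent (re-adjusting adjusted values changes them); the tested
invariants are order-invariance, domination of raw p-values and the cap at 1.

## The synthetic world

The simulator states one fixed world rather than a tuning surface:

- **Genome**: 5 chromosomes × 400 genes (first chromosome is the X), gene
  lengths lognormal(ln 3000, 0.6) and intergenic gaps lognormal(ln 9000,
  0.7) — about 14 kb of sequence per gene, the density of a ~400 Mb /
  27k-gene aphid genome.
- **Rearrangements**: 5 inversions, 5 reciprocal terminal-segment
  translocations, 1 fission, 1 fusion; X protected by default. Breakpoints
  fall only in intergenic space, so the gene-anchor abstraction is exact.
  True junctions are the gene adjacencies present in the descendant but not
  the ancestor, located at intergenic midpoints; adjacencies destroyed by
  later events drop out automatically.
- **TEs**: class fractions DNA 6%, LTR 5%, RC 4%, Unknown 4%, LINE 3%,
  SINE 0.5% (~22% of the genome), lengths lognormal(ln 600, 0.8), no
  same-class overlap. Optional per-class placement-intensity multipliers
  within 50 kb of true junctions; because placement is rejection-sampled
  against same-class overlap, the realized density ratio sits slightly
  below the planted multiplier (≈ 2.3 for a planted 2.5). Ages are a
  mixture: recent exponential burst (scale 2 divergence points, weight 0.4)
  plus an old uniform component on [10, 40].
- **Coverage**: Lander–Waterman read counts — reads per window ~
  Poisson(depth × window / 150 bp), window depth = reads × 150 / window;
  male mean halved on the X. A literal single Poisson draw of the mean
  depth per 100-kb window would give the ratio a spread (~0.2 at 50×) that
  no window-fraction caller could work with; real window means average
  thousands of read placements.
- **Expression**: log2 TPM baseline N(2, 1.5) across genes (the 1.5 spread
  is what lets a −0.5 log2 X shift remain detectable at ~2,000 genes
  through the TPM > 1 filter, which truncates the low tail), replicate
  noise 0.25 log2 (0.1 in the dosage scenarios), X shift −0.5 log2, 5% of
  genes male-biased (+2 log2 in males), 70% of them on the X, 6 replicates
  × 4 morphs. Counts are Poisson(TPM × 20). With `dosage_compensated=False`
  X genes lose one additional log2 unit in males. The emitted DE table
  derives q and betas from the generative truth with small noise — it
  emulates the *output shape* of a DE fit, not its sampling distribution.

What a green synthetic test establishes: the formulas, the chaining and
complement logic, the permutation machinery's calibration and power, and
the callers' decision rules, against a world where the truth is known. What
it does not establish: robustness to annotation error, missing or
many-to-many orthologs, assembly gaps, GC- or gene-density-confounded TE
placement, or real RNA-seq dispersion — none of which the generator
emulates.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) is converted only at the format boundary. Empty inputs raise
`ValueError` where a statistic would be undefined (empty groups, empty null
sets, zero denominators); undefined summaries are returned as `None` with
`n=0` rather than NaN. The rank-sum exact path compares twice-the-rank
integers so midrank ties never hit floating-point equality. All simulation
entry points take an explicit integer seed and are byte-deterministic given
it.
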