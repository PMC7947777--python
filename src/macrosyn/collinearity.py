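"""Collinear synteny-block detection between two genomes.

Anchors are one-to-one ortholog pairs carrying gene order ranks from each
genome. Per chromosome pair and orientation, maximal chains are found by
longest-increasing-subsequence dynamic programming under a gap constraint
(at most ``max_gap`` intervening genes on either genome between consecutive
anchors); chains are extracted greedily by descending anchor count and
chains below ``min_genes`` anchors are discarded. The defaults (10 anchors,
gap 25) are the standard MCScanX-style parameterization for insect-genome
comparisons.

Among equal-count candidate chains the deterministic order is: smaller
rank-A tuple first (lexicographic), then '+' orientation before '-'.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats
from .types import Anchor, Genome, SyntenyBlock, TestResult

__all__ = ["build_anchors", "chain_blocks", "block_spans", "block_stats"]

logger = logging.getLogger(__name__)


def build_anchors(
    genome_a: Genome, genome_b: Genome, orthologs: list[tuple[str, str]]
) -> list[Anchor]:
    """Turn an ortholog table into rank-bearing anchors.

    Pairs with a gene on an unplaced scaffold are excluded (count logged);
    an id missing from either gene set is an error.
    """
    idx_a = genome_a.gene_index()
    idx_b = genome_b.gene_index()
    anchors: list[Anchor] = []
    n_excluded = 0
    for ga, gb in orthologs:
        if ga not in idx_a:
            raise KeyError(f"ortholog id {ga!r} not in genome A")
        if gb not in idx_b:
            raise KeyError(f"ortholog id {gb!r} not in genome B")
        a, b = idx_a[ga], idx_b[gb]
        if (
            genome_a.chromosomes.roles.get(a.chrom) == "unplaced"
            or genome_b.chromosomes.roles.get(b.chrom) == "unplaced"
        ):
            n_excluded += 1
            continue
        anchors.append(Anchor(ga, gb, a.chrom, b.chrom, a.rank, b.rank))
    if n_excluded:
        logger.info("build_anchors: excluded %d unplaced-scaffold pairs", n_excluded)
    return anchors


def _best_chain_oriented(
    ra: np.ndarray, rb: np.ndarray, max_gap: int
) -> list[int] | None:
    """Lexicographically-smallest (by rank-A sequence) maximum-length chain
    with strictly increasing ra and rb and per-genome gaps <= max_gap.
    ``ra`` must be sorted ascending. Returns indices into ra/rb."""
    n = ra.size
    if n == 0:
        return None
    # f[i] = length of the longest valid chain starting at i
    f = np.ones(n, dtype=np.int64)
    for i in range(n - 2, -1, -1):
        tail = slice(i + 1, n)
        ok = (
            (ra[tail] > ra[i])
            & (ra[tail] - ra[i] - 1 <= max_gap)
            & (rb[tail] > rb[i])
            & (rb[tail] - rb[i] - 1 <= max_gap)
        )
        if ok.any():
            f[i] = 1 + f[tail][ok].max()
    best_len = int(f.max())
    chain: list[int] = []
    need = best_len
    prev = -1
    for i in range(n):
        if f[i] < need:
            continue
        if prev >= 0:
            if not (
                ra[i] > ra[prev]
                and ra[i] - ra[prev] - 1 <= max_gap
                and rb[i] > rb[prev]
                and rb[i] - rb[prev] - 1 <= max_gap
            ):
                continue
        chain.append(i)
        prev = i
        need -= 1
        if need == 0:
            break
    return chain


def _extract_chains(
    group: list[Anchor], min_genes: int, max_gap: int
) -> list[tuple[str, list[Anchor]]]:
    """Greedy extraction of anchor-disjoint chains from one chromosome pair."""
    remaining = sorted(group, key=lambda a: a.rank_a)
    chains: list[tuple[str, list[Anchor]]] = []
    while len(remaining) >= min_genes:
        ra = np.array([a.rank_a for a in remaining], dtype=np.int64)
        candidates: list[tuple[int, tuple, int, list[int]]] = []
        for orient_idx, orient in enumerate("+-"):
            rb = np.array(
                [a.rank_b if orient == "+" else -a.rank_b for a in remaining],
                dtype=np.int64,
            )
            chain = _best_chain_oriented(ra, rb, max_gap)
            if chain:
                key_ra = tuple(int(ra[i]) for i in chain)
                candidates.append((-len(chain), key_ra, orient_idx, chain))
        if not candidates:
            break
        candidates.sort()
        neg_len, _, orient_idx, chain = candidates[0]
        if -neg_len < min_genes:
            break
        members = [remaining[i] for i in chain]
        chains.append(("+-"[orient_idx], members))
        taken = set(chain)
        remaining = [a for i, a in enumerate(remaining) if i not in taken]
    return chains


def chain_blocks(
    anchors: list[Anchor],
    min_genes: int = 10,
    max_gap: int = 25,
    max_multiplicity: int = 2,
) -> list[SyntenyBlock]:
    """Detect synteny blocks from anchors.

    ``max_multiplicity`` caps how many accepted blocks may cover the same
    genomic region (rank interval) on either genome; blocks beyond the cap
    are dropped in extraction order. Output is invariant to the input
    anchor order.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    block_id = 0
    for key in sorted(groups):
        chrom_a, chrom_b = key
        for orientation, members in _extract_chains(groups[key], min_genes, max_gap):
            blocks.append(
                SyntenyBlock(
                    block_id=block_id,
                    chrom_a=chrom_a,
                    chrom_b=chrom_b,
                    orientation=orientation,
                    anchors=members,
                )
            )
            block_id += 1

    if max_multiplicity is not None:
        kept: list[SyntenyBlock] = []
        for blk in blocks:
            lo_a = min(a.rank_a for a in blk.anchors)
            hi_a = max(a.rank_a for a in blk.anchors)
            lo_b = min(a.rank_b for a in blk.anchors)
            hi_b = max(a.rank_b for a in blk.anchors)
            n_over_a = n_over_b = 0
            for other in kept:
                if other.chrom_a == blk.chrom_a:
                    o_lo = min(a.rank_a for a in other.anchors)
                    o_hi = max(a.rank_a for a in other.anchors)
                    if o_lo <= hi_a and lo_a <= o_hi:
                        n_over_a += 1
                if other.chrom_b == blk.chrom_b:
                    o_lo = min(a.rank_b for a in other.anchors)
                    o_hi = max(a.rank_b for a in other.anchors)
                    if o_lo <= hi_b and lo_b <= o_hi:
                        n_over_b += 1
            if n_over_a < max_multiplicity and n_over_b < max_multiplicity:
                kept.append(blk)
        blocks = kept
    return blocks


def block_spans(
    blocks: list[SyntenyBlock], genome_a: Genome, genome_b: Genome
) -> list[SyntenyBlock]:
    """Attach genomic spans: start of the first member gene to the end of
    the last, on each genome."""
    idx_a = genome_a.gene_index()
    idx_b = genome_b.gene_index()
    for blk in blocks:
        ga = [idx_a[a.gene_a] for a in blk.anchors]
        gb = [idx_b[a.gene_b] for a in blk.anchors]
        blk.span_a = (min(g.start for g in ga), max(g.end for g in ga))
        blk.span_b = (min(g.start for g in gb), max(g.end for g in gb))
    return blocks


def block_stats(
    blocks: list[SyntenyBlock],
    genome_a: Genome,
) -> dict:
    """Per-chromosome block-size summary on genome A.

    Returns the per-chromosome table (gene count, block count, mean block
    size in anchors), the Pearson correlation of mean block size against
    chromosome gene count, and the Wilcoxon rank-sum comparison of block
    sizes on the X versus the autosomes.
    """
    if not blocks:
        raise ValueError("no blocks")
    chroms = genome_a.chromosomes
    by_chrom = genome_a.genes_by_chrom()
    sizes: dict[str, list[int]] = {}
    for blk in blocks:
        sizes.setdefault(blk.chrom_a, []).append(blk.n_anchors)
    rows = []
    for chrom, blist in sorted(sizes.items()):
        rows.append(
            {
                "chrom": chrom,
                "role": chroms.roles.get(chrom, "autosome"),
                "n_genes": len(by_chrom.get(chrom, [])),
                "n_blocks": len(blist),
                "mean_block_size": float(np.mean(blist)),
            }
        )
    table = pd.DataFrame(rows)

    correlation: TestResult | None = None
    corr_error: str | None = None
    if len(table) >= 3:
        try:
            correlation = stats.pearson_r(table["n_genes"], table["mean_block_size"])
        except ValueError as exc:  # constant vector: r undefined
            corr_error = str(exc)
    else:
        corr_error = "need >= 3 chromosomes with blocks for correlation"

    x_sizes = [
        b.n_anchors for b in blocks if chroms.roles.get(b.chrom_a) == "X"
    ]
    a_sizes = [
        b.n_anchors for b in blocks if chroms.roles.get(b.chrom_a) == "autosome"
    ]
    x_vs_a: TestResult | None = None
    if x_sizes and a_sizes:
        x_vs_a = stats.wilcoxon_rank_sum(x_sizes, a_sizes, sided="two")
    return {
        "per_chrom": table,
        "correlation": correlation,
        "correlation_error": corr_error,
        "x_vs_autosome": x_vs_a,
    }
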