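"""Rearrangement breakpoint regions: the complement of merged synteny-block
spans on each autosome, excluding chromosome ends.

A breakpoint region is the interval between two consecutive merged block
footprints, so every region is flanked by a block on both sides; the
segments before the first and after the last block on a chromosome are
never regions (chromosome ends may be subtelomeric repeat, not breakpoints).
Overlapping block spans are merged before complementing, so regions always
have positive length. No minimum-length filter is applied beyond that.
"""

from __future__ import annotations

import numpy as np

from .types import BreakpointRegion, ChromosomeSet, SyntenyBlock

__all__ = [
    "autosomal_spans",
    "breakpoint_regions",
    "region_summary",
    "breakpoint_recovery",
]


def autosomal_spans(
    blocks: list[SyntenyBlock], chromosomes: ChromosomeSet, genome: str = "a"
) -> list[tuple[str, int, int, int]]:
    """Block spans on the focal genome's autosomes as
    (chrom, start, end, block_id) tuples. ``genome`` selects span A or B."""
    out = []
    for blk in blocks:
        chrom = blk.chrom_a if genome == "a" else blk.chrom_b
        span = blk.span_a if genome == "a" else blk.span_b
        if span is None:
            raise ValueError("blocks need spans; run block_spans first")
        if chromosomes.roles.get(chrom) == "autosome":
            out.append((chrom, span[0], span[1], blk.block_id))
    return out


def breakpoint_regions(
    block_spans: list[tuple[str, int, int, int]], chromosomes: ChromosomeSet
) -> list[BreakpointRegion]:
    """Complement of merged block spans per autosome, interior gaps only."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, block_id in block_spans:
        role = chromosomes.roles.get(chrom)
        if role != "autosome":
            raise ValueError(f"block span on non-autosome {chrom!r} (role {role})")
        by_chrom.setdefault(chrom, []).append((start, end, block_id))

    regions: list[BreakpointRegion] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        # merge overlapping/abutting spans, remembering flanking block ids
        merged: list[list] = []  # [start, end, id_of_max_end_block, id_of_min_start]
        for start, end, bid in spans:
            if merged and start <= merged[-1][1]:
                if end > merged[-1][1]:
                    merged[-1][1] = end
                    merged[-1][2] = bid
            else:
                merged.append([start, end, bid, bid])
        for left, right in zip(merged, merged[1:]):
            gap_start, gap_end = left[1], right[0]
            if gap_end - gap_start > 0:
                regions.append(
                    BreakpointRegion(
                        chrom=chrom,
                        start=gap_start,
                        end=gap_end,
                        left_block=left[2],
                        right_block=right[3],
                    )
                )
    return regions


def region_summary(
    regions: list[BreakpointRegion], chromosomes: ChromosomeSet | None = None
) -> dict:
    """Arithmetic summary: n, total/mean/min/max bp, and (when chromosome
    lengths are available) the fraction of autosomal sequence covered."""
    n = len(regions)
    if n == 0:
        return {
            "n": 0,
            "total_bp": 0,
            "mean_bp": None,
            "min_bp": None,
            "max_bp": None,
            "fraction_autosomal": None,
        }
    lengths = np.array([r.length for r in regions], dtype=np.int64)
    total = int(lengths.sum())
    frac = None
    if chromosomes is not None:
        auto_bp = chromosomes.total_autosomal_bp
        frac = total / auto_bp if auto_bp else None
    return {
        "n": n,
        "total_bp": total,
        "mean_bp": float(lengths.mean()),
        "min_bp": int(lengths.min()),
        "max_bp": int(lengths.max()),
        "fraction_autosomal": frac,
    }


def breakpoint_recovery(
    regions: list[BreakpointRegion],
    junctions: list[tuple[str, int]],
    slack: int = 50_000,
) -> tuple[float, float | None]:
    """Recall and precision of regions against true junctions.

    Recall: fraction of junctions within ``slack`` bp of a region on the
    same chromosome. Precision: fraction of regions containing at least one
    junction (no slack). Precision is None when there are no regions;
    recall is 1.0 when there are no junctions to recover.
    """
    by_chrom: dict[str, list[BreakpointRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    if junctions:
        hit = 0
        for chrom, pos in junctions:
            for r in by_chrom.get(chrom, []):
                if r.start - slack <= pos <= r.end + slack:
                    hit += 1
                    break
        recall = hit / len(junctions)
    else:
        recall = 1.0

    if not regions:
        return recall, None
    n_with = 0
    for r in regions:
        if any(
            chrom == r.chrom and r.start <= pos < r.end for chrom, pos in junctions
        ):
            n_with += 1
    return recall, n_with / len(regions)
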