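"""TE overlap statistics over genomic regions and the size-matched
permutation enrichment test.

The permutation null shuffles the observed region set 10,000 times (each
set keeps the observed region length distribution; chromosomes are drawn
with probability proportional to length, starts uniformly), recomputes the
per-class TE count each time, and reports the empirical p as the fraction
of null sets with a count at least as large as the observed one. Random
regions within a set may overlap one another: a non-overlap constraint
would bias long-region placement on short chromosomes and the uniform
genomic-position null does not require it.

Fold enrichment is span-based: observed clipped TE span in the regions over
the span expected from the autosome-wide TE proportion of the class.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats
from .types import ChromosomeSet, EnrichmentResult, TERecord, TestResult

__all__ = [
    "overlap_stats",
    "random_region_sets",
    "permutation_enrichment",
    "expected_span",
    "window_density",
    "end_distance_correlation",
]


def _as_triples(regions) -> list[tuple[str, int, int]]:
    out = []
    for r in regions:
        if isinstance(r, tuple):
            out.append((r[0], int(r[1]), int(r[2])))
        else:
            out.append((r.chrom, r.start, r.end))
    return out


def _te_arrays(tes: list[TERecord]) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """class -> chrom -> (starts sorted, ends sorted independently)."""
    grouped: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for te in tes:
        grouped.setdefault(te.te_class, {}).setdefault(te.chrom, []).append(
            (te.start, te.end)
        )
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for cls, by_chrom in grouped.items():
        out[cls] = {}
        for chrom, ivals in by_chrom.items():
            starts = np.sort(np.array([s for s, _ in ivals], dtype=np.int64))
            ends = np.sort(np.array([e for _, e in ivals], dtype=np.int64))
            out[cls][chrom] = (starts, ends)
    return out


def overlap_stats(regions, tes: list[TERecord]) -> dict[str, tuple[int, int]]:
    """Per-class (count, clipped span in bp) of TEs overlapping the regions.

    A TE counts once per region it overlaps by >= 1 bp; span contributions
    are clipped to the region. Classes are summed independently.
    """
    triples = _as_triples(regions)
    keys = [(c, s) for c, s, _ in triples]
    if keys != sorted(keys):
        raise ValueError("regions must be sorted by (chrom, start)")

    by_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for te in tes:
        by_class.setdefault(te.te_class, {}).setdefault(te.chrom, []).append(
            (te.start, te.end)
        )
    result: dict[str, tuple[int, int]] = {}
    for cls, by_chrom in sorted(by_class.items()):
        arrs = {}
        for chrom, ivals in by_chrom.items():
            pairs = np.array(sorted(ivals), dtype=np.int64)
            arrs[chrom] = (pairs[:, 0], pairs[:, 1])
        count = 0
        span = 0
        for chrom, rs, re_ in triples:
            if chrom not in arrs:
                continue
            s_arr, e_arr = arrs[chrom]
            hi = int(np.searchsorted(s_arr, re_, side="left"))
            if hi == 0:
                continue
            mask = e_arr[:hi] > rs
            count += int(mask.sum())
            if mask.any():
                ov = np.minimum(e_arr[:hi][mask], re_) - np.maximum(
                    s_arr[:hi][mask], rs
                )
                span += int(ov.sum())
        result[cls] = (count, span)
    return result


def _sample_region_matrix(
    region_lengths: list[int],
    chromosomes: ChromosomeSet,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """For each observed region length, sample n_perm (chrom, start) pairs.

    Returns (autosome names, chrom index matrix [n_regions, n_perm], start
    matrix). Chromosomes are drawn proportionally to length among the
    autosomes long enough to hold the region.
    """
    autos = chromosomes.autosomes()
    if not autos:
        raise ValueError("no autosomes to place regions on")
    lens = np.array([chromosomes.lengths[c] for c in autos], dtype=np.float64)
    chrom_idx = np.empty((len(region_lengths), n_perm), dtype=np.int64)
    start_pos = np.empty((len(region_lengths), n_perm), dtype=np.int64)
    for ri, rlen in enumerate(region_lengths):
        feasible = lens >= rlen
        if not feasible.any():
            raise ValueError(f"region of {rlen} bp longer than every autosome")
        p = np.where(feasible, lens, 0.0)
        p = p / p.sum()
        ci = rng.choice(len(autos), size=n_perm, p=p)
        max_start = (lens[ci] - rlen).astype(np.int64)
        start_pos[ri] = (rng.random(n_perm) * (max_start + 1)).astype(np.int64)
        chrom_idx[ri] = ci
    return autos, chrom_idx, start_pos


def random_region_sets(
    regions, chromosomes: ChromosomeSet, n_perm: int = 10_000, seed: int = 0
):
    """Yield ``n_perm`` random region sets size-matched to the observed set."""
    triples = _as_triples(regions)
    lengths = [e - s for _, s, e in triples]
    rng = np.random.default_rng(seed)
    autos, chrom_idx, start_pos = _sample_region_matrix(
        lengths, chromosomes, n_perm, rng
    )
    for k in range(n_perm):
        regs = [
            (autos[chrom_idx[ri, k]], int(start_pos[ri, k]), int(start_pos[ri, k]) + lengths[ri])
            for ri in range(len(lengths))
        ]
        yield sorted(regs)


def permutation_enrichment(
    regions,
    tes: list[TERecord],
    chromosomes: ChromosomeSet,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, EnrichmentResult]:
    """Size-matched permutation test of per-class TE counts in the regions.

    The permutation statistic is the count (a TE counts once per region it
    overlaps); span-based fold enrichment against the autosome-wide class
    proportion is reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse empirical p", stacklevel=2)
    triples = sorted(_as_triples(regions))
    lengths = [e - s for _, s, e in triples]
    region_total = sum(lengths)
    observed = overlap_stats(triples, tes)

    autosomes = chromosomes.autosomes()
    autosome_total = chromosomes.total_autosomal_bp
    whole_autosomes = sorted((c, 0, chromosomes.lengths[c]) for c in autosomes)
    genome_wide = overlap_stats(whole_autosomes, tes)

    rng = np.random.default_rng(seed)
    autos, chrom_idx, start_pos = _sample_region_matrix(
        lengths, chromosomes, n_perm, rng
    )
    classes = sorted({te.te_class for te in tes})
    arrays = _te_arrays(tes)
    null_counts = {cls: np.zeros(n_perm, dtype=np.int64) for cls in classes}
    n_regions = len(lengths)
    rlen = np.array(lengths, dtype=np.int64)
    for ci, chrom in enumerate(autos):
        sel = chrom_idx == ci  # [n_regions, n_perm]
        if not sel.any():
            continue
        reg_starts = start_pos[sel]
        reg_ends = reg_starts + rlen[np.nonzero(sel)[0]]
        perm_of = np.nonzero(sel)[1]
        for cls in classes:
            if chrom not in arrays.get(cls, {}):
                continue
            starts, ends = arrays[cls][chrom]
            # overlapping TEs = #(start < region_end) - #(end <= region_start)
            c = np.searchsorted(starts, reg_ends, side="left") - np.searchsorted(
                ends, reg_starts, side="right"
            )
            np.add.at(null_counts[cls], perm_of, c)

    results: dict[str, EnrichmentResult] = {}
    for cls in classes:
        obs_count, obs_span = observed.get(cls, (0, 0))
        p_empirical, p_cons = stats.empirical_p(obs_count, null_counts[cls])
        _, class_total = genome_wide.get(cls, (0, 0))
        exp = expected_span(class_total, region_total, autosome_total)
        fold = obs_span / exp if exp > 0 else 0.0
        results[cls] = EnrichmentResult(
            te_class=cls,
            observed_count=obs_count,
            observed_span=obs_span,
            expected_span=exp,
            fold=fold,
            p_empirical=p_empirical,
            p_conservative=p_cons,
            n_perm=n_perm,
            seed=seed,
        )
    return results


def expected_span(
    class_total_span_autosomal: float, region_total: float, autosome_total: float
) -> float:
    """Expected bp of a TE class inside the regions under proportionality:
    class autosomal span x (region bp / autosomal bp). The fold
    observed/expected equals the ratio of the class's fraction-in-regions to
    the regions' fraction of the autosomes."""
    if autosome_total <= 0:
        raise ValueError("autosome total must be positive")
    return class_total_span_autosomal * (region_total / autosome_total)


def _merge(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def window_density(
    features, chromosomes: ChromosomeSet, window: int = 100_000
) -> pd.DataFrame:
    """Fraction of bp covered by each feature class in fixed windows.

    ``features`` are objects with chrom/start/end and an optional class
    label (``te_class`` or 4th tuple element); unlabeled features fall into
    class 'feature'. Overlapping same-class intervals are merged before
    counting, so densities never exceed 1. The trailing partial window uses
    its true width as denominator.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    labeled: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for f in features:
        if isinstance(f, tuple):
            chrom, start, end = f[0], int(f[1]), int(f[2])
            cls = f[3] if len(f) > 3 else "feature"
        else:
            chrom, start, end = f.chrom, f.start, f.end
            cls = getattr(f, "te_class", "feature")
        labeled.setdefault(cls, {}).setdefault(chrom, []).append((start, end))

    classes = sorted(labeled)
    rows = []
    for chrom, length in chromosomes.lengths.items():
        edges = list(range(0, length, window)) + [length]
        starts = np.array(edges[:-1], dtype=np.int64)
        ends = np.array(edges[1:], dtype=np.int64)
        covered = {cls: np.zeros(starts.size, dtype=np.int64) for cls in classes}
        for cls in classes:
            for s, e in _merge(labeled[cls].get(chrom, [])):
                e = min(e, length)
                if e <= s:
                    continue
                lo = int(np.searchsorted(ends, s, side="right"))
                hi = int(np.searchsorted(starts, e, side="left"))
                for w in range(lo, hi):
                    covered[cls][w] += min(e, ends[w]) - max(s, starts[w])
        width = (ends - starts).astype(float)
        for w in range(starts.size):
            row = {"chrom": chrom, "start": int(starts[w]), "end": int(ends[w])}
            for cls in classes:
                row[cls] = covered[cls][w] / width[w]
            rows.append(row)
    return pd.DataFrame(rows)


def end_distance_correlation(
    density: pd.DataFrame, chromosomes: ChromosomeSet, classes=None
) -> dict[str, TestResult]:
    """Pearson correlation of window density against the distance from the
    window midpoint to the nearest chromosome end, per feature class."""
    if len(density) < 3:
        raise ValueError("need >= 3 windows")
    mid = (density["start"] + density["end"]) / 2.0
    chrom_len = density["chrom"].map(chromosomes.lengths)
    dist = np.minimum(mid, chrom_len - mid)
    if classes is None:
        classes = [c for c in density.columns if c not in ("chrom", "start", "end")]
    return {cls: stats.pearson_r(density[cls], dist) for cls in classes}
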