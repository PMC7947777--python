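"""Synthetic paired genomes with known rearrangement, TE, coverage and
expression ground truth.

The generator states a world resembling an aphid genome pair that diverged
by inversions, reciprocal translocations, fissions and fusions, with an
optionally rearrangement-protected X chromosome: genes laid end to end with
lognormal intergenic gaps, TE intervals planted to class-specific genome
fractions (optionally enriched near true rearrangement junctions), Poisson
read depth with the male X at half depth (X0 males), and lognormal
expression with reduced X expression and X-enriched male-biased genes.

Rearrangement breakpoints fall only in intergenic space, which keeps the
gene-anchor abstraction exact: block detection downstream is gene-based.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import assign_ranks
from .types import ChromosomeSet, GeneRecord, Genome, TERecord

__all__ = [
    "SimulationConfig",
    "RearrangementEvent",
    "TruthLog",
    "simulate_ancestor",
    "evolve_descendant",
    "plant_tes",
    "simulate_coverage",
    "simulate_expression",
    "simulate_pair",
]


@dataclass
class SimulationConfig:
    """All knobs of the stated world, with aphid-scale defaults.

    Lengths are lognormal ``(mu, sigma)`` on the natural-log scale. The
    defaults give ~3 kb genes and ~11 kb intergenic gaps (about 14 kb of
    sequence per gene, the gene density of a ~400 Mb / 27k-gene aphid
    genome), TE class fractions summing to ~22% of the genome, and equal
    male/female sequencing depth with the male X halved.
    """

    seed: int
    n_chrom: int = 5
    genes_per_chrom: int = 400
    gene_len: tuple[float, float] = (math.log(3000.0), 0.6)
    intergenic_len: tuple[float, float] = (math.log(9000.0), 0.7)
    # rearrangement events applied to a descendant
    n_inversions: int = 5
    n_translocations: int = 5
    n_fissions: int = 1
    n_fusions: int = 1
    protect_x: bool = True
    # transposable elements
    te_class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "DNA": 0.06,
            "LINE": 0.03,
            "LTR": 0.05,
            "RC": 0.04,
            "SINE": 0.005,
            "Unknown": 0.04,
        }
    )
    te_len: tuple[float, float] = (math.log(600.0), 0.8)
    breakpoint_enrichment: dict[str, float] = field(default_factory=dict)
    breakpoint_window: int = 50_000
    # divergence-age mixture: recent exponential burst (scale, in % points),
    # old uniform range (%), and the mixing weight of the recent component
    te_age_mixture: tuple[float, tuple[float, float], float] = (2.0, (10.0, 40.0), 0.4)
    # coverage
    depth_m: float = 50.0
    depth_f: float = 50.0
    coverage_window: int = 100_000
    read_len: int = 150
    # expression (log2 scale unless noted)
    expr_mu_log2: float = 2.0
    expr_sigma_log2: float = 1.5
    x_log2_shift: float = 0.5
    male_effect_log2: float = 2.0
    frac_male_biased: float = 0.05
    male_biased_x_frac: float = 0.7
    n_reps: int = 6
    rep_sigma_log2: float = 0.25
    dosage_compensated: bool = True
    counts_per_tpm: float = 20.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(self.te_class_fractions.values()) > 0.8:
            raise ValueError("TE class fractions must sum to <= 0.8")
        for name in ("n_inversions", "n_translocations", "n_fissions", "n_fusions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.frac_male_biased <= 1.0):
            raise ValueError("frac_male_biased must lie in [0, 1]")


@dataclass
class RearrangementEvent:
    kind: str  # inversion | translocation | fission | fusion
    chroms: tuple[str, ...]
    # gene adjacencies this event created; bp positions filled after layout
    created_pairs: list[frozenset] = field(default_factory=list)
    junctions: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class TruthLog:
    """Ground truth of one simulated descendant: events with their junction
    positions (descendant coordinates), the true X label, planted TE
    enrichment and the planted male-biased gene list."""

    events: list[RearrangementEvent] = field(default_factory=list)
    junctions: list[tuple[str, int]] = field(default_factory=list)
    x_label: str | None = None
    te_enrichment: dict[str, float] = field(default_factory=dict)
    male_biased_genes: list[str] = field(default_factory=list)


def _layout(
    chrom_genes: dict[str, list[str]],
    gene_lengths: dict[str, int],
    config: SimulationConfig,
    rng: np.random.Generator,
    roles: dict[str, str],
) -> tuple[Genome, dict[frozenset, tuple[str, int]]]:
    """Lay genes end to end with sampled intergenic gaps.

    Returns the genome and a map from each adjacent gene pair to the bp
    midpoint of the gap between them (used to place true junctions).
    """
    mu, sigma = config.intergenic_len
    genes: list[GeneRecord] = []
    lengths: dict[str, int] = {}
    gap_mid: dict[frozenset, tuple[str, int]] = {}
    for chrom in chrom_genes:
        ids = chrom_genes[chrom]
        n_gaps = len(ids) + 1  # leading + between + trailing
        gaps = np.maximum(50, rng.lognormal(mu, sigma, size=n_gaps)).astype(np.int64)
        pos = int(gaps[0])
        prev_id: str | None = None
        prev_end = 0
        for i, gid in enumerate(ids):
            start = pos
            end = start + gene_lengths[gid]
            genes.append(GeneRecord(gid, chrom, start, end))
            if prev_id is not None:
                gap_mid[frozenset((prev_id, gid))] = (chrom, (prev_end + start) // 2)
            prev_id, prev_end = gid, end
            pos = end + int(gaps[i + 1])
        lengths[chrom] = pos
    genome = Genome(
        genes=assign_ranks(genes),
        chromosomes=ChromosomeSet(lengths=lengths, roles=dict(roles)),
    )
    return genome, gap_mid


def _adjacencies(chrom_genes: dict[str, list[str]]) -> set[frozenset]:
    adj: set[frozenset] = set()
    for ids in chrom_genes.values():
        for a, b in zip(ids, ids[1:]):
            adj.add(frozenset((a, b)))
    return adj


def simulate_ancestor(config: SimulationConfig) -> Genome:
    """Generate the ancestral genome: ``n_chrom`` chromosomes, the first
    designated X, each carrying ``genes_per_chrom`` genes."""
    if config.n_chrom < 1 or config.genes_per_chrom < 1:
        raise ValueError("need at least one chromosome and one gene")
    rng = np.random.default_rng(config.seed)
    mu, sigma = config.gene_len
    chrom_genes: dict[str, list[str]] = {}
    gene_lengths: dict[str, int] = {}
    gid = 0
    for c in range(config.n_chrom):
        name = f"chr{c + 1}"
        ids = []
        for _ in range(config.genes_per_chrom):
            gene_id = f"g{gid:05d}"
            gene_lengths[gene_id] = int(max(200, rng.lognormal(mu, sigma)))
            ids.append(gene_id)
            gid += 1
        chrom_genes[name] = ids
    roles = {f"chr{c + 1}": "autosome" for c in range(config.n_chrom)}
    roles["chr1"] = "X"
    genome, _ = _layout(chrom_genes, gene_lengths, config, rng, roles)
    return genome


def _eligible(names: list[str], roles: dict[str, str], protect_x: bool) -> list[str]:
    if protect_x:
        return [n for n in names if roles[n] != "X"]
    return list(names)


def evolve_descendant(
    ancestor: Genome, config: SimulationConfig, seed: int
) -> tuple[Genome, TruthLog, list[tuple[str, str]]]:
    """Apply inversions, reciprocal translocations, fissions and fusions to
    the ancestral gene order and return the rearranged descendant, the truth
    log and the (identity) ortholog table.

    With ``protect_x`` no event touches the X. Junction positions are the
    intergenic midpoints of gene adjacencies that exist in the descendant
    but not in the ancestor; adjacencies destroyed by later events drop out
    of the log automatically.
    """
    rng = np.random.default_rng(seed)
    anc_by_chrom = ancestor.genes_by_chrom()
    chrom_order = list(anc_by_chrom)
    chrom_genes = {c: [g.gene_id for g in anc_by_chrom[c]] for c in chrom_order}
    gene_lengths = {g.gene_id: g.end - g.start for g in ancestor.genes}
    roles = dict(ancestor.chromosomes.roles)
    ancestor_adj = _adjacencies(chrom_genes)

    events: list[RearrangementEvent] = []

    def record(ev: RearrangementEvent, before: set[frozenset]) -> None:
        ev.created_pairs = sorted(
            _adjacencies(chrom_genes) - before, key=lambda p: sorted(p)
        )
        events.append(ev)

    for _ in range(config.n_inversions):
        cands = [
            c
            for c in _eligible(list(chrom_genes), roles, config.protect_x)
            if len(chrom_genes[c]) >= 2
        ]
        if not cands:
            raise ValueError("inversion infeasible: no eligible chromosome")
        c = cands[rng.integers(len(cands))]
        n = len(chrom_genes[c])
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 2, n + 1))
        ids = chrom_genes[c]
        before = _adjacencies(chrom_genes)
        chrom_genes[c] = ids[:i] + ids[i:j][::-1] + ids[j:]
        record(RearrangementEvent("inversion", (c,)), before)

    for _ in range(config.n_translocations):
        cands = [
            c
            for c in _eligible(list(chrom_genes), roles, config.protect_x)
            if len(chrom_genes[c]) >= 2
        ]
        if len(cands) < 2:
            raise ValueError("translocation infeasible: need two eligible chromosomes")
        idx = rng.choice(len(cands), size=2, replace=False)
        c1, c2 = cands[int(idx[0])], cands[int(idx[1])]
        k1 = int(rng.integers(1, len(chrom_genes[c1])))
        k2 = int(rng.integers(1, len(chrom_genes[c2])))
        a, b = chrom_genes[c1], chrom_genes[c2]
        before = _adjacencies(chrom_genes)
        chrom_genes[c1] = a[:k1] + b[k2:]
        chrom_genes[c2] = b[:k2] + a[k1:]
        record(RearrangementEvent("translocation", (c1, c2)), before)

    for _ in range(config.n_fissions):
        cands = [
            c
            for c in _eligible(list(chrom_genes), roles, config.protect_x)
            if len(chrom_genes[c]) >= 2
        ]
        if not cands:
            raise ValueError("fission infeasible: no eligible chromosome")
        c = cands[rng.integers(len(cands))]
        k = int(rng.integers(1, len(chrom_genes[c])))
        before = _adjacencies(chrom_genes)
        left, right = chrom_genes[c][:k], chrom_genes[c][k:]
        del chrom_genes[c]
        role = roles.pop(c)
        chrom_genes[f"{c}a"], chrom_genes[f"{c}b"] = left, right
        roles[f"{c}a"] = roles[f"{c}b"] = role
        record(RearrangementEvent("fission", (c,)), before)

    for _ in range(config.n_fusions):
        cands = _eligible(list(chrom_genes), roles, config.protect_x)
        if len(cands) < 2:
            raise ValueError("fusion infeasible: need two eligible chromosomes")
        idx = rng.choice(len(cands), size=2, replace=False)
        c1, c2 = cands[int(idx[0])], cands[int(idx[1])]
        fused = chrom_genes[c1] + chrom_genes[c2]
        role = "X" if "X" in (roles[c1], roles[c2]) else "autosome"
        before = _adjacencies(chrom_genes)
        del chrom_genes[c1], chrom_genes[c2]
        roles.pop(c1), roles.pop(c2)
        name = f"{c1}+{c2}"
        chrom_genes[name] = fused
        roles[name] = role
        record(RearrangementEvent("fusion", (c1, c2)), before)

    genome, gap_mid = _layout(chrom_genes, gene_lengths, config, rng, roles)

    # novel interior adjacencies = true junctions
    truth = TruthLog(events=events)
    novel = _adjacencies(chrom_genes) - ancestor_adj
    truth.junctions = sorted(gap_mid[p] for p in novel)
    x_scaffolds = [c for c, r in roles.items() if r == "X"]
    truth.x_label = x_scaffolds[0] if x_scaffolds else None

    # attribute surviving novel adjacencies back to the events that made them
    surviving = novel & _adjacencies(chrom_genes)
    for ev in events:
        ev.junctions = sorted(
            gap_mid[p] for p in ev.created_pairs if p in surviving
        )
    ortho = [(g.gene_id, g.gene_id) for g in ancestor.genes]
    return genome, truth, ortho


def _sample_divergence(config: SimulationConfig, rng: np.random.Generator) -> float:
    scale, (lo, hi), weight = config.te_age_mixture
    if rng.random() < weight:
        return float(min(50.0, rng.exponential(scale)))
    return float(rng.uniform(lo, hi))


def plant_tes(
    genome: Genome,
    config: SimulationConfig,
    seed: int,
    truth: TruthLog | None = None,
) -> list[TERecord]:
    """Plant TE intervals until each class reaches its target genome fraction.

    Placement is uniform over the genome except within
    ``breakpoint_window`` bp of true junctions (if a truth log with
    junctions is given), where the per-class intensity is multiplied by the
    configured enrichment factor. Same-class TEs never overlap; divergence
    is drawn from the recent-burst / old-uniform age mixture. Updates
    ``truth.te_enrichment`` with the planted multipliers.
    """
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    names = list(chroms.lengths)
    lens = np.array([chroms.lengths[c] for c in names], dtype=np.float64)
    total_bp = float(lens.sum())
    mu, sigma = config.te_len

    # per-chromosome sorted, merged enrichment zones
    zones: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    if truth is not None and truth.junctions:
        w = config.breakpoint_window
        tmp: dict[str, list[tuple[int, int]]] = {}
        for chrom, pos in truth.junctions:
            if chrom in chroms.lengths:
                s = max(0, pos - w)
                e = min(chroms.lengths[chrom], pos + w)
                tmp.setdefault(chrom, []).append((s, e))
        for chrom, ivals in tmp.items():
            merged: list[tuple[int, int]] = []
            for s, e in sorted(ivals):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            zones[chrom] = merged

    zone_bp = np.array(
        [sum(e - s for s, e in zones[c]) for c in names], dtype=np.float64
    )
    records: list[TERecord] = []
    for te_class in sorted(config.te_class_fractions):
        frac = config.te_class_fractions[te_class]
        if frac <= 0:
            continue
        target = frac * total_bp
        if target > 0.9 * total_bp:
            raise ValueError("infeasible TE fraction for genome size")
        mult = 1.0
        if truth is not None:
            mult = config.breakpoint_enrichment.get(te_class, 1.0)
            if mult != 1.0:
                truth.te_enrichment[te_class] = mult
        weights = (lens - zone_bp) + mult * zone_bp
        probs = weights / weights.sum()
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
        starts_sorted: dict[str, list[int]] = {c: [] for c in names}
        ends_sorted: dict[str, list[int]] = {c: [] for c in names}
        planted_bp = 0.0
        attempts = 0
        max_attempts = int(50 * target / max(100.0, math.exp(mu))) + 10_000
        while planted_bp < target and attempts < max_attempts:
            attempts += 1
            ci = int(rng.choice(len(names), p=probs))
            chrom = names[ci]
            length = int(max(50, rng.lognormal(mu, sigma)))
            clen = chroms.lengths[chrom]
            if length >= clen:
                continue
            z = zones[chrom]
            zb = sum(e - s for s, e in z)
            bg = clen - zb
            if z and rng.random() < (mult * zb) / (mult * zb + bg):
                # start uniform within the enrichment zones
                pick = z
                offset = rng.uniform(0, zb)
            elif z:
                # start uniform within the zone complement
                comp = []
                prev = 0
                for s, e in z:
                    if s > prev:
                        comp.append((prev, s))
                    prev = e
                if prev < clen:
                    comp.append((prev, clen))
                pick = comp
                offset = rng.uniform(0, bg)
            else:
                pick = [(0, clen)]
                offset = rng.uniform(0, clen)
            start = None
            for s, e in pick:
                if offset < (e - s):
                    start = int(s + offset)
                    break
                offset -= e - s
            if start is None:
                start = int(pick[-1][1] - 1)
            if start + length > clen:
                continue
            end = min(start + length, clen)
            if end <= start:
                continue
            # reject overlap with same-class TEs
            ss = starts_sorted[chrom]
            es = ends_sorted[chrom]
            i = bisect.bisect_left(ss, end)
            j = bisect.bisect_right(es, start)
            if i - j > 0:
                continue
            ivals = placed[chrom]
            bisect.insort(ss, start)
            bisect.insort(es, end)
            ivals.append((start, end))
            planted_bp += end - start
            records.append(
                TERecord(chrom, start, end, te_class, _sample_divergence(config, rng))
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def simulate_coverage(
    genome: Genome, config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window Poisson read depth for male and asexual-female libraries.

    Read counts per window follow the Lander-Waterman model: the number of
    ``read_len``-bp reads landing in a window is Poisson with mean
    depth x window / read_len, and the reported window depth is
    reads x read_len / window. The male mean is halved on the X (X0 males
    carry a single X copy); female depth is uniform. Returns (male table,
    female table) with columns chrom, start, end, depth; the trailing
    partial window is kept (consumers decide whether to drop it).
    """
    if config.depth_m <= 0 or config.depth_f <= 0:
        raise ValueError("depths must be positive")
    if config.coverage_window <= 0:
        raise ValueError("window size must be positive")
    rng = np.random.default_rng(seed)
    rows_m, rows_f = [], []
    w = config.coverage_window
    rl = config.read_len
    for chrom, length in genome.chromosomes.lengths.items():
        is_x = genome.chromosomes.roles[chrom] == "X"
        lam_m = config.depth_m / 2.0 if is_x else config.depth_m
        for start in range(0, length, w):
            end = min(start + w, length)
            span = end - start
            depth_m = rng.poisson(lam_m * span / rl) * rl / span
            depth_f = rng.poisson(config.depth_f * span / rl) * rl / span
            rows_m.append((chrom, start, end, float(depth_m)))
            rows_f.append((chrom, start, end, float(depth_f)))
    cols = ["chrom", "start", "end", "depth"]
    return pd.DataFrame(rows_m, columns=cols), pd.DataFrame(rows_f, columns=cols)


MORPHS = ("FA", "FW", "M", "N")


def simulate_expression(
    genome: Genome, config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Lognormal TPM for four morphs (FA, FW, M, N) with planted effects.

    X-linked genes are shifted down by ``x_log2_shift`` in every morph.
    A fraction ``frac_male_biased`` of genes is upregulated in males only
    (by ``male_effect_log2``), with ``male_biased_x_frac`` of them placed
    on the X. With ``dosage_compensated=False``, X genes additionally lose
    one log2 unit in males (single-copy X, no compensation). Returns
    (tpm, counts, de table, true male-biased gene ids); the DE table's q
    and per-morph betas are derived from the generative effects.
    """
    if config.n_reps < 2:
        raise ValueError("need >= 2 replicates per morph")
    rng = np.random.default_rng(seed)
    genes = sorted(genome.genes, key=lambda g: g.gene_id)
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    is_x = np.array(
        [genome.chromosomes.roles[g.chrom] == "X" for g in genes], dtype=bool
    )

    base = rng.normal(config.expr_mu_log2, config.expr_sigma_log2, size=n_genes)
    base = base - config.x_log2_shift * is_x

    n_mb = int(round(config.frac_male_biased * n_genes))
    x_idx = np.flatnonzero(is_x)
    a_idx = np.flatnonzero(~is_x)
    n_mb_x = min(int(round(config.male_biased_x_frac * n_mb)), x_idx.size)
    n_mb_a = min(n_mb - n_mb_x, a_idx.size)
    mb_idx = np.concatenate(
        [
            rng.choice(x_idx, size=n_mb_x, replace=False) if n_mb_x else [],
            rng.choice(a_idx, size=n_mb_a, replace=False) if n_mb_a else [],
        ]
    ).astype(np.int64)
    male_biased = np.zeros(n_genes, dtype=bool)
    male_biased[mb_idx] = True

    samples = [f"{m}_{r + 1}" for m in MORPHS for r in range(config.n_reps)]
    tpm = np.empty((n_genes, len(samples)))
    for j, sample in enumerate(samples):
        morph = sample.rsplit("_", 1)[0]
        mean_log2 = base.copy()
        if morph == "M":
            mean_log2 = mean_log2 + config.male_effect_log2 * male_biased
            if not config.dosage_compensated:
                mean_log2 = mean_log2 - 1.0 * is_x
        noise = rng.normal(0.0, config.rep_sigma_log2, size=n_genes)
        tpm[:, j] = np.exp2(mean_log2 + noise)
    tpm_df = pd.DataFrame(tpm, index=gene_ids, columns=samples)
    tpm_df.index.name = "gene"
    counts_df = pd.DataFrame(
        rng.poisson(tpm * config.counts_per_tpm).astype(np.int64),
        index=gene_ids,
        columns=samples,
    )
    counts_df.index.name = "gene"

    # DE table consistent with the generative truth
    qval = np.where(
        male_biased,
        10.0 ** (-rng.uniform(4.0, 8.0, size=n_genes)),
        rng.uniform(0.06, 1.0, size=n_genes),
    )
    b_m = rng.normal(0.0, 0.1, size=n_genes) + config.male_effect_log2 * male_biased
    if not config.dosage_compensated:
        b_m = b_m - 1.0 * is_x
    b_fw = rng.normal(0.0, 0.1, size=n_genes)
    b_n = rng.normal(0.0, 0.1, size=n_genes)
    de_df = pd.DataFrame(
        {"qval": qval, "b_M": b_m, "b_FW": b_fw, "b_N": b_n}, index=gene_ids
    )
    de_df.index.name = "gene"
    truth_mb = [gene_ids[i] for i in sorted(mb_idx.tolist())]
    return tpm_df, counts_df, de_df, truth_mb


def simulate_pair(
    config: SimulationConfig,
) -> tuple[Genome, Genome, list[tuple[str, str]], TruthLog]:
    """Convenience: an ancestor-as-is genome A and a rearranged descendant B
    with its truth log and the one-to-one ortholog table between them."""
    ancestor = simulate_ancestor(config)
    descendant, truth, ortho = evolve_descendant(
        ancestor, config, seed=config.seed + 1
    )
    return ancestor, descendant, ortho, truth
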