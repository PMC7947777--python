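"""Cross-species chromosome homology from ortholog placement.

Where two genomes are too diverged for collinear blocks, chromosome
homology can still be read from where one-to-one orthologs land: for each
(focal, target) chromosome pair, a one-sided binomial test asks whether the
focal chromosome carries more orthologs from the target chromosome than
expected from the target's genome-wide ortholog share, with BH correction
across the whole focal x target grid in one family. Depletion is read from
odds ratios (observed/expected) below 1 rather than from a second test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats
from .types import Genome, TestResult

__all__ = [
    "build_chromosome_map",
    "chromosome_enrichment",
    "x_vs_autosome_or_test",
    "x_conservation",
]

logger = logging.getLogger(__name__)


def build_chromosome_map(
    orthologs: list[tuple[str, str]], genome_a: Genome, genome_b: Genome
) -> pd.DataFrame:
    """Map each ortholog pair onto (focal_chrom, target_chrom).

    Pairs with either gene on an unplaced scaffold are excluded (logged).
    """
    idx_a = genome_a.gene_index()
    idx_b = genome_b.gene_index()
    rows = []
    n_excluded = 0
    for ga, gb in orthologs:
        if ga not in idx_a or gb not in idx_b:
            raise KeyError(f"unresolvable ortholog pair ({ga!r}, {gb!r})")
        ca, cb = idx_a[ga].chrom, idx_b[gb].chrom
        if (
            genome_a.chromosomes.roles.get(ca) == "unplaced"
            or genome_b.chromosomes.roles.get(cb) == "unplaced"
        ):
            n_excluded += 1
            continue
        rows.append((ga, gb, ca, cb))
    if n_excluded:
        logger.info("build_chromosome_map: excluded %d unplaced pairs", n_excluded)
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "focal_chrom", "target_chrom"]
    )


def chromosome_enrichment(chrom_map: pd.DataFrame) -> pd.DataFrame:
    """Per (focal, target) chromosome pair: one-sided binomial enrichment.

    For each pair, successes = orthologs from the target chromosome found on
    the focal chromosome, trials = all orthologs on the focal chromosome,
    and the success probability = the target chromosome's share of all
    mapped orthologs. q-values are BH across the full grid; the odds ratio
    is observed/expected with expected = trials x prob.
    """
    if len(chrom_map) == 0:
        raise ValueError("empty chromosome map")
    total = len(chrom_map)
    target_share = chrom_map["target_chrom"].value_counts() / total
    counts = (
        chrom_map.groupby(["focal_chrom", "target_chrom"]).size().rename("observed")
    )
    trials = chrom_map["focal_chrom"].value_counts()

    rows = []
    for focal in sorted(trials.index):
        for target in sorted(target_share.index):
            observed = int(counts.get((focal, target), 0))
            n = int(trials[focal])
            prob = float(target_share[target])
            res = stats.binomial_test(observed, n, prob, sided="one-greater")
            expected = n * prob
            odds = observed / expected if expected > 0 else np.nan
            rows.append(
                {
                    "focal_chrom": focal,
                    "target_chrom": target,
                    "observed": observed,
                    "trials": n,
                    "prob": prob,
                    "p": res.p_value,
                    "odds_ratio": odds,
                    "abs_log2_or": abs(np.log2(odds)) if odds > 0 else np.inf,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = stats.bh_adjust(df["p"]).adjusted
    return df


def x_vs_autosome_or_test(
    enrichments: pd.DataFrame, focal_x: str
) -> TestResult:
    """Rank-sum comparison of absolute log2 odds ratios for focal-X pairs
    versus focal-autosome pairs: larger X values mean the X maps more
    coherently (and is more strongly depleted elsewhere) than autosomes."""
    if focal_x not in set(enrichments["focal_chrom"]):
        raise ValueError(f"focal X {focal_x!r} not present in enrichment grid")
    if enrichments["target_chrom"].nunique() < 2:
        raise ValueError("need >= 2 target chromosomes")
    x_vals = enrichments.loc[enrichments["focal_chrom"] == focal_x, "abs_log2_or"]
    a_vals = enrichments.loc[enrichments["focal_chrom"] != focal_x, "abs_log2_or"]
    return stats.wilcoxon_rank_sum(x_vals, a_vals, sided="two")


def x_conservation(
    chrom_map: pd.DataFrame, focal_x: str, target_x: str, ndigits: int = 0
) -> float:
    """Percentage of focal-X orthologs whose partner sits on the target X."""
    on_x = chrom_map[chrom_map["focal_chrom"] == focal_x]
    if len(on_x) == 0:
        raise ValueError(f"no orthologs on focal X {focal_x!r}")
    conserved = int((on_x["target_chrom"] == target_x).sum())
    return round(100.0 * conserved / len(on_x), ndigits)
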