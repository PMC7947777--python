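"""Morph-biased expression, X-linked expression and dosage compensation.

Works from a gene x sample TPM matrix, a matching estimated-count matrix,
a differential-expression table (q-value and per-morph effect sizes beta,
log2-fold-change scale, each morph contrasted against unwinged asexual
females), and a gene -> chromosome map. Morphs: FA (unwinged asexual
female), FW (winged asexual female), M (winged male), N (nymph).

Morph means are arithmetic means of replicate TPM. The DE model itself is
an input contract, not recomputed here.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from . import stats
from .types import TestResult

__all__ = [
    "expressed_filter",
    "classify_morph_bias",
    "male_biased_fraction",
    "scaffold_enrichment",
    "x_expression_test",
    "dosage_compensation_test",
]

logger = logging.getLogger(__name__)


def _morph_means(tpm: pd.DataFrame, morphs: dict[str, str], morph: str) -> pd.Series:
    cols = [c for c in tpm.columns if morphs.get(c) == morph]
    if not cols:
        raise ValueError(f"no samples for morph {morph!r}")
    return tpm[cols].mean(axis=1)


def expressed_filter(
    counts: pd.DataFrame, min_count: float = 4, min_fraction: float = 0.5
) -> pd.Series:
    """Expressed = estimated count strictly above ``min_count`` in at least
    ceil(min_fraction x n_samples) samples (e.g. >4 in 12/24)."""
    n_samples = counts.shape[1]
    if n_samples == 0:
        raise ValueError("no samples")
    need = math.ceil(min_fraction * n_samples)
    return (counts > min_count).sum(axis=1) >= need


def classify_morph_bias(
    de: pd.DataFrame, q_max: float = 0.05, beta_min: float = 0.5
) -> pd.DataFrame:
    """Classify genes as morph-biased and male-specific.

    Morph-biased: q < q_max and |beta| > beta_min in any morph contrast.
    Male-specific: morph-biased with beta_M > beta_min while beta_FW and
    beta_N stay below beta_min (upregulation specific to males).
    """
    for col in ("qval", "b_M", "b_FW", "b_N"):
        if col not in de.columns:
            raise ValueError(f"DE table missing contrast column {col!r}")
    betas = de[["b_M", "b_FW", "b_N"]]
    morph_biased = (de["qval"] < q_max) & (betas.abs() > beta_min).any(axis=1)
    male_specific = (
        morph_biased
        & (de["b_M"] > beta_min)
        & (de["b_FW"] < beta_min)
        & (de["b_N"] < beta_min)
    )
    return pd.DataFrame(
        {"morph_biased": morph_biased, "male_specific": male_specific},
        index=de.index,
    )


def male_biased_fraction(n_male_specific: int, n_morph_biased: int) -> float:
    """Percentage of morph-biased genes that are male-specific (1 dp)."""
    if n_morph_biased <= 0:
        raise ValueError("need a positive morph-biased denominator")
    return round(100.0 * n_male_specific / n_morph_biased, 1)


def scaffold_enrichment(
    male_specific: set[str],
    expressed: set[str],
    gene_chrom: dict[str, str],
) -> pd.DataFrame:
    """Per-chromosome binomial enrichment of male-specific genes.

    Trials = expressed genes on the chromosome; success probability = the
    overall proportion of male-specific genes among chromosome-placed
    expressed genes. Score = log2(observed/expected). Chromosomes without
    expressed genes are skipped (logged).
    """
    if not expressed:
        raise ValueError("expressed gene set is empty")
    placed_expressed = [g for g in expressed if g in gene_chrom]
    placed_ms = [g for g in male_specific if g in gene_chrom and g in expressed]
    if not placed_expressed:
        raise ValueError("no expressed genes are placed on chromosomes")
    prob = len(placed_ms) / len(placed_expressed)

    by_chrom_exp: dict[str, int] = {}
    by_chrom_ms: dict[str, int] = {}
    for g in placed_expressed:
        by_chrom_exp[gene_chrom[g]] = by_chrom_exp.get(gene_chrom[g], 0) + 1
    for g in placed_ms:
        by_chrom_ms[gene_chrom[g]] = by_chrom_ms.get(gene_chrom[g], 0) + 1

    rows = []
    for chrom in sorted(set(gene_chrom.values())):
        n_exp = by_chrom_exp.get(chrom, 0)
        if n_exp == 0:
            logger.info("scaffold_enrichment: chromosome %s has no expressed genes", chrom)
            continue
        obs = by_chrom_ms.get(chrom, 0)
        res = stats.binomial_test(obs, n_exp, prob, sided="one-greater")
        expected = n_exp * prob
        score = np.log2(obs / expected) if obs > 0 and expected > 0 else -np.inf
        rows.append(
            {
                "chrom": chrom,
                "n_expressed": n_exp,
                "n_male_specific": obs,
                "expected": expected,
                "score": score,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def x_expression_test(
    tpm: pd.DataFrame,
    morphs: dict[str, str],
    gene_chrom: dict[str, str],
    x_label: str,
    tpm_min: float = 1.0,
    fa_morph: str = "FA",
) -> TestResult:
    """Rank-sum comparison of log10 mean asexual-female TPM, X vs autosomes,
    over genes expressed above ``tpm_min`` (TPM > 1 by default)."""
    fa = _morph_means(tpm, morphs, fa_morph)
    fa = fa[fa > tpm_min]
    chrom = fa.index.map(gene_chrom.get)
    x_vals = np.log10(fa[chrom == x_label])
    a_vals = np.log10(fa[(chrom != x_label) & chrom.notna()])
    if len(x_vals) < 2 or len(a_vals) < 2:
        raise ValueError("need >= 2 expressed genes on X and autosomes")
    return stats.wilcoxon_rank_sum(x_vals, a_vals, sided="two")


def dosage_compensation_test(
    tpm: pd.DataFrame,
    morphs: dict[str, str],
    gene_chrom: dict[str, str],
    x_label: str,
    tpm_min: float = 1.0,
    extreme_cut: float = 2.5,
) -> tuple[TestResult, pd.DataFrame]:
    """Dosage compensation: log2 male:female TPM ratio, X vs autosomes.

    Genes enter when their mean TPM reaches ``tpm_min`` in both morphs. The
    rank-sum test uses all passing genes; the per-gene table flags
    |log2 ratio| > ``extreme_cut`` genes as extreme so figure exports can
    drop them without changing the test. Full compensation predicts an X
    median ratio near 0 (p large); no compensation predicts about -1.
    """
    m = _morph_means(tpm, morphs, "M")
    fa = _morph_means(tpm, morphs, "FA")
    passing = (m >= tpm_min) & (fa >= tpm_min)
    if not passing.any():
        raise ValueError("no genes pass the TPM filter in both morphs")
    ratio = np.log2(m[passing] / fa[passing])
    chrom = ratio.index.map(gene_chrom.get)
    table = pd.DataFrame(
        {
            "gene": ratio.index,
            "chrom": chrom,
            "is_x": chrom == x_label,
            "log2_m_fa": ratio.values,
            "extreme": np.abs(ratio.values) > extreme_cut,
        }
    ).set_index("gene")
    x_vals = table.loc[table["is_x"], "log2_m_fa"]
    a_vals = table.loc[~table["is_x"] & table["chrom"].notna(), "log2_m_fa"]
    if len(x_vals) < 2 or len(a_vals) < 2:
        raise ValueError("need >= 2 passing genes on X and autosomes")
    res = stats.wilcoxon_rank_sum(x_vals, a_vals, sided="two")
    return res, table
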