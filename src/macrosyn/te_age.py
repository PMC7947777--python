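"""TE age landscapes from Kimura 2-parameter divergence.

A TE insertion's divergence from its family consensus proxies its age. The
K2P distance d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) separates transitions
(P) and transversions (Q); the optional CpG adjustment drops transition
columns at consensus CpG dinucleotides (hypermutable sites) from both the
transition count and the scored-column total. Landscapes bin TE bp by
divergence (1 percentage-point bins over [0, 50)) split into autosomal and
X sets; the recency threshold is half the median synonymous-site divergence
between the two species' orthologs, below which an insertion likely
postdates the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ChromosomeSet, TERecord

__all__ = [
    "K2PSaturationError",
    "kimura2p",
    "kimura2p_from_alignment",
    "AgeLandscape",
    "age_landscape",
    "recency_threshold",
    "recent_te_span",
    "x_size_attribution",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


class K2PSaturationError(ValueError):
    """Raised when substitution fractions saturate the K2P distance."""


def kimura2p(p: float, q: float, as_percent: bool = False) -> float:
    """Kimura 2-parameter distance from transition (p) and transversion (q)
    fractions: d = -1/2 ln((1 - 2p - q) sqrt(1 - 2q))."""
    if p < 0 or q < 0:
        raise ValueError("substitution fractions must be non-negative")
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0 or b <= 0:
        raise K2PSaturationError(f"saturated: 1-2P-Q={a:g}, 1-2Q={b:g}")
    d = -0.5 * np.log(a * np.sqrt(b))
    return float(100.0 * d if as_percent else d)


def kimura2p_from_alignment(
    insertion: str, consensus: str, cpg_adjust: bool = False, as_percent: bool = False
) -> float:
    """K2P distance from a gapless pairwise alignment of an insertion
    against its consensus.

    Columns with a gap or N on either side are skipped. With
    ``cpg_adjust``, transition columns at consensus CpG positions (the C or
    the G of a consensus 'CG') are excluded from both the transition count
    and the scored-column count.
    """
    if len(insertion) != len(consensus):
        raise ValueError("aligned sequences must have equal length")
    ins = insertion.upper()
    con = consensus.upper()
    cpg = [False] * len(con)
    for i in range(len(con) - 1):
        if con[i] == "C" and con[i + 1] == "G":
            cpg[i] = cpg[i + 1] = True

    scored = transitions = transversions = 0
    for i, (a, b) in enumerate(zip(ins, con)):
        if a not in "ACGT" or b not in "ACGT":
            continue
        if a != b:
            is_transition = (a in PURINES) == (b in PURINES)
            if is_transition and cpg_adjust and cpg[i]:
                continue  # excluded from numerator and column count
            scored += 1
            if is_transition:
                transitions += 1
            else:
                transversions += 1
        else:
            scored += 1
    if scored == 0:
        raise ValueError("no scored alignment columns")
    return kimura2p(
        transitions / scored, transversions / scored, as_percent=as_percent
    )


@dataclass
class AgeLandscape:
    """bp per (chromosome set, TE class, divergence bin); the table's bins
    are left edges of width ``bin_width`` percentage points over [0, 50).
    ``excluded_bp`` totals records without usable divergence."""

    table: pd.DataFrame
    bin_width: float
    excluded_bp: int = 0

    def total_bp(self, chrom_set: str | None = None, te_class: str | None = None) -> int:
        t = self.table
        if chrom_set is not None:
            t = t[t["chrom_set"] == chrom_set]
        if te_class is not None:
            t = t[t["te_class"] == te_class]
        return int(t["bp"].sum())


def age_landscape(
    tes: list[TERecord],
    chromosomes: ChromosomeSet,
    bin_width: float = 1.0,
    max_divergence: float = 50.0,
) -> AgeLandscape:
    """Bin TE bp by percent divergence, split autosomes (A) vs X.

    TEs on unplaced scaffolds or with missing/out-of-range divergence are
    counted in ``excluded_bp`` and contribute to no bin.
    """
    rows: dict[tuple[str, str, float], int] = {}
    excluded = 0
    for te in tes:
        role = chromosomes.roles.get(te.chrom)
        d = te.divergence_pct
        if role not in ("autosome", "X") or d is None or d < 0 or d >= max_divergence:
            excluded += te.length
            continue
        chrom_set = "X" if role == "X" else "A"
        b = float(np.floor(d / bin_width) * bin_width)
        key = (chrom_set, te.te_class, b)
        rows[key] = rows.get(key, 0) + te.length
    table = pd.DataFrame(
        [
            {"chrom_set": cs, "te_class": cls, "bin": b, "bp": bp}
            for (cs, cls, b), bp in sorted(rows.items())
        ],
        columns=["chrom_set", "te_class", "bin", "bp"],
    )
    return AgeLandscape(table=table, bin_width=bin_width, excluded_bp=excluded)


def recency_threshold(ds_values) -> float:
    """Half the median synonymous-site divergence between the two species'
    one-to-one orthologs, in the same units as the input (so feed percent
    dS to compare against percent TE divergence)."""
    ds = np.asarray(list(ds_values), dtype=float)
    if ds.size == 0:
        raise ValueError("empty dS list")
    return float(0.5 * np.median(ds))


def recent_te_span(
    tes: list[TERecord], threshold: float, chroms: set[str] | None = None
) -> int:
    """Total bp of TE insertions with divergence strictly below the
    threshold (likely inserted after the species split); optionally
    restricted to a chromosome subset."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    total = 0
    for te in tes:
        if chroms is not None and te.chrom not in chroms:
            continue
        if te.divergence_pct is not None and te.divergence_pct < threshold:
            total += te.length
    return total


def x_size_attribution(
    recent_x_te_bp: float,
    x_len_a: float,
    x_len_b: float,
    genome_a: float,
    genome_b: float,
) -> dict[str, int]:
    """How much of the X-size difference between two genomes recent TE
    insertions on the larger X account for.

    Genome A must carry the larger X. Returns integer percentages:
    ``pct_x_larger`` (X_a vs X_b), ``pct_diff_from_x`` (share of the
    genome-size difference due to the X), and ``pct_attributable`` (share
    of the X-size difference covered by recent TE bp).
    """
    x_diff = x_len_a - x_len_b
    genome_diff = genome_a - genome_b
    if x_diff <= 0:
        raise ValueError("x_len_a must exceed x_len_b")
    if genome_diff <= 0:
        raise ValueError("genome_a must exceed genome_b")
    return {
        "pct_x_larger": round(100.0 * x_diff / x_len_b),
        "pct_diff_from_x": round(100.0 * x_diff / genome_diff),
        "pct_attributable": round(100.0 * recent_x_te_bp / x_diff),
    }
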