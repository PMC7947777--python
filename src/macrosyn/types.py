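"""Shared domain types for the macrosynteny toolkit.

All genomic coordinates are internal 0-based half-open; conversion to and
from 1-based inclusive conventions (GFF3) happens only in :mod:`macrosyn.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TE_CLASSES = ("DNA", "LINE", "LTR", "RC", "SINE", "Unknown")

ROLE_AUTOSOME = "autosome"
ROLE_X = "X"
ROLE_UNPLACED = "unplaced"


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A gene with its chromosome, 0-based half-open span, strand and a dense
    order rank on its chromosome (assigned by midpoint)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True, slots=True)
class TERecord:
    """A transposable-element interval with a class label and optional
    percent divergence from the family consensus."""

    chrom: str
    start: int
    end: int
    te_class: str = "Unknown"
    divergence_pct: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"TE interval start {self.start} >= end {self.end}")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ChromosomeSet:
    """Chromosome lengths and roles (autosome / X / unplaced) for one genome.

    A genome has at most one X *set*; several scaffolds may carry the X role
    (fragmented assemblies), but they form a single sex-chromosome unit.
    """

    lengths: dict[str, int]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for chrom in self.roles:
            if chrom not in self.lengths:
                raise ValueError(f"role given for unknown chromosome {chrom}")
        for chrom in self.lengths:
            self.roles.setdefault(chrom, ROLE_AUTOSOME)
        bad = {r for r in self.roles.values()} - {ROLE_AUTOSOME, ROLE_X, ROLE_UNPLACED}
        if bad:
            raise ValueError(f"unknown chromosome roles: {sorted(bad)}")

    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if self.roles[c] == ROLE_AUTOSOME]

    def x_scaffolds(self) -> list[str]:
        return [c for c in self.lengths if self.roles[c] == ROLE_X]

    def role(self, chrom: str) -> str:
        return self.roles[chrom]

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def total_autosomal_bp(self) -> int:
        return sum(self.lengths[c] for c in self.autosomes())


@dataclass
class Genome:
    """A gene complement plus its chromosome set."""

    genes: list[GeneRecord]
    chromosomes: ChromosomeSet

    def genes_by_chrom(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: g.rank)
        return out

    def gene_index(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}


@dataclass(frozen=True, slots=True)
class Anchor:
    """An ortholog pair used as a positional marker for collinearity."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int


@dataclass
class SyntenyBlock:
    """A maximal chain of collinear ortholog anchors between two genomes."""

    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # '+' or '-'
    anchors: list[Anchor]
    span_a: tuple[int, int] | None = None
    span_b: tuple[int, int] | None = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True, slots=True)
class BreakpointRegion:
    """Interval between two consecutive merged block spans on one autosome;
    both flanks are blocks, so chromosome ends are never regions."""

    chrom: str
    start: int
    end: int
    left_block: int
    right_block: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("breakpoint region must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class TestResult:
    """Result of one statistical test."""

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    sided: str  # 'one-greater' or 'two'

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("sample sizes must be non-negative")


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """Observed/expected/fold/empirical-p bundle for one TE class."""

    te_class: str
    observed_count: int
    observed_span: int
    expected_span: float
    fold: float
    p_empirical: float
    p_conservative: float
    n_perm: int
    seed: int
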