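"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; the GFF3 boundary is
the only place 1-based inclusive coordinates appear. Gene order ranks are
assigned per chromosome by midpoint (ties broken by start, then gene id),
which is robust to nested gene models.
"""

from __future__ import annotations

import gffutils
import pandas as pd

from .types import (
    TE_CLASSES,
    ChromosomeSet,
    GeneRecord,
    Genome,
    TERecord,
)

__all__ = [
    "assign_ranks",
    "read_gff3_genes",
    "write_gff3",
    "read_te_bed",
    "read_repeatmasker_out",
    "write_bed",
    "read_ortholog_tsv",
    "read_coverage_tsv",
    "read_tpm_tsv",
    "read_de_tsv",
    "morphs_from_columns",
]


def assign_ranks(genes: list[GeneRecord]) -> list[GeneRecord]:
    """Return genes with dense per-chromosome order ranks (0-based, by
    midpoint; ties broken by start then gene id). Deterministic for any
    input permutation."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneRecord] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(
            by_chrom[chrom], key=lambda g: (g.midpoint, g.start, g.gene_id)
        )
        for rank, g in enumerate(ordered):
            out.append(
                GeneRecord(g.gene_id, g.chrom, g.start, g.end, g.strand, rank)
            )
    return out


def _prevalidate_gff3(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: "
                                 f"expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: non-integer coordinate"
                ) from exc
            if end < start:
                raise ValueError(f"{path}: GFF3 line {lineno}: end < start")


def read_gff3_genes(
    path,
    x_chroms=(),
    unplaced_chroms=(),
) -> tuple[list[GeneRecord], ChromosomeSet]:
    """Read gene features from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open spans. Chromosome lengths come from ``##sequence-region``
    directives where present, else from the maximal gene end. Roles default
    to autosome; pass ``x_chroms``/``unplaced_chroms`` to assign the others
    (GFF3 itself carries no role information).
    """
    _prevalidate_gff3(path)
    genes: list[GeneRecord] = []
    directives: list[str] = []
    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if has_features:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
        for feat in db.features_of_type("gene"):
            genes.append(
                GeneRecord(
                    gene_id=feat.id,
                    chrom=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                )
            )
        directives = list(db.directives)
    else:  # gffutils rejects a feature-less file; directives still matter
        with open(path) as fh:
            directives = [
                line[2:].strip() for line in fh if line.startswith("##")
            ]
    genes = assign_ranks(genes)

    lengths: dict[str, int] = {}
    for directive in directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            lengths[parts[1]] = int(parts[3])
    for g in genes:
        if g.chrom not in lengths:
            lengths[g.chrom] = 0
        lengths[g.chrom] = max(lengths[g.chrom], g.end)
    roles = {c: "X" for c in x_chroms if c in lengths}
    roles.update({c: "unplaced" for c in unplaced_chroms if c in lengths})
    return genes, ChromosomeSet(lengths=lengths, roles=roles)


def write_gff3(genome: Genome, path) -> None:
    """Write gene features as GFF3 (1-based inclusive), with
    ``##sequence-region`` directives carrying chromosome lengths."""
    chroms = genome.chromosomes
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chroms.lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(genome.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tmacrosyn\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def _map_te_class(label: str) -> str:
    """Map a free-form class or class/family label onto the six TE classes."""
    for token in label.replace("?", "").split("/"):
        token = token.strip()
        for cls in TE_CLASSES:
            if token.upper() == cls.upper():
                return cls
    return "Unknown"


def read_te_bed(path) -> list[TERecord]:
    """Read TE intervals from BED4/BED5 (0-based half-open; class in column
    4, percent divergence in optional column 5). Classes outside the
    enumeration map to Unknown; records are returned sorted by (chrom, start).
    """
    records: list[TERecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: BED line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: BED line {lineno}: unparseable coordinate"
                ) from exc
            if start < 0 or end < 0:
                raise ValueError(f"{path}: BED line {lineno}: negative coordinate")
            te_class = _map_te_class(fields[3]) if len(fields) > 3 else "Unknown"
            div = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            records.append(TERecord(fields[0], start, end, te_class, div))
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def read_repeatmasker_out(path) -> list[TERecord]:
    """Read a RepeatMasker ``.out`` annotation table.

    Standard column layout: score, %div, %del, %ins, query, begin (1-based),
    end (inclusive), (left), strand, repeat, class/family, ... The
    class/family string is mapped onto the six TE classes; %div becomes
    ``divergence_pct``.
    """
    records: list[TERecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            # header lines start with 'SW'/'score' or are separator rows
            if not fields[0].replace(".", "").isdigit():
                continue
            if len(fields) < 11:
                raise ValueError(f"{path}: .out line {lineno}: too few columns")
            try:
                div = float(fields[1])
                start = int(fields[5]) - 1
                end = int(fields[6])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: .out line {lineno}: unparseable coordinate"
                ) from exc
            if start < 0:
                raise ValueError(f"{path}: .out line {lineno}: negative coordinate")
            records.append(
                TERecord(fields[4], start, end, _map_te_class(fields[10]), div)
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def write_bed(intervals, path) -> None:
    """Write sorted intervals as 0-based half-open BED.

    TE records round-trip bit-exactly through :func:`read_te_bed`. Accepts
    any objects with chrom/start/end (TERecord adds class and divergence).
    """
    rows = list(intervals)
    keys = [(getattr(r, "chrom"), getattr(r, "start")) for r in rows]
    if keys != sorted(keys):
        raise ValueError("intervals must be sorted by (chrom, start)")
    with open(path, "w") as fh:
        for r in rows:
            cols = [r.chrom, str(r.start), str(r.end)]
            te_class = getattr(r, "te_class", None)
            if te_class is not None:
                cols.append(te_class)
                div = getattr(r, "divergence_pct", None)
                if div is not None:
                    cols.append(format(div, "g"))
            fh.write("\t".join(cols) + "\n")


def read_ortholog_tsv(path) -> list[tuple[str, str]]:
    """Read a two-column one-to-one ortholog table (no header).

    Raises on a duplicated id in either column: the one-to-one contract is
    an input precondition, not something this reader repairs.
    """
    pairs: list[tuple[str, str]] = []
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            a, b = fields[0], fields[1]
            if a in seen_a:
                raise ValueError(f"{path}: line {lineno}: duplicate id {a!r} in column 1")
            if b in seen_b:
                raise ValueError(f"{path}: line {lineno}: duplicate id {b!r} in column 2")
            seen_a.add(a)
            seen_b.add(b)
            pairs.append((a, b))
    return pairs


def read_coverage_tsv(path) -> pd.DataFrame:
    """Read a per-window read-depth table (chrom, start, end, depth)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"chrom", "start", "end", "depth"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: coverage table needs columns {sorted(expected)}")
    return df


def read_tpm_tsv(path) -> pd.DataFrame:
    """Read a gene x sample expression matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_de_tsv(path) -> pd.DataFrame:
    """Read a differential-expression result table (gene, qval, b_M, b_FW, b_N)."""
    df = pd.read_csv(path, sep="\t")
    if "gene" in df.columns:
        df = df.set_index("gene")
    return df


def morphs_from_columns(columns) -> dict[str, str]:
    """Infer the sample -> morph map from column names like ``FA_1``."""
    return {c: c.rsplit("_", 1)[0] for c in columns}
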