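"""Genome annotation model and genic/intergenic partition.

Genes are read from GFF3 (1-based inclusive) or BED (0-based half-open) into a
uniform internal representation: 0-based half-open coordinates, sorted by
(chrom, start). The partition step merges overlapping gene models into disjoint
genic spans and takes the per-chromosome complement, yielding intergenic
regions that carry the identity and strand of their flanking genes. Together
the genic and intergenic spans tile each chromosome exactly.

All TSV reports emit 1-based inclusive coordinates to match genome-browser
display; internal coordinates never leave the 0-based half-open convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils.iterators


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene body (whole-ORF granularity; no transcript structure)."""

    gene_id: str
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime_end(self) -> int:
        """Coordinate of the 5' extremity (start for '+', end for '-')."""
        return self.start if self.strand == "+" else self.end

    def three_prime_end(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Flank:
    """Identity and strand of a gene abutting an intergenic region."""

    gene_id: str
    strand: str


@dataclass(frozen=True)
class IntergenicRegion:
    interval: GenomicInterval
    left_gene: Optional[Flank]  # gene ending at interval.start
    right_gene: Optional[Flank]  # gene starting at interval.end
    edge: bool = False  # a scaffold end replaces one flank

    def __post_init__(self) -> None:
        if self.left_gene is None and self.right_gene is None:
            raise AnnotationError("intergenic region must have at least one flank")


@dataclass(frozen=True)
class GenicSpan:
    """A maximal run of (possibly merged) gene models."""

    interval: GenomicInterval
    member_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def region_id(self) -> str:
        return self.member_ids[0] if len(self.member_ids) == 1 else "+".join(self.member_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected 'name\\tlength'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_genes(
    annotation_source: str | Path,
    feature_type: str = "gene",
    fmt: Optional[str] = None,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[GeneModel]:
    """Read a gene catalog from GFF3 or BED.

    Parameters
    ----------
    annotation_source
        Path to a GFF3 (``.gff``, ``.gff3``) or BED (``.bed``) file; the
        dialect is taken from the extension unless ``fmt`` is given.
    feature_type
        GFF3 feature type (column 3) to keep; ignored for BED.
    fmt
        Force ``"gff3"`` or ``"bed"``.
    chrom_sizes
        When given, genes on chromosomes absent from the table, or extending
        past a chromosome end, raise :class:`AnnotationError`.

    Returns
    -------
    list of :class:`GeneModel` in 0-based half-open coordinates, sorted by
    (chrom, start). Duplicate gene ids are rejected.
    """
    path = Path(annotation_source)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    genes = _read_bed(path) if fmt == "bed" else _read_gff3(path, feature_type)

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
        if chrom_sizes is not None:
            if g.chrom not in chrom_sizes:
                raise AnnotationError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.end > chrom_sizes[g.chrom]:
                raise AnnotationError(
                    f"gene {g.gene_id} ends at {g.end} beyond chromosome "
                    f"{g.chrom} length {chrom_sizes[g.chrom]}"
                )
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))


def _read_gff3(path: Path, feature_type: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for recno, feat in enumerate(gffutils.iterators.DataIterator(str(path)), 1):
        if feat.featuretype != feature_type:
            continue
        if feat.start > feat.end:
            raise AnnotationError(f"{path} record {recno}: start {feat.start} > end {feat.end}")
        gid = feat.attributes.get("ID", [feat.id or f"record{recno}"])[0]
        desc = feat.attributes.get("description", [None])[0]
        # GFF3 is 1-based inclusive -> 0-based half-open
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                description=desc,
            )
        )
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise AnnotationError(f"{path}:{lineno}: BED needs >=4 columns (name required)")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start > end:
                raise AnnotationError(f"{path}:{lineno}: start {start} > end {end}")
            name = parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            genes.append(GeneModel(name, chrom, start, end, strand))
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path, fmt: Optional[str] = None) -> None:
    """Write a gene catalog as GFF3 or BED6 (round-trip safe with read_genes)."""
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                attrs = f"ID={g.gene_id}"
                if g.description:
                    attrs += f";description={g.description}"
                fh.write(
                    f"{g.chrom}\tchipregions\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
        else:
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------


def partition_genome(
    genes: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    min_intergenic_length: int = 1,
) -> tuple[list[GenicSpan], list[IntergenicRegion]]:
    """Partition every chromosome into genic spans and intergenic regions.

    Overlapping or bookended gene models are merged into one genic span (member
    ids retained). Internal gaps become two-flank intergenic regions; terminal
    gaps become ``edge`` regions with one flank. Gaps shorter than
    ``min_intergenic_length`` are dropped (so the tiling is exact only at the
    default of 1). Flanks are always the nearest gene model on each side of the
    gap, with its own strand.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise AnnotationError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        if g.end > chrom_sizes[g.chrom]:
            raise AnnotationError(
                f"gene {g.gene_id} extends beyond chromosome {g.chrom} "
                f"(end {g.end} > {chrom_sizes[g.chrom]})"
            )
        by_chrom.setdefault(g.chrom, []).append(g)

    genic: list[GenicSpan] = []
    intergenic: list[IntergenicRegion] = []

    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        cgenes = sorted(by_chrom.get(chrom, []), key=lambda g: (g.start, g.end))
        spans: list[tuple[int, int, list[GeneModel]]] = []
        for g in cgenes:
            if spans and g.start <= spans[-1][1]:  # overlap or bookended: merge
                s, e, members = spans[-1]
                spans[-1] = (s, max(e, g.end), members + [g])
            else:
                spans.append((g.start, g.end, [g]))

        for s, e, members in spans:
            genic.append(
                GenicSpan(GenomicInterval(chrom, s, e), tuple(m.gene_id for m in members))
            )

        # boundary flank of each merged span: the member gene actually touching
        # the gap (leftmost start / rightmost end within the span)
        def _left_flank(members: list[GeneModel]) -> Flank:
            g = max(members, key=lambda m: m.end)
            return Flank(g.gene_id, g.strand)

        def _right_flank(members: list[GeneModel]) -> Flank:
            g = min(members, key=lambda m: m.start)
            return Flank(g.gene_id, g.strand)

        prev_end = 0
        prev_members: Optional[list[GeneModel]] = None
        for s, e, members in spans:
            if s - prev_end >= min_intergenic_length:
                intergenic.append(
                    IntergenicRegion(
                        GenomicInterval(chrom, prev_end, s),
                        left_gene=_left_flank(prev_members) if prev_members else None,
                        right_gene=_right_flank(members),
                        edge=prev_members is None,
                    )
                )
            prev_end, prev_members = e, members
        if prev_members is not None and length - prev_end >= min_intergenic_length:
            intergenic.append(
                IntergenicRegion(
                    GenomicInterval(chrom, prev_end, length),
                    left_gene=_left_flank(prev_members),
                    right_gene=None,
                    edge=True,
                )
            )

    return genic, intergenic


def intergenic_region_id(r: IntergenicRegion) -> str:
    """Stable id for an intergenic region: IG:<chrom>:<start1>-<end1> (1-based)."""
    return f"IG:{r.interval.chrom}:{r.interval.start + 1}-{r.interval.end}"


def write_partition_report(
    genic: Sequence[GenicSpan],
    intergenic: Sequence[IntergenicRegion],
    path: str | Path,
    header_comment: Optional[str] = None,
) -> None:
    """Partition TSV, 1-based inclusive coordinates for browser display."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "region_id", "chrom", "start", "end", "type",
                "left_gene", "left_strand", "right_gene", "right_strand", "edge",
            ]
        )
        for g in genic:
            iv = g.interval
            w.writerow([g.region_id, iv.chrom, iv.start + 1, iv.end, "ORF",
                        ".", ".", ".", ".", "False"])
        for r in intergenic:
            iv = r.interval
            w.writerow(
                [
                    intergenic_region_id(r), iv.chrom, iv.start + 1, iv.end, "INTERGENIC",
                    r.left_gene.gene_id if r.left_gene else ".",
                    r.left_gene.strand if r.left_gene else ".",
                    r.right_gene.gene_id if r.right_gene else ".",
                    r.right_gene.strand if r.right_gene else ".",
                    str(r.edge),
                ]
            )
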