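"""Positional classification of enriched intergenic regions.

An intergenic region sits between two genes (or one gene and a scaffold end).
Which *end* of each flanking gene abuts the region follows from strand alone:
a '+' gene to the left abuts via its 3' end, a '-' gene via its 5' end, and
mirrored on the right. A flank is "addressed" by the peak when the summit lies
within ``d_max`` of that abutting end, or unconditionally when the region is
short (length <= ``both_flank_len``, default 2*d_max). The addressed ends map
onto five positional categories:

    one 5' end                -> PROMOTER_SINGLE
    one 3' end                -> TERMINATOR_SINGLE
    two 5' ends (divergent)   -> BIDIRECTIONAL_PROMOTER
    two 3' ends (convergent)  -> SHARED_TERMINATOR
    one 5' + one 3' (tandem)  -> PROMOTER_TERMINATOR_OVERLAP

with UNCLASSIFIED when the summit addresses neither flank. "Promoter" and
"terminator" here are purely positional (5'- or 3'-proximal intergenic space);
no TSS or motif evidence is implied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from chipregions.annotation import (
    Flank,
    IntergenicRegion,
    intergenic_region_id,
)


class IntergenicClass(str, Enum):
    PROMOTER_SINGLE = "PROMOTER_SINGLE"
    TERMINATOR_SINGLE = "TERMINATOR_SINGLE"
    PROMOTER_TERMINATOR_OVERLAP = "PROMOTER_TERMINATOR_OVERLAP"
    BIDIRECTIONAL_PROMOTER = "BIDIRECTIONAL_PROMOTER"
    SHARED_TERMINATOR = "SHARED_TERMINATOR"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ClassifierConfig:
    d_max: int = 300  # max summit-to-gene-end distance to address a flank (bp)
    both_flank_len: Optional[int] = None  # default 2*d_max

    def __post_init__(self) -> None:
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")
        if self.both_flank_len is None:
            object.__setattr__(self, "both_flank_len", 2 * self.d_max)


@dataclass(frozen=True)
class FlankEnd:
    """One flank of an intergenic region, resolved to the abutting gene end."""

    gene_id: str
    strand: str
    end_kind: str  # '5p' or '3p': which end of the gene touches the region
    distance: int  # bp from summit to that end


@dataclass(frozen=True)
class Classification:
    label: IntergenicClass
    # (gene_id, end_kind) for each addressed flank, left flank first
    addressed: tuple[tuple[str, str], ...]
    summit: int
    summit_is_midpoint: bool = False


def flank_geometry(region: IntergenicRegion, summit: int) -> tuple[Optional[FlankEnd], Optional[FlankEnd]]:
    """Resolve both flanks to (gene, abutting end, summit distance).

    Distances are measured from the summit to the region boundary the gene
    touches: ``summit - start`` on the left, ``end - summit`` on the right.
    """
    iv = region.interval
    if not (iv.start <= summit < iv.end):
        raise ValueError(
            f"summit {summit} outside region {iv.chrom}:{iv.start}-{iv.end}"
        )
    left = right = None
    if region.left_gene is not None:
        # '+' left gene ends (3') at the region start; '-' starts (5') there
        kind = "3p" if region.left_gene.strand == "+" else "5p"
        left = FlankEnd(region.left_gene.gene_id, region.left_gene.strand, kind,
                        summit - iv.start)
    if region.right_gene is not None:
        kind = "5p" if region.right_gene.strand == "+" else "3p"
        right = FlankEnd(region.right_gene.gene_id, region.right_gene.strand, kind,
                         iv.end - summit)
    return left, right


def classify_intergenic(
    region: IntergenicRegion,
    summit: Optional[int],
    config: Optional[ClassifierConfig] = None,
) -> Classification:
    """Classify one intergenic region from its summit and flank orientations.

    A missing summit (no strong peak) falls back to the region midpoint and is
    flagged. Edge regions are classified on their single flank.
    """
    config = config or ClassifierConfig()
    midpoint_used = summit is None
    if summit is None:
        summit = region.interval.midpoint()
    left, right = flank_geometry(region, summit)

    short = region.interval.length <= config.both_flank_len
    addressed = [
        f for f in (left, right)
        if f is not None and (short or f.distance <= config.d_max)
    ]

    kinds = [f.end_kind for f in addressed]
    if len(addressed) == 2:
        if kinds == ["5p", "5p"]:
            label = IntergenicClass.BIDIRECTIONAL_PROMOTER
        elif kinds == ["3p", "3p"]:
            label = IntergenicClass.SHARED_TERMINATOR
        else:
            label = IntergenicClass.PROMOTER_TERMINATOR_OVERLAP
    elif len(addressed) == 1:
        label = (
            IntergenicClass.PROMOTER_SINGLE
            if kinds[0] == "5p"
            else IntergenicClass.TERMINATOR_SINGLE
        )
    else:
        label = IntergenicClass.UNCLASSIFIED
    return Classification(
        label=label,
        addressed=tuple((f.gene_id, f.end_kind) for f in addressed),
        summit=summit,
        summit_is_midpoint=midpoint_used,
    )


def classify_all(
    enriched_intergenic: pd.DataFrame,
    intergenic_regions: Sequence[IntergenicRegion],
    config: Optional[ClassifierConfig] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every enriched intergenic region and tally classes.

    ``enriched_intergenic`` is an enrichment table filtered to INTERGENIC rows
    at the chosen threshold; regions are matched on region_id. Returns the
    per-region assignment table and a count per class (all six labels present,
    summing to the number of input rows).
    """
    config = config or ClassifierConfig()
    by_id = {intergenic_region_id(r): r for r in intergenic_regions}
    rows = []
    counts = {c.value: 0 for c in IntergenicClass}
    for _, rec in enriched_intergenic.iterrows():
        rid = rec["region_id"]
        if rid not in by_id:
            raise KeyError(f"region {rid!r} absent from partition")
        region = by_id[rid]
        summit = rec.get("summit")
        summit = None if pd.isna(summit) else int(summit)
        cls = classify_intergenic(region, summit, config)
        counts[cls.label.value] += 1
        rows.append(
            {
                "region_id": rid,
                "class": cls.label.value,
                "gene_ids": ",".join(g for g, _ in cls.addressed) or ".",
                "gene_ends": ",".join(k for _, k in cls.addressed) or ".",
                "summit": cls.summit,
                "summit_is_midpoint": cls.summit_is_midpoint,
                "fold_enrichment": rec.get("fold_enrichment", float("nan")),
            }
        )
    cols = ["region_id", "class", "gene_ids", "gene_ends", "summit",
            "summit_is_midpoint", "fold_enrichment"]
    return pd.DataFrame(rows, columns=cols), counts


def combine_orf_flanks(
    enriched_orf_ids: Iterable[str],
    assignments: pd.DataFrame,
) -> tuple[set[str], set[str]]:
    """Combined genic+flank categories at one threshold.

    An enriched ORF joins PROMOTER_PLUS_ORF when some enriched intergenic
    region addresses its 5' end under a promoter-type class (PROMOTER_SINGLE
    or BIDIRECTIONAL_PROMOTER), and ORF_PLUS_TERMINATOR when a terminator-type
    class (TERMINATOR_SINGLE or SHARED_TERMINATOR) addresses its 3' end. An
    ORF may appear in both sets.
    """
    promoter_classes = {
        IntergenicClass.PROMOTER_SINGLE.value,
        IntergenicClass.BIDIRECTIONAL_PROMOTER.value,
    }
    terminator_classes = {
        IntergenicClass.TERMINATOR_SINGLE.value,
        IntergenicClass.SHARED_TERMINATOR.value,
    }
    promoter_hit: set[str] = set()
    terminator_hit: set[str] = set()
    for _, rec in assignments.iterrows():
        if rec["gene_ids"] == ".":
            continue
        genes = rec["gene_ids"].split(",")
        ends = rec["gene_ends"].split(",")
        for g, k in zip(genes, ends):
            if rec["class"] in promoter_classes and k == "5p":
                promoter_hit.add(g)
            if rec["class"] in terminator_classes and k == "3p":
                terminator_hit.add(g)
    enriched = set(map(str, enriched_orf_ids))
    return enriched & promoter_hit, enriched & terminator_hit


def write_class_report(
    assignments: pd.DataFrame,
    counts: Mapping[str, int],
    path: Union[str, Path],
    config: Optional[ClassifierConfig] = None,
) -> None:
    config = config or ClassifierConfig()
    with open(path, "w") as fh:
        fh.write(f"# d_max={config.d_max} both_flank_len={config.both_flank_len}\n")
        assignments.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    summary = Path(path).with_suffix(".summary.tsv")
    with open(summary, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["class", "count"])
        for c in IntergenicClass:
            w.writerow([c.value, counts.get(c.value, 0)])
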