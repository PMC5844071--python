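"""Positional classifier: oracle enumeration, strand symmetry, combined categories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import chipregions as cr
from chipregions.annotation import Flank, GenomicInterval, IntergenicRegion
from chipregions.classify import (
    ClassifierConfig,
    IntergenicClass,
    classify_all,
    classify_intergenic,
    combine_orf_flanks,
)
from chipregions.enrichment import select_enriched
from chipregions.simulate import simulate_genome, simulate_tracks
from tests.conftest import small_config

# which gene end touches the gap, per (side, strand) — written as a lookup
# table rather than derived, so the oracle is independent of the implementation
ORIENTATION_ENDS = {
    ("left", "+"): "3p",
    ("left", "-"): "5p",
    ("right", "+"): "5p",
    ("right", "-"): "3p",
}

CLASS_OF_ADDRESSED = {
    ("5p",): "PROMOTER_SINGLE",
    ("3p",): "TERMINATOR_SINGLE",
    ("5p", "5p"): "BIDIRECTIONAL_PROMOTER",
    ("3p", "3p"): "SHARED_TERMINATOR",
    ("3p", "5p"): "PROMOTER_TERMINATOR_OVERLAP",
    (): "UNCLASSIFIED",
}


def oracle_class(left_strand, right_strand, length, summit_offset, d_max=300,
                 both_flank_len=600) -> str:
    """Hand-written truth table over orientations and summit positions."""
    lk = ORIENTATION_ENDS[("left", left_strand)]
    rk = ORIENTATION_ENDS[("right", right_strand)]
    addressed = []
    short = length <= both_flank_len
    if short or summit_offset <= d_max:
        addressed.append(lk)
    if short or (length - summit_offset) <= d_max:
        addressed.append(rk)
    return CLASS_OF_ADDRESSED[tuple(sorted(addressed))]


def make_region(left_strand, right_strand, start, end, chrom="chr1"):
    return IntergenicRegion(
        GenomicInterval(chrom, start, end),
        left_gene=Flank("L", left_strand),
        right_gene=Flank("R", right_strand),
    )


class TestClassifyIntergenic:
    def test_terminator_single(self):
        """Summit near the 3' end of a left '+' gene, far from the right gene."""
        region = make_region("+", "+", 500, 1500)
        cls = classify_intergenic(region, summit=520, config=ClassifierConfig(d_max=300))
        assert cls.label == IntergenicClass.TERMINATOR_SINGLE
        assert cls.addressed == (("L", "3p"),)

    def test_bidirectional_promoter_short_divergent(self):
        region = make_region("-", "+", 500, 900)  # 400 bp <= both_flank_len
        cls = classify_intergenic(region, summit=700)
        assert cls.label == IntergenicClass.BIDIRECTIONAL_PROMOTER
        assert {g for g, _ in cls.addressed} == {"L", "R"}

    def test_shared_terminator_convergent_equidistant(self):
        region = make_region("+", "-", 500, 900)
        cls = classify_intergenic(region, summit=700)
        assert cls.label == IntergenicClass.SHARED_TERMINATOR

    def test_unclassified_when_summit_addresses_neither(self):
        region = make_region("+", "+", 0, 3000)
        cls = classify_intergenic(region, summit=1500)
        assert cls.label == IntergenicClass.UNCLASSIFIED

    def test_midpoint_substitutes_for_missing_summit(self):
        region = make_region("-", "+", 500, 900)
        cls = classify_intergenic(region, summit=None)
        assert cls.summit == 700
        assert cls.summit_is_midpoint
        assert cls.label == IntergenicClass.BIDIRECTIONAL_PROMOTER

    def test_edge_region_classified_on_single_flank(self):
        region = IntergenicRegion(
            GenomicInterval("chr1", 0, 500), left_gene=None,
            right_gene=Flank("R", "+"), edge=True,
        )
        cls = classify_intergenic(region, summit=450)
        assert cls.label == IntergenicClass.PROMOTER_SINGLE
        assert cls.addressed == (("R", "5p"),)

    def test_summit_outside_region_rejected(self):
        region = make_region("+", "+", 500, 900)
        with pytest.raises(ValueError, match="outside"):
            classify_intergenic(region, summit=1200)

    def test_exhaustive_truth_table_oracle(self):
        """All 4 orientations x summit grid on a 3 kb region match the oracle."""
        length = 3000
        for ls in "+-":
            for rs in "+-":
                region = make_region(ls, rs, 1000, 1000 + length)
                for off in range(0, length, 37):
                    got = classify_intergenic(region, summit=1000 + off)
                    assert got.label.value == oracle_class(ls, rs, length, off), (
                        ls, rs, off,
                    )

    def test_exhaustive_oracle_short_regions(self):
        """Short regions (<= both_flank_len) address both flanks regardless of summit."""
        for length in (200, 400, 600):
            for ls in "+-":
                for rs in "+-":
                    region = make_region(ls, rs, 1000, 1000 + length)
                    for off in range(0, length, 23):
                        got = classify_intergenic(region, summit=1000 + off)
                        assert got.label.value == oracle_class(ls, rs, length, off)

    def test_strand_symmetry(self):
        """Reverse-complementing the toy genome preserves every class."""
        M = 10_000  # mirror: x -> M - x, strands flip, flanks swap
        flip = {"+": "-", "-": "+"}
        for ls in "+-":
            for rs in "+-":
                for start, end in ((1000, 4000), (1000, 1400)):
                    region = make_region(ls, rs, start, end)
                    for off in range(0, end - start, 61):
                        summit = start + off
                        mirrored = make_region(flip[rs], flip[ls], M - end, M - start)
                        # mirrored summit: reflect, then clamp into [start, end)
                        m_summit = min(max(M - summit, M - end), M - start - 1)
                        a = classify_intergenic(region, summit)
                        b = classify_intergenic(mirrored, m_summit)
                        assert a.label == b.label, (ls, rs, start, end, off)


class TestClassifyAll:
    def test_planted_classes_recovered_exactly(self):
        """End-to-end: partition + enrichment summits reproduce planted labels."""
        sim = simulate_genome(small_config(seed=5))
        ip, inp = simulate_tracks(sim)
        genic, intergenic = cr.partition_genome(sim.genes, sim.chrom_sizes)
        table = cr.enrich_regions(ip, inp, list(genic) + list(intergenic))
        enriched_ig = select_enriched(table[table["region_type"] == "INTERGENIC"], 2.0)
        assignments, counts = classify_all(enriched_ig, intergenic)
        truth = sim.truth_intergenic
        assert len(assignments) == len(truth)
        merged = assignments.merge(truth[["region_id", "class"]], on="region_id",
                                   suffixes=("_got", "_true"))
        assert len(merged) == len(truth)
        assert (merged["class_got"] == merged["class_true"]).all()
        assert counts == {
            **{c.value: 0 for c in IntergenicClass},
            **truth["class"].value_counts().to_dict(),
        }

    def test_counts_sum_to_input(self):
        sim = simulate_genome(small_config(seed=6))
        ip, inp = simulate_tracks(sim)
        genic, intergenic = cr.partition_genome(sim.genes, sim.chrom_sizes)
        table = cr.enrich_regions(ip, inp, list(genic) + list(intergenic))
        enriched_ig = select_enriched(table[table["region_type"] == "INTERGENIC"], 2.0)
        assignments, counts = classify_all(enriched_ig, intergenic)
        assert sum(counts.values()) == len(enriched_ig) == len(assignments)

    def test_empty_input_all_zero(self):
        assignments, counts = classify_all(
            pd.DataFrame(columns=["region_id", "summit", "fold_enrichment"]), []
        )
        assert len(assignments) == 0
        assert all(v == 0 for v in counts.values())

    def test_unknown_region_id_rejected(self):
        df = pd.DataFrame([{"region_id": "IG:chrZ:1-100", "summit": 50}])
        with pytest.raises(KeyError, match="chrZ"):
            classify_all(df, [])


class TestCombineOrfFlanks:
    def _assignments(self, rows):
        return pd.DataFrame(
            rows, columns=["region_id", "class", "gene_ids", "gene_ends", "summit",
                           "summit_is_midpoint", "fold_enrichment"],
        )

    def test_promoter_plus_orf_membership(self):
        assigns = self._assignments(
            [["IG:1", "PROMOTER_SINGLE", "g", "5p", 0, False, 5.0]]
        )
        promoter, terminator = combine_orf_flanks({"g"}, assigns)
        assert promoter == {"g"} and terminator == set()

    def test_orf_without_enriched_flank_in_neither(self):
        promoter, terminator = combine_orf_flanks({"g"}, self._assignments([]))
        assert promoter == set() == terminator

    def test_bidirectional_counts_for_both_genes(self):
        assigns = self._assignments(
            [["IG:1", "BIDIRECTIONAL_PROMOTER", "a,b", "5p,5p", 0, False, 5.0]]
        )
        promoter, _ = combine_orf_flanks({"a", "b", "c"}, assigns)
        assert promoter == {"a", "b"}

    def test_overlap_class_feeds_neither_category(self):
        # promoter/terminator overlap is its own category in the five-way split
        assigns = self._assignments(
            [["IG:1", "PROMOTER_TERMINATOR_OVERLAP", "a,b", "3p,5p", 0, False, 5.0]]
        )
        promoter, terminator = combine_orf_flanks({"a", "b"}, assigns)
        assert promoter == set() == terminator

    def test_planted_composites_recovered(self):
        """Composite promoter+ORF / ORF+terminator sets match truth construction."""
        sim = simulate_genome(small_config(seed=9, n_occupied_genes=14))
        ip, inp = simulate_tracks(sim)
        genic, intergenic = cr.partition_genome(sim.genes, sim.chrom_sizes)
        table = cr.enrich_regions(ip, inp, list(genic) + list(intergenic))
        orf = table[table["region_type"] == "ORF"]
        enriched_orfs = set(select_enriched(orf, 2.0)["region_id"])
        enriched_ig = select_enriched(table[table["region_type"] == "INTERGENIC"], 2.0)
        assignments, _ = classify_all(enriched_ig, intergenic)
        promoter, terminator = combine_orf_flanks(enriched_orfs, assignments)
        # truth: occupied genes whose planted flanking region addresses them
        truth_prom, truth_term = set(), set()
        occupied = set(sim.truth_genes.loc[sim.truth_genes["occupied"], "gene_id"])
        truth_assign, _ = classify_all(
            sim.truth_intergenic.rename(columns={"true_fe": "fold_enrichment"}),
            intergenic,
        )
        truth_prom, truth_term = combine_orf_flanks(occupied, truth_assign)
        assert promoter == truth_prom
        assert terminator == truth_term
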