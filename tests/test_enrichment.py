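"""Fold-enrichment computation, strong-peak scan and region ranking."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipregions.annotation import GenomicInterval, GenicSpan
from chipregions.enrichment import (
    CoverageTrack,
    EnrichmentConfig,
    TrackError,
    bin_label,
    enrich_regions,
    fold_enrichment,
    ordered_bin_labels,
    region_signal,
    select_enriched,
    strong_peak_scan,
)
from tests.conftest import uniform_track

SIZES = {"chr1": 1000}


def brute_force_fe(ip, inp, start, end, pseudocount=1.0):
    """Per-base loop oracle for region fold enrichment."""
    ip_sum = sum(float(ip.depth["chr1"][i]) for i in range(start, end))
    in_sum = sum(float(inp.depth["chr1"][i]) for i in range(start, end))
    num = (ip_sum + pseudocount) / ip.total_signal
    den = (in_sum + pseudocount) / inp.total_signal
    return num / den


class TestRegionSignal:
    def test_uniform_depth(self):
        t = uniform_track(3, {"chr1": 100})
        assert region_signal(t, GenomicInterval("chr1", 10, 20)) == 30

    def test_all_zero_track(self):
        t = CoverageTrack({"chr1": np.zeros(100)}, {"chr1": 100})
        assert region_signal(t, GenomicInterval("chr1", 0, 100)) == 0

    def test_matches_per_base_loop(self):
        rng = np.random.default_rng(3)
        depth = rng.integers(0, 50, size=5000).astype(float)
        t = CoverageTrack({"chr1": depth}, {"chr1": 5000})
        iv = GenomicInterval("chr1", 1200, 2200)
        assert region_signal(t, iv) == sum(float(depth[i]) for i in range(1200, 2200))

    def test_off_chromosome_errors(self):
        t = uniform_track(1, {"chr1": 100})
        with pytest.raises(TrackError):
            region_signal(t, GenomicInterval("chr1", 50, 200))


class TestFoldEnrichment:
    def test_plain_ratio(self):
        assert fold_enrichment(200, 1e6, 100, 1e6, pseudocount=0) == pytest.approx(2.0)

    def test_zero_ip_with_pseudocount(self):
        # ((0+1)/1e6) / ((100+1)/1e6) = 1/101
        assert fold_enrichment(0, 1e6, 100, 1e6, pseudocount=1) == pytest.approx(1 / 101)

    def test_zero_input_zero_pseudocount_is_infinite(self):
        assert math.isinf(fold_enrichment(10, 1e6, 0, 1e6, pseudocount=0))

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            fold_enrichment(-1, 1e6, 10, 1e6)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.floats(0.5, 1e4), st.floats(0.5, 1e4),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, ip_sum, input_sum, c):
        """Scaling sums and totals by any c leaves the ratio unchanged (pc=0)."""
        base = fold_enrichment(ip_sum, 1e6, input_sum, 1e6, pseudocount=0)
        scaled = fold_enrichment(c * ip_sum, c * 1e6, c * input_sum, c * 1e6, pseudocount=0)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_depth_invariance_one_track(self):
        """Multiplying one track's depths by a constant changes no FE (pc=0)."""
        rng = np.random.default_rng(4)
        depth = rng.integers(1, 40, 1000).astype(float)
        ip = CoverageTrack({"chr1": depth}, SIZES)
        ip5 = CoverageTrack({"chr1": 5 * depth}, SIZES)
        inp = uniform_track(10, SIZES)
        iv = GenomicInterval("chr1", 100, 600)
        fe1 = fold_enrichment(region_signal(ip, iv), ip.total_signal,
                              region_signal(inp, iv), inp.total_signal, 0)
        fe5 = fold_enrichment(region_signal(ip5, iv), ip5.total_signal,
                              region_signal(inp, iv), inp.total_signal, 0)
        assert fe5 == pytest.approx(fe1, rel=1e-12)


class TestBins:
    def test_half_open_bins(self):
        cfg = EnrichmentConfig()
        assert [bin_label(v, cfg) for v in (1.5, 2, 3.9, 4, 6, 8, 20)] == [
            "<2", "2-4", "2-4", "4-6", "6-8", ">=8", ">=8",
        ]

    def test_cumulative_bins(self):
        cfg = EnrichmentConfig(cumulative_bins=True)
        assert bin_label(5, cfg) == ">=4"
        assert bin_label(9, cfg) == ">=8"
        assert ordered_bin_labels(cfg) == [">=2", ">=4", ">=6", ">=8"]

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(thresholds=(4, 2))


class TestStrongPeak:
    def test_ip_equal_input_not_strong(self):
        ip = uniform_track(10, SIZES)
        inp = uniform_track(10, SIZES)
        strong, _ = strong_peak_scan(ip, inp, GenomicInterval("chr1", 0, 1000),
                                     EnrichmentConfig())
        assert not strong

    def test_planted_plateau_found_with_summit_inside(self):
        """5x plateau over a 600 bp stretch on flat input, wide background."""
        sizes = {"chr1": 10_000}
        depth = np.full(10_000, 10.0)
        depth[2200:2800] = 50.0
        ip = CoverageTrack({"chr1": depth}, sizes)
        inp = uniform_track(10, sizes)
        region = GenomicInterval("chr1", 2100, 2900)
        cfg = EnrichmentConfig()
        strong, summit = strong_peak_scan(ip, inp, region, cfg)
        assert strong
        assert 2200 <= summit < 2800
        # oracle: enumerate every candidate window by hand, ties -> leftmost
        def window_fe(s):
            ip_sum = sum(float(depth[i]) for i in range(s, s + cfg.window))
            in_sum = 10.0 * cfg.window
            return ((ip_sum + 1) / ip.total_signal) / ((in_sum + 1) / inp.total_signal)

        starts = list(range(2100, 2900 - cfg.window + 1, cfg.step))
        best = max(starts, key=lambda s: (window_fe(s), -s))
        assert summit == best + cfg.window // 2

    def test_region_shorter_than_window_single_window(self):
        sizes = {"chr1": 10_000}
        depth = np.full(10_000, 10.0)
        depth[100:180] = 30.0
        ip = CoverageTrack({"chr1": depth}, sizes)
        inp = uniform_track(10, sizes)
        region = GenomicInterval("chr1", 100, 180)  # 80 bp < window 200
        strong, summit = strong_peak_scan(ip, inp, region, EnrichmentConfig())
        assert strong  # single window covering the region, FE ~3
        assert summit == 100 + 80 // 2

    def test_min_ip_depth_gate(self):
        depth = np.zeros(1000)
        depth[0:200] = 0.02  # window IP sum 4 < min_window_ip
        ip = CoverageTrack({"chr1": depth}, SIZES)
        inp = uniform_track(0.02, SIZES)
        cfg = EnrichmentConfig()
        region = GenomicInterval("chr1", 0, 200)
        # window FE = (5/4) / (5/20) = 5 clears the threshold ...
        assert brute_force_fe(ip, inp, 0, 200) >= cfg.thresholds[0]
        strong, _ = strong_peak_scan(ip, inp, region, cfg)
        assert not strong  # ... but the depth gate vetoes it


class TestEnrichRegions:
    def _spans(self):
        return [
            GenicSpan(GenomicInterval("chr1", 0, 200), ("a",)),
            GenicSpan(GenomicInterval("chr1", 300, 500), ("b",)),
            GenicSpan(GenomicInterval("chr1", 600, 800), ("c",)),
        ]

    def test_descending_order_and_filters(self):
        depth = np.full(1000, 10.0)
        depth[0:200] = 10.0  # FE 1
        depth[300:500] = 25.0  # FE 2.5
        depth[600:800] = 60.0  # FE 6
        ip = CoverageTrack({"chr1": depth}, SIZES)
        inp = uniform_track(10, SIZES)
        cfg = EnrichmentConfig(pseudocount=0)
        table = enrich_regions(ip, inp, self._spans(), cfg)
        # normalization: ip_total/input_total rescales; check the *order* and filters
        assert list(table["region_id"]) == ["c", "b", "a"]
        fes = dict(zip(table["region_id"], table["fold_enrichment"]))
        assert fes["c"] > fes["b"] > fes["a"]
        assert len(select_enriched(table, fes["b"])) == 2
        assert len(select_enriched(table, fes["c"])) == 1

    def test_fe_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        depth_ip = rng.integers(0, 60, 1000).astype(float)
        depth_in = rng.integers(1, 40, 1000).astype(float)
        ip = CoverageTrack({"chr1": depth_ip}, SIZES)
        inp = CoverageTrack({"chr1": depth_in}, SIZES)
        table = enrich_regions(ip, inp, self._spans(), EnrichmentConfig())
        for _, row in table.iterrows():
            expect = brute_force_fe(ip, inp, row["start"], row["end"])
            assert row["fold_enrichment"] == pytest.approx(expect, rel=1e-12)

    def test_ranking_is_permutation(self):
        rng = np.random.default_rng(10)
        ip = CoverageTrack({"chr1": rng.integers(0, 30, 1000).astype(float)}, SIZES)
        inp = uniform_track(10, SIZES)
        table = enrich_regions(ip, inp, self._spans())
        assert sorted(table["region_id"]) == ["a", "b", "c"]

    def test_empty_region_list(self):
        ip = uniform_track(1, SIZES)
        table = enrich_regions(ip, ip, [])
        assert len(table) == 0

    def test_low_input_flagged_not_dropped(self):
        depth_in = np.full(1000, 10.0)
        depth_in[0:200] = 0.1  # far below 0.1 * mean
        inp = CoverageTrack({"chr1": depth_in}, SIZES)
        ip = uniform_track(10, SIZES)
        table = enrich_regions(ip, inp, self._spans())
        flags = dict(zip(table["region_id"], table["low_input_flag"]))
        assert flags["a"] and not flags["b"] and not flags["c"]
        assert len(table) == 3


class TestBedgraphIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        depth = rng.integers(0, 5, 500).astype(float)
        t = CoverageTrack({"chr1": depth}, {"chr1": 500})
        p = tmp_path / "t.bedgraph"
        t.to_bedgraph(p)
        back = CoverageTrack.from_bedgraph(p, {"chr1": 500})
        assert np.array_equal(back.depth["chr1"], depth)

    def test_absent_chromosome_reads_as_zero(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t10\t2\n")
        t = CoverageTrack.from_bedgraph(p, {"chr1": 20, "chr2": 30})
        assert t.depth["chr2"].sum() == 0
        assert t.total_signal == 20


def test_bam_and_bed_interval_depth(tmp_path):
    """The alignment path and the interval emitter agree with hand pileup."""
    import pysam

    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100}]}
    sam = tmp_path / "toy.sam"
    with pysam.AlignmentFile(sam, "wh", header=header) as fh:
        for i, start in enumerate((0, 10, 10)):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"r{i}"
            a.query_sequence = "A" * 20
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = "20M"
            a.mapping_quality = 60
            fh.write(a)
    t = CoverageTrack.from_bam(sam, {"chr1": 100})
    expect = np.zeros(100)
    for start in (0, 10, 10):
        expect[start : start + 20] += 1
    assert np.array_equal(t.depth["chr1"], expect)

    bed = tmp_path / "toy.bed"
    bed.write_text("chr1\t0\t20\nchr1\t10\t30\nchr1\t10\t30\n")
    t2 = CoverageTrack.from_bed_intervals(bed, {"chr1": 100})
    expect2 = np.zeros(100)
    for s, e in ((0, 20), (10, 30), (10, 30)):
        expect2[s:e] += 1
    assert np.array_equal(t2.depth["chr1"], expect2)
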