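"""Per-region IP/INPUT fold enrichment from coverage tracks.

Fold enrichment of a region is the library-normalized ratio

    FE = ((ip_sum + c) / ip_total) / ((input_sum + c) / input_total)

where the sums are per-base depth totals over the region, the totals are the
whole-track depth sums (library-size proxies) and c is a pseudocount in depth
units (default 1). Regions are binned by configurable thresholds (default
2/4/6/8), flagged as carrying a "strong peak" when a sliding window inside the
region itself clears the first threshold with adequate IP depth, and ranked in
descending fold-enrichment order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from chipregions.annotation import (
    GenicSpan,
    GenomicInterval,
    IntergenicRegion,
    intergenic_region_id,
)


class TrackError(ValueError):
    pass


class CoverageTrack:
    """Per-base depth by chromosome, with the track total as library size.

    Chromosomes from ``chrom_sizes`` that carry no signal read as all-zero.
    """

    def __init__(self, depth: dict[str, np.ndarray], chrom_sizes: dict[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self.depth: dict[str, np.ndarray] = {}
        for chrom, size in self.chrom_sizes.items():
            arr = np.asarray(depth.get(chrom, np.zeros(size)), dtype=float)
            if arr.shape[0] != size:
                raise TrackError(
                    f"{chrom}: depth length {arr.shape[0]} != chromosome size {size}"
                )
            if (arr < 0).any():
                raise TrackError(f"{chrom}: negative depth values")
            self.depth[chrom] = arr
        for chrom in depth:
            if chrom not in self.chrom_sizes:
                raise TrackError(f"track chromosome {chrom!r} absent from chrom_sizes")
        self.total_signal = float(sum(a.sum() for a in self.depth.values()))

    # -- construction -----------------------------------------------------

    @classmethod
    def from_bedgraph(cls, path: Union[str, Path], chrom_sizes: dict[str, int]) -> "CoverageTrack":
        """4-column bedGraph (chrom, start, end, value; 0-based half-open)."""
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": int, "end": int, "value": float},
        )
        depth = {c: np.zeros(s) for c, s in chrom_sizes.items()}
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in depth:
                raise TrackError(f"bedGraph chromosome {chrom!r} absent from chrom_sizes")
            arr = depth[chrom]
            for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
                if end > arr.shape[0]:
                    raise TrackError(f"{chrom}:{start}-{end} beyond chromosome end")
                arr[start:end] += value
        return cls(depth, chrom_sizes)

    @classmethod
    def from_bam(
        cls,
        path: Union[str, Path],
        chrom_sizes: dict[str, int],
        extension: int = 0,
    ) -> "CoverageTrack":
        """Per-base depth of read-spanning bases from a coordinate-sorted BAM/SAM.

        ``extension`` > 0 extends each read to that fragment length in its 5'->3'
        direction before counting (0 = no extension).
        """
        import pysam

        depth = {c: np.zeros(s) for c, s in chrom_sizes.items()}
        with pysam.AlignmentFile(str(path)) as bam:
            for read in bam.fetch(until_eof=True):
                if read.is_unmapped or read.reference_name not in depth:
                    continue
                arr = depth[read.reference_name]
                start, end = read.reference_start, read.reference_end
                if extension > 0:
                    if read.is_reverse:
                        start = max(0, end - extension)
                    else:
                        end = min(arr.shape[0], start + extension)
                arr[start:end] += 1
        return cls(depth, chrom_sizes)

    @classmethod
    def from_bed_intervals(
        cls, path: Union[str, Path], chrom_sizes: dict[str, int]
    ) -> "CoverageTrack":
        """Depth-1 pileup of plain BED intervals (the read-interval emitter's format)."""
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={"chrom": str, "start": int, "end": int},
        )
        depth = {c: np.zeros(s) for c, s in chrom_sizes.items()}
        for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
            depth[chrom][start:end] += 1
        return cls(depth, chrom_sizes)

    def to_bedgraph(self, path: Union[str, Path]) -> None:
        """Run-length-encoded bedGraph; zero runs are omitted."""
        with open(path, "w") as fh:
            for chrom in sorted(self.depth):
                arr = self.depth[chrom]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    def mean_depth(self) -> float:
        genome = sum(self.chrom_sizes.values())
        return self.total_signal / genome if genome else 0.0


@dataclass(frozen=True)
class EnrichmentConfig:
    pseudocount: float = 1.0  # depth units per region
    thresholds: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    window: int = 200  # strong-peak window width (bp)
    step: int = 50
    min_window_ip: float = 5.0  # min IP depth sum within the best window
    low_input_fraction: float = 0.1  # of genome-mean input density
    cumulative_bins: bool = False  # label by >=t rather than half-open [t, next)

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly increasing")
        if not (self.window >= self.step >= 1):
            raise ValueError("require window >= step >= 1")


RegionLike = Union[GenicSpan, IntergenicRegion]


def region_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Sum of per-base depth over [start, end)."""
    if interval.chrom not in track.depth:
        raise TrackError(f"unknown chromosome {interval.chrom!r}")
    arr = track.depth[interval.chrom]
    if interval.start < 0 or interval.end > arr.shape[0]:
        raise TrackError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} off chromosome"
        )
    return float(arr[interval.start : interval.end].sum())


def fold_enrichment(
    ip_sum: float,
    ip_total: float,
    input_sum: float,
    input_total: float,
    pseudocount: float = 1.0,
) -> float:
    """Library-normalized IP/INPUT ratio with a shared pseudocount."""
    if min(ip_sum, input_sum) < 0 or ip_total <= 0 or input_total <= 0 or pseudocount < 0:
        raise ValueError("sums must be >= 0, totals > 0, pseudocount >= 0")
    num = (ip_sum + pseudocount) / ip_total
    den = (input_sum + pseudocount) / input_total
    if den == 0.0:
        return math.inf
    return num / den


def bin_label(fe: float, config: EnrichmentConfig) -> str:
    """Threshold bin for a fold enrichment value.

    Default half-open bins: ``<2``, ``2-4``, ``4-6``, ``6-8``, ``>=8``;
    with ``cumulative_bins`` every bin at or below FE applies and the label is
    the highest cleared threshold (``>=t``).
    """
    ts = list(config.thresholds)
    if fe < ts[0]:
        return f"<{ts[0]:g}"
    if config.cumulative_bins:
        top = max(t for t in ts if fe >= t)
        return f">={top:g}"
    for lo, hi in zip(ts, ts[1:]):
        if lo <= fe < hi:
            return f"{lo:g}-{hi:g}"
    return f">={ts[-1]:g}"


def ordered_bin_labels(config: EnrichmentConfig) -> list[str]:
    """Bin labels from weakest to strongest enrichment (excluding the sub-threshold bin)."""
    ts = list(config.thresholds)
    if config.cumulative_bins:
        return [f">={t:g}" for t in ts]
    return [f"{lo:g}-{hi:g}" for lo, hi in zip(ts, ts[1:])] + [f">={ts[-1]:g}"]


def strong_peak_scan(
    ip_track: CoverageTrack,
    input_track: CoverageTrack,
    interval: GenomicInterval,
    config: EnrichmentConfig,
) -> tuple[bool, Optional[int]]:
    """Sliding-window peak test inside one region.

    Windows of ``config.window`` bp advance by ``config.step``; each window's
    fold enrichment uses the same normalized-ratio formula with the configured
    pseudocount. The region carries a strong peak when the best window clears
    the first bin threshold AND holds at least ``min_window_ip`` IP depth. The
    summit is the center of the best window (ties -> leftmost). Regions shorter
    than the window collapse to a single window covering the region.
    """
    ip = ip_track.depth[interval.chrom][interval.start : interval.end]
    inp = input_track.depth[interval.chrom][interval.start : interval.end]
    n = interval.length
    w = min(config.window, n)
    starts = list(range(0, max(n - w, 0) + 1, config.step))
    if starts[-1] != n - w:  # keep the right edge covered
        starts.append(n - w)

    ip_cum = np.concatenate(([0.0], np.cumsum(ip)))
    inp_cum = np.concatenate(([0.0], np.cumsum(inp)))
    best_fe, best_start, best_ip = -math.inf, 0, 0.0
    for s in starts:
        ip_sum = float(ip_cum[s + w] - ip_cum[s])
        inp_sum = float(inp_cum[s + w] - inp_cum[s])
        fe = fold_enrichment(
            ip_sum, ip_track.total_signal, inp_sum, input_track.total_signal,
            config.pseudocount,
        )
        if fe > best_fe:
            best_fe, best_start, best_ip = fe, s, ip_sum
    strong = best_fe >= config.thresholds[0] and best_ip >= config.min_window_ip
    summit = interval.start + best_start + w // 2
    return strong, summit


def _region_fields(region: RegionLike) -> tuple[str, str, GenomicInterval]:
    if isinstance(region, IntergenicRegion):
        return intergenic_region_id(region), "INTERGENIC", region.interval
    return region.region_id, "ORF", region.interval


def enrich_regions(
    ip_track: CoverageTrack,
    input_track: CoverageTrack,
    regions: Sequence[RegionLike],
    config: Optional[EnrichmentConfig] = None,
) -> pd.DataFrame:
    """Rank all regions by IP/INPUT fold enrichment (descending).

    Returns one row per region with columns: region_id, chrom, start, end
    (0-based half-open), region_type, ip_sum, input_sum, fold_enrichment, bin,
    strong_peak, summit, low_input_flag. Ties in fold enrichment break
    lexicographically on region_id.
    """
    config = config or EnrichmentConfig()
    mean_input_density = input_track.mean_depth()
    rows = []
    for region in regions:
        region_id, region_type, iv = _region_fields(region)
        ip_sum = region_signal(ip_track, iv)
        input_sum = region_signal(input_track, iv)
        fe = fold_enrichment(
            ip_sum, ip_track.total_signal, input_sum, input_track.total_signal,
            config.pseudocount,
        )
        strong, summit = strong_peak_scan(ip_track, input_track, iv, config)
        low_input = (input_sum / iv.length) < config.low_input_fraction * mean_input_density
        rows.append(
            {
                "region_id": region_id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "region_type": region_type,
                "ip_sum": ip_sum,
                "input_sum": input_sum,
                "fold_enrichment": fe,
                "bin": bin_label(fe, config),
                "strong_peak": strong,
                "summit": summit,
                "low_input_flag": low_input,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "region_id", "chrom", "start", "end", "region_type", "ip_sum",
            "input_sum", "fold_enrichment", "bin", "strong_peak", "summit",
            "low_input_flag",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["fold_enrichment", "region_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df


def select_enriched(
    table: pd.DataFrame, min_fe: float = 2.0, strong_only: bool = False
) -> pd.DataFrame:
    """Filter helper mirroring the 'all >= t' and '>= t with strong peaks' lists."""
    mask = table["fold_enrichment"] >= min_fe
    if strong_only:
        mask &= table["strong_peak"]
    return table.loc[mask].reset_index(drop=True)


def write_enrichment_report(
    table: pd.DataFrame, path: Union[str, Path], config: Optional[EnrichmentConfig] = None
) -> None:
    """Report TSV with 1-based inclusive coordinates and a parameter header."""
    out = table.copy()
    out["start"] = out["start"] + 1
    with open(path, "w") as fh:
        if config is not None:
            fh.write(
                f"# pseudocount={config.pseudocount} thresholds={list(config.thresholds)} "
                f"window={config.window} step={config.step} "
                f"min_window_ip={config.min_window_ip} "
                f"low_input_fraction={config.low_input_fraction}\n"
            )
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_enrichment_report(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["start"] = df["start"] - 1
    return df
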