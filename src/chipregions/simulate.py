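"""Synthetic data generator with truth files for every pipeline stage.

The generator emits a gene-dense two-chromosome annotation containing every
flanking-orientation configuration (tandem both ways, divergent, convergent),
an expression table with planted quantile tiers, IP/input coverage tracks with
Poisson (optionally negative-binomial) per-base noise and planted region-level
enrichments, a ChIP-qPCR measurement table generated from a log-linear
standard curve, and peptide-array replicate intensities — plus truth tables
tying every planted quantity to its region/target/spot.

Planted fold enrichments are *region-level* truths: because fold enrichment is
computed on library-size-normalized densities, enrichment planted anywhere in
the genome deflates the apparent enrichment everywhere else. The generator
compensates analytically — profiles are scaled by

    s = (G - sum(L_i)) / (G - sum(t_i * L_i))

(G genome size, L_i planted region lengths, t_i target fold enrichments) so
that the normalized ratio the enrichment module measures equals the planted
truth in expectation. Genic enrichment is a plateau over the gene body;
intergenic enrichment is a triangular bump (400 bp base) at the planted
summit, scaled so the region mean hits the target.

Everything is driven by one integer seed; a fixed seed yields byte-identical
output files.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from chipregions.annotation import (
    GeneModel,
    GenomicInterval,
    write_chrom_sizes,
    write_genes,
)
from chipregions.classify import IntergenicClass
from chipregions.enrichment import CoverageTrack

DEFAULT_CLASS_COUNTS: dict[str, int] = {
    IntergenicClass.PROMOTER_SINGLE.value: 10,
    IntergenicClass.TERMINATOR_SINGLE.value: 5,
    IntergenicClass.BIDIRECTIONAL_PROMOTER.value: 3,
    IntergenicClass.SHARED_TERMINATOR.value: 3,
    IntergenicClass.PROMOTER_TERMINATOR_OVERLAP.value: 2,
}

# flank strands (left, right) per planted class; summits near 'left'/'right'
# boundary for the single-gene classes, centered otherwise
_CLASS_GEOMETRY = {
    "PROMOTER_SINGLE": ("+", "+", "right", "long"),
    "TERMINATOR_SINGLE": ("+", "+", "left", "long"),
    "BIDIRECTIONAL_PROMOTER": ("-", "+", "center", "short"),
    "SHARED_TERMINATOR": ("+", "-", "center", "short"),
    "PROMOTER_TERMINATOR_OVERLAP": ("+", "+", "center", "short"),
}

# default peptide-array layout: top binder affinities shaped like a Kac-reader
# profile (acetyl-marked H3/H2A/H4 peptides high, methyl/unmodified low)
DEFAULT_ARRAY_SPOTS: list[tuple[str, str, str, float]] = [
    ("pep01", "H3", "K9ac;K14ac", 0.95),
    ("pep02", "H2A", "K5ac;K9ac;K13ac", 0.92),
    ("pep03", "H4", "R3me2s;K5ac;K8ac;K12ac", 0.90),
    ("pep04", "H4", "K5ac;K8ac;K12ac;K16ac", 0.89),
    ("pep05", "H3", "K9me3;K14ac", 0.88),
    ("pep06", "H3", "S10P;K14ac", 0.88),
    ("pep07", "H4", "K5ac;K8ac;K12ac", 0.84),
    ("pep08", "H3", "T11P;K14ac", 0.82),
    ("pep09", "H2A", "S1P;K5ac;K9ac;K13ac", 0.82),
    ("pep10", "H2A", "S1P;K9ac;K13ac", 0.81),
    ("pep11", "H3", "K4me3", 0.12),
    ("pep12", "H3", "K9me2", 0.08),
    ("pep13", "H3", "K27me3", 0.05),
    ("pep14", "H4", "K20me3", 0.04),
    ("pep15", "H3", "R2me2a", 0.06),
    ("pep16", "H2B", "K5ac", 0.30),
    ("pep17", "H3", "K14ac", 0.70),
    ("pep18", "H3", "K9ac", 0.66),
    ("pep19", "H4", "K16ac", 0.35),
    ("pep20", "H3", "K36me3", 0.07),
]

# qPCR targets: (name, true fold enrichment of tagged over untagged)
DEFAULT_QPCR_TARGETS: list[tuple[str, float]] = [
    ("HTA3", 12.75),
    ("RPS22", 9.50),
    ("HFF1", 9.38),
    ("PDD1", 1.00),
]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 200
    n_chroms: int = 2
    gene_len_median: float = 1500.0  # bp, log-normal
    gene_len_sigma: float = 0.4
    gap_median: float = 400.0  # bp, log-normal (unplanted internal gaps)
    gap_sigma: float = 0.5
    edge_margin: int = 500_000  # gene-free bp at each chromosome end
    q_high: float = 0.09
    q_mod: float = 0.29
    no_data_fraction: float = 0.0  # genes absent from the expression table
    rho: float = 0.8  # occupancy-expression correlation in [0, 1]
    n_occupied_genes: int = 40
    fe_range: tuple[float, float] = (2.0, 13.0)  # planted genic FE
    intergenic_fe_range: tuple[float, float] = (4.0, 13.0)  # classified set is >=4x
    planted_class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    lambda_input: float = 30.0  # base input depth per bp
    overdispersion: Optional[float] = None  # NB shape; None = pure Poisson
    d_max: int = 300  # classifier convention the planted geometry respects
    bump_width: int = 400  # triangular intergenic profile base (bp)
    qpcr_intercept: float = 26.64  # Cq at 1% input
    qpcr_slope: float = -3.32  # Cq per log10(percent)
    qpcr_sigma: float = 0.15  # Cq noise sd
    qpcr_untagged_percent: float = 0.5  # true % input in untagged cells
    qpcr_n_tagged: int = 4
    qpcr_n_untagged: int = 3
    array_noise_sd: float = 0.02
    array_n_reps: int = 4

    @property
    def both_flank_len(self) -> int:
        return 2 * self.d_max

    @property
    def short_gap(self) -> int:
        return self.both_flank_len

    @property
    def long_gap(self) -> int:
        return self.both_flank_len + 2 * self.d_max + 200

    @property
    def summit_offset(self) -> int:
        # summit distance from the addressed boundary in long (single-flank) gaps
        return self.d_max // 3


@dataclass
class GenomeSim:
    """In-memory synthetic genome bundle with its truth tables."""

    config: SimulationConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    expression: pd.DataFrame  # gene_id, value (planted tiers recoverable by rank)
    truth_genes: pd.DataFrame  # gene_id, tier, occupied, true_fe
    truth_intergenic: pd.DataFrame  # region_id, chrom, start, end, class, summit, true_fe


def _validate(config: SimulationConfig) -> None:
    n_planted = sum(config.planted_class_counts.values())
    per_chrom = config.n_genes // config.n_chroms
    n_gaps = config.n_chroms * (per_chrom - 1)
    if 3 * n_planted > n_gaps:
        raise ValueError(
            f"{n_planted} planted intergenic classes need {3 * n_planted} gap slots, "
            f"only {n_gaps} available with n_genes={config.n_genes}"
        )
    unknown = set(config.planted_class_counts) - {c.value for c in IntergenicClass}
    if unknown:
        raise ValueError(f"unknown planted classes: {sorted(unknown)}")
    if config.n_occupied_genes > config.n_genes:
        raise ValueError("cannot occupy more genes than exist")


def simulate_genome(config: SimulationConfig) -> GenomeSim:
    """Generate annotation, expression and planted-enrichment truth.

    Planted intergenic classes occupy every third internal gap so no gene
    flanks two planted gaps; flank strands and gap lengths are set per class
    and the remaining strands are random. Expression tiers are planted by
    drawing values from disjoint ranges (HIGH 1e3-1e4, MODERATE 1e2-1e3,
    LOW_NO 1-1e2) so rank-based tiering recovers them exactly. Occupied genes
    are sampled with tier-dependent weights controlled by ``rho`` and their
    planted fold enrichment increases with tier, again scaled by ``rho``.
    """
    _validate(config)
    rng = np.random.default_rng(config.seed)

    per_chrom = config.n_genes // config.n_chroms
    counts = [per_chrom] * config.n_chroms
    counts[-1] += config.n_genes - per_chrom * config.n_chroms

    # planted classes -> global gap slot list (every 3rd internal gap)
    planted_classes: list[str] = []
    for cls, k in sorted(config.planted_class_counts.items()):
        planted_classes.extend([cls] * k)
    rng.shuffle(planted_classes)

    gene_rows: list[dict] = []
    chrom_sizes: dict[str, int] = {}
    ig_rows: list[dict] = []
    planted_iter = iter(planted_classes)
    slot_countdown = 0  # spacing counter
    gid = 0
    mu_gene = math.log(config.gene_len_median)
    mu_gap = math.log(config.gap_median)

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        m = counts[ci]
        lengths = np.maximum(
            rng.lognormal(mu_gene, config.gene_len_sigma, size=m).astype(int), 200
        )
        gaps = np.maximum(
            rng.lognormal(mu_gap, config.gap_sigma, size=max(m - 1, 0)).astype(int), 50
        )
        strands = rng.choice(["+", "-"], size=m)
        gap_class: list[Optional[str]] = [None] * max(m - 1, 0)
        for j in range(m - 1):
            if slot_countdown > 0:
                slot_countdown -= 1
                continue
            cls = next(planted_iter, None)
            if cls is None:
                break
            gap_class[j] = cls
            left_strand, right_strand, where, size_kind = _CLASS_GEOMETRY[cls]
            strands[j] = left_strand
            strands[j + 1] = right_strand
            gaps[j] = config.short_gap if size_kind == "short" else config.long_gap
            slot_countdown = 2  # leave two unplanted gaps before the next

        pos = config.edge_margin
        for j in range(m):
            start, end = pos, pos + int(lengths[j])
            gene_rows.append(
                {
                    "gene_id": f"g{gid:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": str(strands[j]),
                }
            )
            gid += 1
            pos = end
            if j < m - 1:
                gap_start, gap_end = pos, pos + int(gaps[j])
                if gap_class[j] is not None:
                    cls = gap_class[j]
                    _, _, where, _ = _CLASS_GEOMETRY[cls]
                    if where == "left":
                        summit = gap_start + config.summit_offset
                    elif where == "right":
                        summit = gap_end - config.summit_offset
                    else:
                        summit = (gap_start + gap_end) // 2
                    ig_rows.append(
                        {
                            "region_id": f"IG:{chrom}:{gap_start + 1}-{gap_end}",
                            "chrom": chrom,
                            "start": gap_start,
                            "end": gap_end,
                            "class": cls,
                            "summit": summit,
                            "true_fe": float(
                                rng.uniform(*config.intergenic_fe_range)
                            ),
                        }
                    )
                pos = gap_end
        chrom_sizes[chrom] = pos + config.edge_margin

    if next(planted_iter, None) is not None:
        raise ValueError("ran out of gap slots for planted classes")  # pragma: no cover

    genes = [GeneModel(**r) for r in gene_rows]
    gdf = pd.DataFrame(gene_rows)

    # --- expression tiers (planted by value range, recovered by rank) -----
    n = config.n_genes
    n_nodata = int(round(config.no_data_fraction * n))
    n_data = n - n_nodata
    n_high = math.ceil(config.q_high * n_data)
    n_mod = math.ceil(config.q_mod * n_data)
    order = rng.permutation(n)
    tier = np.full(n, "LOW_NO", dtype=object)
    tier[order[:n_high]] = "HIGH"
    tier[order[n_high : n_high + n_mod]] = "MODERATE"
    tier[order[n_data:]] = "NO_DATA"
    value = np.empty(n)
    value[tier == "HIGH"] = 10 ** rng.uniform(3, 4, size=(tier == "HIGH").sum())
    value[tier == "MODERATE"] = 10 ** rng.uniform(2, 3, size=(tier == "MODERATE").sum())
    value[tier == "LOW_NO"] = 10 ** rng.uniform(0, 2, size=(tier == "LOW_NO").sum())
    value[tier == "NO_DATA"] = np.nan

    expression = pd.DataFrame(
        {"gene_id": gdf["gene_id"], "value": value}
    ).dropna().reset_index(drop=True)

    # --- occupancy: tier-weighted sampling, FE increasing with tier -------
    tier_pref = {"HIGH": 1.0, "MODERATE": 0.4, "LOW_NO": 0.05, "NO_DATA": 0.05}
    tier_level = {"HIGH": 0.85, "MODERATE": 0.45, "LOW_NO": 0.12, "NO_DATA": 0.12}
    w = np.array([(1 - config.rho) + config.rho * tier_pref[t] for t in tier])
    occupied_idx = rng.choice(
        n, size=config.n_occupied_genes, replace=False, p=w / w.sum()
    )
    occupied = np.zeros(n, dtype=bool)
    occupied[occupied_idx] = True
    fe_lo, fe_hi = config.fe_range
    beta = np.clip(
        config.rho * np.array([tier_level[t] for t in tier])
        + (1 - config.rho) * rng.uniform(0, 1, size=n)
        + 0.03 * rng.normal(size=n),
        0.05,
        1.0,
    )
    true_fe = np.where(occupied, fe_lo + (fe_hi - fe_lo) * beta, np.nan)

    truth_genes = pd.DataFrame(
        {
            "gene_id": gdf["gene_id"],
            "chrom": gdf["chrom"],
            "start": gdf["start"],
            "end": gdf["end"],
            "tier": tier,
            "occupied": occupied,
            "true_fe": true_fe,
        }
    )
    truth_intergenic = pd.DataFrame(
        ig_rows,
        columns=["region_id", "chrom", "start", "end", "class", "summit", "true_fe"],
    )
    return GenomeSim(
        config=config,
        genes=genes,
        chrom_sizes=chrom_sizes,
        expression=expression,
        truth_genes=truth_genes,
        truth_intergenic=truth_intergenic,
    )


def _enrichment_profile(sim: GenomeSim) -> dict[str, np.ndarray]:
    """Relative IP rate f(x) per chromosome, scaled for library normalization."""
    config = sim.config
    G = sum(sim.chrom_sizes.values())

    planted: list[tuple[float, int]] = []  # (target FE, length)
    occ = sim.truth_genes[sim.truth_genes["occupied"]]
    for _, r in occ.iterrows():
        planted.append((r["true_fe"], int(r["end"] - r["start"])))
    for _, r in sim.truth_intergenic.iterrows():
        planted.append((r["true_fe"], int(r["end"] - r["start"])))

    sum_l = sum(l for _, l in planted)
    sum_tl = sum(t * l for t, l in planted)
    if sum_tl >= G:
        raise ValueError(
            f"planted enrichment mass ({sum_tl:.3g}) exceeds genome size ({G}); "
            "reduce planted regions/FEs or enlarge the genome"
        )
    s = (G - sum_l) / (G - sum_tl)

    f = {c: np.ones(size) for c, size in sim.chrom_sizes.items()}
    for _, r in occ.iterrows():
        f[r["chrom"]][int(r["start"]) : int(r["end"])] = r["true_fe"] * s
    half = config.bump_width / 2.0
    for _, r in sim.truth_intergenic.iterrows():
        arr = f[r["chrom"]]
        start, end, summit = int(r["start"]), int(r["end"]), int(r["summit"])
        x = np.arange(start, end)
        tri = np.clip(1.0 - np.abs(x - summit) / half, 0.0, None)
        area = tri.sum()
        L = end - start
        height = (r["true_fe"] * s - 1.0) * L / area
        arr[start:end] = 1.0 + height * tri
    return f


def simulate_tracks(
    sim: GenomeSim, seed_offset: int = 1
) -> tuple[CoverageTrack, CoverageTrack]:
    """Draw IP and input coverage with per-base Poisson (or NB) noise.

    Input depth ~ Poisson(lambda); IP depth ~ Poisson(lambda * f(x)) with the
    planted, normalization-compensated profile f. With ``overdispersion`` r
    set, depth ~ NB with that shape (gamma-mixed Poisson).
    """
    config = sim.config
    rng = np.random.default_rng((config.seed, seed_offset))
    f = _enrichment_profile(sim)
    lam = config.lambda_input

    def draw(mean: np.ndarray) -> np.ndarray:
        if config.overdispersion is None:
            return rng.poisson(mean).astype(float)
        r = config.overdispersion
        return rng.poisson(rng.gamma(r, mean / r)).astype(float)

    input_depth = {c: draw(np.full(size, lam)) for c, size in sim.chrom_sizes.items()}
    ip_depth = {c: draw(lam * f[c]) for c in sim.chrom_sizes}
    return (
        CoverageTrack(ip_depth, sim.chrom_sizes),
        CoverageTrack(input_depth, sim.chrom_sizes),
    )


def simulate_read_intervals(
    sim: GenomeSim, read_len: int = 50, seed_offset: int = 2
) -> pd.DataFrame:
    """Read-shaped BED intervals whose pileup approximates the IP profile.

    Exercises the alignment-input path without an aligner: read starts are
    sampled proportionally to the planted IP rate at expected depth
    ``lambda_input``.
    """
    config = sim.config
    rng = np.random.default_rng((config.seed, seed_offset))
    f = _enrichment_profile(sim)
    rows = []
    for chrom, size in sim.chrom_sizes.items():
        weights = f[chrom]
        n_reads = int(config.lambda_input * size / read_len)
        starts = rng.choice(size, size=n_reads, p=weights / weights.sum())
        starts.sort()
        for s in starts:
            rows.append((chrom, int(s), min(int(s) + read_len, size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# qPCR and peptide array
# ---------------------------------------------------------------------------


def simulate_qpcr(
    config: SimulationConfig,
    targets: Optional[Sequence[tuple[str, float]]] = None,
    seed_offset: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR measurement table from a log-linear standard curve.

    Per target: a 100/10/1% input-dilution series plus tagged and untagged IP
    replicates. True percent input is ``qpcr_untagged_percent`` for untagged
    cells and fold * that for tagged; Cq = a + b*log10(percent) + N(0, sigma).
    Returns (measurements, truth) with truth carrying true percents per group.
    """
    rng = np.random.default_rng((config.seed, seed_offset))
    targets = list(targets if targets is not None else DEFAULT_QPCR_TARGETS)
    a, b, sigma = config.qpcr_intercept, config.qpcr_slope, config.qpcr_sigma

    def cq(percent: float) -> float:
        return a + b * math.log10(percent) + float(rng.normal(0.0, sigma))

    rows, truth_rows = [], []
    for name, fold in targets:
        for pct in (100.0, 10.0, 1.0):
            rows.append(
                {"target": name, "group": "input-dilution", "replicate": f"d{pct:g}",
                 "cq": cq(pct), "percent": pct}
            )
        p_untagged = config.qpcr_untagged_percent
        p_tagged = fold * p_untagged
        for i in range(config.qpcr_n_tagged):
            rows.append(
                {"target": name, "group": "tagged", "replicate": f"t{i + 1}",
                 "cq": cq(p_tagged), "percent": np.nan}
            )
        for i in range(config.qpcr_n_untagged):
            rows.append(
                {"target": name, "group": "untagged", "replicate": f"u{i + 1}",
                 "cq": cq(p_untagged), "percent": np.nan}
            )
        truth_rows.append(
            {"target": name, "true_fold": fold, "true_percent_tagged": p_tagged,
             "true_percent_untagged": p_untagged}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_array(
    config: SimulationConfig,
    spots: Optional[Sequence[tuple[str, str, str, float]]] = None,
    seed_offset: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide-array replicate intensities: affinity + N(0, sd), clipped to [0, 1]."""
    rng = np.random.default_rng((config.seed, seed_offset))
    spots = list(spots if spots is not None else DEFAULT_ARRAY_SPOTS)
    rows, truth_rows = [], []
    for pid, histone, mods, affinity in spots:
        reps = np.clip(
            affinity + rng.normal(0.0, config.array_noise_sd, size=config.array_n_reps),
            0.0,
            1.0,
        )
        row = {"peptide_id": pid, "histone": histone, "modifications": mods}
        row.update({f"rep{i + 1}": float(v) for i, v in enumerate(reps)})
        rows.append(row)
        truth_rows.append({"peptide_id": pid, "true_affinity": affinity})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# bundle + files
# ---------------------------------------------------------------------------


@dataclass
class SimBundle:
    genome: GenomeSim
    ip: CoverageTrack
    input: CoverageTrack
    qpcr: pd.DataFrame
    qpcr_truth: pd.DataFrame
    array: pd.DataFrame
    array_truth: pd.DataFrame


def simulate_bundle(config: Optional[SimulationConfig] = None) -> SimBundle:
    """Generate the full synthetic study in memory."""
    config = config or SimulationConfig()
    genome = simulate_genome(config)
    ip, inp = simulate_tracks(genome)
    qpcr, qpcr_truth = simulate_qpcr(config)
    array, array_truth = simulate_array(config)
    return SimBundle(genome, ip, inp, qpcr, qpcr_truth, array, array_truth)


def write_bundle(bundle: SimBundle, outdir: Union[str, Path], tracks: bool = True) -> dict[str, Path]:
    """Write every input format the pipeline reads, plus truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = bundle.genome
    paths = {
        "annotation": outdir / "genes.gff3",
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "expression": outdir / "expression.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "array": outdir / "array.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_intergenic": outdir / "truth_intergenic.tsv",
        "qpcr_truth": outdir / "truth_qpcr.tsv",
        "array_truth": outdir / "truth_array.tsv",
    }
    write_genes(g.genes, paths["annotation"], fmt="gff3")
    write_chrom_sizes(g.chrom_sizes, paths["chrom_sizes"])
    g.expression.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6f")
    bundle.qpcr.to_csv(paths["qpcr"], sep="\t", index=False, float_format="%.6f")
    bundle.array.to_csv(paths["array"], sep="\t", index=False, float_format="%.6f")
    g.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False, float_format="%.6f")
    g.truth_intergenic.to_csv(
        paths["truth_intergenic"], sep="\t", index=False, float_format="%.6f"
    )
    bundle.qpcr_truth.to_csv(paths["qpcr_truth"], sep="\t", index=False, float_format="%.6f")
    bundle.array_truth.to_csv(paths["array_truth"], sep="\t", index=False, float_format="%.6f")
    if tracks:
        paths["ip"] = outdir / "ip.bedgraph"
        paths["input"] = outdir / "input.bedgraph"
        bundle.ip.to_bedgraph(paths["ip"])
        bundle.input.to_bedgraph(paths["input"])
    return paths


def file_checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
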