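"""Whole-pipeline orchestration: partition -> enrich -> crosstab -> classify.

``run_occupancy`` chains every stage over file inputs and writes the report
bundle: partition table, descending-ranked enrichment tables for ORFs and
intergenic regions (the "all >= 2x" analogs), strong-peak-filtered tables,
the expression-tier crosstab and per-bin trend, intergenic class assignments
with summary counts, the combined promoter+ORF / ORF+terminator lists,
optional over-representation results, and a manifest recording every
parameter and input checksum. Reports are deterministic: identical inputs and
configuration give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from chipregions import __version__
from chipregions.annotation import (
    read_chrom_sizes,
    read_genes,
    partition_genome,
    write_partition_report,
)
from chipregions.assays import analyze_qpcr, read_qpcr_table, write_qpcr_report
from chipregions.classify import (
    ClassifierConfig,
    classify_all,
    combine_orf_flanks,
    write_class_report,
)
from chipregions.enrichment import (
    CoverageTrack,
    EnrichmentConfig,
    enrich_regions,
    ordered_bin_labels,
    select_enriched,
    write_enrichment_report,
)
from chipregions.expression import (
    assign_tiers,
    crosstab_occupancy,
    read_expression_table,
    tier_trend_by_bin,
    write_crosstab,
)
from chipregions.ora import overrepresentation, read_term_map, write_ora_report
from chipregions.simulate import file_checksum

logger = logging.getLogger("chipregions")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    annotation: Union[str, Path]
    chrom_sizes: Union[str, Path]
    ip: Union[str, Path]
    input: Union[str, Path]
    outdir: Union[str, Path]
    expression: Optional[Union[str, Path]] = None
    term_map: Optional[Union[str, Path]] = None
    qpcr: Optional[Union[str, Path]] = None
    feature_type: str = "gene"
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    q_high: float = 0.09
    q_mod: float = 0.29
    report_threshold: float = 2.0  # the "all >= t" lists
    classify_threshold: float = 2.0  # intergenic regions sent to the classifier
    crosstab_threshold: float = 2.0  # ORFs counted as occupied
    ora_threshold: float = 4.0  # gene set for over-representation

    def to_manifest(self) -> dict:
        d = {
            "version": __version__,
            "feature_type": self.feature_type,
            "q_high": self.q_high,
            "q_mod": self.q_mod,
            "report_threshold": self.report_threshold,
            "classify_threshold": self.classify_threshold,
            "crosstab_threshold": self.crosstab_threshold,
            "ora_threshold": self.ora_threshold,
            "enrichment": {
                "pseudocount": self.enrichment.pseudocount,
                "thresholds": list(self.enrichment.thresholds),
                "window": self.enrichment.window,
                "step": self.enrichment.step,
                "min_window_ip": self.enrichment.min_window_ip,
                "low_input_fraction": self.enrichment.low_input_fraction,
                "cumulative_bins": self.enrichment.cumulative_bins,
            },
            "classifier": {
                "d_max": self.classifier.d_max,
                "both_flank_len": self.classifier.both_flank_len,
            },
            "inputs": {},
        }
        for key in ("annotation", "chrom_sizes", "ip", "input", "expression",
                    "term_map", "qpcr"):
            path = getattr(self, key)
            if path is not None:
                d["inputs"][key] = {
                    "path": str(path),
                    "sha256": file_checksum(path),
                }
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def run_occupancy(config: PipelineConfig) -> dict[str, Path]:
    """Run the full occupancy analysis; returns the report-name -> path map."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    # partition ----------------------------------------------------------
    @_stage("partition")
    def _partition():
        sizes = read_chrom_sizes(config.chrom_sizes)
        genes = read_genes(config.annotation, config.feature_type, chrom_sizes=sizes)
        genic, intergenic = partition_genome(genes, sizes)
        logger.info("partition: %d genic spans, %d intergenic regions",
                    len(genic), len(intergenic))
        return sizes, genes, genic, intergenic

    sizes, genes, genic, intergenic = _partition()
    out["partition"] = outdir / "partition.tsv"
    write_partition_report(genic, intergenic, out["partition"],
                           header_comment=f"chipregions {__version__}")

    # enrichment ---------------------------------------------------------
    @_stage("enrich")
    def _enrich():
        ip = CoverageTrack.from_bedgraph(config.ip, sizes)
        inp = CoverageTrack.from_bedgraph(config.input, sizes)
        return enrich_regions(ip, inp, list(genic) + list(intergenic), config.enrichment)

    table = _enrich()
    orf_table = table[table["region_type"] == "ORF"].reset_index(drop=True)
    ig_table = table[table["region_type"] == "INTERGENIC"].reset_index(drop=True)
    t = config.report_threshold
    for name, sub in (
        ("enrichment_orf_all", select_enriched(orf_table, t)),
        ("enrichment_intergenic_all", select_enriched(ig_table, t)),
        ("enrichment_orf_strong", select_enriched(orf_table, t, strong_only=True)),
        ("enrichment_intergenic_strong", select_enriched(ig_table, t, strong_only=True)),
    ):
        out[name] = outdir / f"{name}.tsv"
        write_enrichment_report(sub, out[name], config.enrichment)

    # expression tiers ---------------------------------------------------
    gene_ids = [g.gene_id for g in genes]
    tiers = None
    if config.expression is not None:
        @_stage("crosstab")
        def _crosstab():
            expr = read_expression_table(config.expression)
            tiers = assign_tiers(expr, universe=gene_ids,
                                 q_high=config.q_high, q_mod=config.q_mod)
            occupied = _enriched_gene_ids(orf_table, config.crosstab_threshold)
            ct = crosstab_occupancy(occupied, tiers, gene_ids)
            trend, monotone = tier_trend_by_bin(
                select_enriched(orf_table, config.enrichment.thresholds[0]),
                tiers, ordered_bin_labels(config.enrichment),
            )
            return tiers, ct, trend, monotone

        tiers, ct, trend, monotone = _crosstab()
        out["tiers"] = outdir / "tiers.tsv"
        tiers.to_csv(out["tiers"], sep="\t", index=False, float_format="%.6g")
        out["crosstab"] = outdir / "crosstab.tsv"
        write_crosstab(ct, out["crosstab"])
        out["tier_trend"] = outdir / "tier_trend.tsv"
        with open(out["tier_trend"], "w") as fh:
            fh.write(f"# high_fraction_monotone={monotone}\n")
            trend.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    else:
        logger.warning("no expression table: tier reports skipped")

    # intergenic classification -----------------------------------------
    @_stage("classify")
    def _classify():
        enriched_ig = select_enriched(ig_table, config.classify_threshold)
        return classify_all(enriched_ig, intergenic, config.classifier)

    assignments, counts = _classify()
    out["intergenic_classes"] = outdir / "intergenic_classes.tsv"
    write_class_report(assignments, counts, out["intergenic_classes"], config.classifier)
    out["intergenic_classes_summary"] = outdir / "intergenic_classes.summary.tsv"

    # combined ORF + flank categories ------------------------------------
    @_stage("combine")
    def _combine():
        occupied = _enriched_gene_ids(orf_table, config.classify_threshold)
        return combine_orf_flanks(occupied, assignments)

    promoter_orf, orf_terminator = _combine()
    out["combined_categories"] = outdir / "combined_categories.tsv"
    with open(out["combined_categories"], "w") as fh:
        fh.write("category\tgene_id\n")
        for g in sorted(promoter_orf):
            fh.write(f"PROMOTER_PLUS_ORF\t{g}\n")
        for g in sorted(orf_terminator):
            fh.write(f"ORF_PLUS_TERMINATOR\t{g}\n")

    # over-representation -------------------------------------------------
    if config.term_map is not None:
        @_stage("ora")
        def _ora():
            term_map = read_term_map(config.term_map)
            gene_set = _enriched_gene_ids(orf_table, config.ora_threshold)
            return overrepresentation(gene_set, gene_ids, term_map, q_threshold=None)

        out["ora"] = outdir / "ora.tsv"
        write_ora_report(_ora(), out["ora"])

    # qPCR ----------------------------------------------------------------
    if config.qpcr is not None:
        @_stage("qpcr")
        def _qpcr():
            _, results, _ = analyze_qpcr(read_qpcr_table(config.qpcr))
            return results

        out["qpcr"] = outdir / "qpcr_results.tsv"
        write_qpcr_report(_qpcr(), out["qpcr"])

    # manifest ------------------------------------------------------------
    out["manifest"] = outdir / "manifest.json"
    with open(out["manifest"], "w") as fh:
        json.dump(config.to_manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _enriched_gene_ids(orf_table: pd.DataFrame, min_fe: float) -> set[str]:
    """Member gene ids of ORF regions at or above the threshold (merged spans
    contribute every member)."""
    ids: set[str] = set()
    for rid in select_enriched(orf_table, min_fe)["region_id"]:
        ids.update(rid.split("+"))
    return ids


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
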