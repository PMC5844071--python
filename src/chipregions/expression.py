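"""Expression tiers and occupancy/expression cross-tabulation.

Genes with expression data are ranked descending and cut into quantile tiers:
the top ``q_high`` fraction is HIGH, the next ``q_mod`` MODERATE, the remainder
LOW_NO. Genes absent from the expression table form a first-class NO_DATA tier
(real annotations always contain genes the RNA-Seq ranking lacks). Defaults of
9% / 29% reproduce the global high/moderate fractions of the Tetrahymena
vegetative-growth RNA-Seq ranking the occupancy analysis is built on. Tiering
operates on any monotone expression score (FPKM, counts, ranks alike).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

TIERS = ("HIGH", "MODERATE", "LOW_NO", "NO_DATA")


def read_expression_table(path: Union[str, Path]) -> pd.DataFrame:
    """Two-column TSV (gene_id, value), optional header line."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["gene_id", "value"]:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        df = df.iloc[:, :2]
        df.columns = ["gene_id", "value"]
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "value"]
    df["gene_id"] = df["gene_id"].astype(str)
    df["value"] = df["value"].astype(float)
    return df


def assign_tiers(
    expression: Union[pd.DataFrame, Mapping[str, float]],
    universe: Optional[Iterable[str]] = None,
    q_high: float = 0.09,
    q_mod: float = 0.29,
) -> pd.DataFrame:
    """Assign every gene in the universe to an expression tier.

    Parameters
    ----------
    expression
        gene -> expression value; a DataFrame with gene_id/value columns or a
        mapping. Values must be non-negative.
    universe
        Gene ids to tier. Defaults to the genes in the expression table; genes
        in the universe without a value become NO_DATA.
    q_high, q_mod
        Quantile fractions of the genes *with data* assigned HIGH and
        MODERATE (top ceil(q_high*n), next ceil(q_mod*n), after a descending
        sort with ties broken stably by gene_id).

    Returns
    -------
    DataFrame with columns gene_id, value (NaN when missing), rank (1-based
    among genes with data; 0 for NO_DATA), tier.
    """
    if not (0 < q_high and 0 < q_mod and q_high + q_mod < 1):
        raise ValueError("require 0 < q_high, q_mod and q_high + q_mod < 1")
    if isinstance(expression, pd.DataFrame):
        expr = dict(zip(expression["gene_id"].astype(str), expression["value"]))
    else:
        expr = {str(k): float(v) for k, v in expression.items()}
    if any(v < 0 for v in expr.values()):
        bad = [k for k, v in expr.items() if v < 0]
        raise ValueError(f"negative expression for {bad[:5]}")

    genes = sorted(set(map(str, universe))) if universe is not None else sorted(expr)
    with_data = [g for g in genes if g in expr]
    # descending by value, ties stable by gene_id (list is pre-sorted by id)
    with_data.sort(key=lambda g: -expr[g])

    n = len(with_data)
    n_high = math.ceil(q_high * n)
    n_mod = math.ceil(q_mod * n)
    tier_of: dict[str, str] = {}
    rank_of: dict[str, int] = {}
    for i, g in enumerate(with_data):
        rank_of[g] = i + 1
        tier_of[g] = "HIGH" if i < n_high else "MODERATE" if i < n_high + n_mod else "LOW_NO"

    rows = [
        {
            "gene_id": g,
            "value": expr.get(g, float("nan")),
            "rank": rank_of.get(g, 0),
            "tier": tier_of.get(g, "NO_DATA"),
        }
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene_id", "value", "rank", "tier"])


def _tier_map(tiers: Union[pd.DataFrame, Mapping[str, str]]) -> dict[str, str]:
    if isinstance(tiers, pd.DataFrame):
        return dict(zip(tiers["gene_id"].astype(str), tiers["tier"]))
    return {str(k): str(v) for k, v in tiers.items()}


def crosstab_occupancy(
    enriched_ids: Iterable[str],
    tiers: Union[pd.DataFrame, Mapping[str, str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-tier counts/percentages for the enriched gene set and the universe.

    The universe columns are the global expression distribution (left panel);
    the enriched columns are the occupied-gene distribution (right panel).
    """
    tier_of = _tier_map(tiers)
    universe = set(map(str, universe))
    enriched = set(map(str, enriched_ids))
    offenders = sorted(enriched - universe)
    if offenders:
        raise ValueError(f"enriched genes outside universe: {offenders[:10]}")

    rows = []
    n_u, n_e = len(universe), len(enriched)
    for tier in TIERS:
        cu = sum(1 for g in universe if tier_of.get(g, "NO_DATA") == tier)
        ce = sum(1 for g in enriched if tier_of.get(g, "NO_DATA") == tier)
        rows.append(
            {
                "tier": tier,
                "universe_count": cu,
                "universe_pct": 100.0 * cu / n_u if n_u else 0.0,
                "enriched_count": ce,
                "enriched_pct": 100.0 * ce / n_e if n_e else 0.0,
            }
        )
    return pd.DataFrame(rows)


def tier_trend_by_bin(
    enrichment_table: pd.DataFrame,
    tiers: Union[pd.DataFrame, Mapping[str, str]],
    bin_order: Sequence[str],
) -> tuple[pd.DataFrame, bool]:
    """Tier composition of ORF rows per fold-enrichment bin, plus monotonicity.

    ``bin_order`` lists bins from weakest to strongest enrichment (see
    :func:`chipregions.enrichment.ordered_bin_labels`). Returns the per-bin
    tier fractions and whether the HIGH fraction is non-decreasing across the
    occupied bins — the signature of occupancy tracking expression.
    """
    tier_of = _tier_map(tiers)
    orfs = enrichment_table[enrichment_table["region_type"] == "ORF"]
    rows = []
    high_fracs = []
    for b in bin_order:
        ids = orfs.loc[orfs["bin"] == b, "region_id"]
        n = len(ids)
        counts = {t: 0 for t in TIERS}
        for rid in ids:
            counts[tier_of.get(rid, "NO_DATA")] += 1
        row = {"bin": b, "n": n}
        for t in TIERS:
            row[f"frac_{t}"] = counts[t] / n if n else float("nan")
        rows.append(row)
        if n:
            high_fracs.append(counts["HIGH"] / n)
    monotone = all(b >= a - 1e-12 for a, b in zip(high_fracs, high_fracs[1:]))
    return pd.DataFrame(rows), monotone


def write_crosstab(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
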