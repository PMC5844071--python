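"""Over-representation analysis: hypergeometric test with BH FDR control.

For a gene set of size n drawn from a universe of size N, a term annotating K
universe genes and overlapping the set in k, the enrichment p-value is the
hypergeometric upper tail P(X >= k). Benjamini-Hochberg adjustment is applied
across all tested terms. This is a deliberately plain replacement for
network-aware term grouping: the scientific claim it supports is "which
functional categories are over-represented among occupied genes", not any
particular network statistic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def read_term_map(path: Union[str, Path]) -> dict[str, set[str]]:
    """Gene->term TSV (gene_id, term_id[, term columns...]) or GMT.

    GMT (``.gmt``): one term per line, ``term<TAB>description<TAB>gene...``.
    TSV: one (gene, term) pair per line.
    """
    path = Path(path)
    term_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if path.suffix.lower() == ".gmt":
                term, genes = parts[0], parts[2:]
                term_map.setdefault(term, set()).update(genes)
            else:
                gene, term = parts[0], parts[1]
                term_map.setdefault(term, set()).add(gene)
    return term_map


def overrepresentation(
    gene_set: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    q_threshold: Optional[float] = 0.05,
    drop_unannotated: bool = False,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of ``gene_set`` within ``universe``.

    Terms are restricted to universe genes; empty terms after restriction and
    terms with zero overlap are dropped. Genes with no annotation stay in the
    universe unless ``drop_unannotated``. Results carry k (overlap), n (set
    size), K (term size), N (universe size), p (upper tail), q (BH), sorted by
    (q, p, term_id); ``q_threshold`` of None returns all terms, otherwise only
    those with q <= threshold.
    """
    universe = set(map(str, universe))
    gene_set = set(map(str, gene_set))
    outside = sorted(gene_set - universe)
    if outside:
        raise ValueError(f"genes outside universe: {outside[:10]}")

    restricted = {t: set(map(str, gs)) & universe for t, gs in term_map.items()}
    restricted = {t: gs for t, gs in restricted.items() if gs}
    if drop_unannotated:
        annotated = set().union(*restricted.values()) if restricted else set()
        universe = universe & annotated
        gene_set = gene_set & annotated
        restricted = {t: gs & universe for t, gs in restricted.items()}
        restricted = {t: gs for t, gs in restricted.items() if gs}

    N, n = len(universe), len(gene_set)
    rows = []
    for term in sorted(restricted):
        genes = restricted[term]
        K = len(genes)
        k = len(genes & gene_set)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)
        if q_threshold is not None:
            df = df[df["q"] <= q_threshold].reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def write_ora_report(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
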