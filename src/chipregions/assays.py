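"""ChIP-qPCR standard-curve normalization and histone peptide-array ranking.

qPCR quantification rests on the log-linear standard curve

    Cq = a + b * log10(percent_of_input)

fitted per target on a dilution series of the input sample (100/10/1% in the
assay this models). A measured Cq inverts to percent input via
``10**((Cq - a) / b)``; amplification efficiency is ``10**(-1/b) - 1`` (100%
at b = -1/log10(2) ~ -3.32 cycles per 10-fold dilution). Per-replicate fold
enrichment is percent input of the IP relative to the input reference (100%),
and tagged vs untagged groups are compared with a two-sided t-test — Welch by
default since the modeled design has unequal group sizes (4 vs 3).

The peptide-array branch averages replicate spot intensities per modified
peptide, ranks descending, and flags modified residues that are absent from
the target species' histone sequences (a hit on a non-conserved residue
cannot be read as in-vivo specificity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats


class AssayError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ChIP-qPCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # b: Cq per log10(percent)
    intercept: float  # a: Cq at 1% input (log10 = 0)
    r_squared: float
    n_points: int

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 == 100% (doubling per cycle)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0

    def predict_cq(self, percent: float) -> float:
        return self.intercept + self.slope * np.log10(percent)


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Cq = a + b*log10(percent) on (percent, Cq) points."""
    if len(points) < 3:
        raise AssayError(f"standard curve needs >= 3 points, got {len(points)}")
    percents = np.array([p for p, _ in points], dtype=float)
    cqs = np.array([c for _, c in points], dtype=float)
    if (percents <= 0).any():
        raise AssayError("dilution percents must be positive")
    if len(set(percents)) < 3:
        raise AssayError("need >= 3 distinct dilution percents")
    res = stats.linregress(np.log10(percents), cqs)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(points),
    )


def percent_input(cq: float, curve: StandardCurve) -> float:
    """Invert the standard curve: Cq -> percent of input."""
    if not curve.valid:
        raise AssayError(f"invalid standard curve (slope {curve.slope:.3g} >= 0)")
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


@dataclass(frozen=True)
class QpcrResult:
    target: str
    tagged_fold: tuple[float, ...]
    untagged_fold: tuple[float, ...]
    tagged_mean: float
    untagged_mean: float
    tagged_sem: float
    untagged_sem: float
    t_statistic: float
    p_value: float


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def qpcr_compare(
    tagged: Sequence[float],
    untagged: Sequence[float],
    target: str = "",
    welch: bool = True,
) -> QpcrResult:
    """Two-sample two-sided t-test between tagged and untagged fold enrichments.

    Welch (unequal variances) by default; ``welch=False`` gives Student's t.
    Two identical zero-variance groups yield t=0, p=1 by convention.
    """
    tagged = np.asarray(tagged, dtype=float)
    untagged = np.asarray(untagged, dtype=float)
    if len(tagged) < 2 or len(untagged) < 2:
        raise AssayError("need >= 2 replicates per group")
    if (
        np.std(tagged) == 0.0
        and np.std(untagged) == 0.0
        and np.mean(tagged) == np.mean(untagged)
    ):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(tagged, untagged, equal_var=not welch)
    return QpcrResult(
        target=target,
        tagged_fold=tuple(tagged),
        untagged_fold=tuple(untagged),
        tagged_mean=float(np.mean(tagged)),
        untagged_mean=float(np.mean(untagged)),
        tagged_sem=_sem(tagged),
        untagged_sem=_sem(untagged),
        t_statistic=float(t),
        p_value=float(p),
    )


def read_qpcr_table(path: Union[str, Path]) -> pd.DataFrame:
    """qPCR TSV: target, group {tagged, untagged, input-dilution}, replicate, cq,
    percent (known percent for dilution rows, empty otherwise)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"target", "group", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise AssayError(f"qPCR table missing columns {sorted(missing)}")
    if "percent" not in df.columns:
        df["percent"] = np.nan
    if (df["cq"] <= 0).any():
        raise AssayError("Cq values must be positive")
    return df


def analyze_qpcr(
    measurements: pd.DataFrame, welch: bool = True
) -> tuple[dict[str, StandardCurve], list[QpcrResult], pd.DataFrame]:
    """Full per-target qPCR workflow on a measurements table.

    Each target gets its own standard curve (fitted on its input-dilution
    rows), every IP Cq is converted to percent input, per-replicate fold
    enrichment is percent input / 100 (the undiluted input reference), and
    tagged vs untagged folds are compared. Returns curves, group comparisons,
    and the per-replicate table.
    """
    curves: dict[str, StandardCurve] = {}
    results: list[QpcrResult] = []
    rep_rows = []
    for target, sub in measurements.groupby("target", sort=True):
        dil = sub[sub["group"] == "input-dilution"]
        if len(dil) < 3:
            raise AssayError(f"target {target}: needs >= 3 input-dilution points")
        curve = fit_standard_curve(list(zip(dil["percent"], dil["cq"])))
        curves[str(target)] = curve
        folds: dict[str, list[float]] = {"tagged": [], "untagged": []}
        for _, rec in sub[sub["group"].isin(("tagged", "untagged"))].iterrows():
            pct = percent_input(rec["cq"], curve)
            fold = pct / 100.0  # normalized IP over normalized (undiluted) input
            folds[rec["group"]].append(fold)
            rep_rows.append(
                {
                    "target": target,
                    "group": rec["group"],
                    "replicate": rec["replicate"],
                    "cq": rec["cq"],
                    "percent_input": pct,
                    "fold_enrichment": fold,
                }
            )
        results.append(
            qpcr_compare(folds["tagged"], folds["untagged"], target=str(target), welch=welch)
        )
    per_rep = pd.DataFrame(
        rep_rows,
        columns=["target", "group", "replicate", "cq", "percent_input", "fold_enrichment"],
    )
    return curves, results, per_rep


def write_qpcr_report(results: Sequence[QpcrResult], path: Union[str, Path]) -> None:
    rows = [
        {
            "target": r.target,
            "tagged_mean_fold": r.tagged_mean,
            "tagged_sem": r.tagged_sem,
            "untagged_mean_fold": r.untagged_mean,
            "untagged_sem": r.untagged_sem,
            "t_statistic": r.t_statistic,
            "p_value": r.p_value,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# histone peptide array
# ---------------------------------------------------------------------------

_MOD_RE = re.compile(r"^([A-Z])(\d+)([A-Za-z0-9]+)$")  # e.g. K9ac, R3me2s, S10P


@dataclass(frozen=True)
class Modification:
    histone: str  # H3, H4, H2A, H2B
    residue: str  # one-letter amino acid
    position: int  # 1-based within the histone
    mark: str  # ac, me1, me2s, P, ...

    @classmethod
    def parse(cls, histone: str, token: str) -> "Modification":
        m = _MOD_RE.match(token.strip())
        if not m:
            raise AssayError(f"cannot parse modification token {token!r}")
        return cls(histone=histone, residue=m.group(1), position=int(m.group(2)),
                   mark=m.group(3))

    def __str__(self) -> str:
        return f"{self.histone}{self.residue}{self.position}{self.mark}"


def read_array_table(path: Union[str, Path]) -> pd.DataFrame:
    """Array TSV: peptide_id, histone, modifications (';'-separated tokens),
    then one column per replicate (rep1, rep2, ...)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"peptide_id", "histone", "modifications"}
    missing = required - set(df.columns)
    if missing:
        raise AssayError(f"array table missing columns {sorted(missing)}")
    return df


def read_histone_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Histone FASTA; record ids are histone names (H3, H4, H2A, H2B).

    Positions in modification tokens are 1-based in the mature protein
    (initiator methionine removed), the field's histone-numbering convention;
    sequences here are stored as given.
    """
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def residue_conserved(mod: Modification, histone_seqs: Mapping[str, str]) -> Optional[bool]:
    """Whether the modified residue exists in the target species' histone.

    None when the histone sequence is unavailable.
    """
    seq = histone_seqs.get(mod.histone)
    if seq is None:
        return None
    if mod.position > len(seq):
        return False
    return seq[mod.position - 1] == mod.residue


def rank_array(
    spots: pd.DataFrame,
    top_k: int = 10,
    histone_seqs: Optional[Mapping[str, str]] = None,
    normalize: Optional[bool] = None,
) -> pd.DataFrame:
    """Average replicate intensities per peptide, rank descending, flag conservation.

    Replicate columns are every column named ``rep*``; all spots must have a
    complete replicate set. Raw intensities (any value outside [0, 1]) are
    min-max normalized across the array before averaging; pre-normalized
    inputs pass through (auto-detected, override with ``normalize``). Ties in
    mean intensity break on peptide_id. ``top_k`` of None returns all spots.
    """
    rep_cols = [c for c in spots.columns if c.startswith("rep")]
    if not rep_cols:
        raise AssayError("no replicate columns (rep*) found")
    vals = spots[rep_cols].to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = spots.loc[np.isnan(vals).any(axis=1), "peptide_id"].tolist()
        raise AssayError(f"missing replicate intensity for spots {bad[:5]}")
    if normalize is None:
        normalize = bool(vals.min() < 0 or vals.max() > 1)
    if normalize:
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            vals = (vals - lo) / (hi - lo)
        else:
            vals = np.zeros_like(vals)

    out = spots[["peptide_id", "histone", "modifications"]].copy()
    out["mean_intensity"] = vals.mean(axis=1)

    flags = []
    for _, rec in out.iterrows():
        toks = [t for t in str(rec["modifications"]).split(";") if t.strip()]
        mods = [Modification.parse(rec["histone"], t) for t in toks]
        if histone_seqs is None:
            flags.append(".")
        else:
            non_conserved = [
                str(m) for m in mods if residue_conserved(m, histone_seqs) is False
            ]
            flags.append(",".join(non_conserved) or ".")
    out["non_conserved_residues"] = flags
    out = out.sort_values(
        ["mean_intensity", "peptide_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out
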