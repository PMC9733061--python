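"""Differential-expression filtering and two-knockdown concordance.

Genes pass per-contrast selection when |fold change| >= ``min_fold``
(inclusive; default 1.25) and Benjamini-Hochberg FDR < ``max_fdr`` (strict;
default 0.05).  The high-confidence regulated set is the direction-wise
intersection of the two independent knockdown contrasts.  Also provides the
2^-ddCt relative qPCR quantification as a utility.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DERecord",
    "ConcordantSet",
    "read_de_table",
    "write_de_table",
    "adjust_fdr",
    "filter_de",
    "concordant_genes",
    "ddct_fold_change",
]

DE_COLUMNS = ["gene_id", "contrast", "log2fc", "pvalue"]


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    contrast: str
    log2fc: float
    pvalue: float
    fdr: float | None = None


@dataclass(frozen=True)
class ConcordantSet:
    """Direction-consistent regulated genes across two contrasts."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    discordant: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("a gene cannot be both up and down")

    @property
    def high_confidence(self) -> frozenset[str]:
        return self.up_genes | self.down_genes

    def direction(self, gene: str) -> str:
        if gene in self.up_genes:
            return "up"
        if gene in self.down_genes:
            return "down"
        raise KeyError(gene)


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-contrast DE table (TSV with header gene_id, contrast,
    log2fc, pvalue[, fdr])."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns {missing}")
    _validate_pvalues(df["pvalue"])
    dup = df.duplicated(subset=["gene_id", "contrast"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (gene, contrast) rows")
    return df


def write_de_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def _validate_pvalues(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr <= 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return arr


def adjust_fdr(pvalues: Mapping[str, float] | Iterable[float]):
    """Benjamini-Hochberg step-up adjusted values, order-preserving.

    Accepts a mapping (returns a dict with the same keys) or a sequence
    (returns an ndarray aligned with the input).
    """
    if isinstance(pvalues, Mapping):
        keys = list(pvalues)
        arr = _validate_pvalues([pvalues[k] for k in keys])
        if arr.size == 0:
            return {}
        q = multipletests(arr, method="fdr_bh")[1]
        return dict(zip(keys, q))
    arr = _validate_pvalues(list(pvalues))
    if arr.size == 0:
        return np.empty(0)
    return multipletests(arr, method="fdr_bh")[1]


def filter_de(
    records: pd.DataFrame | Iterable[DERecord],
    min_fold: float = 1.25,
    max_fdr: float = 0.05,
    max_fold: float | None = None,
) -> dict[str, tuple[frozenset[str], frozenset[str]]]:
    """Per-contrast up/down gene sets from fold-change and FDR thresholds.

    FDR is computed per contrast (BH) when the input lacks an ``fdr`` column.
    The fold boundary is inclusive, the FDR boundary strict.  ``max_fold``
    optionally caps |fold| (inclusive); by default there is no cap.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
        if "fdr" in df.columns and df["fdr"].isna().all():
            df = df.drop(columns="fdr")
    _validate_pvalues(df["pvalue"])
    thr = math.log2(min_fold)
    cap = math.log2(max_fold) if max_fold is not None else None
    out: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for contrast, sub in df.groupby("contrast", sort=True):
        fdr = (
            sub["fdr"].to_numpy(dtype=float)
            if "fdr" in sub.columns
            else adjust_fdr(sub["pvalue"].tolist())
        )
        fc = sub["log2fc"].to_numpy(dtype=float)
        sig = fdr < max_fdr
        if cap is not None:
            sig &= np.abs(fc) <= cap
        up = frozenset(sub.loc[sig & (fc >= thr), "gene_id"])
        down = frozenset(sub.loc[sig & (fc <= -thr), "gene_id"])
        out[contrast] = (up, down)
    return out


def concordant_genes(
    sets_a: tuple[frozenset[str], frozenset[str]],
    sets_b: tuple[frozenset[str], frozenset[str]],
) -> ConcordantSet:
    """Direction-wise intersection of two contrasts' up/down sets.

    Genes changing in opposite directions across the contrasts are excluded
    from both sets and reported in ``discordant``.
    """
    up_a, down_a = map(frozenset, sets_a)
    up_b, down_b = map(frozenset, sets_b)
    discordant = (up_a & down_b) | (down_a & up_b)
    return ConcordantSet(
        up_genes=(up_a & up_b) - discordant,
        down_genes=(down_a & down_b) - discordant,
        discordant=discordant,
    )


def ddct_fold_change(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control;
    the returned linear fold change is 2**(-ddCt).
    """
    cts = (ct_target_treated, ct_reference_treated,
           ct_target_control, ct_reference_control)
    if not all(math.isfinite(c) and c > 0 for c in cts):
        raise ValueError("Ct values must be finite and positive")
    ddct = (ct_target_treated - ct_reference_treated) - (
        ct_target_control - ct_reference_control
    )
    return 2.0 ** (-ddct)
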