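"""Preranked gene-set enrichment: weighted running-sum enrichment score with
gene-set permutation normalization.

The statistic walks down a metric-ranked gene list accumulating
``|metric|^p`` (normalized over set members) for hits minus ``1/(N - N_hits)``
for misses; the enrichment score (ES) is the running-sum value of maximal
absolute deviation from zero.  The null distribution comes from random gene
sets of identical size drawn without replacement from the list; NES and the
permutation p-value are sign-stratified.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .de_concordance import adjust_fdr

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "enrichment_score",
    "permutation_normalize",
    "gsea_collection",
    "read_rnk",
    "read_gmt",
]


class RankedList:
    """Genes ordered by descending metric (e.g. log2 fold change).

    Ties are broken by lexicographic gene id (stable, deterministic); gene
    ids must be unique.
    """

    def __init__(self, genes: Sequence[str], metric: Sequence[float]) -> None:
        if len(genes) != len(metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids must be unique")
        order = sorted(range(len(genes)), key=lambda i: (-metric[i], genes[i]))
        self.genes: list[str] = [genes[i] for i in order]
        self.metric: np.ndarray = np.asarray(
            [metric[i] for i in order], dtype=float
        )

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_mapping(cls, scores: Mapping[str, float]) -> "RankedList":
        keys = list(scores)
        return cls(keys, [scores[k] for k in keys])


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    pvalue: float
    n_hits: int
    n_null_same_sign: int


def _hit_indicator(ranked: RankedList, gene_set: Iterable[str]) -> np.ndarray:
    members = set(gene_set)
    return np.fromiter((g in members for g in ranked.genes), dtype=bool,
                       count=len(ranked))


def _batch_es(
    metric: np.ndarray, hits: np.ndarray, weight_p: float
) -> tuple[np.ndarray, np.ndarray]:
    """ES for each row of a boolean hit matrix (B x N); returns (es, running)."""
    n = metric.shape[0]
    n_hits = hits.sum(axis=1)
    if (n_hits == 0).any():
        raise ValueError("gene set has no member in the ranked list")
    if (n_hits == n).any():
        raise ValueError("gene set covers the whole list (degenerate)")
    absw = np.abs(metric) ** weight_p
    w = hits * absw
    nr = w.sum(axis=1, keepdims=True)
    # all-zero hit weights (e.g. every member metric 0): fall back to equal steps
    flat = nr[:, 0] == 0
    if flat.any():
        w[flat] = hits[flat].astype(float)
        nr[flat, 0] = n_hits[flat]
    p_hit = np.cumsum(w / nr, axis=1)
    p_miss = np.cumsum((~hits) / (n - n_hits)[:, None], axis=1)
    running = p_hit - p_miss
    idx = np.argmax(np.abs(running), axis=1)
    es = running[np.arange(running.shape[0]), idx]
    return es, running


def enrichment_score(
    ranked: RankedList,
    gene_set: Iterable[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """ES of one gene set: ``(es, running_sum, hit_positions)``."""
    if weight_p < 0:
        raise ValueError("weight_p must be >= 0")
    hits = _hit_indicator(ranked, gene_set)
    es, running = _batch_es(ranked.metric, hits[None, :], weight_p)
    return float(es[0]), running[0], np.nonzero(hits)[0]


def permutation_normalize(
    ranked: RankedList,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
    set_name: str = "set",
) -> EnrichmentResult:
    """Gene-set permutation null: NES and sign-stratified empirical p-value.

    ``NES = ES / mean(|null ES| of the same sign)``;
    ``p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign null)``.
    Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    es, _, hit_pos = enrichment_score(ranked, gene_set, weight_p)
    n, k = len(ranked), len(hit_pos)
    rng = np.random.default_rng(seed)
    # k draws without replacement per permutation
    ranks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    null_hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(null_hits, ranks, True, axis=1)
    null_es, _ = _batch_es(ranked.metric, null_hits, weight_p)
    same_sign = null_es >= 0 if es >= 0 else null_es <= 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        return EnrichmentResult(set_name, es, np.nan, 1.0, k, 0)
    null_mag = np.abs(null_es[same_sign])
    nes = es / null_mag.mean() if null_mag.mean() > 0 else np.nan
    p = (1 + int((null_mag >= abs(es)).sum())) / (1 + n_same)
    return EnrichmentResult(set_name, float(es), float(nes), float(p), k, n_same)


def gsea_collection(
    ranked: RankedList,
    gene_sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Run permutation-normalized enrichment for a collection of gene sets.

    The ``fdr`` column is a BH adjustment of the permutation p-values within
    each NES sign stratum (a simple empirical surrogate for the rank-of-NES
    procedure).
    """
    results = []
    for i, (name, gs) in enumerate(sorted(gene_sets.items())):
        results.append(
            permutation_normalize(
                ranked, gs, n_perm=n_perm, seed=None if seed is None else seed + i,
                weight_p=weight_p, set_name=name,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in results])
    df["fdr"] = np.nan
    for sign in (1, -1):
        mask = (df["es"] >= 0) if sign == 1 else (df["es"] < 0)
        if mask.any():
            df.loc[mask, "fdr"] = adjust_fdr(df.loc[mask, "pvalue"].tolist())
    return df


def read_rnk(path: str | os.PathLike) -> RankedList:
    """Read a two-column (gene, metric) ranked-list file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "metric"])
    return RankedList(df["gene"].astype(str).tolist(),
                      df["metric"].astype(float).tolist())


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets
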