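"""Gene models, genomic-feature classification of peaks, and signed
nearest-TSS distances.

A peak is placed into exactly one of five genomic categories by the position
of its anchor, with precedence ``promoter > exon > intron > downstream >
intergenic`` evaluated across all genes.  The promoter is the
``promoter_window`` bp lying upstream of a TSS (strand-aware, boundary
inclusive); the downstream window extends ``downstream_window`` bp past the
TTS.  Signed TSS distances are negative upstream of the gene in its own
transcription direction.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals_io import Peak

__all__ = [
    "GeneModel",
    "FeatureAnnotation",
    "CATEGORIES",
    "read_gtf",
    "write_gtf",
    "nearest_tss",
    "classify_peak_location",
    "annotate_peaks",
    "distance_distribution",
    "feature_distribution",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "exon", "intron", "downstream", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene: transcript span plus exon structure.

    ``tss``/``tts`` are strand-aware single positions inside the half-open
    span [tx_start, tx_end): for a '+' gene the TSS is tx_start and the TTS is
    tx_end - 1; for a '-' gene the reverse.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        prev_end = self.tx_start
        for start, end in self.exons:
            if start < prev_end or end > self.tx_end or start >= end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, disjoint and "
                    "inside the transcript span"
                )
            prev_end = end

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


@dataclass(frozen=True)
class FeatureAnnotation:
    peak_name: str
    category: str
    assigned_gene: str | None
    signed_tss_distance: int | None
    tie: bool = False


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from a GTF file (1-based inclusive, converted to
    0-based half-open at this boundary).

    When a gene has several transcripts, the longest one is kept.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for tx_by_gene in _transcripts_by_gene(db):
        gene_id, transcripts = tx_by_gene
        tx = max(transcripts, key=lambda t: (t.end - t.start, t.id))
        exons = sorted(
            (e.start - 1, e.end)
            for e in db.children(tx, featuretype="exon")
        )
        if not exons:
            exons = [(tx.start - 1, tx.end)]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=tx.seqid,
                strand=tx.strand,
                tx_start=tx.start - 1,
                tx_end=tx.end,
                exons=tuple(exons),
            )
        )
    genes.sort(key=lambda g: g.gene_id)
    return genes


def _transcripts_by_gene(db):
    by_gene: dict[str, list] = {}
    for tx in db.features_of_type("transcript"):
        gid = tx.attributes.get("gene_id", [tx.id])[0]
        by_gene.setdefault(gid, []).append(tx)
    return sorted(by_gene.items())


def write_gtf(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GTF (gene/transcript/exon features)."""
    with open(path, "w") as handle:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            for feat, s, e in [("gene", g.tx_start, g.tx_end), ("transcript", g.tx_start, g.tx_end)]:
                handle.write(
                    f"{g.chrom}\tsim\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            for i, (es, ee) in enumerate(g.exons, start=1):
                handle.write(
                    f"{g.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def _signed_distance(anchor: int, gene: GeneModel) -> int:
    sign = 1 if gene.strand == "+" else -1
    return (anchor - gene.tss) * sign


def nearest_tss(
    peak: Peak, genes: Sequence[GeneModel]
) -> tuple[str | None, int | None, bool]:
    """Gene with the TSS closest to the peak anchor on the same chromosome.

    Returns ``(gene_id, signed_distance, tie)``; ties in absolute distance are
    broken by lexicographically smaller gene_id and flagged.
    """
    anchor = peak.anchor
    best: GeneModel | None = None
    best_abs = None
    tie = False
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = abs(anchor - g.tss)
        if best is None or d < best_abs or (d == best_abs and g.gene_id < best.gene_id):
            if best is not None and d == best_abs:
                tie = True
            best, best_abs = g, d
        elif d == best_abs:
            tie = True
    if best is None:
        return None, None, False
    return best.gene_id, _signed_distance(anchor, best), tie


def classify_peak_location(
    peak: Peak,
    genes: Sequence[GeneModel],
    promoter_window: int = 10_000,
    downstream_window: int = 10_000,
) -> FeatureAnnotation:
    """Classify a peak anchor into promoter/exon/intron/downstream/intergenic."""
    if promoter_window <= 0 or downstream_window <= 0:
        raise ValueError("windows must be positive")
    if not genes:
        raise ValueError("gene collection is empty")
    anchor = peak.anchor
    chrom_genes = [g for g in genes if g.chrom == peak.chrom]
    if not chrom_genes:
        logger.warning(
            "peak %s on chromosome %s absent from gene model; intergenic",
            peak.name, peak.chrom,
        )
        return FeatureAnnotation(peak.name, "intergenic", None, None)

    is_promoter = is_exon = is_intron = is_downstream = False
    for g in chrom_genes:
        up = (g.tss - anchor) if g.strand == "+" else (anchor - g.tss)
        if 0 <= up <= promoter_window:
            is_promoter = True
        if g.tx_start <= anchor < g.tx_end:
            if any(s <= anchor < e for s, e in g.exons):
                is_exon = True
            else:
                is_intron = True
        past = (anchor - g.tts) if g.strand == "+" else (g.tts - anchor)
        if 1 <= past <= downstream_window:
            is_downstream = True

    if is_promoter:
        category = "promoter"
    elif is_exon:
        category = "exon"
    elif is_intron:
        category = "intron"
    elif is_downstream:
        category = "downstream"
    else:
        category = "intergenic"
    gene_id, dist, tie = nearest_tss(peak, chrom_genes)
    return FeatureAnnotation(peak.name, category, gene_id, dist, tie)


def annotate_peaks(
    peaks: Iterable[Peak],
    genes: Sequence[GeneModel],
    promoter_window: int = 10_000,
    downstream_window: int = 10_000,
) -> list[FeatureAnnotation]:
    return [
        classify_peak_location(p, genes, promoter_window, downstream_window)
        for p in peaks
    ]


def distance_distribution(
    annotations: Iterable[FeatureAnnotation],
    breaks: Sequence[int],
) -> tuple[pd.DataFrame, int]:
    """Histogram of |signed TSS distance| over the given breaks.

    Bins are ``[0, b1], (b1, b2], ...`` (closed right boundary, so a distance
    exactly at a break counts as within it) plus a final open bin.  Returns
    the table and the number of peaks with no assigned gene (excluded).
    """
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    anns = list(annotations)
    dists = [abs(a.signed_tss_distance) for a in anns if a.signed_tss_distance is not None]
    n_unassigned = sum(1 for a in anns if a.signed_tss_distance is None)
    edges = [0] + breaks
    labels = []
    counts = []
    arr = np.asarray(dists, dtype=float)
    for lo, hi in zip(edges, edges[1:]):
        if lo == 0:
            counts.append(int(np.sum(arr <= hi)))
            labels.append(f"0-{hi}")
        else:
            counts.append(int(np.sum((arr > lo) & (arr <= hi))))
            labels.append(f"{lo + 1}-{hi}")
    counts.append(int(np.sum(arr > edges[-1])) if breaks else len(arr))
    labels.append(f">{edges[-1]}" if breaks else "all")
    total = len(arr)
    frac = [c / total if total else 0.0 for c in counts]
    table = pd.DataFrame(
        {"bin": labels, "count": counts, "fraction": frac}
    )
    table["cumulative_fraction"] = table["fraction"].cumsum()
    if total == 0:
        table = table.iloc[0:0]
    return table, n_unassigned


def feature_distribution(annotations: Sequence[FeatureAnnotation]) -> pd.DataFrame:
    """Counts and fractions per genomic category (all five rows always)."""
    if not annotations:
        raise ValueError("no annotations")
    counts = {c: 0 for c in CATEGORIES}
    for a in annotations:
        counts[a.category] += 1
    total = len(annotations)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "fraction": [counts[c] / total for c in CATEGORIES],
        }
    )
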