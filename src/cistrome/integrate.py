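"""Join regulatory-element classifications, nearest-TSS gene assignments and
the high-confidence regulated set to nominate candidate direct target genes.

A gene is nominated when (i) it passes the two-knockdown concordance filter
and (ii) it is the nearest-TSS gene of at least one peak classified into one
of the candidate regulatory classes (cAP/cAE/cIP/cIE by default).  Remaining
regulated genes are candidate indirect targets; bound-but-unregulated genes
are reported for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotate import FeatureAnnotation
from .chromatin_state import RegClassification
from .de_concordance import ConcordantSet

__all__ = [
    "SupportingPeak",
    "TargetNomination",
    "classified_peak_genes",
    "nominate_direct_targets",
    "venn_summary",
]

DEFAULT_STATES = ("cAP", "cAE", "cIP", "cIE")


@dataclass(frozen=True)
class SupportingPeak:
    peak_name: str
    state: str
    open_chromatin: bool
    signed_tss_distance: int


@dataclass(frozen=True)
class TargetNomination:
    gene_id: str
    direction: str
    supporting_peaks: tuple[SupportingPeak, ...]

    @property
    def n_peaks(self) -> int:
        return len(self.supporting_peaks)


def classified_peak_genes(
    classifications: Iterable[RegClassification],
    annotations: Iterable[FeatureAnnotation],
    states: Sequence[str] = DEFAULT_STATES,
) -> dict[str, list[SupportingPeak]]:
    """Genes whose nearest TSS receives >= 1 peak in the selected states,
    each with its supporting peak details.

    Raises when a classified peak is missing from the annotation table (the
    two tables are out of sync).  Peaks with no assigned gene are ignored.
    """
    ann_by_peak = {a.peak_name: a for a in annotations}
    states = set(states)
    out: dict[str, list[SupportingPeak]] = {}
    for c in classifications:
        ann = ann_by_peak.get(c.peak_name)
        if ann is None:
            raise KeyError(
                f"peak {c.peak_name} classified but absent from annotations"
            )
        if c.state not in states or ann.assigned_gene is None:
            continue
        out.setdefault(ann.assigned_gene, []).append(
            SupportingPeak(
                c.peak_name, c.state, c.open_chromatin, ann.signed_tss_distance
            )
        )
    return {g: sorted(v, key=lambda s: s.peak_name) for g, v in sorted(out.items())}


def nominate_direct_targets(
    highconf: ConcordantSet,
    peak_genes: dict[str, list[SupportingPeak]],
) -> tuple[list[TargetNomination], list[str], list[str]]:
    """Intersect the regulated set with the bound-gene set.

    Returns ``(nominations, candidate_indirect, bound_not_regulated)``, all in
    lexicographic gene order.
    """
    bound = set(peak_genes)
    nominations = [
        TargetNomination(
            gene_id=g,
            direction=highconf.direction(g),
            supporting_peaks=tuple(peak_genes[g]),
        )
        for g in sorted(highconf.high_confidence & bound)
    ]
    indirect = sorted(highconf.high_confidence - bound)
    bound_only = sorted(bound - highconf.high_confidence)
    return nominations, indirect, bound_only


def venn_summary(
    highconf: ConcordantSet, peak_genes: Iterable[str]
) -> dict[str, int]:
    """Three-way partition counts of regulated vs peak-bearing genes."""
    regulated = set(highconf.high_confidence)
    bound = set(peak_genes)
    return {
        "regulated_only": len(regulated - bound),
        "bound_only": len(bound - regulated),
        "both": len(regulated & bound),
    }
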