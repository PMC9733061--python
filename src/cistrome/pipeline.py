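"""End-to-end driver: from replicate peaks, marks, ATAC, genome, gene models
and DE tables to classified elements, motif content, the concordant regulated
set and nominated direct targets.

This is a thin orchestration layer over the individual modules; every step
can also be run on its own.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import annotate, chromatin_state, de_concordance, integrate, intervals_io
from .intervals_io import PeakSet
from .motif_scan import PWM, peak_motif_fractions

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    common_peaks: PeakSet
    annotations: list
    classifications: list
    feature_table: pd.DataFrame
    distance_table: pd.DataFrame
    state_table: pd.DataFrame
    motif_table: pd.DataFrame
    per_contrast_sets: dict
    highconf: de_concordance.ConcordantSet
    nominations: list
    indirect: list
    bound_only: list
    venn: dict
    summary: dict = field(default_factory=dict)

    def write_summary(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            json.dump(self.summary, handle, indent=1, sort_keys=True)
            handle.write("\n")


def run_pipeline(
    rep1: PeakSet,
    rep2: PeakSet,
    genes: Sequence[annotate.GeneModel],
    marks: Mapping[str, PeakSet],
    atac: PeakSet,
    genome,
    pwms: Sequence[PWM],
    de_table: pd.DataFrame,
    contrasts: Sequence[str] | None = None,
    min_overlap: int = 1,
    promoter_window: int = 10_000,
    downstream_window: int = 10_000,
    flank: int = 1000,
    motif_threshold_p: float = 1e-4,
    min_fold: float = 1.25,
    max_fdr: float = 0.05,
    distance_breaks: Sequence[int] = (10_000, 50_000, 100_000),
) -> PipelineResult:
    """Run every analysis stage and collect a scalar summary.

    ``contrasts`` defaults to the two contrasts found in ``de_table`` (there
    must be exactly two in that case).
    """
    common = intervals_io.intersect_replicates(rep1, rep2, min_overlap=min_overlap)
    annotations = annotate.annotate_peaks(
        common, genes, promoter_window, downstream_window
    )
    feature_table = annotate.feature_distribution(annotations)
    distance_table, n_unassigned = annotate.distance_distribution(
        annotations, list(distance_breaks)
    )
    classifications = chromatin_state.classify_peaks(common, marks, atac, flank=flank)
    state_table = chromatin_state.state_summary(classifications)
    motif_table, motif_bool, motif_hits = peak_motif_fractions(
        common, genome, list(pwms), threshold_p=motif_threshold_p
    )

    per_contrast = de_concordance.filter_de(
        de_table, min_fold=min_fold, max_fdr=max_fdr
    )
    if contrasts is None:
        contrasts = sorted(per_contrast)
    if len(contrasts) != 2:
        raise ValueError("exactly two contrasts are required for concordance")
    highconf = de_concordance.concordant_genes(
        per_contrast[contrasts[0]], per_contrast[contrasts[1]]
    )
    peak_genes = integrate.classified_peak_genes(classifications, annotations)
    nominations, indirect, bound_only = integrate.nominate_direct_targets(
        highconf, peak_genes
    )
    venn = integrate.venn_summary(highconf, peak_genes)

    breaks = list(distance_breaks)
    within = {}
    if not distance_table.empty:
        cum = distance_table["cumulative_fraction"].tolist()
        for i, b in enumerate(breaks):
            within[f"frac_within_{b}bp"] = float(cum[i])
    summary = {
        "n_rep1": len(rep1),
        "n_rep2": len(rep2),
        "n_common_peaks": len(common),
        "n_unassigned_peaks": n_unassigned,
        **within,
        **{
            f"frac_{row.category}": float(row.fraction)
            for row in feature_table.itertuples()
        },
        **{
            f"frac_state_{row.state}": float(row.fraction)
            for row in state_table.itertuples()
        },
        **{
            f"frac_peaks_with_{row.pwm}": float(row.fraction)
            for row in motif_table.itertuples()
        },
        "n_up": len(highconf.up_genes),
        "n_down": len(highconf.down_genes),
        "n_high_confidence": len(highconf.high_confidence),
        "n_bound_genes": len(peak_genes),
        "n_direct_nominations": len(nominations),
        "venn": venn,
    }
    return PipelineResult(
        common_peaks=common,
        annotations=annotations,
        classifications=classifications,
        feature_table=feature_table,
        distance_table=distance_table,
        state_table=state_table,
        motif_table=motif_table,
        per_contrast_sets=per_contrast,
        highconf=highconf,
        nominations=nominations,
        indirect=indirect,
        bound_only=bound_only,
        venn=venn,
        summary=summary,
    )
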