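"""Binned histone-mark signal around peak anchors and rule-based
classification of peaks into candidate regulatory element classes.

A peak is classed from the presence of three marks within a flanking window
around its anchor:

========  ========  ========  =========
H3K27ac   H3K4me1   H3K4me3   state
========  ========  ========  =========
yes       any       yes       cAP   (candidate active promoter)
yes       yes       no        cAE   (candidate active enhancer)
no        any       yes       cIP   (candidate inactive promoter)
no        yes       no        cIE   (candidate inactive enhancer)
yes       no        no        other
no        no        no        other
========  ========  ========  =========

The promoter mark dominates when all three marks co-occur, matching standard
chromatin-state conventions.  Mark presence is interval-overlap based (any
mark interval overlapping the +/- ``flank`` window by >= 1 bp), not
signal-threshold based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals_io import Peak, PeakSet, _build_trees

__all__ = [
    "STATES",
    "MARKS",
    "SignalMatrix",
    "RegClassification",
    "bin_signal",
    "mark_presence",
    "classify_regulatory_state",
    "classify_peaks",
    "open_chromatin_flag",
    "state_summary",
]

logger = logging.getLogger(__name__)

STATES = ("cAP", "cAE", "cIP", "cIE", "other")
MARKS = ("H3K27ac", "H3K4me1", "H3K4me3")


@dataclass
class SignalMatrix:
    """Peaks x bins matrix of mark element counts around peak anchors."""

    peak_names: list[str]
    mark_name: str
    n_bins: int
    bin_size: int
    values: np.ndarray

    @property
    def window(self) -> int:
        return self.n_bins * self.bin_size

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.peak_names), self.n_bins):
            raise ValueError("matrix shape does not match peaks x bins")
        if (self.values < 0).any():
            raise ValueError("signal counts must be non-negative")

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.peak_names, name="peak"),
            columns=[f"bin{j}" for j in range(self.n_bins)],
        )
        df.to_csv(path, sep="\t")

    def sorted_by_total(self) -> "SignalMatrix":
        """Rows sorted by decreasing total signal (heatmap display order)."""
        order = np.argsort(-self.values.sum(axis=1), kind="stable")
        return SignalMatrix(
            [self.peak_names[i] for i in order],
            self.mark_name,
            self.n_bins,
            self.bin_size,
            self.values[order],
        )

    def plot_heatmap(self, path: str, cmap: str = "viridis") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 6))
        ax.imshow(self.sorted_by_total().values, aspect="auto", cmap=cmap,
                  interpolation="nearest")
        ax.set_title(self.mark_name)
        ax.set_xlabel(f"bins ({self.bin_size} bp)")
        ax.set_ylabel("peaks (decreasing total signal)")
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass(frozen=True)
class RegClassification:
    peak_name: str
    state: str
    open_chromatin: bool
    mark_presence: Mapping[str, bool]


def bin_signal(
    peaks: PeakSet | Sequence[Peak],
    mark_elements: PeakSet,
    n_bins: int = 60,
    bin_size: int = 100,
) -> SignalMatrix:
    """Count mark elements per bin around each peak anchor.

    Bin ``j`` of a peak spans ``[anchor - window/2 + j*bin_size, ... +
    (j+1)*bin_size)`` and counts elements whose midpoint falls inside it, so
    an element centred exactly on the anchor lands in bin ``n_bins/2``.  Bins
    clipped at the chromosome start simply stay zero.
    """
    if n_bins % 2 != 0 or n_bins <= 0:
        raise ValueError("n_bins must be a positive even number")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    half = n_bins * bin_size // 2
    mids: dict[str, np.ndarray] = {}
    for chrom, elems in mark_elements.by_chrom().items():
        mids[chrom] = np.sort(
            np.array([(e.start + e.end) // 2 for e in elems], dtype=np.int64)
        )
    plist = list(peaks)
    values = np.zeros((len(plist), n_bins), dtype=np.int64)
    for i, p in enumerate(plist):
        chrom_mids = mids.get(p.chrom)
        if chrom_mids is None or chrom_mids.size == 0:
            continue
        wstart = p.anchor - half
        if wstart < 0:
            logger.warning("peak %s window clipped at chromosome start", p.name)
        edges = wstart + bin_size * np.arange(n_bins + 1, dtype=np.int64)
        cum = np.searchsorted(chrom_mids, edges, side="left")
        values[i] = np.diff(cum)
    return SignalMatrix(
        [p.name for p in plist], mark_elements.source_label or "mark",
        n_bins, bin_size, values,
    )


def mark_presence(
    peak: Peak, mark_intervals: PeakSet, flank: int = 1000
) -> bool:
    """True iff any mark interval overlaps ``[anchor - flank, anchor + flank)``
    by at least 1 bp."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    lo, hi = peak.anchor - flank, peak.anchor + flank
    for m in mark_intervals:
        if m.chrom == peak.chrom and m.start < hi and m.end > lo:
            return True
    return False


def classify_regulatory_state(presence: Mapping[str, bool]) -> str:
    """Map the three mark-presence booleans to a regulatory state.

    Total and deterministic on all 8 combinations; see the module docstring
    for the rule table.
    """
    ac = bool(presence["H3K27ac"])
    me1 = bool(presence["H3K4me1"])
    me3 = bool(presence["H3K4me3"])
    if ac and me3:
        return "cAP"
    if ac and me1:
        return "cAE"
    if not ac and me3:
        return "cIP"
    if not ac and me1:
        return "cIE"
    return "other"


def open_chromatin_flag(
    peaks: PeakSet | Sequence[Peak], atac: PeakSet
) -> dict[str, bool]:
    """Per-peak flag: >= 1 bp overlap between the full peak interval and any
    open-chromatin (ATAC) interval."""
    trees = _build_trees(atac)
    out: dict[str, bool] = {}
    for p in peaks:
        tree = trees.get(p.chrom)
        out[p.name] = bool(tree is not None and tree.overlap(p.start, p.end))
    return out


def classify_peaks(
    peaks: PeakSet | Sequence[Peak],
    marks: Mapping[str, PeakSet],
    atac: PeakSet | None = None,
    flank: int = 1000,
) -> list[RegClassification]:
    """Classify every peak from mark-interval presence in the anchor window.

    ``marks`` maps mark names (must include the three histone marks) to their
    interval sets; ``atac`` optionally supplies open-chromatin intervals.
    """
    plist = list(peaks)
    trees = {name: _build_trees(ps) for name, ps in marks.items()}
    open_flags = (
        open_chromatin_flag(plist, atac) if atac is not None
        else {p.name: False for p in plist}
    )
    out: list[RegClassification] = []
    for p in plist:
        presence = {}
        lo, hi = p.anchor - flank, p.anchor + flank
        for mark in MARKS:
            tree = trees[mark].get(p.chrom)
            presence[mark] = bool(tree is not None and tree.overlap(max(lo, 0), hi))
        out.append(
            RegClassification(
                p.name, classify_regulatory_state(presence),
                open_flags[p.name], presence,
            )
        )
    return out


def state_summary(classifications: Iterable[RegClassification]) -> pd.DataFrame:
    """Counts, fractions and open-chromatin fraction per regulatory state."""
    cls = list(classifications)
    if not cls:
        raise ValueError("no classifications")
    rows = []
    for state in STATES:
        members = [c for c in cls if c.state == state]
        n = len(members)
        n_open = sum(c.open_chromatin for c in members)
        rows.append(
            {
                "state": state,
                "count": n,
                "fraction": n / len(cls),
                "open_fraction": (n_open / n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
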