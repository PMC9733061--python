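"""Core interval data model, BED/narrowPeak readers and writers, and replicate
peak intersection.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; formats that use other conventions are converted at the reader
boundary.  The overlap of two half-open intervals [a, b) and [c, d) is
``max(0, min(b, d) - max(a, c))``, so abutting intervals do not overlap.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "overlap_bp",
    "read_intervals",
    "write_intervals",
    "intersect_replicates",
]

_STRANDS = {"+", "-", "."}
_HEADER_PREFIXES = ("#", "track", "browser")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional name, score and strand."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two half-open intervals (0 if different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Peak:
    """A peak: an interval plus an optional summit (point source).

    The *anchor* is the position used for distances and signal binning: the
    summit if present, else the interval midpoint.
    """

    interval: GenomicInterval
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def name(self) -> str | None:
        return self.interval.name

    @property
    def anchor(self) -> int:
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2


class PeakSet:
    """An ordered collection of peaks with unique names.

    Peaks lacking a name are auto-named ``chrom:start-end``; residual
    collisions among auto-generated names get a numeric suffix, while
    duplicated explicit names raise.
    """

    def __init__(self, peaks: Iterable[Peak], source_label: str = "") -> None:
        named: list[Peak] = []
        seen: dict[str, int] = {}
        for peak in peaks:
            name = peak.interval.name
            auto = name is None
            if auto:
                name = f"{peak.chrom}:{peak.start}-{peak.end}"
            if name in seen:
                if not auto:
                    raise ValueError(f"duplicate peak name {name!r} in set")
                seen[name] += 1
                name = f"{name}.{seen[name]}"
            seen.setdefault(name, 0)
            if name != peak.interval.name:
                peak = Peak(
                    replace(peak.interval, name=name), peak.summit_offset
                )
            named.append(peak)
        self.peaks: list[Peak] = named
        self.source_label = source_label
        self._by_name = {p.name: p for p in self.peaks}

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, idx: int) -> Peak:
        return self.peaks[idx]

    def get(self, name: str) -> Peak:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.peaks]

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = defaultdict(list)
        for p in self.peaks:
            out[p.chrom].append(p)
        return dict(out)


def _infer_format(path: str) -> str:
    if str(path).lower().endswith(".narrowpeak"):
        return "narrowpeak"
    return "bed"


def read_intervals(path: str | os.PathLike, format: str | None = None) -> PeakSet:
    """Read a BED3+/BED6 or ENCODE narrowPeak file into a :class:`PeakSet`.

    narrowPeak column 10 (point source) maps to ``summit_offset``; -1 means
    absent.  Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    """
    fmt = (format or _infer_format(path)).lower()
    if fmt not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown format {fmt!r}")
    peaks: list[Peak] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score = None
                if len(fields) > 4 and fields[4] not in (".", ""):
                    score = float(fields[4])
                strand = fields[5] if len(fields) > 5 else "."
                if strand not in _STRANDS:
                    strand = "."
                summit = None
                if fmt == "narrowpeak":
                    if len(fields) < 10:
                        raise ValueError("narrowPeak requires 10 columns")
                    summit_raw = int(fields[9])
                    summit = None if summit_raw == -1 else summit_raw
                interval = GenomicInterval(chrom, start, end, name, score, strand)
                peaks.append(Peak(interval, summit))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: parse error at line {lineno}: {exc}") from exc
    return PeakSet(peaks, source_label=str(path))


def write_intervals(
    peaks: PeakSet, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a :class:`PeakSet` as BED6 or narrowPeak.

    Round trip through :func:`read_intervals` reproduces coordinates, names
    and summit offsets exactly.
    """
    fmt = (format or _infer_format(path)).lower()
    if fmt not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown format {fmt!r}")
    try:
        with open(path, "w") as handle:
            for p in peaks:
                iv = p.interval
                score = 0 if iv.score is None else iv.score
                score_str = f"{score:g}"
                base = [iv.chrom, str(iv.start), str(iv.end), iv.name, score_str, iv.strand]
                if fmt == "narrowpeak":
                    summit = -1 if p.summit_offset is None else p.summit_offset
                    base += ["0", "-1", "-1", str(summit)]
                handle.write("\t".join(base) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing intervals to {path}: {exc}") from exc


def _build_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, plist in peaks.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples((p.start, p.end, p) for p in plist)
    return trees


def intersect_replicates(
    rep1: PeakSet,
    rep2: PeakSet,
    min_overlap: int = 1,
    mode: str = "rep1",
) -> PeakSet:
    """Peaks of ``rep1`` overlapping at least one ``rep2`` peak by
    ``min_overlap`` bp or more.

    ``mode`` controls the coordinates of the returned peaks:

    - ``rep1``: replicate-1 coordinates verbatim (default);
    - ``merge-union``: union span with the best-overlapping rep2 partner;
    - ``merge-intersection``: intersection span with the best partner.

    Output order follows ``rep1``; each rep1 peak is counted once however many
    rep2 peaks it touches.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if mode not in ("rep1", "merge-union", "merge-intersection"):
        raise ValueError(f"unknown mode {mode!r}")
    trees = _build_trees(rep2)
    kept: list[Peak] = []
    for p in rep1:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        best: Peak | None = None
        best_ov = 0
        for hit in tree.overlap(p.start, p.end):
            ov = min(p.end, hit.end) - max(p.start, hit.begin)
            if ov > best_ov:
                best_ov = ov
                best = hit.data
        if best_ov < min_overlap:
            continue
        if mode == "rep1":
            kept.append(p)
        elif mode == "merge-union":
            start = min(p.start, best.start)
            end = max(p.end, best.end)
            iv = replace(p.interval, start=start, end=end)
            kept.append(Peak(iv, None if p.summit_offset is None else p.anchor - start))
        else:  # merge-intersection
            start = max(p.start, best.start)
            end = min(p.end, best.end)
            iv = replace(p.interval, start=start, end=end)
            summit = None
            if p.summit_offset is not None and start <= p.anchor < end:
                summit = p.anchor - start
            kept.append(Peak(iv, summit))
    return PeakSet(kept, source_label=f"{rep1.source_label}&{rep2.source_label}")
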