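"""Seeded synthetic-data generator with planted ground truth.

Produces a miniature genome with stranded multi-exon genes, two replicate
peak sets whose shared peaks carry planted regulatory-class labels with
class-conditional bimodal flanking mark intervals and ATAC openness, peak
sequences with embedded TRE/CRE consensus motifs on a 0-order background,
and a two-contrast knockdown differential-expression table in which a
designated subset of peak-proximal genes carries concordant signed effects.

Every artifact is a pure function of :class:`SimConfig`.  A single global
seed feeds independent substreams per component (genome, genes, peaks,
marks, motifs, decoys, DE), so changing one component's parameters does not
shift the draws of the others.
"""

from __future__ import annotations

import bisect
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotate import GeneModel, write_gtf
from .chromatin_state import STATES
from .intervals_io import GenomicInterval, Peak, PeakSet, write_intervals
from .motif_scan import ALPHABET, PWM, build_pwm

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "default_tre_pfm",
    "default_cre_pfm",
    "simulate_genome",
    "simulate_cistrome",
    "simulate_de_tables",
    "simulate_all",
    "write_fasta",
]

_COMP = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G on integer codes

# class -> marks planted around the peak anchor
CLASS_MARKS = {
    "cAP": ("H3K27ac", "H3K4me3"),
    "cAE": ("H3K27ac", "H3K4me1"),
    "cIP": ("H3K4me3",),
    "cIE": ("H3K4me1",),
    "other": (),
}


@dataclass
class SimConfig:
    """Study conditions for a synthetic run (defaults are the reference
    configuration used throughout the test suite)."""

    seed: int = 1234
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 60
    n_peaks: int = 400
    class_proportions: dict = field(default_factory=lambda: {
        "other": 0.60, "cAE": 0.27, "cIE": 0.09, "cAP": 0.03, "cIP": 0.01,
    })
    open_prob_by_class: dict = field(default_factory=lambda: {
        "cAE": 0.964, "cAP": 0.928, "cIE": 0.60, "cIP": 0.60, "other": 0.10,
    })
    motif_rates: dict = field(default_factory=lambda: {"TRE": 0.90, "CRE": 0.20})
    gc_content: float = 0.41
    # DE model
    n_direct_targets: int = 20
    effect_mean: float = 1.0   # log2 units (2-fold)
    effect_sd: float = 0.1
    null_sd: float = 0.1
    p_scale: float = 0.1       # z-model scale linking |log2fc| to the p-value
    # cistrome geometry
    peak_width: tuple = (200, 400)
    flank_mark_offset: int = 600
    mark_halfwidth: int = 75
    mark_noise: float = 0.0
    atac_halfwidth: int = 150
    rep2_jitter: int = 50
    decoy_frac: float = 0.15
    min_peak_spacing: int = 1700
    margin: int = 3200
    gene_length: tuple = (3000, 10_000)
    contrasts: tuple = ("siRNA_1", "siRNA_2")

    def __post_init__(self) -> None:
        props = self.class_proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if set(props) - set(STATES):
            raise ValueError(f"unknown class in proportions: {set(props) - set(STATES)}")
        for p in list(self.open_prob_by_class.values()) + list(self.motif_rates.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.effect_mean <= 0:
            raise ValueError("effect_mean must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SimTruth:
    """Planted ground truth of a simulated run."""

    peak_class_labels: dict
    planted_motifs: dict
    direct_targets: dict       # gene -> "up"/"down"
    true_log2fc: dict
    shared_peak_names: list
    nearest_gene: dict         # peak -> gene id (or None)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=1, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimTruth":
        with open(path) as handle:
            raw = json.load(handle)
        raw["planted_motifs"] = {
            k: [tuple(x) for x in v] for k, v in raw["planted_motifs"].items()
        }
        return cls(**raw)


def default_tre_pfm() -> PWM:
    """TRE (AP-1) motif TGACTCA with a 60/40 C/G split at position 4."""
    cols = "T G A S T C A".split()
    counts = np.zeros((4, 7))
    for j, c in enumerate(cols):
        if c == "S":
            counts[1, j] = 60  # C
            counts[2, j] = 40  # G
        else:
            counts[ALPHABET.index(c), j] = 100
    return build_pwm(counts, name="TRE")


def default_cre_pfm() -> PWM:
    """CRE (AP-1/ATF) 8-bp palindrome TGACGTCA."""
    counts = np.zeros((4, 8))
    for j, c in enumerate("TGACGTCA"):
        counts[ALPHABET.index(c), j] = 100
    return build_pwm(counts, name="CRE")


def _largest_remainder(props: dict, total: int) -> dict:
    """Exact integer composition matching the proportions (largest remainder)."""
    raw = {k: v * total for k, v in props.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


def _spaced_positions(
    rng: np.random.Generator, n: int, length: int, spacing: int, margin: int
) -> np.ndarray:
    """n sorted positions in [margin, length - margin) at least ``spacing``
    apart, uniformly over the feasible region."""
    extra = length - 2 * margin - (n - 1) * spacing
    if n > 0 and extra < 0:
        raise ValueError(
            "cannot place elements with the requested spacing; "
            "increase chrom_length or reduce counts"
        )
    if n == 0:
        return np.empty(0, dtype=np.int64)
    slack = np.sort(rng.uniform(0, extra, size=n)).astype(np.int64)
    return margin + spacing * np.arange(n) + slack


def simulate_genome(config: SimConfig) -> tuple[dict, list[GeneModel]]:
    """I.i.d. genome with the configured GC content plus non-overlapping
    stranded multi-exon genes.  Returns (chrom -> uint8 code array, genes)."""
    if config.chrom_length < 100 * config.n_genes / config.n_chroms:
        raise ValueError("chromosomes too short for the requested gene count")
    rng_seq = config.rng(0)
    gc = config.gc_content
    base_p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = {
        chrom: rng_seq.choice(4, size=config.chrom_length, p=base_p).astype(np.uint8)
        for chrom in config.chrom_names()
    }
    rng_genes = config.rng(1)
    genes: list[GeneModel] = []
    chroms = config.chrom_names()
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gi = 0
    for chrom, n_c in zip(chroms, per_chrom):
        lengths = rng_genes.integers(
            config.gene_length[0], config.gene_length[1] + 1, size=n_c
        )
        slack = config.chrom_length - 2_000 - int(lengths.sum())
        if slack < n_c:
            raise ValueError("genes do not fit; increase chrom_length")
        gaps = rng_genes.uniform(0, 1, size=n_c + 1)
        gaps = (gaps / gaps.sum() * slack).astype(np.int64)
        cursor = 1_000
        for k in range(n_c):
            cursor += int(gaps[k])
            start, end = cursor, cursor + int(lengths[k])
            strand = "+" if rng_genes.random() < 0.5 else "-"
            n_ex = int(rng_genes.integers(2, 9))
            cuts = np.sort(
                rng_genes.choice(int(lengths[k]) + 1, size=2 * n_ex, replace=False)
            )
            exons = tuple(
                (start + int(cuts[2 * e]), start + int(cuts[2 * e + 1]))
                for e in range(n_ex)
                if cuts[2 * e] < cuts[2 * e + 1]
            )
            if not exons:
                exons = ((start, end),)
            genes.append(
                GeneModel(f"gene_{gi:03d}", chrom, strand, start, end, exons)
            )
            cursor = end
            gi += 1
    return genome, genes


def _plant_motif(
    genome: dict, chrom: str, pos: int, consensus: str, strand: str
) -> None:
    codes = [ALPHABET.index(c) for c in consensus]
    if strand == "-":
        codes = [_COMP[c] for c in reversed(codes)]
    genome[chrom][pos:pos + len(codes)] = np.array(codes, dtype=np.uint8)


def simulate_cistrome(
    config: SimConfig, genome: dict, genes: list[GeneModel]
) -> tuple[PeakSet, PeakSet, dict, PeakSet, SimTruth]:
    """Replicate peak sets, mark/ATAC interval tracks and the planted truth.

    Shared peaks (present in both replicates, replicate 2 jittered by at most
    ``rep2_jitter`` bp) carry the class labels; each replicate additionally
    receives ``decoy_frac * n_peaks`` replicate-specific decoy peaks placed
    away from every other peak so that replicate intersection truth is exact.
    Motif consensus strings are embedded in place (no insertion) within
    shared peaks at the configured rates.
    """
    rng_peaks = config.rng(2)
    rng_marks = config.rng(3)
    rng_motifs = config.rng(4)
    rng_decoys = config.rng(5)
    chroms = config.chrom_names()
    L = config.chrom_length

    per_chrom = [config.n_peaks // config.n_chroms] * config.n_chroms
    for i in range(config.n_peaks % config.n_chroms):
        per_chrom[i] += 1
    anchors: list[tuple[str, int]] = []
    for chrom, n_c in zip(chroms, per_chrom):
        for pos in _spaced_positions(
            rng_peaks, n_c, L, config.min_peak_spacing, config.margin
        ):
            anchors.append((chrom, int(pos)))

    counts = _largest_remainder(config.class_proportions, config.n_peaks)
    labels = [s for s in STATES for _ in range(counts.get(s, 0))]
    labels = [labels[i] for i in rng_peaks.permutation(config.n_peaks)]

    wlo, whi = config.peak_width
    shared_r1: list[Peak] = []
    shared_r2: list[Peak] = []
    truth_labels: dict[str, str] = {}
    mark_intervals: dict[str, list[GenomicInterval]] = {m: [] for m in
                                                       ("H3K27ac", "H3K4me1", "H3K4me3")}
    atac_intervals: list[GenomicInterval] = []
    for i, ((chrom, anchor), label) in enumerate(zip(anchors, labels)):
        width = int(rng_peaks.integers(wlo, whi + 1))
        offset = int(rng_peaks.integers(int(0.3 * width), int(0.7 * width) + 1))
        start = anchor - offset
        name = f"peak_{i:04d}"
        shared_r1.append(
            Peak(GenomicInterval(chrom, start, start + width, name), offset)
        )
        jitter = int(rng_peaks.integers(-config.rep2_jitter, config.rep2_jitter + 1))
        shared_r2.append(
            Peak(
                GenomicInterval(chrom, start + jitter, start + width + jitter,
                                f"r2_{name}"),
                offset,
            )
        )
        truth_labels[name] = label
        planted = set(CLASS_MARKS[label])
        for mark in mark_intervals:
            present = mark in planted
            if config.mark_noise > 0 and rng_marks.random() < config.mark_noise:
                present = not present
            if present:
                for side in (-1, 1):
                    centre = anchor + side * config.flank_mark_offset
                    mark_intervals[mark].append(
                        GenomicInterval(
                            chrom,
                            centre - config.mark_halfwidth,
                            centre + config.mark_halfwidth,
                        )
                    )
        if rng_marks.random() < config.open_prob_by_class[label]:
            atac_intervals.append(
                GenomicInterval(
                    chrom, anchor - config.atac_halfwidth,
                    anchor + config.atac_halfwidth,
                )
            )

    # replicate-specific decoys, kept clear of everything else
    taken: dict[str, list[int]] = {c: [] for c in chroms}
    for chrom, anchor in anchors:
        bisect.insort(taken[chrom], anchor)
    n_decoy = round(config.decoy_frac * config.n_peaks)
    decoys: dict[str, list[Peak]] = {"r1": [], "r2": []}
    min_sep = 2 * config.rep2_jitter + whi + 200
    for rep in ("r1", "r2"):
        placed = 0
        tries = 0
        while placed < n_decoy:
            tries += 1
            if tries > 200 * max(n_decoy, 1):
                raise ValueError(
                    "could not place decoy peaks; increase chrom_length"
                )
            chrom = chroms[int(rng_decoys.integers(config.n_chroms))]
            anchor = int(rng_decoys.integers(config.margin, L - config.margin))
            idx = bisect.bisect_left(taken[chrom], anchor)
            neighbours = taken[chrom][max(0, idx - 1):idx + 1]
            if any(abs(anchor - nb) < min_sep for nb in neighbours):
                continue
            width = int(rng_decoys.integers(wlo, whi + 1))
            off = width // 2
            decoys[rep].append(
                Peak(
                    GenomicInterval(chrom, anchor - off, anchor - off + width,
                                    f"{rep}_decoy_{placed:03d}"),
                    off,
                )
            )
            bisect.insort(taken[chrom], anchor)
            placed += 1

    def _ordered(peaks: list[Peak]) -> list[Peak]:
        return sorted(peaks, key=lambda p: (p.chrom, p.start, p.name))

    rep1 = PeakSet(_ordered(shared_r1 + decoys["r1"]), source_label="rep1")
    rep2 = PeakSet(_ordered(shared_r2 + decoys["r2"]), source_label="rep2")
    marks = {
        name: PeakSet(
            [Peak(iv) for iv in sorted(ivs, key=lambda iv: (iv.chrom, iv.start))],
            source_label=name,
        )
        for name, ivs in mark_intervals.items()
    }
    atac = PeakSet(
        [Peak(iv) for iv in sorted(atac_intervals, key=lambda iv: (iv.chrom, iv.start))],
        source_label="ATAC",
    )

    # motif planting (sequence edited in place; coordinates stay fixed)
    pwms = {"TRE": default_tre_pfm(), "CRE": default_cre_pfm()}
    consensus = {name: pwm.consensus().replace("S", "C") for name, pwm in pwms.items()}
    planted_motifs: dict[str, list[tuple[str, int, str]]] = {}
    for p in shared_r1:
        entries: list[tuple[str, int, str]] = []
        occupied: list[tuple[int, int]] = []
        for mname in sorted(config.motif_rates):
            if rng_motifs.random() >= config.motif_rates[mname]:
                continue
            word = consensus[mname]
            wlen = len(word)
            for _ in range(50):
                off = int(rng_motifs.integers(10, p.interval.length - wlen - 10))
                if all(off + wlen <= s or off >= e for s, e in occupied):
                    strand = "+" if rng_motifs.random() < 0.5 else "-"
                    _plant_motif(genome, p.chrom, p.start + off, word, strand)
                    occupied.append((off, off + wlen))
                    entries.append((mname, off, strand))
                    break
        planted_motifs[p.name] = entries

    # nearest-TSS truth by direct all-pairs search
    nearest: dict[str, str | None] = {}
    for p in shared_r1:
        candidates = [g for g in genes if g.chrom == p.chrom]
        if not candidates:
            nearest[p.name] = None
            continue
        best = min(candidates, key=lambda g: (abs(p.anchor - g.tss), g.gene_id))
        nearest[p.name] = best.gene_id

    truth = SimTruth(
        peak_class_labels=truth_labels,
        planted_motifs=planted_motifs,
        direct_targets={},
        true_log2fc={},
        shared_peak_names=[p.name for p in _ordered(shared_r1)],
        nearest_gene=nearest,
    )
    return rep1, rep2, marks, atac, truth


def simulate_de_tables(
    config: SimConfig, genes: list[GeneModel], truth: SimTruth
) -> pd.DataFrame:
    """Two-contrast DE table with concordant planted effects on direct
    targets.  P-values follow a one-sample z-model, ``p = 2 * Phi(-|log2fc| /
    p_scale)``, so planted targets pass the fold/FDR filter at zero noise and
    null genes fail at the configured rates.  Fills the ``direct_targets``
    and ``true_log2fc`` fields of ``truth`` in place.
    """
    rng = config.rng(6)
    eligible = sorted(
        {
            truth.nearest_gene[p]
            for p in truth.shared_peak_names
            if truth.peak_class_labels[p] != "other"
            and truth.nearest_gene.get(p) is not None
        }
    )
    if config.n_direct_targets > len(eligible):
        raise ValueError(
            f"only {len(eligible)} genes receive classified peaks; cannot "
            f"plant {config.n_direct_targets} direct targets"
        )
    targets = sorted(
        rng.choice(eligible, size=config.n_direct_targets, replace=False).tolist()
    )
    directions = {
        g: ("up" if rng.random() < 0.5 else "down") for g in targets
    }
    truth.direct_targets = directions
    truth.true_log2fc = {
        g.gene_id: (
            (config.effect_mean if directions[g.gene_id] == "up" else -config.effect_mean)
            if g.gene_id in directions else 0.0
        )
        for g in genes
    }
    rows = []
    for contrast in config.contrasts:
        for g in sorted(genes, key=lambda g: g.gene_id):
            if g.gene_id in directions:
                sign = 1.0 if directions[g.gene_id] == "up" else -1.0
                fc = sign * rng.normal(config.effect_mean, config.effect_sd)
            else:
                fc = rng.normal(0.0, config.null_sd)
            p = float(np.clip(2 * norm.sf(abs(fc) / config.p_scale), 1e-300, 1.0))
            rows.append(
                {"gene_id": g.gene_id, "contrast": contrast,
                 "log2fc": fc, "pvalue": p}
            )
    return pd.DataFrame(rows)


def decode_genome(genome: dict) -> dict:
    """uint8 code arrays -> plain sequence strings."""
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return {
        chrom: lut[codes].tobytes().decode("ascii")
        for chrom, codes in genome.items()
    }


def write_fasta(sequences: dict, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(sequences):
            handle.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


@dataclass
class SimData:
    """All artifacts of one simulated run, in memory."""

    config: SimConfig
    sequences: dict
    genes: list
    rep1: PeakSet
    rep2: PeakSet
    marks: dict
    atac: PeakSet
    de_table: pd.DataFrame
    truth: SimTruth

    def write(self, outdir: str | os.PathLike) -> dict:
        """Write every artifact as plain text; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "gtf": out / "genes.gtf",
            "rep1": out / "rep1.narrowPeak",
            "rep2": out / "rep2.narrowPeak",
            "atac": out / "atac.bed",
            "de": out / "de.tsv",
            "truth": out / "truth.json",
        }
        write_fasta(self.sequences, paths["fasta"])
        write_gtf(self.genes, paths["gtf"])
        write_intervals(self.rep1, paths["rep1"], "narrowpeak")
        write_intervals(self.rep2, paths["rep2"], "narrowpeak")
        write_intervals(self.atac, paths["atac"], "bed")
        for mark, ps in self.marks.items():
            paths[mark] = out / f"{mark}.bed"
            write_intervals(ps, paths[mark], "bed")
        self.de_table.to_csv(paths["de"], sep="\t", index=False)
        self.truth.to_json(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def simulate_all(config: SimConfig | None = None) -> SimData:
    """Run the full generator: genome, genes, cistrome, motifs, DE tables."""
    config = config or SimConfig()
    genome, genes = simulate_genome(config)
    rep1, rep2, marks, atac, truth = simulate_cistrome(config, genome, genes)
    de_table = simulate_de_tables(config, genes, truth)
    return SimData(
        config=config,
        sequences=decode_genome(genome),
        genes=genes,
        rep1=rep1,
        rep2=rep2,
        marks=marks,
        atac=atac,
        de_table=de_table,
        truth=truth,
    )
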