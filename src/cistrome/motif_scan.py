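"""PWM construction, log-odds scanning of both strands, and exact score
p-values under a 0-order background.

Scores are in bits (log2 odds).  At construction the log-odds matrix is
discretized to a fixed grid (default 1e-3 bits per step); the score
distribution of a random background string is then obtained by an exact
dynamic-programming convolution of the per-column integer score
distributions, so ``exact_score_pvalue`` carries no approximation beyond the
initial discretization (whose worst-case score error, ``width * grid / 2``,
is checked at construction).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals_io import Peak, PeakSet

__all__ = [
    "PWM",
    "MotifHit",
    "build_pwm",
    "read_pfm",
    "scan_sequence",
    "exact_score_pvalue",
    "peak_motif_fractions",
    "fetch_sequence",
]

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AC"): "M", frozenset("AG"): "R",
    frozenset("AT"): "W", frozenset("CG"): "S", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class MotifHit:
    peak_name: str
    offset: int
    strand: str
    score: float
    pvalue: float


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over A/C/G/T with its background model.

    ``log_odds`` is derived from the pseudocounted probability matrix and
    snapped to the discretization grid; ``int_scores`` holds the same values
    as integer grid steps (``log_odds = grid * int_scores`` exactly).
    """

    name: str
    counts: np.ndarray
    pseudocount: float
    background: np.ndarray
    grid: float
    log_odds: np.ndarray = field(repr=False)
    int_scores: np.ndarray = field(repr=False)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0) + self.pseudocount
        return (self.counts + self.pseudocount * self.background[:, None]) / colsum

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def consensus(self) -> str:
        """Argmax letter per column, IUPAC code where runners-up are within
        2-fold of the column maximum."""
        probs = self.probabilities
        out = []
        for j in range(self.width):
            col = probs[:, j]
            top = col.max()
            letters = frozenset(ALPHABET[i] for i in range(4) if col[i] >= top / 2)
            out.append(_IUPAC[letters])
        return "".join(out)

    def with_background(self, background: Sequence[float]) -> "PWM":
        return build_pwm(
            self.counts, name=self.name, pseudocount=self.pseudocount,
            background=background, grid=self.grid,
        )

    def reverse_complement_matrix(self) -> np.ndarray:
        """Integer score matrix that scores the reverse complement of a
        forward-strand window."""
        return self.int_scores[::-1, ::-1]

    def score_distribution(self) -> tuple[int, np.ndarray]:
        """Exact distribution of the integer score of a background string.

        Returns ``(base, probs)`` where ``probs[k]`` is the probability of
        integer score ``base + k``.
        """
        cached = getattr(self, "_dist", None)
        if cached is not None:
            return cached
        dist = np.array([1.0])
        base = 0
        for j in range(self.width):
            col = self.int_scores[:, j]
            lo, hi = int(col.min()), int(col.max())
            new = np.zeros(len(dist) + (hi - lo), dtype=float)
            for b in range(4):
                off = int(col[b]) - lo
                new[off:off + len(dist)] += self.background[b] * dist
            dist = new
            base += lo
        object.__setattr__(self, "_dist", (base, dist))
        return base, dist

    def survival(self) -> tuple[int, np.ndarray]:
        """``(base, sf)`` with ``sf[k] = P(integer score >= base + k)``."""
        base, dist = self.score_distribution()
        return base, np.cumsum(dist[::-1])[::-1]

    def score_threshold(self, threshold_p: float) -> int | None:
        """Smallest achievable integer score whose p-value is <= threshold_p,
        or None when even the maximum score is not significant."""
        base, sf = self.survival()
        idx = np.nonzero(sf <= threshold_p)[0]
        if idx.size == 0:
            return None
        return base + int(idx[0])


def build_pwm(
    pfm: np.ndarray | Sequence[Sequence[float]],
    name: str = "pwm",
    pseudocount: float = 0.1,
    background: Sequence[float] | None = None,
    grid: float = 1e-3,
    max_score_error: float = 0.02,
) -> PWM:
    """Build a PWM from a 4 x width count (or frequency) matrix.

    Probabilities are ``(count + pseudocount * bg) / (colsum + pseudocount)``;
    log-odds against the background are snapped to the ``grid`` (bits).  The
    worst-case total score discretization error ``width * grid / 2`` must stay
    below ``max_score_error`` or construction refuses.
    """
    counts = np.asarray(pfm, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("PFM must be a 4 x width matrix (rows A, C, G, T)")
    if counts.shape[1] < 4:
        raise ValueError("PWM width must be >= 4")
    if (counts < 0).any():
        raise ValueError("PFM counts must be non-negative")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("PFM has an all-zero column")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities")
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must sum to 1")
    bg = bg / bg.sum()
    width = counts.shape[1]
    if width * grid / 2 > max_score_error:
        raise ValueError(
            f"discretization grid {grid} too coarse for width {width}: "
            f"score error bound {width * grid / 2:.3g} bits exceeds "
            f"{max_score_error}; use a finer grid"
        )
    colsum = counts.sum(axis=0) + pseudocount
    probs = (counts + pseudocount * bg[:, None]) / colsum
    raw = np.log2(probs / bg[:, None])
    int_scores = np.rint(raw / grid).astype(np.int64)
    log_odds = int_scores * grid
    return PWM(
        name=name, counts=counts, pseudocount=pseudocount, background=bg,
        grid=grid, log_odds=log_odds, int_scores=int_scores,
    )


def read_pfm(path: str | os.PathLike, format: str = "jaspar") -> list[PWM]:
    """Read position frequency matrices (JASPAR text or MEME minimal format)
    and build PWMs with default pseudocount and uniform background."""
    from Bio import motifs as bio_motifs

    fmt = {"jaspar": "jaspar", "meme": "minimal", "minimal": "minimal"}.get(
        format.lower()
    )
    if fmt is None:
        raise ValueError(f"unknown PFM format {format!r}")
    out: list[PWM] = []
    with open(path) as handle:
        records = bio_motifs.parse(handle, fmt)
        for m in records:
            counts = np.array([list(m.counts[base]) for base in ALPHABET])
            name = m.name or getattr(m, "matrix_id", None) or "pwm"
            out.append(build_pwm(counts, name=name))
    return out


def exact_score_pvalue(pwm: PWM, score: float) -> float:
    """P(S >= score) for the log-odds score S of a random background string.

    Monotone non-increasing in ``score``; 1 at or below the minimum
    achievable score, 0 above the maximum.
    """
    if math.isinf(score):
        return 1.0 if score < 0 else 0.0
    base, sf = pwm.survival()
    # snap to the grid: scores of real windows are exact grid multiples
    t = math.ceil((score - 1e-9) / pwm.grid)
    if t <= base:
        return 1.0
    if t > base + len(sf) - 1:
        return 0.0
    return float(sf[t - base])


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0 C=1 G=2 T=3, anything else -1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for letter, code in _CODE.items():
        codes[arr == ord(letter)] = code
    return codes


def _window_int_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Integer scores of every window of len(matrix columns) over ``codes``;
    windows containing non-ACGT positions are returned as int min."""
    w = matrix.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = codes < 0
    safe = np.where(bad, 0, codes)
    scores = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(w):
        scores += matrix[safe[j:j + n], j]
        invalid |= bad[j:j + n]
    scores[invalid] = np.iinfo(np.int64).min
    return scores


def scan_sequence(
    seq: str, pwm: PWM, threshold_p: float = 1e-4, peak_name: str = ""
) -> list[MotifHit]:
    """Score every window of both strands and report hits with exact
    p-value <= ``threshold_p``.

    Windows containing N are skipped.  Reverse-strand windows are scored on
    the reverse complement; hits are sorted by offset, then strand ('+'
    first).
    """
    if not (0 < threshold_p < 1):
        raise ValueError("threshold_p must be in (0, 1)")
    w = pwm.width
    if len(seq) < w:
        return []
    thr = pwm.score_threshold(threshold_p)
    if thr is None:
        return []
    base, sf = pwm.survival()
    codes = encode(seq)
    hits: list[MotifHit] = []
    for strand, matrix in (
        ("+", pwm.int_scores),
        ("-", pwm.reverse_complement_matrix()),
    ):
        scores = _window_int_scores(codes, matrix)
        for offset in np.nonzero(scores >= thr)[0]:
            q = int(scores[offset])
            hits.append(
                MotifHit(
                    peak_name=peak_name,
                    offset=int(offset),
                    strand=strand,
                    score=q * pwm.grid,
                    pvalue=float(sf[q - base]),
                )
            )
    hits.sort(key=lambda h: (h.offset, 0 if h.strand == "+" else 1))
    return hits


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Slice ``[start, end)`` from a genome source (dict of strings or an
    indexed FASTA such as ``pyfaidx.Fasta``)."""
    record = genome[chrom]
    return str(record[start:end])


def peak_motif_fractions(
    peaks: PeakSet,
    genome,
    pwms: Sequence[PWM],
    threshold_p: float = 1e-4,
    background: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[MotifHit]]:
    """Fraction of peaks containing >= 1 hit of each PWM.

    The 0-order background is estimated from the scanned peak sequences
    unless given explicitly, and each PWM is rebuilt against it.  Returns the
    per-PWM summary, the per-peak boolean table, and the full hit list.
    """
    seqs: dict[str, str] = {}
    for p in peaks:
        seq = fetch_sequence(genome, p.chrom, p.start, p.end)
        if len(seq) != p.end - p.start:
            raise ValueError(
                f"peak {p.name} extends outside chromosome {p.chrom}"
            )
        seqs[p.name] = seq
    if not pwms:
        return (
            pd.DataFrame(columns=["pwm", "n_peaks_with_hit", "fraction"]),
            pd.DataFrame(index=list(seqs)),
            [],
        )
    if background is None and seqs:
        counts = np.ones(4)  # pseudocount guards all-N or single-letter input
        for seq in seqs.values():
            codes = encode(seq)
            counts += np.bincount(codes[codes >= 0], minlength=4)
        background = counts / counts.sum()
    scaled = [p.with_background(background) for p in pwms]
    bool_table = pd.DataFrame(index=list(seqs), dtype=bool)
    all_hits: list[MotifHit] = []
    rows = []
    for pwm in scaled:
        flags = {}
        for name, seq in seqs.items():
            hits = scan_sequence(seq, pwm, threshold_p, peak_name=name)
            flags[name] = bool(hits)
            all_hits.extend(hits)
        bool_table[pwm.name] = pd.Series(flags)
        n_hit = sum(flags.values())
        rows.append(
            {
                "pwm": pwm.name,
                "n_peaks_with_hit": n_hit,
                "fraction": n_hit / len(seqs) if seqs else float("nan"),
            }
        )
    return pd.DataFrame(rows), bool_table, all_hits
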