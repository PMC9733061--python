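"""PWM construction, exact score p-values, and both-strand scanning."""

import itertools
import math

import numpy as np
import pytest

from cistrome.intervals_io import GenomicInterval, Peak, PeakSet
from cistrome.motif_scan import (
    ALPHABET,
    build_pwm,
    exact_score_pvalue,
    peak_motif_fractions,
    read_pfm,
    scan_sequence,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(COMP)[::-1]


def enumerate_distribution(pwm):
    """Exhaustive oracle: score and probability of every width-length string."""
    scores, probs = [], []
    for word in itertools.product(range(4), repeat=pwm.width):
        scores.append(sum(pwm.log_odds[b, j] for j, b in enumerate(word)))
        probs.append(math.prod(pwm.background[b] for b in word))
    return np.array(scores), np.array(probs)


def oracle_scan(seq, pwm, threshold_p):
    """Score every window of both strands the slow way."""
    hits = []
    w = pwm.width
    for strand in "+-":
        for off in range(len(seq) - w + 1):
            window = seq[off:off + w]
            if strand == "-":
                window = revcomp(window)
            if any(c not in ALPHABET for c in window):
                continue
            score = sum(
                pwm.log_odds[ALPHABET.index(c), j] for j, c in enumerate(window)
            )
            p = exact_score_pvalue(pwm, score)
            if p <= threshold_p:
                hits.append((off, strand))
    return sorted(hits, key=lambda h: (h[0], 0 if h[1] == "+" else 1))


def random_pfm(rng, width, sharpness=20.0):
    return rng.dirichlet([0.5] * 4, size=width).T * sharpness + 0.5


class TestBuildPwm:
    def test_concentrated_column_log_odds(self):
        counts = np.zeros((4, 4))
        counts[3, :] = 100  # all-T columns
        pwm = build_pwm(counts, pseudocount=0.25)
        # prob = (100 + 0.25*0.25) / (100 + 0.25); odds vs 0.25
        expected = math.log2((100.0625 / 100.25) / 0.25)
        assert pwm.log_odds[3, 0] == pytest.approx(expected, abs=1e-3)

    def test_uniform_column_scores_zero(self):
        counts = np.full((4, 4), 25.0)
        pwm = build_pwm(counts)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_tre_consensus_string(self, tre_pwm):
        assert tre_pwm.consensus() == "TGASTCA"

    def test_cre_consensus_string(self, cre_pwm):
        assert cre_pwm.consensus() == "TGACGTCA"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(np.zeros((4, 4)))
        good = np.full((4, 4), 10.0)
        with pytest.raises(ValueError):
            build_pwm(good, background=[0.0, 0.5, 0.25, 0.25])
        with pytest.raises(ValueError):
            build_pwm(good, grid=0.5)  # error bound advisory refuses

    def test_jaspar_round_trip(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0000.1 TEST\n"
            "A [ 10  0 80  5 ]\n"
            "C [  5  0 10  5 ]\n"
            "G [  5 90  5  5 ]\n"
            "T [ 80 10  5 85 ]\n"
        )
        pwm = read_pfm(path, "jaspar")[0]
        assert pwm.width == 4
        assert pwm.consensus() == "TGAT"


class TestExactPvalue:
    def test_single_column_best_letter(self):
        counts = np.zeros((4, 4))
        for j in range(4):
            counts[j % 4, j] = 100
        pwm = build_pwm(counts)
        # only the consensus word achieves the maximum score
        assert exact_score_pvalue(pwm, pwm.max_score) == pytest.approx(
            0.25 ** 4, abs=1e-9
        )

    def test_total_probability_at_minimum(self, tre_pwm):
        assert exact_score_pvalue(tre_pwm, tre_pwm.min_score) == pytest.approx(1.0)
        assert exact_score_pvalue(tre_pwm, -1e9) == 1.0

    @pytest.mark.parametrize("width", [4, 5])
    def test_dp_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        for trial in range(3):
            bg = rng.dirichlet([5] * 4)
            pwm = build_pwm(random_pfm(rng, width), background=bg)
            scores, probs = enumerate_distribution(pwm)
            for t in np.quantile(scores, [0.0, 0.1, 0.5, 0.9, 1.0]):
                expected = probs[scores >= t - 1e-9].sum()
                assert exact_score_pvalue(pwm, t) == pytest.approx(
                    expected, abs=1e-9
                )

    def test_monotone_non_increasing(self, tre_pwm):
        grid = np.linspace(tre_pwm.min_score - 1, tre_pwm.max_score + 1, 200)
        ps = [exact_score_pvalue(tre_pwm, s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestScan:
    def test_consensus_self_match_both_strands(self, tre_pwm):
        # TGAGTCA: '+' window is the G-variant, '-' reads TGACTCA (argmax)
        hits = scan_sequence("TGAGTCA", tre_pwm, threshold_p=1e-3)
        assert [(h.offset, h.strand) for h in hits] == [(0, "+"), (0, "-")]
        # at the stricter default only the C-variant string is significant
        strict = scan_sequence("TGACTCA", tre_pwm, threshold_p=1e-4)
        assert [(h.offset, h.strand) for h in strict] == [(0, "+")]

    def test_homopolymer_has_no_hits(self, tre_pwm, cre_pwm):
        for pwm in (tre_pwm, cre_pwm):
            assert scan_sequence("A" * 50, pwm, 1e-4) == []

    def test_sequence_shorter_than_width_is_empty(self, tre_pwm):
        assert scan_sequence("TGA", tre_pwm) == []

    def test_n_windows_skipped(self, tre_pwm):
        hits = scan_sequence("TGANTCA", tre_pwm, threshold_p=0.5)
        assert hits == []

    def test_matches_brute_force_scan(self, tre_pwm):
        rng = np.random.default_rng(77)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), 300))
            pwm = build_pwm(random_pfm(rng, 6), name="r")
            got = [(h.offset, h.strand) for h in scan_sequence(seq, pwm, 1e-3)]
            assert got == oracle_scan(seq, pwm, 1e-3)

    def test_reverse_complement_symmetry(self, tre_pwm):
        rng = np.random.default_rng(78)
        seq = "".join(rng.choice(list("ACGT"), 200))
        fwd = scan_sequence(seq, tre_pwm, 1e-3)
        rev = scan_sequence(revcomp(seq), tre_pwm, 1e-3)
        L, w = len(seq), tre_pwm.width
        mirrored = sorted(
            (L - w - h.offset, "+" if h.strand == "-" else "-", round(h.score, 6))
            for h in rev
        )
        assert mirrored == sorted(
            (h.offset, h.strand, round(h.score, 6)) for h in fwd
        )


class TestPeakFractions:
    def _peakset_with_sequences(self, seqs):
        genome = {"chr1": "".join(seqs)}
        peaks, pos = [], 0
        for i, s in enumerate(seqs):
            peaks.append(
                Peak(GenomicInterval("chr1", pos, pos + len(s), f"p{i}"))
            )
            pos += len(s)
        return PeakSet(peaks), genome

    def test_planted_nine_of_ten(self, tre_pwm):
        rng = np.random.default_rng(5)
        seqs = []
        for i in range(10):
            # low-complexity background with no chance consensus hits
            s = list("".join(rng.choice(list("AT"), 60)))
            if i < 9:
                s[20:27] = "TGACTCA"
            seqs.append("".join(s))
        peaks, genome = self._peakset_with_sequences(seqs)
        summary, booltab, _ = peak_motif_fractions(
            peaks, genome, [tre_pwm], threshold_p=1e-4,
            background=[0.25] * 4,
        )
        assert summary.iloc[0]["fraction"] == pytest.approx(0.9)

    def test_no_pwms_gives_empty_table(self, default_sim):
        summary, booltab, hits = peak_motif_fractions(
            default_sim.rep1, default_sim.sequences, []
        )
        assert summary.empty and hits == []

    def test_peak_outside_chromosome_raises(self, tre_pwm):
        peaks = PeakSet([Peak(GenomicInterval("chr1", 90, 200, "p"))])
        with pytest.raises(ValueError, match="p"):
            peak_motif_fractions(peaks, {"chr1": "A" * 100}, [tre_pwm])

    def test_planted_rates_recovered_within_3se(self, default_sim, default_pipeline):
        cfg = default_sim.config
        n = cfg.n_peaks
        table = default_pipeline.motif_table.set_index("pwm")
        for name, rate in cfg.motif_rates.items():
            se = math.sqrt(rate * (1 - rate) / n)
            # background hits can only add; planted hits are never missed
            assert table.loc[name, "fraction"] >= rate - 3 * se
            assert table.loc[name, "fraction"] <= rate + 3 * se + 0.05

    def test_fraction_invariant_to_peak_order(self, tre_pwm):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(20)]
        peaks, genome = self._peakset_with_sequences(seqs)
        shuffled = PeakSet([peaks[i] for i in rng.permutation(len(peaks))])
        s1, _, _ = peak_motif_fractions(peaks, genome, [tre_pwm])
        s2, _, _ = peak_motif_fractions(shuffled, genome, [tre_pwm])
        assert s1.iloc[0]["fraction"] == s2.iloc[0]["fraction"]
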