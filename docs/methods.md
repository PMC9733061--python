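# Methods

This note records the models and procedures the package implements, the
parameters that matter, the design choices made where conventions diverge,
and what the synthetic benchmark does and does not demonstrate.

## Interval model and replicate intersection

All coordinates are 0-based half-open internally (BED convention); GTF input
(1-based inclusive) is converted at the reader boundary. Overlap of
`[a, b)` and `[c, d)` is `max(0, min(b, d) − max(a, c))`, so abutting
intervals do not overlap and a 1-bp touch does.

Replicate-consistent peaks are the replicate-1 peaks overlapping at least
one replicate-2 peak by `min_overlap` bp (default 1). Reported coordinates
are replicate 1's verbatim (`mode="rep1"`); union/intersection spans with
the best-overlapping partner are available but change coordinates, not
membership. Each replicate-1 peak is counted once however many partners it
touches.

## Peak annotation

The annotation point is the peak *anchor*: the narrowPeak summit when
present, else the interval midpoint — the summit is the natural point source
of a transcription-factor ChIP signal. Categories are assigned with
precedence `promoter > exon > intron > downstream > intergenic` evaluated
over all genes, so a peak that is simultaneously upstream of one gene and
inside another is called a promoter; promoter-first matches the intent of
counting promoter binding. Windows: promoter = 10 kb upstream of a TSS
(inclusive at exactly 10 kb, strand-aware); downstream = 10 kb past the TTS.
Both are parameters.

Nearest-TSS assignment searches the whole chromosome with no distance cap;
ties in absolute distance break to the lexicographically smaller gene id and
are flagged. The signed distance is `(anchor − tss) × strand_sign`, negative
upstream of the gene in its own orientation. Distance histograms use closed
right boundaries ("within 50 kb" means ≤ 50 000 bp). When a GTF supplies
several transcripts per gene, the longest is used, avoiding double counting
of genes in downstream set logic.

## Chromatin-state classification

Mark presence is interval-overlap based: a mark is present at a peak when
any of its intervals overlaps `[anchor − flank, anchor + flank)` by ≥ 1 bp
(`flank` default 1 kb). A numeric signal threshold is deliberately not used
— published mark tracks arrive as peak calls of heterogeneous depth, and an
overlap rule is reproducible without depth calibration. The rule table over
(H3K27ac, H3K4me1, H3K4me3):

| ac | me1 | me3 | state |
|----|-----|-----|-------|
| 1  | any | 1   | cAP   |
| 1  | 1   | 0   | cAE   |
| 0  | any | 1   | cIP   |
| 0  | 1   | 0   | cIE   |
| 1  | 0   | 0   | other |
| 0  | 0   | 0   | other |

The promoter mark dominates when all three co-occur, following standard
chromatin-state conventions. The table is total and mutually exclusive on
the 8-element boolean cube; swapping the me1/me3 tracks maps enhancer states
to promoter states and vice versa.

Signal matrices count mark-element midpoints in 60 bins of 100 bp centred
on anchors (6 kb total; both are flags). Midpoint binning is the simplest
deterministic fragment-centre proxy; no read extension or shifting is
applied. Open chromatin is ≥ 1 bp overlap between the *full* peak interval
and any ATAC interval — openness is a property of the element, not of the
anchor's immediate vicinity.

## Motif scanning and exact p-values

PWMs are built from count matrices with per-cell pseudocount
`pc · background` and column normalization by `colsum + pc` (pc default
0.1); log-odds are in bits. At construction the log-odds matrix is snapped
to a 1e−3-bit grid; the worst-case total score error, `width · grid / 2`, is
checked and construction refuses if it exceeds 0.02 bits. On that grid the
null score distribution of a background string is computed *exactly* by
convolving the per-column integer score distributions, so
`exact_score_pvalue` is an exact tail probability for the scored model —
this is why the DP matches exhaustive enumeration over all `4^w` strings to
float round-off in the tests.

Scanning scores every window on both strands (reverse strand via the
reverse-complemented matrix), skips windows containing N rather than scoring
them with background odds, reports all overlapping hits (no greedy masking),
and keeps hits with p ≤ 1e−4 (the common default of motif-occurrence
scanners; exposed as a flag). The 0-order background is estimated from the
scanned sequences unless supplied. A practical note on the threshold: a
strict 7-bp consensus has a minimal achievable p-value of roughly 6e−5
under a GC≈0.41 background, so 1e−4 admits exact consensus matches but not
their one-off degenerate variants; wider or softer matrices relax this.

## Differential expression and concordance

Inputs are per-gene, per-contrast tables of log2 fold change and p-value;
model fitting is upstream and out of scope. Multiple testing uses
Benjamini–Hochberg per contrast (via statsmodels), computed only when an
`fdr` column is absent. Selection is |log2fc| ≥ log2(1.25) (inclusive) and
FDR < 0.05 (strict). No upper fold cap is applied by default — an upper cap
would discard the strongest responders — but `max_fold` exists. The
high-confidence set is the direction-wise intersection of the two knockdown
contrasts; genes moving in opposite directions are excluded and reported as
discordant. `ddct_fold_change` implements 2^−ΔΔCt for qPCR validation
arithmetic.

## Target nomination

Only peaks in {cAP, cAE, cIP, cIE} are carried into integration; genes are
matched by exact string id (silent fuzzy matching corrupts Venn counts —
an alias table can be layered on by the caller). Nominated direct targets =
high-confidence ∩ nearest-TSS-bound genes, each with its supporting peaks
(state, openness, signed distance); remaining high-confidence genes are
candidate indirect targets, and bound-but-unregulated genes are reported for
completeness. Genes hit by peaks of several states are counted once.

## Preranked enrichment

The ranked list sorts genes by descending metric with lexicographic
tie-break. The running sum adds `|metric|^p / N_R` at members (p default 1)
and subtracts `1/(N − N_hits)` at non-members; ES is the extremum of
largest magnitude. The null model permutes gene-set membership (random sets
of identical size without replacement) — the only null available to a
preranked analysis. NES divides ES by the mean |null ES| of the same sign;
the p-value is the same-sign exceedance fraction with add-one smoothing,
`(1 + k) / (1 + n_same)`. Across a collection, the reported FDR is a BH
adjustment of permutation p-values within each sign stratum — a simple
empirical surrogate for the original rank-of-NES procedure, adequate for
the small collections this package targets. All permutation results are
bit-reproducible given the seed.

## Synthetic benchmark

The generator emulates the statistical structure of the real inputs on a
miniature genome. Reference configuration: 2 chromosomes × 500 kb, i.i.d.
bases at GC 0.41 (human-like), 60 non-overlapping genes of 3–10 kb with 2–8
exons and random strand; 400 shared peaks of 200–400 bp with summits,
placed ≥ 1.7 kb apart so that mark evidence cannot bleed between peaks;
class composition other 0.60 / cAE 0.27 / cIE 0.09 / cAP 0.03 / cIP 0.01 by
exact largest-remainder counts (active enhancers dominating active
promoters, as observed for AP-1 family factors); class-defining marks placed
as bimodal ±600 bp flanking intervals of 150 bp; ATAC intervals with
class-conditional probabilities (cAE 0.964, cAP 0.928 — matching reported
open-chromatin rates for such elements — cIE/cIP 0.6, other 0.1); TRE
consensus embedded in 90 % and CRE in 20 % of peaks at random offsets and
strands, replacing bases in place so coordinates stay fixed. The embedded
word is the PWM argmax string, which guarantees detection at the 1e−4
threshold (see above). Replicate 2 is replicate 1 jittered by ≤ 50 bp
(width ≥ 200 guarantees ≥ 150 bp overlap), plus 15 % replicate-specific
decoys per replicate kept ≥ 700 bp from every other peak, making
intersection truth exact.

The DE model plants 20 direct targets (genes nearest to classified peaks)
with concordant log2 effects ±1.0 (sd 0.1) in both contrasts; null genes
draw from N(0, 0.1). P-values follow a one-sample z-model,
`p = 2Φ(−|log2fc| / 0.1)`, making p consistent with the printed effect:
planted targets pass the 1.25-fold/FDR filter with overwhelming margin and
nulls essentially never do at zero noise. `mark_noise` flips mark presence
per peak and mark, degrading classification gradually (recovery is
non-increasing in noise, verified over a grid).

Substreams: one `numpy` Philox-family generator per component, seeded as
`[seed, component_index]`.

What passing these tests shows — and does not. Zero-noise recovery
demonstrates the *logic* of every stage (boundary conventions, joins, set
arithmetic, determinism), and the noise/null simulations demonstrate
statistical calibration of the filter and the permutation test. The
generator does not model read-level artifacts, mappability, copy number,
fragment-size effects, correlated probe noise, or enhancer–gene looping
beyond nearest-TSS assignment, so recovery rates here do not predict
sensitivity or specificity on real data.

## Numerical and degenerate-input choices

- PWM p-values: grid 1e−3 bits; queries are guarded by a 1e−9 tolerance so
  float-summed window scores never straddle a grid boundary.
- `exact_score_pvalue` returns 1 at or below the minimum achievable score
  and 0 above the maximum; scanning only ever queries achievable scores.
- Empty inputs: empty peak sets intersect to empty sets; an empty distance
  table is returned for zero assignable peaks; `feature_distribution` and
  `state_summary` refuse empty input (a pipeline bug, not a data state).
- Enrichment is undefined (error) when the set has no member in the list or
  covers it entirely; all-zero hit weights fall back to equal steps.
- All result orderings are deterministic (gene id or peak name
  lexicographic; input order for replicate intersection).

## Problem sizes

The default test and acceptance runs use the reference configuration above
(1 Mb genome, 460 peaks per replicate, 120 DE rows, 1000 permutations for
power checks, 200 repeats for calibration checks), chosen so the entire
suite exercises every stage end-to-end in seconds while keeping binomial
standard errors small enough for 3-SE assertions to be meaningful.
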