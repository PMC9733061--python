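# cistrome

Integration of a transcription factor's binding landscape (its *cistrome*,
mapped by ChIP-seq) with knockdown transcriptomics, to nominate candidate
direct target genes.

The package is aimed at regulatory-genomics analysts who have, for one
factor: replicate peak calls (narrowPeak/BED), histone-mark interval tracks
(H3K27ac, H3K4me1, H3K4me3), ATAC open-chromatin intervals, a gene model
(GTF), the genome sequence (FASTA), position frequency matrices for the
factor's binding motifs, and per-contrast differential-expression tables
from siRNA knockdowns. From those it computes, step by step:

1. **Replicate-consistent peaks** — peaks of replicate 1 overlapping
   replicate 2 by ≥ 1 bp (half-open interval arithmetic:
   `overlap([a,b), [c,d)) = max(0, min(b,d) − max(a,c))`).
2. **Genomic annotation** — each peak anchor (summit, else midpoint) is
   classified as promoter (≤ 10 kb upstream of a TSS, strand-aware), exon,
   intron, downstream (≤ 10 kb past a TTS) or intergenic, with precedence in
   that order, and assigned to the gene with the nearest TSS; signed
   distances are negative upstream in the gene's own orientation.
3. **Chromatin-state classes** — from mark presence within ±1 kb of the
   anchor: H3K27ac ∧ H3K4me3 → candidate active promoter (cAP);
   H3K27ac ∧ H3K4me1 (without me3) → candidate active enhancer (cAE);
   me3 alone → cIP; me1 alone → cIE; otherwise unclassified. ATAC overlap
   flags open chromatin. Binned signal matrices (60 × 100 bp around
   anchors) support heatmap QC.
4. **Motif content** — log-odds scanning of peak sequences on both strands
   with JASPAR-style PWMs (TRE `TGASTCA`, CRE) against a 0-order background,
   using *exact* score p-values obtained by dynamic-programming convolution
   of the per-column score distributions (hits at p ≤ 1e−4 by default).
5. **High-confidence regulated genes** — per contrast, genes with
   |fold| ≥ 1.25 (inclusive) and Benjamini–Hochberg FDR < 0.05 (strict);
   the high-confidence set is the direction-wise intersection of the two
   independent siRNA contrasts.
6. **Direct-target nomination** — the intersection of the high-confidence
   set with genes whose nearest TSS carries ≥ 1 peak in
   {cAP, cAE, cIP, cIE}, with a Venn-style summary.

It also provides a preranked gene-set enrichment score (weighted running-sum
statistic with gene-set permutation NES/p-values), the 2^−ΔΔCt qPCR
quantification utility, and a fully seeded synthetic-data generator that
plants ground truth (peak classes, marks, openness, embedded motif
instances, concordant knockdown effects) for every stage — the backbone of
the test suite.

## Worked example

```python
from cistrome import SimConfig, simulate_all, run_pipeline
from cistrome.simulate import default_tre_pfm, default_cre_pfm

sim = simulate_all(SimConfig(seed=1234))      # plants ground truth
res = run_pipeline(sim.rep1, sim.rep2, sim.genes, sim.marks, sim.atac,
                   sim.sequences, [default_tre_pfm(), default_cre_pfm()],
                   sim.de_table)
print(res.state_table.to_string(index=False))
print(res.motif_table.to_string(index=False))
print("high-confidence:", res.summary["n_high_confidence"],
      "direct nominations:", res.summary["n_direct_nominations"])
```

prints

```
state  count  fraction  open_fraction
  cAP     12      0.03       0.916667
  cAE    108      0.27       0.972222
  cIP      4      0.01       0.750000
  cIE     36      0.09       0.722222
other    240      0.60       0.125000
pwm  n_peaks_with_hit  fraction
TRE               357    0.8925
CRE               101    0.2525
high-confidence: 20 direct nominations: 20
```

Reading this: the 400 replicate-consistent peaks split over the regulatory
classes exactly as planted (27 % candidate active enhancers, 3 % candidate
active promoters, 60 % unclassified); active elements are almost always in
open chromatin while unclassified regions rarely are; 89 % of peaks contain
a TRE motif and 25 % a CRE (planting rates 90 %/20 % plus chance background
hits); and all 20 genes planted as direct targets — and no others — are
recovered with their correct direction of regulation.

The same steps are available as a CLI (`cistrome simulate / intersect /
annotate / classify / scan / de-filter / integrate / gsea`), reading and
writing the standard text formats (narrowPeak, BED, GTF, FASTA, JASPAR PFM,
GMT, RNK, TSV).

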