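# te-exonize

Analysis of transposable-element (TE) **exonization** in coding sequences:
how often repeats (Alu, L1, LTR retrotransposons, DNA transposons, L2, MIR)
end up inside the exons of assembled transcripts, whether they are enriched
in **first exons** (where a TE donates an alternative TSS), how each TE
family contributes relative to its genomic abundance and age, and whether
the expression of TE-derived exons tracks epigenetic signal (histone-mark,
DHS and CAGE peaks).

The package is aimed at regulatory-genomics analysts who have transcriptome
assemblies (GTF + FPKM), repeat annotation (RepeatMasker `.out` or
rmsk-style BED) and peak/cluster calls (BED), and want a tested, scriptable
version of the classic overlap-based workflow — plus a synthetic-data
generator with planted ground truth so every step can be validated without
touching real data.

## The method

* **TE-derived classification** — an exon is TE-derived iff it shares ≥ 1 bp
  with a repeat (half-open genomic coordinates, strand ignored); a
  transcript is TE-derived iff any of its exons is, with a separate flag
  for a TE-derived *first* exon (5′-most in transcription order).
  Fractions are reported as numerator/denominator with half-up one-decimal
  percentages.
* **Cross-assembly matching** — records from two assemblies match when both
  boundaries agree within a wiggle tolerance (default ±10 bp on start and
  end, same chromosome and strand). A one-to-one matching of maximum
  cardinality and minimum total boundary distance Σ(|Δstart| + |Δend|)
  yields Venn-style shared/unique counts.
* **Family contribution** — each TE-derived exon credits every distinct
  repeat family it overlaps; counts are normalized by the family's genomic
  abundance (element count, or bp). Heterogeneity across families is tested
  with a χ² goodness-of-fit against abundance-proportional expectations.
  Family age is ranked by mean divergence from consensus (millidiv,
  substitutions/kb — smaller is younger).
* **Expression–signal trend** — TE-derived exons are sorted by FPKM into
  100 equal-count bins; per bin the mean FPKM and mean per-exon peak count
  are computed per track, and the trend is summarized by Pearson's *r*
  with significance from the Student's-t approximation
  `t = r·√(n−2) / √(1−r²)`, df = n − 2.
* **Differential expression** — per gene (summed transcript FPKM,
  log₂(x+1)-transformed), a two-sample Student's t-test between two
  conditions, Benjamini–Hochberg q-values, significance at q < 0.05, and
  the intersection with genes carrying TE-derived first exons.

## Worked example

Simulate a study (two 5 Mb chromosomes, 600 elements per family, 2000
transcripts whose first exons overlap a TE with probability 0.40 vs 0.10
for later exons), then classify it:

```sh
$ te-exonize simulate --seed 1 --out demo
wrote 13 files under demo

$ te-exonize classify --gtf demo/assembly_a.gtf --te demo/te.bed --out demo/cls
all_exons: 1057/5063 = 20.9%
first_exons: 757/2000 = 37.9%
transcripts: 929/2000 = 46.5%

$ te-exonize families --gtf demo/assembly_a.gtf --te demo/te.bed --out demo/fam
age order (youngest first): Alu, L1, LTR, DNA, L2, MIR; chi2=6.03 df=5 p=0.304
```

Reading the output: 37.9% of first exons are TE-derived against 20.9% of
all exons — first-exon enrichment recovering the planted 0.40 vs 0.10
rates (the all-exon rate is the mixture over first and later exons). The
age ranking recovers the planted millidiv ordering; the χ² is
non-significant because the default generator plants family-uniform
exonization, so hits are proportional to abundance. Other subcommands
(`compare`, `episignal`, `diffexp`, `run`) follow the same pattern; the
truth tables under `demo/truth/` hold every planted label.

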