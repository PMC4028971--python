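# Methods

## Coordinate model

All intervals are 0-based half-open `[start, end)` internally. GTF input
(1-based closed) is converted on read (`start−1, end`) and back on write;
BED-family inputs are native. Overlap between two intervals means
`max(starts) < min(ends)` — any shared base counts, with no minimum
overlap fraction, because co-location of an exon with a repeat is defined
as *any* genomic overlap. Adjacent half-open intervals never overlap.
Unstranded exons are rejected at parse time: first-exon and TSS calling
are strand-dependent and a `.` strand would make them undefined.

Overlap queries run on per-chromosome interval trees (`intervaltree`),
with a serial number per entry so duplicate intervals are preserved and
query results have a deterministic order. The engine is property-tested
against a brute-force all-pairs scan.

## TE-derived classification

An exon is TE-derived iff ≥ 1 bp of it overlaps a repeat annotation;
strand is ignored (exonization of an antisense repeat is still
exonization). A transcript is TE-derived iff any exon is; a separate flag
records whether the *first exon* — minimal start on `+`, maximal end on
`-`, ties broken toward the longer exon then coordinate order — is
TE-derived. The TSS is the first exon's 5′ base (`start` on `+`,
`end − 1` on `-`).

The all-exon universe counts exon records exactly as emitted by the
assembler, with no coordinate deduplication across transcripts, so
denominators match raw assembler totals. Reported percentages use half-up
rounding to one decimal; raw numerator/denominator are always carried
alongside and are the source of truth.

Repeat class/family strings map to six named families by prefix —
`SINE/Alu`→Alu, `SINE/MIR`→MIR, `LINE/L1`→L1, `LINE/L2`→L2, `LTR`→LTR,
`DNA`→DNA — and everything else to `other`. `other` is tallied in
contributions but excluded from age ranking. RepeatMasker `.out` percent
divergence is stored per-mille (×10) so both supported dialects yield
identical annotations for the same repeat.

## Cross-assembly matching

Two records match when same chromosome and strand, `|Δstart| ≤ w` and
`|Δend| ≤ w` (default w = 10 bp, compensating assembler imprecision).
Transcript-level matching compares the genomic span (first-exon start to
last-exon end); requiring every internal boundary to agree would be a
stricter, different statistic, and span matching is what shared/unique
transcript counts need.

Among feasible candidate pairs we compute a one-to-one matching that
maximizes pair count and, among those, minimizes total distance
Σ(|Δstart| + |Δend|). A cheapest-first greedy pass was considered and
rejected: when records cluster within the wiggle, taking the globally
cheapest pair first can starve a neighbouring record of its only partner,
losing a match — the exact assignment (Hungarian algorithm per connected
component of the candidate graph) is immune to this and agrees with
exhaustive enumeration on arbitrary instances, which the tests verify.
Components are near-singletons for realistic jittered assemblies, so cost
is linear in practice. With w = 0 matching reduces to exact coordinate
equality; pair count is non-decreasing in w.

## Family contribution and age

Each TE-derived exon contributes one hit to every *distinct* family among
its overlapping repeats. Abundance defaults to element count (`bp` mode
sums element lengths); contribution = hits/abundance, undefined (reported
missing, never divided) for zero-abundance families. Heterogeneity is a
χ² goodness-of-fit with abundance-proportional expected counts
`e_i = N·a_i/Σa` and df = k − 1; uniform expectations are available by
passing equal abundances. Age rank orders the six named families by
ascending mean millidiv (ties alphabetical): divergence from consensus
accumulates with time, so smaller means younger.

## Expression-binned epigenetic profiles

TE-derived exons are sorted by FPKM (ties broken by coordinates for
reproducible membership) and split into 100 equal-count bins — with
n = q·100 + r, the first r bins take q+1. Equal-count rather than
equal-width bins: FPKM is heavy-tailed, and equal-width bins would leave
most bins empty. Per-exon signal defaults to the count of overlapping
peaks/clusters (inputs are calls, not raw tags); `bp` and summed-`score`
modes and a `--flank` extension (default 0) are available. The trend is
the Pearson correlation of the 100 per-bin mean signals against per-bin
mean FPKM, with two-sided significance from
`t = r·√(n−2)/√(1−r²)`, df = n − 2, at n = 100 bins (the plotted trend is
the binned one; a per-exon correlation is available in the library).

## Differential expression

Gene expression is the per-replicate sum of the gene's transcript FPKMs,
log₂(x+1)-transformed by default (variance stabilization at low counts);
genes enter testing only if mean FPKM > 0 in at least one group. The test
is the classical equal-variance two-sample Student's t (df = n_A+n_B−2);
Welch is an option. Zero pooled variance with equal means is defined as
t = 0, p = 1; with unequal means it is an error rather than a silent
infinity. Multiplicity uses Benjamini–Hochberg step-up q-values
(`statsmodels`, hand-computed values frozen in tests), significance at
q < 0.05, and the final intersection keeps significant genes whose first
exon is TE-derived (a gene inherits the flag from any of its transcripts).

## Synthetic data generator

The generator emulates the statistical structure every stage assumes, with
all planted labels written to sidecar truth tables (never inferable from
the data files, so oracles stay independent):

* **TE landscape** — per family, `count` elements of normal-distributed
  length placed uniformly (elements may overlap, as real nested repeats
  do); millidiv ~ Normal truncated at 0 with family means ordered
  Alu 80 < L1 130 < LTR 180 < DNA 230 < L2 280 < MIR 330 (sd 30), so the
  planted age order is Alu, L1, LTR, DNA, L2, MIR. Defaults: two 5 Mb
  chromosomes, 600 elements/family.
* **Transcriptome** — 2000 transcripts, 1 + Poisson(1.5) exons of
  log-normal length (median ≈ 150 bp), introns 50–2000 bp, random strand.
  The first exon (transcription order) is placed to overlap a uniformly
  chosen repeat with probability ρ_first = 0.4; later exons with
  ρ_later = 0.1; non-overlapping exons are rejection-sampled to be
  repeat-free, so planted labels equal overlap classification *exactly*.
  A second assembly duplicates a 0.6 fraction of transcripts with ≤ 3 bp
  boundary jitter (within the 10 bp matching wiggle) plus 30% novel
  records.
* **Expression** — per-gene baseline log₂FPKM ~ N(3, 2), replicate noise
  sd 0.15 on the log₂ scale (≈ 10% CV), 2 replicates per condition; 5% of
  genes get a ±2 log₂FC shift in condition B. One gene per transcript.
* **Signal tracks** — per exon and track, expected peak count
  `max(0, a + b·ln(FPKM+1)) + N(0, σ)`, rounded, with that many 50 bp
  peaks dropped uniformly inside the exon; slopes b > 0 for the six
  default tracks; b = 0 yields a null track uncoupled from expression.

One `numpy` generator seeded from `config.seed` drives everything; the
same config produces a byte-identical file bundle.

What the generator does **not** emulate: sequence content, splice-site
motifs, read-level sampling noise, isoform sharing of exons, clustered
repeat insertion, GC/mappability biases, or family-biased exonization
(repeat choice is family-uniform, so the family χ² is null-true at
defaults, and its calibration rather than its power is what the synthetic
tests establish). Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure, not performance on
real data.

## Numerical and scale choices

* Percent reporting uses decimal half-up rounding (banker's rounding
  would turn 0.25 into 0.2).
* Monte-Carlo suites use fixed seed ranges (0–99 for replicate studies)
  with reduced problem sizes chosen for desk-scale runtimes: replicate
  studies use a single 2–4 Mb chromosome with 150–200 elements/family;
  overlap-rate recovery keeps the full 2000 transcripts; trend-recovery
  runs 400 transcripts (≈ 150–200 TE-derived exons, comfortably above the
  100-bin minimum).
* Statistical calibration checks use 3-standard-error bands: null trend
  rejection at p < 0.05 within 0.05 ± 3·√(0.05·0.95/100); χ² type-I
  error within the analogous band at 1000 draws; global-null BH rejections
  below 0.05 + 3 SE pooled over 200 replicates.

## Known limitations

* With 2 replicates per condition the per-gene equal-variance t-test has
  df = 2, whose p-values cannot fall much below ~10⁻³–10⁻⁴ except when
  the pooled variance is tiny by chance; after BH correction across ~2000
  genes, planted 4-fold shifts are mostly *not* recoverable at q < 0.05
  under the default generator conditions (observed recovery ≈ 0–2%). This
  is a property of per-gene t-tests at n = 2, not a defect: power tests
  therefore demonstrate monotonic recovery versus effect size at 3
  replicates per group, and real studies at n = 2 would reach for
  moderated-variance methods, which are out of scope here.
* Exon-level matching treats each exon record independently; splice-chain
  (intron-structure) transcript equivalence is not implemented.
* Signal aggregation consumes peak/cluster calls; read-level tag pileups
  (BAM) are out of scope.
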