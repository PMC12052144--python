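# Methods

## The problem and the model

Somatic single-nucleotide variants (SNVs) can rewire splicing and
transcription both locally (cis) and at a distance (trans), but testing
every mutated gene against every one of tens of thousands of transcript
isoforms is computationally heavy and statistically underpowered at the
2–30% mutation prevalences typical of cancer genes.  `isomas` replaces the
exhaustive gene-by-isoform scan with a two-step procedure:

1. **Dimension reduction.**  The isoform-by-sample FPKM matrix is filtered,
   restricted to isoforms of multi-isoform genes, LogNormalized per sample
   (`y = ln(1 + x / Σx · 10,000)`), reduced to the most variable isoforms by
   the mean-variance-plot (mvp) criterion, z-scaled per isoform, and
   decomposed by PCA into K = 50 "meta-isoforms" satisfying the exact
   identity `E × L = S` (samples-by-features matrix × loading matrix =
   score matrix).

2. **Association scan.**  For each gene whose SNV mutant fraction is at
   least 2% of samples, the cohort is split into mutant and wildtype groups
   and a two-sided Wilcoxon rank-sum test compares PC scores along each of
   the K coordinates.  A gene is *called* when it passes a two-layer test:
   Bonferroni over the K PCs (`K · P_min < 0.05`, i.e. raw `P_min < 0.001`
   at K = 50) and then Benjamini–Hochberg at FDR < 0.05 across the
   Bonferroni-adjusted minima of all tested genes.  On the first
   significant PC (lowest index whose adjusted p clears the per-PC level),
   isoforms are ranked by loading magnitude; the top 100 form the gene's
   target list.

Because `S = E × L`, a PC score is a linear combination of all input
isoforms, so a mutation–PC association is equivalent to an association
between the mutation and the isoforms carrying the largest (positive or
negative) loadings.  The scan therefore costs `G × K` rank-sum tests —
independent of the number of isoforms — while retaining per-isoform
attribution through the loadings.

## Downstream characterization

* **Dual-direction (isoform switch) detection.**  For every gene
  represented in a called gene's target list, each of its isoforms is
  tested directly on FPKM (Wilcoxon + log2 fold change with a pseudocount
  of 1 FPKM).  A target gene is *dual* when at least one isoform is
  significantly up and another significantly down (both p < 0.05).  The
  harmonic mean p-value (HMP) is taken over the significant isoforms, the
  per-called-gene `mHMP` is the plain mean of the dual genes' HMPs, and
  the summary is reported as −log10(mHMP).  The HMP is used as a raw
  combined-significance summary with a 0.05 threshold; no asymptotic
  (Landau) calibration is applied.
* **Cis/trans localization.**  With the cis-region defined as ±1 Mb of a
  gene's TSS (the 5′-most transcript start on its strand), an upper-tail
  hypergeometric test asks whether the target list concentrates inside the
  called gene's cis window relative to the annotated PCA-input universe.
  p > 0.999 is flagged as consistent with the opposite (trans) null at the
  0.001 level.
* **Chromosome preference.**  Target and universe transcripts are binned
  into the ordered 24-chromosome axis and the two relative-frequency
  vectors are compared by the maximum CDF gap D.  The default converts D
  through the asymptotic two-sample KS distribution — the convention used
  in practice on such frequency vectors, though the axis is discrete, so
  the p-value is approximate.  A seeded permutation mode
  (`chrom_test: permutation`) draws size-matched target sets from the
  universe and is the statistically clean alternative.
* **Inter-cohort overlap.**  Called gene sets are compared with the
  Szymkiewicz–Simpson coefficient |A∩B|/min(|A|,|B|); target overlap is the
  three-step mean over shared called genes of their top-k target
  intersections (transcript identity; a gene-level collapse is available).
* **Gene-set enrichment.**  Upper-tail hypergeometric
  `P = Σ_{j=k}^{q} C(m,j) C(N−m,q−j) / C(N,q)` against user-supplied GMT
  sets, trimmed to the mutation background.

## Chromatin accessibility

Peaks (0-based half-open BED intervals) map to transcripts by interval
intersection against the annotated transcript spans (GTF spans, or a TSS
point for the minimal TSV dialect).  The mutation side uses Welch t-tests
per peak (accessibility cohorts are small), the expression side Kendall
tau-b; p-values combine by HMP overall, per direction and per region class
(Promoter/Intron/Exon/Distal/3′UTR/5′UTR).  For a called gene and one of
its targets, Kendall p-values of all peak pairs between the two loci
(self-pairs excluded) combine into a pair HMP; the distribution of
log10 HMP over called pairs is compared against an equally sized, seeded
random pool of non-called pairs by a two-sample KS test.

## Statistical conventions

* Wilcoxon rank-sum: two-sided; exact enumeration when the smaller group
  has ≤ 8 observations and the pooled sample is tie-free, otherwise the
  tie-corrected normal approximation with continuity correction.  A pooled
  sample with zero range returns p = 1.
* Kendall: tau-b; exact p for tie-free n ≤ 33.
* Hypergeometric tails and BH adjustment come from scipy/statsmodels; the
  exact tail at k = 0 is 1 by construction.
* PCA: deterministic full SVD by default (a seeded randomized solver is
  available for very large feature counts); K is clamped to
  min(n − 1, p) and truncated to the numerical rank with a warning.  Sign
  ambiguity is resolved by flipping each PC so its largest-|loading| entry
  is positive (ties: lowest feature index), with scores flipped
  consistently — without this, target rankings are platform-dependent.
* Scaling uses the sample (n − 1) standard deviation; scaled values are
  clipped at ±10 so single samples cannot dominate a PC.
* mvp selection: dispersion = variance/mean of the back-transformed
  (expm1) values; the mean metric is log1p of the back-transformed mean.
  Features are cut into 20 equal-width bins of the mean metric and the
  log-dispersion is z-scored within each bin; kept are features with
  z ≥ 1 and mean metric in [0.1, 8].  Binning on the log1p scale keeps the
  bins populated and makes the z-score genuinely mean-controlled; on the
  raw mean scale a handful of highly expressed isoforms would collapse
  nearly all features into one bin and the "dispersion" ranking would
  reduce to a mean ranking.  Bins with fewer than two usable features
  contribute no z-scores (their features are excluded with a warning), and
  dispersions below 1e-12 are treated as zero so numerically constant
  features are never selected.
* All parameters above are configurable; the defaults are the
  conventions of the single-cell toolkit ecosystem this preprocessing
  follows.

## The synthetic cohort generator

The generator emulates the statistical structure the scan assumes in a
tumor cohort, with planted ground truth for recovery testing:

* ~800 genes with 1–5 isoforms (mode 2–3, matching the genome-wide ratio
  of ≈2.5 transcripts/gene); log-normal FPKM baselines around e² ≈ 7 FPKM
  with per-isoform natural-log sd drawn in 0.18–0.42 (`baseline_log_sd`
  0.3 scaled by a uniform 0.6–1.4 factor); log-normal library-size factors
  (sd 0.2) so LogNormalize is exercised nontrivially; exact zeros injected
  at 2% (bulk isoform data has few true zeros).
* Drivers mutated at a configurable prevalence (default 10%; mutant counts
  binomial); each driver's 50 target isoforms are multiplied by
  2^(±effect) in mutant samples (default 1.5 log2 units).  Target genes are
  drawn from multi-isoform non-driver genes — the scan's input universe
  excludes single-isoform genes by construction, so a target planted there
  would be unrecoverable by design, not by failure.  30% of target genes
  receive an opposite-sign isoform pair (a planted isoform switch); the
  rest a single signed isoform.  Passenger genes (default 200; 500 in the
  null-calibration benchmark) are mutated at uniform 5–15% prevalence.
* Annotation assigns genes to the 24 chromosomes with length-weighted
  probabilities and uniform TSS; cis-configured drivers have their target
  genes' loci relocated into the ±1 Mb window around the driver TSS.
* Optional accessibility peaks: 1–3 Gaussian log2-scale peaks per gene
  span; peaks of target genes are coupled to an isoform of their gene,
  peaks of driver genes receive a mutant-sample shift.

**Design choices.**  The continuous log-normal baseline (rather than a
negative-binomial count model) matches the FPKM scale the pipeline
consumes.  The baseline noise level is deliberately moderate: in real
cohorts the most variable isoforms are variable *because of* sample
subgroup structure (subtype, mutation status), and the generator
reproduces that by letting planted associations — not the baseline —
create the high-dispersion tail.  What the generator does **not** emulate:
correlated co-expression modules, batch effects, isoform-ratio coupling
within a gene, mutational signatures, or the heavy-tailed expression of
real transcriptomes.  Passing recovery benchmarks on these cohorts
therefore demonstrates the machinery is correct and calibrated, not that
equal power is attainable on noisier real data.

## Benchmark study conditions

Cohort-level checks run at sizes chosen to finish in minutes on one core:

* **Null calibration** — 50 driver-free cohorts, n = 200 samples, ~500
  passenger genes tested each; the fraction of cohorts yielding any called
  gene at FDR < 0.05 stays within 0.10.  (Bonferroni alone would pass ~5%
  of genes per cohort at P_min < 0.001 across 50 PCs; the second,
  across-gene BH layer is what controls the cohort-level rate.)
* **Power/recovery** — 20 cohorts, n = 300, two drivers (one cis) at 10%
  prevalence, 50 targets at 1.5 log2 units: driver sensitivity, mean
  target recall@100, dual-direction detection sensitivity and the cis flag
  rate are averaged over seeds.
* **Equivalence** — a single-driver cohort at 50% prevalence (the regime
  of the classic high-prevalence tumor-suppressor exemplars); Spearman
  rho between |loading| on the selected PC and −log10 of the direct
  per-isoform test across all input isoforms.  With several drivers the
  selected PC can mix signatures and the per-driver correlation dilutes —
  which is a property of the display, not of the calling procedure.

Because synthetic cohorts carry a few thousand transcripts rather than a
transcriptome, benchmark runs lower the per-sample quality filter
(`min_isoforms_per_sample = 10`, vs the default 200 intended for ~70k
transcript panels); all other analysis parameters are the defaults.

## Known limitations

* The mvp cutoffs of the source toolchain are conventions, not published
  values; per-cohort variable-feature counts depend on them.
* The first-significant-PC rule is a heuristic; when a gene is significant
  on several PCs the target list reflects only the lowest-indexed one.
* Absolute-value target ranking reproduces both the positive and negative
  target subsets; a signed top/bottom split is available
  (`rank_mode = "signed-top-bottom"`) for workflows that want explicit
  direction-stratified lists.
* The KS chromosome-preference p-value treats a discrete 24-bin axis as
  continuous; use the permutation mode when calibration matters.
* Replicate accessibility samples are averaged per biological sample
  before testing; this is a choice, not a community standard.
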