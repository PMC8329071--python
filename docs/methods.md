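# Methods

This note documents the statistical procedures the package implements, the
assumptions behind them, the synthetic-cohort model used to exercise them,
and the numerical and design choices that were genuinely open.

## Setting

The package analyses a multi-omic glioma cohort: bulk RNA-seq expression
counts and promoter-level signal for H3K4me3, H3K27ac, H3K27me3, ATAC and
DNase assays across tumour samples labelled with WHO grade groups — PA
(pilocytic astrocytoma, grade I), DA (diffuse astrocytoma, grade II/III)
and GBM (glioblastoma, grade IV; a paediatric case is pooled into GBM).
Genes are reduced to one canonical, strand-aware TSS; the promoter is the
symmetric window TSS ± 2 kb. Genes are grouped by topologically
associating domains (TADs), consumed as a precomputed non-overlapping BED
segmentation; overlap of TADs on one chromosome is rejected at load
because every TAD-level statistic assumes a partition.

All coordinates are 0-based half-open internally; 1-based inclusive tables
are converted at the I/O boundary and back on write.

## Differential calling

The built-in caller is a per-feature two-sided Mann–Whitney–Wilcoxon test
between two grade groups on counts-per-million-scaled values (scaling is
switchable off; rank tests are affected by it only through ties). The null
distribution is exact when both groups have ≤ 8 tie-free observations,
otherwise the normal approximation with tie and continuity corrections.
An all-tied feature carries no information against the null and is
reported with p = 1. Correction is Bonferroni or Benjamini–Hochberg
(step-up, hand-implemented and cross-checked against statsmodels in the
tests); the significance threshold is adjusted p < 0.01 by default.
Externally produced differential tables (e.g. from a negative-binomial
GLM) can be injected in the same schema and used downstream unchanged.

Fold changes are log2((mean₂ + c)/(mean₁ + c)) with pseudocount c = 1
(configurable; no published value exists for this constant). "Active"
genes are those with mean raw count ≥ 10 across all samples (inclusive).
Promoter hypermethylation is the count of cytosines with beta ≥ 0.8
(inclusive) per region and sample; betas are inputs, bisulfite processing
is out of scope.

## TAD-level statistics

**Enrichment.** For each TAD with ≥ 3 genes, the probability of observing
its flagged-gene count or more under Binomial(n genes, background), where
the background probability is the global share of flagged genes among all
TAD-assigned genes. This is the upper-tail survival function, identical to
summing the pmf from the observed count upward. BH correction runs across
the tested TADs; a TAD is "enriched" when adjusted p < 0.05. Smaller TADs
are excluded before correction and can never be called.

**Fold-change homogeneity.** Kruskal–Wallis with log2 fold changes as
values and TADs as groups, tie-corrected, with the asymptotic chi-square
p complemented by a permutation null that shuffles the values among TADs
while preserving each TAD's gene count. Permutation p-values use the
(k+1)/(n+1) estimator and are therefore never zero. The statistic is
rank-based, hence invariant under monotone transformation of the fold
changes — a property the tests assert.

**Fold-change coupling.** Per TAD, the mean expression fold change of its
differential genes and the mean mark fold change; one Spearman rho across
TADs. At least 3 TADs with both means are required.

**Bivalent chromatin.** Genes are ranked by mean promoter H3K4me3 and by
mean H3K27me3 across the analysed group's samples (GBM by default, where
the repressive-mark data exist); the bivalent set is the intersection of
the two top-1000 sets with the differential genes. Ties at the top-N
boundary break lexicographically by gene id so runs are reproducible. The
overlap between enrichment-positive TADs and TADs containing bivalent
differential genes is scored with the upper-tail hypergeometric test over
the universe of TADs that passed the gene-count filter (the universe is
configurable; no published choice exists).

## Expression–mark correlation

Spearman rho per gene between promoter mark signal and expression across
patients, with average ranks for ties; a constant vector has no rank
information, so its rho is undefined (NaN) and excluded from summaries
rather than silently zeroed. "Highly correlating" genes are those with
rho strictly greater than 0.7.

Random backgrounds are expression-matched: a set of non-differential
active genes of the same size whose overall mean expression is at least
the differential set's mean. The constraint is on the set mean — the
literal condition — not per-gene matching; it is enforced by whole-set
rejection sampling with a decile-stratified fallback, and an infeasible
constraint raises an error reporting the achieved mean. The overlap of
differential-expression and differential-mark gene sets is scored by
bootstrap: the fraction of matched random sets overlapping at least as
much, again with the never-zero estimator. Prognostic status is an input
flag table; overlap proportions between named gene sets and the
prognostic set are compared with the exact rank test.

## Enhancers and long-range contacts

Enhancers are H3K27ac peaks that overlap no promoter window by even one
base. Contact pairs (BEDPE; inter-chromosomal rows dropped on load with a
logged count) link a gene to an enhancer when one anchor overlaps the
gene's promoter and the other overlaps the enhancer, in either
orientation, with the promoter–enhancer midpoint distance ≤ 2 Mb.
Multiple supporting contacts collapse to one link carrying the count.
Genes are classed by total contact count: none, few (1–5), multi (≥ 6);
expression of multi- vs few-class genes is compared with the rank test.

Differential enhancer acetylation and differential enhancer CpG
methylation use the raw Mann–Whitney p < 0.01 cut-off with no multiplicity
correction — that is the procedure as stated, and a BH option exists but
is off by default. Enhancer methylation is the arithmetic mean beta over
CpGs inside the enhancer per sample; samples with no covered CpG are
undefined and excluded. Per-link Spearman correlations between gene
expression and enhancer acetylation are computed overall and per grade
group (strata under 3 samples skipped). The permutation null randomly
re-pairs expression vectors with acetylation vectors — not within-sample
labels — 100 times, recording the mean rho per replicate; its median is
the null summary, expected near zero under heterogeneous pairs.

## TF–target filtering

Candidate (TF, target) pairs are an input (motif scanning is upstream and
out of scope). Each pair's Spearman rho across samples is compared with
the envelope of that TF's correlations against 100 randomly drawn active
genes (excluding itself and its real targets): the pair survives only if
rho exceeds the envelope maximum, or falls below the minimum for
repressive pairs. The envelope is per TF, since each TF's random-target
distribution has its own width; both per-pair decisions and the per-TF
median rho are reported. The draw count (100) is a package default; no
published value exists.

## Synthetic cohorts

The generator emulates the study's data structure so every stage can be
scored against ground truth:

* **Genome.** TADs tile each chromosome without overlap; every TAD holds
  exactly `genes_per_tad` genes (the construction contract the tests rely
  on), TSSs drawn uniformly inside the TAD with a margin so promoters do
  not cross TAD edges.
* **Cohort.** Group sizes default to PA 11 / DA 7 / GBM 15, mirroring the
  study design with the paediatric GBM pooled in.
* **Expression.** Negative binomial with variance μ + μ²·d (default mean
  100, dispersion 0.2, lognormal per-gene baselines). A fraction
  `frac_deg` (default 0.1) of genes carry a grade-graded effect: 2^lfc in
  GBM, 2^(lfc/2) in DA, random sign, lfc defaulting to 2. A fraction
  `tad_coupling` of true DEGs is concentrated into `n_enriched_tads`
  designated TADs.
* **Promoter marks.** H3K4me3/H3K27ac/ATAC/DNase are coupled to
  expression through a Gaussian copula on ranks; the requested Spearman
  rho (default 0.7) is converted to the latent Pearson correlation via
  r = 2·sin(π·rho/6), so the emitted rank correlation matches the target.
  H3K27me3 is independent lognormal noise.
* **Enhancers.** Placed outside all promoter windows; 20% get a
  grade-shifted acetylation effect. Contacts link each gene's promoter to
  Poisson-many eligible enhancers within 2 Mb on the same chromosome, with
  the promoter window and the enhancer interval as anchors.
* **Methylation.** Six CpGs per enhancer; per-sample betas are generated
  on a logistic scale from a latent negatively coupled (same copula
  conversion, strength `methyl_anticorr`) to that enhancer's acetylation
  ranks.

One seed governs a cohort; each data type draws from its own child stream
derived from the seed by a fixed key, so adding a data type never
perturbs the others and identical configs give byte-identical cohorts.

What the generator does **not** model: library-size variation between
samples, batch effects, gene-length or GC bias, spatially autocorrelated
signal along the chromosome beyond the TAD block structure, copy-number
alterations, IDH-status substructure within DA, enhancer-to-target-gene
expression coupling, or sequence-level artefacts. Passing tests therefore
demonstrate correctness and calibration of the statistics under a clean
generative model, not performance on real tumour data.

## Problem sizes and numerical choices

The default simulated cohort is 50 TADs × 8 genes on two chromosomes with
200 enhancers and 33 samples — large enough for every stage to have
non-trivial input while a full pipeline run stays in the tens of seconds.
Calibration studies use 200 null cohorts of 50 TADs × 10 genes with 99
permutations each; recovery studies use 300 TADs with 20 genes each and
10 spiked TADs (flag probability 0.6 inside vs 0.1 outside). At 20 genes
per TAD the 0.6-vs-0.1 contrast gives the binomial test enough power to
recover ≥ 9/10 spiked TADs at BH < 0.05; at 10 genes it does not — an
intrinsic power limit of the test, not an implementation artefact.

Permutation and bootstrap p-values are never zero ((k+1)/(n+1)).
Degenerate inputs are handled explicitly: all-tied rank tests report
p = 1, all-equal fold-change sets report H = 0 / p = 1, constant vectors
yield undefined correlations that are excluded and logged, empty
methylation coverage yields an undefined mean. Top-N and set operations
break ties deterministically (lexicographic ids), and every randomised
procedure takes an explicit generator, so full runs are byte-reproducible
given a seed.

## Known limitations

* The rank-test differential caller is less powerful than a
  negative-binomial GLM at small n; external GLM results can be injected
  instead, but are not computed here.
* The binomial enrichment background is estimated globally from the same
  data it tests, which is slightly anticonservative for very large flag
  fractions.
* The 2 Mb contact filter uses midpoint distance; anchors wider than the
  cap could be classified differently under an edge-distance rule.
* Contact scores are ignored (each BEDPE row counts once); score
  weighting is a possible extension.
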