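# gliotad

TAD-aware analysis of grade-specific gene regulation in glioma.

Bulk multi-omic tumour cohorts (RNA-seq plus H3K4me3 / H3K27ac / H3K27me3 /
ATAC / DNase promoter signal and DNA methylation) carry regulatory
structure that is organised by topologically associating domains (TADs)
and by long-range promoter–enhancer contacts. `gliotad` implements the
statistics needed to dissect that structure across WHO grade groups
(PA, DA, GBM):

* **Differential calling** — per-feature two-sided Mann–Whitney tests
  between grade groups on CPM-scaled counts (exact null for small
  tie-free groups), Bonferroni/Benjamini–Hochberg correction, log2 fold
  changes, active-gene filtering (mean count ≥ 10) and hypermethylated
  CpG counting (beta ≥ 0.8). Externally computed differential tables can
  be injected in the same schema.
* **TAD statistics** — per-TAD binomial enrichment of differential genes,
  P(X ≥ k) with X ~ Binomial(n_genes, global flag share), BH < 0.05, TADs
  under 3 genes excluded; Kruskal–Wallis homogeneity of log2 fold changes
  grouped by TAD with a gene-count-preserving permutation null; per-TAD
  mean fold-change correlation between expression and marks; bivalent
  chromatin (top-1000 by H3K4me3 ∩ top-1000 by H3K27me3 ∩ DEGs) and the
  hypergeometric overlap of enriched TADs with bivalent-gene TADs.
* **Correlation analysis** — per-gene Spearman rho of promoter marks with
  expression across patients, expression-matched random backgrounds,
  bootstrap overlap significance and prognostic-overlap proportions.
* **Enhancers** — enhancer calling (H3K27ac peaks outside promoter
  windows), gene–enhancer linking through chromatin contact pairs within
  2 Mb, contact-multiplicity classes (1–5 vs ≥ 6), differential
  acetylation/methylation (raw Wilcoxon p < 0.01), per-link
  expression–acetylation correlations and a random-pairing permutation
  null.
* **TF filtering** — TF–target Spearman correlations retained only when
  they escape the envelope of that TF's correlations with randomly drawn
  active genes.
* **Synthetic cohorts** — a generator emulating the full data structure
  (negative-binomial counts with TAD-coupled grade effects, copula-coupled
  promoter marks, grade-shifted enhancers, contacts, anticorrelated
  methylation) with ground truth for scoring every stage.

See `docs/methods.md` for the statistical details and model assumptions.

## Worked example

Simulate a cohort and run the full pipeline:

```sh
gliotad simulate --outdir cohort --seed 1
gliotad run run.yaml --outdir out
```

with `run.yaml`:

```yaml
cohort_dir: cohort
comparisons: [[PA, GBM]]
params:
  rng_seed: 1
  n_perm: 1000
```

Equivalent in Python:

```python
from gliotad.simulate import SimulationConfig, simulate_cohort
from gliotad.promoters import assign_genes_to_tads
from gliotad.differential import rank_test_differential
from gliotad.tadstats import tad_enrichment

cohort = simulate_cohort(SimulationConfig(seed=1))
recs = rank_test_differential(cohort.expression, cohort.samples,
                              "PA", "GBM", correction="bh", alpha=0.01)
degs = {r.feature_id for r in recs if r.significant}
assignment = assign_genes_to_tads(cohort.genes, cohort.tads)
enriched = [r for r in tad_enrichment(assignment, degs) if r.enriched]
print(len(degs), "DEGs,", len(enriched), "enriched TADs")
```

This prints `39 DEGs, 1 enriched TADs` for seed 1: the default cohort
spikes 10% of its 400 genes as true DEGs (the caller recovers 38 of the
40 true ones here, plus one false call at BH < 0.01), and half of those
are concentrated into 5 of the 50 TADs, one of which is dense enough in
DEGs to clear the BH < 0.05 binomial enrichment threshold at this cohort
size.

The `gliotad run` command prints a per-stage summary, e.g.
`n_differential_enhancers: 43` (40 enhancers are truly grade-shifted in
the default cohort; raw p < 0.01 recovers all of them plus ~2% of the
null enhancers) and `link_corr_null_median: -0.013` (the random-pairing
permutation null is centred at zero), and writes every table plus a
`manifest.json` with input/output checksums so identical seeds are
verifiably byte-identical.

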