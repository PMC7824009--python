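# tetrapanel

SNP panel reduction, association mapping and genomic prediction for
autotetraploid breeding populations — built around the economics of
genotyping tetraploid potato (*Solanum tuberosum*).

## The problem

A mid-sized potato program produces 10,000–40,000 new clones a year, yet
high-throughput genotyping of whole breeding populations is unaffordable.
Two reductions make genomics-assisted selection feasible:

1. **Fewer individuals** — from each biparental family, genotype only ~11
   clones chosen by a PCA of field traits so they span the disease
   (AUDPC) axis, plus the shared (grand)parents.
2. **Fewer markers** — after quality filters (per-marker missingness ≤ 10
   calls, probe-alignment identity ≥ 97 %, MAF ≥ 0.05), prune the array
   SNPs for linkage disequilibrium per pseudomolecule: in sliding windows
   of 50 SNPs (step 10), remove one member of every marker pair whose
   squared Pearson correlation r² of genotype codes exceeds a threshold.
   Because tetraploid dosages (0–4, the five states AAAA…aaaa) have three
   heterozygote classes, the matrix is first *diploidized* (1,2,3 → 1) for
   pruning only. Sweeping the r² threshold — or bisecting it for an exact
   target — yields nested panels from ~500 SNPs upward.

The reduced panels are validated two ways:

* **GWAS** under a Q+K polyploid mixed model: marker-based kinship K as
  random effect, two PCoA axes as structure covariates, P3D variance
  components, F-tests of each marker under four gene-action encodings
  (additive, general, simplex-dominant toward either allele), Bonferroni
  corrected over markers × models.
* **Genomic prediction** with the Bayesian alphabet — BRR, BayesA, BayesB,
  BayesC and the Bayesian lasso — fit by Gibbs sampling (10,000 iterations,
  burn-in 5,000, thinning 10 by default), with family optionally a fixed
  effect. Accuracy is the Pearson correlation between observed phenotypes
  and leave-one-out GEBVs, and panels are compared by Fisher's r-to-z test.

Because breeding data of this kind are proprietary, the package bundles a
tetrasomic simulator (`tetrapanel.simulate`): biparental families from four
shared founders, bivalent meiosis with Haldane crossovers and no double
reduction, block-mosaic founder LD, and a four-trait panel in which tuber
number is negatively correlated (target −0.467) with AUDPC susceptibility.

## Worked example

`examples/` holds one short script per capability. The marker-reduction arm
(`python examples/02_filter_and_prune.py`) prints:

```
input markers:          5120
after missingness<=10:  5069
after identity>=97%:    4716
after MAF>=0.05:        4561
target  500: retained  504 at r2 <= 0.092, mean inter-SNP spacing 1.60 Mb
target 1500: retained 1504 at r2 <= 0.170, mean inter-SNP spacing 0.56 Mb
target 2000: retained 2016 at r2 <= 0.207, mean inter-SNP spacing 0.41 Mb
```

Each line is one panel: the bisected r² threshold, the achieved size
(within 1 % of target), and the average physical gap between surviving
markers — smaller panels spread wider. The prediction arm
(`python examples/05_genomic_prediction.py`) then shows that shrinking the
panel costs no measurable accuracy:

```
panel  504 markers: LOO accuracy r = 0.636
panel 1514 markers: LOO accuracy r = 0.635

Fisher r-to-z, 500 vs 1500 markers: z = 0.01, p = 0.991
p > 0.05: the small panel predicts as well as the larger one
```

A thin CLI wraps the same functions
(`tetrapanel simulate|filter|prune|sample-individuals|gwas|predict|pipeline`),
and `tetrapanel.pipeline.run_pipeline` chains every stage from one YAML
config, writing per-stage TSV artifacts and a marker-count audit trail.

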