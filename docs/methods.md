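# Methods

This note records the models implemented in `tetrapanel`, the defaults and
why they were chosen, the numerical decisions, and what the bundled
simulator does and does not emulate.

## Dosage data model

Genotypes are alternate-allele dosages of an autotetraploid: integers 0–4
(AAAA, AAAa, AAaa, Aaaa, aaaa) or missing, stored as floats with NaN.
Orientation (which allele is counted) is internal only; every statistic
used downstream (MAF, r², kinship, regression fits) is invariant or
equivariant under the relabeling d → 4 − d, and the test suite asserts the
MAF symmetry. Coordinates are 1-based, as in VCF. Missing dosages are
written as `NA` in CSV and as the missing value of the dosage FORMAT field
in VCF.

Filters: a marker is kept when (i) it has at most `max_missing = 10`
missing calls, (ii) its probe aligns to the reference with percent identity
≥ 97 (strictly-below is discarded; markers absent from the alignment table
are dropped because an unplaceable probe cannot join windowed pruning), and
(iii) its MAF = min(p̂, 1 − p̂) ≥ 0.05, with p̂ = mean(dosage)/4 over
non-missing calls, computed on tetraploid dosages *before* diploidization.
The three filters commute; order-invariance is tested. Best hit per probe
resolves multi-hit alignment tables.

Diploidization maps 0 → 0, {1,2,3} → 1, 4 → 2, preserving missingness
exactly. It exists because two-allele LD machinery expects three genotype
classes; it is used for pruning only — GWAS and prediction consume the full
tetraploid dosages.

## LD pruning

LD between markers is the squared Pearson correlation of genotype codes
over pairwise-complete samples. A pair with a constant member, or fewer
than two complete observations, contributes r² = 0 (it cannot evidence
LD); the scalar API raises instead when fewer than two complete pairs
exist.

Pruning slides a window of `window_snps = 50` currently-retained markers in
map order (step `step_snps = 10`), per chromosome — unanchored groups "00"
and "UN" are chromosomes for this purpose, and pruning never crosses a
boundary. Within a window, offending pairs (r² strictly above the
threshold) are resolved highest-r² first; the member with the lower MAF is
removed (tie: the one later in map order), preserving the more informative
marker deterministically. Window contents are recomputed from the retained
set after every removal, and whole passes repeat until a sweep removes
nothing, which guarantees the exit condition: re-sliding the windows over
the final set finds no pair above the threshold. On single-window
chromosomes the procedure provably coincides with an exhaustive greedy
oracle, which the tests exploit.

Retained count is non-decreasing in the threshold (strictly `>` comparison;
threshold 1.0 retains everything), so `subset_for_target_size` bisects the
threshold on [0, 1], stopping when the achieved size is within
max(1, 1 % of target) or after 40 iterations, and reports the smallest
tested threshold whose panel reaches the target. A target below the
threshold-0 floor raises an error carrying that floor.

## Phenotypes

* **AUDPC**: trapezoidal integral of disease severity (0–100 %) over
  scoring dates; at least two dates, strictly increasing. Lower = more
  resistant. Units scale the integral but not any downstream ranking.
* **ICC** (proxy for broad-sense heritability in family data): one-way
  random-effects ANOVA estimator, σ̂²_b = (MSB − MSW)/n₀ with n₀ the
  weighted mean family size, ICC = σ̂²_b/(σ̂²_b + MSW), truncated to
  [0, 1]. Matches the classic ICC(1,1) on balanced designs (cross-checked
  against an independent implementation in the tests).
* **Sampling for genotyping**: standardize the trait matrix (tuber number,
  total and average tuber weight, AUDPC; flowering time excluded by default
  because field scoring leaves it incomplete), SVD-based PCA pooled over
  all scored samples, then take the non-degenerate component with the
  largest absolute AUDPC loading, sign-fixed so that loading is positive.
  Within each family, k = 11 clones are taken at evenly spaced empirical
  quantiles (nearest rank, collisions resolved to the nearest free rank,
  score ties broken by sample id) — a deterministic operationalization of
  "an even spread along the disease axis".

## Population structure and GWAS

Kinship is the realized relationship K = M Mᵀ·n/tr(M Mᵀ) with M the
column-centered (about 4p̂), mean-imputed dosage matrix; the normalization
makes the mean diagonal 1. Imputation is never written back to data.
Structure coordinates come from classical metric scaling (PCoA) of the
distance d²ᵢⱼ = Kᵢᵢ + Kⱼⱼ − 2Kᵢⱼ, delegated to scikit-bio.

The association model is y = Xβ + zα + u + e with u ~ N(0, σ²_g K); X
holds an intercept and two PCoA axes. Variance components are REML-estimated
once under the null (P3D) by profiling the restricted likelihood over
δ = σ²_e/σ²_g on the spectrum of K (25-point log-grid then bounded
minimization) — per-marker REML would cost far more and change little at
n ≈ 92. Each marker is then tested by a GLS F-test on the whitened scale
under four gene-action encodings: additive (the dosage), simplex-dominant
toward either allele (dosage ≥ 1, dosage ≤ 3), and general (four indicator
columns, rank-reduced automatically when dosage classes are absent).
Constant encodings are recorded with p = 1 and flagged. Significance uses
the most conservative Bonferroni reading: α/(markers × models), pooled over
models per trait. A QTL is a distinct significant marker (union over
models); no positional merging.

At n = 92 with family-structured material, this scan has honest but limited
power: a QTL that is informative in only some crosses is largely absorbed
by the kinship term, so genome-wide significant hits appear only for
major-effect, widely segregating loci. The calibration tests verify the
other side of the coin — family-wise error ≤ 5 % under the null and >90 %
power for a planted large effect in unstructured genotypes.

## Bayesian genomic prediction

One Gibbs sampler (numba-compiled) covers the five marker-effect priors:

* **BRR** — β_j ~ N(0, σ²_β), σ²_β ~ scaled-inv-χ²(df, S);
* **BayesA** — per-marker σ²_βj, scaled-inv-χ²(df, S);
* **BayesB** — spike at 0 with per-marker BayesA slab; inclusion
  probability π ~ Beta(π₀c, (1−π₀)c), π₀ = 0.05, c = 10. π is the *prior
  inclusion* probability: the model is sparse, with the Beta hyperprior
  letting the data revise it;
* **BayesC** — spike with a common-variance slab, same π treatment;
* **BL** (Bayesian lasso) — β_j ~ N(0, σ²_e τ²_j), τ²_j ~ Exp(λ²/2),
  λ² ~ Gamma(1.1, rate set so the prior mode matches the
  variance-partition value below).

Fixed effects (intercept, family indicators) carry flat priors; the marker
matrix is column-centered with training means stored for prediction.
Default scales follow the standard R²-partition heuristic with R² = 0.5:
the prior expects markers to explain half of Var(y), giving
S_e = Var(y)(1−R²)(df_e+2)/df_e (df_e = 5) and
S_β = Var(y)R²(df_β+2)/(df_β · Σ_j Var(z_j)) (df_β = 5; divided by π₀ for
the spike priors). When data are known to be nearly noise-free, R² should
be raised accordingly — the noiseless-recovery test uses R² = 0.9.
Chain defaults are 10,000 iterations, burn-in 5,000, thinning 10; the
τ²-update uses the Michael–Schucany–Haas inverse-Gaussian sampler.

Reported posterior summaries are means over saved draws, including the
genomic variance Var(Zβ) per draw and the genomic share
Var(Zβ)/(Var(Zβ)+σ²_e). At n = 400 these shares have substantial sampling
spread — REML on the same data shows the same — so recovery is asserted on
the mean of three simulated datasets.

LOO-CV refits the chain n times with fold seed = master seed + fold index
(reproducible, folds independent); accuracy is the Pearson correlation of
observed phenotypes with out-of-fold GEBVs, deliberately *not* divided by
√h². Constant predictions yield accuracy 0 with a warning flag. Accuracies
are compared by Fisher's r-to-z:
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), two-sided normal p. The
grid evaluator crosses trait × panel × prior × family-flag, excludes the
ancestors, and reports every cell against the best by Fisher z.

## Simulator

The generator emulates the study design the pipeline targets: 8 biparental
families from 4 shared founders (families 1–4 cross the founders directly;
families 5–8 cross F1 derivatives, making the founders grandparents), 11
offspring per family by default (n = 92 genotyped including the 4
ancestors; field-scale runs use hundreds per family), ~420 loci on each of
12 pseudomolecules plus two short unanchored groups, 0.9 Morgan per
chromosome.

Meiosis is strictly bivalent: the four homologs pair into two bivalents
(three pairings equiprobable), each yielding one recombinant chromatid with
Poisson(map length) crossovers at Haldane (no-interference) positions; no
double reduction (a config hook reserves the rate, fixed at 0). Founder LD
comes from building homologs as block mosaics of an 8-haplotype pool
(per-locus switch probability 0.08) — cheap, and it produces r² that
decays with genetic distance, which is what pruning needs; it is not a
coalescent model and makes no claim about deeper LD structure.

Traits decompose into an additive genetic value from 20 QTL, a family
effect (variance share 0.15) and a Gaussian residual, with heritabilities
0.35–0.5 per trait. QTL effect sizes follow a geometric series (ratio 0.6,
random signs): a few major loci over a polygenic tail, the architecture
reported for late-blight resistance. Susceptibility drives a logistic
disease-progress curve (midpoint earlier for susceptible clones) scored at
six dates and summarized as AUDPC by the package's own trapezoid. Tuber
number takes a calibrated share of the realized AUDPC axis — its remaining
genetics orthogonalized first — so the phenotypic AUDPC–tuber-number
correlation lands on the configured target of −0.467 (realized within
±0.01 at field scale). Genotyping noise: 0.2 % random missing calls plus
1 % of markers with ≥ 11 missing calls (to exercise the missingness
filter); 5 % of probes draw alignment identity below 97 % and 2 % are
unmapped (QC attrition rates are array-specific; these defaults are modest
placeholders, not estimates of any particular array).

What passing tests on this simulator do **not** show: behavior under
double reduction or preferential pairing, array-chemistry error modes
(systematic cluster miscalls), selection or pedigree loops in real
programs, or real potato LD topology (centromeric LD plateaus). Conclusions
about *relative* panel sizes transfer; absolute accuracies and QTL counts
do not — with 92 clones the GWAS frequently finds no genome-wide
significant marker, and prediction accuracies here run higher than typical
field values because simulated traits are cleaner.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at the study's genotyped
scale (n = 92, ~5,100 markers pre-filter) for pruning, GWAS and
prediction; field-scale checks (trait correlation, ICC, sampling) use
8 × 235 offspring with a thinned map (40 loci/chromosome), which leaves
trait statistics unchanged. Gibbs chains in the cross-validated checks are
shortened to 300–1,000 iterations after verifying on fixed data that
accuracy changes by less than Monte-Carlo noise when the chain is doubled;
single fits use 2,000–3,000 iterations.
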