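# Methods

This note documents the statistical models implemented in `twaskit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that affect results.

## Synthetic data

**Genotypes.** Each population's allele frequencies follow the
Balding–Nichols model: for ancestral frequency p (Uniform over the requested
MAF range, default (0.05, 0.5]) and divergence F_ST = F, per-population
frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F). This gives a closed-form
F_ST expectation that the test suite checks with the Hudson estimator.
Linkage disequilibrium is blockwise: within each block (default 50
variants) haplotype alleles come from a first-order autoregressive latent
Gaussian (parameter ρ, default 0.7) thresholded at each variant's frequency
quantile. We chose the latent-Gaussian form over a literal allele-copying
chain because copying biases per-variant frequencies toward the block mean,
which would break the Balding–Nichols mean-frequency property; the
Gaussian copula preserves marginal frequencies exactly while keeping
tunable, first-order within-block dependence. Dosages are haplotype sums,
so they are exact 0/1/2 counts; imputation uncertainty enters only through
per-variant quality scores (below), not through fractional dosages.

**Imputation quality.** Each variant carries a quality score in [0,1],
drawn Uniform(0.2, 1.0) once per variant; cohorts see that base score plus
Uniform(−0.05, 0.05) jitter. Quality therefore tracks the variant rather
than the cohort, as in real imputed data where the same sparse reference
coverage affects every target cohort; fully independent per-cohort draws
would make a "well-imputed in all cohorts" intersection filter reject half
the genome, which no real study shows. The filters (R² > 0.3 for
discovery training, > 0.8 for replication retraining) still remove ~12% and
~70% of variants respectively, so they remain meaningful constraints.

**Cis architecture.** Each gene receives a small number of causal variants
(default 3) sampled from its ±1 Mb window. Causal effects have equal
magnitude on the standardized-genotype scale with random signs, so the
requested cis heritability (default h²_cis = 0.3) is spread evenly across
the causal set; a `normal` option draws N(0,1) standardized effects
instead. The equal-magnitude default avoids the χ²₁ pile-up near zero that
makes one of three Gaussian effects undetectable at realistic sample sizes
— with it, "recover all causal variants" is a meaningful test of the
trainer rather than a coin flip on the effect draw. Residual noise is
scaled per gene so the realized (not just expected) cis variance fraction
matches h²_cis.

**Traits.** HGB (g/dL), HCT (%), and PLT (10⁹/L) are Gaussian on the
natural scale (means 13.5, 40, 250; SDs 1.4, 3.5, 60); WBC is built on the
log scale (mean log 6.5, SD 0.35 ×liability) and exponentiated, giving the
right-skewed distribution that motivates its log transform downstream. The
standardized liability sums expression-mediated genetic effects (gene–trait
effect × standardized cis-genetic score), covariate effects (age, sex,
genotype PCs computed from the cohort's own dosages), a Duffy-like
large-effect variant on log WBC (default −0.3 per allele), and Gaussian
noise with variance 0.6. With probability `outlier_rate` (default 0.001) a
bounded trait's value is replaced by one beyond its exclusion bound.

**What the generator does not emulate.** No recombination maps, phasing,
admixture tracts, genotyping batch effects, shared environment, or
tissue-specific expression differences. Passing tests therefore demonstrate
the pipeline's statistical correctness under its own assumptions (linear
mediation, blockwise LD, Gaussian noise), not robustness to the full
messiness of cohort data.

## Expression models

Expression is residualized on covariates (sex, age, age², genotype PCs),
then on latent factors — principal components of the covariate-residualized
expression matrix, a deliberately simple stand-in for PEER with the same
interface (count configurable, default 10) — and finally rank
inverse-normal transformed per gene, Φ⁻¹((r−½)/n). Because the factors are
estimated from expression alone, cis-genetic signal is not regressed out by
construction, but with few genes the factors can absorb real signal; the
pipeline therefore caps the factor count at one-sixth of the simulated gene
count (real panels have thousands of genes per factor, desk-scale fixtures
have dozens).

Per-gene training uses scikit-learn's elastic net at mixing α = 0.5 (the
PrediXcan convention), on standardized dosages, with the penalty chosen by
10-fold cross-validation under the **one-standard-error rule**: the
strongest penalty whose CV error is within one SE of the minimum. The min
rule was rejected after measurement: on pure-noise genes (n = 200, p = 100)
its CV curve is flat and the argmin lands at small penalties often enough
that ~50% of noise genes pass the model R² ≥ 0.05 filter; under the 1-SE
rule that rate is ~0% while genes simulated at h²_cis = 0.3 still train
with cv R² ≈ 0.28 and full causal-variant recovery. Fold assignment is a
seeded permutation stored in the model record.

Two fit statistics are kept because the field uses both and their
definitions are often left implicit: `model_r2` is the in-sample squared
Pearson correlation of fitted vs observed expression, and `cv_r2` squares
the correlation of pooled out-of-fold predictions with observations.
Squared correlations are zeroed when the underlying correlation is
negative: pooled out-of-fold predictions of a null model degenerate to
fold-training means, which are *anti*-correlated with their test folds, and
squaring that artifact would report cv R² up to ~0.13 on genes with no
signal. The gene filter is inclusive: model R² ≥ 0.05 is retained.

## Prediction and evaluation

Predicted expression is the weighted dosage sum over matched variants plus
the intercept. Alleles reconcile by REF/ALT string match, flipping dosage
to 2−d when the weight's alleles are swapped relative to the target;
strand-ambiguous A/T and C/G variants match by string only (the generator
never strand-flips). Missing weight variants are dropped, not mean-imputed,
and found/missing counts are reported — predictions stay conservative and
the user can filter. True R² is the squared correlation of predicted and
measured expression over shared samples, with zero-variance predictions
flagged and scored 0. The subsampling experiment retrains the full panel at
a reduced size (seeded draws without replacement), evaluating each
retrained set in the same external cohort, to isolate the sample-size
component of cross-panel performance.

## Association

Traits are prepared by exclusion (WBC > 200×10⁹/L, HCT > 60%,
HGB > 20 g/dL, strict inequalities, none for PLT), log transform of WBC,
residualization on age, age², sex, 10 PCs (plus Duffy dosage for WBC), and
rank inverse-normal transform. Kinship is the standard GRM,
K = ZZ′/m on variants with MAF > 0.01, Z the column-standardized dosages.

The mixed model y = Xb + ĝβ + u + ε, u ~ N(0, σ²_g K), is fit in the
eigenbasis of K. The variance ratio δ = σ²_e/σ²_g is estimated once per
trait by REML on the null model (bounded scalar search over log₁₀δ ∈
[−6, 6]) and reused for every gene — the EMMAX approximation, which makes
each gene test a weighted least squares with a Wald normal p-value. With
K = I the weights are constant and every test reduces exactly to OLS, which
the tests exploit as an oracle. Zero-variance predictions are skipped with
a flag; collinear covariate columns are dropped to a full-rank basis with a
warning.

Meta-analysis is fixed-effect inverse variance with a METAL-style direction
string ("?" for missing cohorts, order fixed by the config's cohort list).
ACAT combines p-values by T = Σwᵢ tan[(0.5−pᵢ)π]/Σwᵢ with the Cauchy upper
tail; weights default to equal (the source analyses do not justify
otherwise), p < 10⁻¹⁵ uses the linearization tan((0.5−p)π) ≈ 1/(pπ), and
exact 0/1 inputs are clamped to [10⁻³⁰⁰, 1−10⁻¹⁶] with a warning. ACAT can
be conservative for signals carried by a single ancestry-specific analysis;
the per-analysis meta p-values remain available for exactly that reason.

## Conditional analysis and loci

Conditioning sets are trait-matched known variants within ±1 Mb of the
gene, extracted from the genotypes (absent entries logged and skipped) and
greedily LD-pruned at |r| > 0.95, keeping the most significant source entry
— "all known variants" at a dense locus is otherwise collinear. The
step-2 ("recent GWAS") list additionally requires source p < 5×10⁻⁸.
Conditioning is implemented per cohort as fixed covariates in the same
mixed model, then meta-analyzed; conditioning on meta statistics with an
external LD reference would introduce approximation error we have no need
for when individual-level (synthetic) data are in hand. Step 2 runs when
step 1 is conditionally significant (p < 0.05, strictly) or the catalog has
no variants in the window; the final conditional p is the maximum across
steps run; empty sets in both steps class the pair `no_known_variants`. A
step-1 p exactly at 0.05 stops the procedure (strict inequality as
specified); the boundary case is noted here because the rule's source
leaves it ambiguous.

Loci are assigned greedily: genes sorted by marginal p; each unassigned
gene founds a locus spanning its body ± 1 Mb; remaining genes overlapping
those bounds on the same chromosome join it. The result is a partition with
sentinel = most significant member.

## Gene-level fine-mapping

For a locus with z-scores z and predicted-expression correlation R
(ridge-regularized by `ridge_eps`, default 10⁻³, then renormalized to unit
diagonal), each causal configuration C has likelihood
z | C ~ N(0, R + R_C s² R_C′) with s² = n_eff · prior_sd² — prior_sd
(default 0.05) is the prior SD of a causal standardized effect per trait
SD, and n_eff the analysis sample size, mirroring FINEMAP's
parameterization of effects on the z scale. All configurations up to k_max
(default 3) causal genes are enumerated exhaustively — loci here hold at
most a handful of genes, so enumeration is exact and directly checkable
against an independent implementation, where a stochastic-search
implementation would not be. The configuration prior is binomial on the
size with mean one causal gene, uniform within a size. PIPs sum the
posterior over configurations containing the gene; the 95% credible set
grows genes in PIP order until the configurations contained in the set
carry ≥ 95% posterior. R defaults to *predicted* expression correlation —
knowingly a limitation, since shared weight variants can make predicted
correlation misrepresent true expression correlation; the function accepts
measured expression for calibration, and `diagnose_locus` reports pairwise
weight-variant Jaccard overlap plus a flag when a credible set contains
genes uncorrelated with the top-PIP gene (the pathology where fine-mapping
stops being informative).

Numerics: likelihoods are evaluated by Cholesky with a 10⁻¹² diagonal
floor; posteriors are normalized in log space. For numerically rank-deficient
R (e.g., duplicated genes) PIP symmetry holds only to the floor's scale.

## Pipeline defaults and problem sizes

The discovery driver simulates three reference panels (one large
European-ancestry-like, n = 350; two smaller ancestry-matched, n = 220 and
240 — the ~1.5:1:1 ratio of real whole-blood vs monocyte panels), two
cohorts per ancestry (n = 600 each), a held-out replication cohort
(n = 1500), 18 genes (12 isolated, 2 clusters of 3 with two shared cis-eQTLs
per cluster member so that multi-gene loci arise), ~1,900 variants at 20 kb
spacing, and 10 gene–trait effects of ±0.2 SD. These sizes keep a full
discovery + replication run around a minute while leaving every stage's
statistics in their realistic operating range (panel-scale cv R²,
suggestive-threshold crossings, conditional and fine-mapping behavior).
Thresholds default to: training MAF > 0.05 and imputation R² > 0.3
(replication 0.8), model R² ≥ 0.05, suggestive meta p < 10⁻⁴, conditional
α = 0.05, tier-2 trigger model R² < 0.01, replication Bonferroni
α/n_signals. Stage outputs are cached with content digests in a manifest;
identical config and seed reproduce byte-identical result tables.

## Known limitations

- The hidden-factor surrogate is PCA, not PEER's variational scheme; with
  very few genes it can absorb cis signal (hence the pipeline cap).
- EMMAX estimates variance components once per trait; genes with very large
  effects would warrant exact per-gene REML, which this desk-scale use does
  not.
- ACAT treats the four panel × ancestry analyses as exchangeable; ancestry-
  specific signals are better read from the per-analysis meta results.
- Fine-mapping trusts the predicted-expression correlation matrix; the
  diagnostics flag, but do not fix, loci where shared weights distort it.
- The generator's LD is blockwise-stationary; long-range LD, inversions,
  and admixture LD are absent, so conditional-analysis behavior near such
  features is untested.
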