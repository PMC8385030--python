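# Methods

## The model

Disease status is analysed on the observed 0/1 scale with linear mixed
models.  The genome-wide (null) model is

    y = Xb + u + e,        Var(u) = G su²,  Var(e) = I se²,

where `X` holds an intercept, sex, genotyping array and the leading
eigenvectors of the genomic relationship matrix (GRM), and `G` is the
whole-genome GRM

    g_jk = (1/N) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

with `p_i` the in-sample allele1 frequency and `N` the number of SNPs.
The regional model adds one component per scan window,

    y = Xb + u + w + e,    Var(w) = Q sw²,

with `Q` the GRM built from exactly the window's SNPs (the whole-genome
component keeps all SNPs; the two components deliberately overlap).
Windows hold 50 adjacent SNPs and shift by 25 for a 50% overlap; a clipped
window closes each chromosome, and a chromosome shorter than one window
yields a single short window.

The regional variance is tested by LRT = −2 ln(L0/L1) against the null
fit.  Because sw² sits on the boundary of its parameter space under H0,
the LRT is referred to a 50–50 mixture of χ²(0) and χ²(1): p = ½·S_χ²(1)(LRT),
with p = ½ at LRT = 0.  Family-wise thresholds are Bonferroni with M/2
effective tests for M overlapping windows; only windows that converge
without extreme estimates count toward M.

Observed-scale variance ratios are converted to the liability scale with
the ascertainment-corrected case-control transformation

    h²_liab = h²_obs · K²(1−K)² / (z² P(1−P)),

where K is population prevalence, P the sample case proportion, t = Φ⁻¹(1−K)
and z = φ(t).  Standard errors scale by the same factor.  The transformation
is exact only under the liability-threshold model and is known to
under-correct slightly for strongly ascertained, highly heritable traits;
the recovery test tolerances (2 reported SEs) absorb this.

## Estimation

Variance components are estimated by restricted maximum likelihood.  The
objective (constant dropped) is −½[log|V| + log|XᵀV⁻¹X| + yᵀPy] with
V = Σ σ²_i K_i and P the usual REML projection.  The optimiser takes one
EM-REML step from the starting values (slow but monotone, it tames bad
starts), then average-information (AI) updates:

* score:  ∂l/∂σ²_i = −½(tr(P K_i) − yᵀP K_i P y)
* AI matrix:  ½ yᵀP K_i P K_j P y
* step-halving, up to ten times, whenever a proposed update would lower the
  restricted likelihood; if halving fails, one EM step substitutes.

Components are constrained at a floor of 1e−6 × phenotypic variance and
flagged when they hit it (constrained REML, which is what justifies the
50–50 mixture null).  The AI solve is active-set: a component pinned at
the floor whose gradient still points downward is held out of the Newton
system that iteration.  Without this, the pinned component's large
negative gradient contaminates the step for the free components and the
optimiser zigzags along a ridge, truncating small LRTs — with it, window
fits converge in a handful of iterations and the fitted likelihood is
insensitive to the convergence tolerance.  Convergence is |Δ logL| < 1e−4 or 100 iterations;
non-convergence returns the best estimate with a flag rather than raising,
so the scan layer can exclude the window.  Standard errors come from the
inverse AI matrix at the optimum; variance-ratio SEs use the delta method
with the full AI-inverse covariance.

All linear algebra is dense with one Cholesky factorisation of V per
likelihood evaluation.  Step-halving candidates are scored with a cheap
likelihood-only evaluation (one Cholesky, no explicit inverse); the full
gradient/AI pieces are computed once per accepted step.

Window fits start from the null-fit estimates with the regional component
at ten times the floor, which keeps ~10³–10⁴ window fits stable and fast.
A window is excluded (and does not count toward M) when its fit fails to
converge or any component exceeds ten times the phenotypic variance; that
multiplier is this package's own operational definition of an "extreme
value".

## The simulator

`simdata` emulates an array-genotyped case-control cohort:

* **Genotypes.**  Each chromosome is split into LD blocks of
  `ld_block_size` SNPs.  A pool of `n_founder_haplotypes` founder
  haplotypes is drawn site-wise from per-SNP MAFs uniform on `maf_range`;
  each individual's two haplotypes copy a uniformly chosen founder per
  block.  Block size 1 gives independent binomial(2, MAF) genotypes;
  small founder pools give strong within-block LD with free recombination
  between blocks.  This is deliberately not a coalescent: it is the
  simplest construct with tunable multi-SNP tagging, which the
  regional-scan-versus-GWAS contrast needs.  Monomorphic columns in the
  emitted cohort are repaired by toggling one haplotype in one individual,
  so every SNP is polymorphic in-sample.
* **Liability.**  liability = Σ_causal β_i z_i + covariate shifts + ε, with
  z the genotype standardised by the founder-pool (population) allele
  frequency.  Population rather than realised-sample standardisation keeps
  accrual batches exchangeable; the two coincide in expectation.  Causal
  SNPs get equal variance shares within a component with random signs:
  polygenic SNPs are all SNPs outside designated regions; each designated
  region places `n_qtls` causal SNPs uniformly in its span.  Residual
  variance tops the genetic variance up to 1, so the liability-scale
  fractions sum to one by construction.  Covariates (sex, array) are
  Bernoulli(0.5), independent of genotype, with zero liability shift by
  default — the analysis adjusts for them but the generator does not
  confound them.
* **Ascertainment.**  An individual is a case when liability exceeds
  Φ⁻¹(1−K).  Individuals are generated in batches until the requested case
  and control quotas are met exactly, so the emitted case fraction equals
  n_cases/(n_cases+n_controls) by construction; an attempt cap turns
  hopeless accrual (tiny K) into an error.  All emitted individuals are
  unrelated — the generator does not model family structure, population
  stratification, genotyping error, or X-linked variation, so passing
  tests say nothing about those features of real cohorts.

Ground truth (causal effects, variance fractions, threshold, realised
pre-ascertainment prevalence) is written as a key=value sidecar next to
the PLINK set, so parameter-recovery tests carry no hidden state.

## Quality control

Filters apply in a fixed, logged order: call rate (samples, then SNPs, to
a fixed point so both thresholds hold simultaneously and the filter is
idempotent) → MAF → exact HWE test → windowed LD pruning → relatedness.
Defaults mirror common array QC: 0.98/0.98 call rates, MAF ≥ 0.01,
HWE p ≥ 1e−6, LD pruning 50/5/0.8, relatedness 0.1.

The HWE test is the exact conditional test: enumerate all heterozygote
counts compatible with the observed allele totals and sum the
probabilities of configurations no more probable than the observed one
(two-sided by probability mass); it is computed on all samples, cases
included.  LD pruning is greedy within a sliding window: of any pair with
genotype r² above the cap, the lower-MAF member goes (tie: later
position).  Relatedness is screened on GRM off-diagonals rather than
method-of-moments IBD pi-hat — at a 0.1 cutoff the two agree in
expectation for an unrelated/related dichotomy — removing the member of
the worst pair with the higher mean relatedness until no pair exceeds the
threshold.  Missing calls are excluded pairwise in MAF, HWE and r²; in
the GRM a missing call contributes zero with the divisor kept at N.

## Numerical and format details

* PLINK 1 binary: SNP-major bed (magic 0x6c 0x1b 0x01), calls count
  allele1, codes 00/10/11 = 2/1/0 copies, 01 missing; round-trips are
  bit-exact.  GCTA GRM triplet: lower triangle (diagonal included) as
  float32, constant per-pair SNP count, tab-separated ids.
* PCA is the eigendecomposition of the GRM (not an SVD of genotypes),
  eigenvalues descending, each eigenvector's largest-magnitude loading
  made positive for determinism.
* GWAS: per-SNP additive logistic regression (effect allele = in-sample
  minor allele) fitted by Newton/IRLS with covariate adjustment;
  separation or non-convergence flags the record and leaves p missing.
  The inflation factor λ converts p-values to χ²(1) quantiles and divides
  the median by 0.4549364; the mixture's point mass at p = 0.5 puts the
  null median exactly at the χ²(1) median, so λ ≈ 1 is the calibrated
  reference for the scan as well.
* The regional GRM re-uses the whole-sample allele frequencies (windowing
  does not change frequencies), which also makes regional GRMs over a
  partition of SNPs average back to the whole GRM exactly.

## Problem sizes in the test suite

The suite exercises the full pipeline at desk scale, chosen so each
end-to-end check completes in minutes on one core: null-calibration scans
use n = 500 with 4000 SNPs (159 windows, overlapping) and n = 300 with
25,500 SNPs (510 non-overlapping windows, for independent null draws);
liability-scale recovery uses n = 2000 with all 2000 SNPs causal at
h² = 0.3 and K = 0.1; the multi-QTL power contrast uses 20 replicates of
n = 1000 over a 500-SNP chromosome with one 5-QTL window at 5% liability
variance.  Single-SNP calibration uses 2000 null SNPs at n = 400.

## Known limitations

* The observed-scale linear mixed model plus liability transformation is
  an approximation for binary traits; generalised (logit/probit) mixed
  models are out of scope.
* The GRM missing-call convention (zero contribution, divisor N) differs
  from per-pair divisors used by some tools; simulations here emit
  complete data, so the difference never enters the calibration results.
* Dense algebra bounds practical cohort sizes to a few thousand
  individuals; no low-rank or sparse acceleration is attempted.
* The simulator draws unrelated individuals only, so the relatedness
  filter is exercised on constructed cases rather than realistic pedigree
  structure.
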