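# Methods

This note records the statistical models, the synthetic-data design, the
numerical choices, and the known limitations of `twasmr`.

## Kinship mixed model (discovery TWAS)

Per gene the model is expr = Xβ + u + ε with u ~ N(0, σ²_g K) and
ε ~ N(0, σ²_e I). K uses the numerator-relationship convention: unit
diagonal, 0.5 expected for full sibs, 0 across families. Estimation is
REML by the standard spectral trick: decompose K = U S Uᵀ once per scan,
rotate y and X by Uᵀ, and profile the restricted likelihood over the
single variance ratio δ = σ²_g/σ²_e. The 1-D search is a bounded Brent
minimisation on log δ over [10⁻⁶, 10⁶] with xatol 10⁻⁸; both interval
ends are also evaluated, and boundary optima are returned with
`converged=True` and `boundary=True`. At the optimum, β̂ and its
covariance come from the weighted (GLS) normal equations with
σ̂²_e = RSS_w/(n−p).

When K is the identity the split between σ²_g and σ²_e is unidentified —
any δ yields the same β̂, SE, and σ̂²_g+σ̂²_e — so only the total variance
is interpretable there.

**Wald reference.** All association p-values in the package (LMM TWAS,
replication GLM, GWAS scan) use the t reference with n − p residual
degrees of freedom. Residual df is exact for the ordinary linear models;
under REML it is the conventional approximation. Using one reference
everywhere makes the LMM collapse *exactly* onto the ordinary model at
K = I, a property the test suite asserts to 10⁻⁶; at the cohort sizes
this package targets, t and normal references agree to three significant
figures anyway.

## Replication GLM, meta-analysis, and the replication protocol

Replication cohorts are modelled per gene as expr = β₀ + β₁·log₁₀(trait)
+ covariates + ε by OLS, vectorised across genes (shared design matrix,
per-gene response). Expression is the response and the log-trait the
predictor in both discovery and replication — the directionality of the
printed effect sizes; causal direction is deferred entirely to the MR
stage.

Study combination is the weighted inverse-normal method on *signed*
one-sided z-scores: z_s = sign(β_s)·Φ⁻¹(1−p_s/2), weights √n_s
normalised so Σw² = 1, combined two-sided p from the normal. Signing
makes opposite-direction effects cancel, which is what a replication
claim requires; an unsigned mode (`signed=False`) and n-proportional
weights (`weight_scheme="n"`) are available for sensitivity analysis.
p-values of exactly 0 or 1 are clamped to [1e−300, 1−1e−16] with a
logged warning.

Replication is declared at meta p strictly below α/m, where m counts the
discovery-significant (BH q < 0.05) features present in the replication
universe; features absent from a cohort reduce m rather than failing.
The bidirectional set is the intersection of the two directed
replication sets.

## Mendelian randomization

**One-sample 2SLS.** Stage 1 regresses the exposure on the instrument
(plus covariates when requested); stage 2 regresses the outcome on the
fitted exposure. The SE follows the 2SLS convention: residuals are
recomputed with the *original* exposure at the 2SLS coefficient, then
Var(β̂) = σ̂²(ŴᵀŴ)⁻¹ with Ŵ the instrument-projected regressor matrix.
MR p-values use the two-sided normal reference, the summary-statistics
MR convention.

Instrument strength is F = (n−2)R²/(1−R²) from the simple
instrument-exposure regression; for instruments selected from summary
eQTL records this is recovered as the squared Wald t. Exclusion is
strictly F < 10, so F = 10 is retained. The weak-instrument filter is
also applied to the reverse-direction risk score — the weak-instrument
argument is symmetric — and can be disabled per call.

Covariates are *not* included in the MR stages by default (pure IV
regression); a flag includes them in both stages.

**Classification rule** at level α (default 0.05), strict < for
significance: `putative_causal` iff p_fwd < α and p_rev ≥ α; `reverse`
for the mirror image; `bidirectional` when both; otherwise `none`.
Under the global null the putative-causal rate is α(1−α) ≈ 0.0475,
which the acceptance suite verifies by simulation.

**Two-sample MR.** Exposure/outcome pairs are matched by SNP ID;
swapped allele pairs flip the outcome sign; irreconcilable allele sets
are dropped with reason `allele_mismatch`. A/T and C/G pairs are flagged
palindromic and *kept* by default (no strand inference is attempted);
`drop_palindromic=True` drops them. Single-SNP genes use the Wald ratio
β_gy/β_gx with first-order SE se_gy/|β_gx|; multi-SNP genes use
fixed-effect IVW over per-SNP ratios. Harmonization is idempotent.

## Over-representation

Upper-tail hypergeometric including the observed count, P[X ≥ k], with
overlaps restricted to the declared universe. The universe defaults to
the genes actually tested in the analysis producing the hit list (not
the genome) — the standard ORA background correction. BH FDR across the
sets tested in one call.

## Synthetic cohorts

The generator emulates a family-based discovery design plus unrelated
replication cohorts:

- **Genotypes.** SNPs are independent Hardy–Weinberg draws with MAF
  uniform on `maf_range` (default 0.05–0.5). Families are sib-ships
  sharing two simulated parents, giving expected relatedness 0.5 within
  a block; remaining subjects are unrelated. Multi-generation pedigrees
  are deliberately not modelled — sib blocks suffice to exercise the
  kinship random effect. No linkage disequilibrium is simulated.
- **Expression.** Per gene: one cis-SNP explaining `eqtl_r2` (default
  0.2) of unit expression variance, a kinship-correlated polygenic term
  (`polygenic_var`, default 0.1) sampled in O(n) from the sib-block
  structure, and Gaussian noise.
- **Trait.** On a log₁₀-IgE-like scale (mean 1.52, matching adult
  population levels in kU/L). Covariate effects (age, sex, smoking,
  pack-years) default to small plausible values and are
  config-controlled. Six designated risk-score SNPs act on the trait in
  *every* scenario — they stand for genome-wide-significant trait loci,
  which exist regardless of any expression-trait edge — with equal
  weights by default (`prs_weights` overrides) and `prs_r2` (default
  0.1) of the genetic-plus-noise trait variance.
- **Scenarios.** `forward`: trait += θ·expr for the first `n_causal`
  genes. `reverse`: expr += θ·(trait − mean). `mediated`: expression
  raises the eosinophil fraction, which raises the trait, with variance
  fractions set by `mediator_strength`. `null`: no path. Truth (scenario,
  θ, cis-SNP) is recorded per gene.
- **Disease GWAS.** A liability-threshold model: standard-normal
  liability plus stated per-allele effects; cases are the top
  `prevalence` fraction; per-SNP summary statistics are then *estimated*
  from the observed data by linear regression of case status on dosage,
  with eaf, n, and info columns filled from the data.

Expression is continuous and Gaussian (array-style RMA-like values);
there is no count model, batch structure, probe-level noise, or
LD between instruments. Passing tests therefore demonstrate the
statistical machinery under clean conditions — calibration, parameter
recovery, protocol logic — not robustness to array normalisation
artefacts, population stratification, or correlated instruments.

## Problem sizes used by the test and acceptance runs

Chosen to make Monte-Carlo error small relative to the tolerances while
keeping desk-scale runtimes:

- Type-I calibration (TWAS and forward MR): 1000 null genes, n = 1000
  subjects (250 sib pairs + 500 unrelated), bands from the binomial 99%
  CI around 0.05 (and around 0.0475 for the classification rule).
- Meta-analysis null uniformity: 10,000 genes, two studies, KS test.
- GWAS inflation: 2000 SNPs × 3 permuted traits pooled (6000 statistics)
  so the median-based λ has SD ≈ 0.03 against the [0.9, 1.1] band.
- Parameter recovery: 200 replicates at n = 5000, θ = 0.5,
  eqtl_r2 = 0.2; bias tolerance 0.05, coverage band [0.92, 0.98].
- Reverse-scenario classification: 20 cohorts × 10 causal genes at
  n = 5000, requiring ≥ 75% labelled `reverse`.

## Numerical conventions and degenerate inputs

- BH step-up by sorted cumulative minimum; ties stable; q capped at 1.
- HWE test: 1-df chi-square against expected counts at the observed
  allele frequency; monomorphic SNPs return p = 1 by convention (nothing
  to test) and are left to the MAF filter.
- QC order and reporting: call rate, HWE, MAF, info; the first failing
  rule is logged per SNP. Retention is ≥ at each threshold except HWE
  (excluded strictly below `hwe_p_min`); imputation info = 0.20 is
  retained.
- Zero-variance genes and constant dosage columns yield p = 1 with a
  logged warning rather than an error.
- eQTL instrument ties: minimum p, then larger |β|, then lexicographic
  SNP ID.
- PCA sign convention: the largest-magnitude loading of each component
  is positive.
- Genomic λ: median implied 1-df chi-square over χ²₁-median
  (≈ 0.454936), computed via scipy at run time.
- Tables are written at 6 significant digits with LF endings, rows
  ordered by ascending p then feature ID, so identical runs are
  byte-identical; sample alignment is always by ID join.

## Known limitations

- Reverse MR instruments every gene with one shared risk score; with
  very many genes the per-gene reverse tests are correlated through it.
- The two-sample MR stage is validated on synthetic summary statistics
  only; outcome-scale effect sizes from biobank GWAS are not
  reconstructible from printed tables.
- The REML df approximation (n − p) is not exact for the mixed model;
  at n in the hundreds-plus it is immaterial.
- The weak-instrument cutoff F ≥ 10 is the conventional rule of thumb,
  not a calibrated size correction.
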