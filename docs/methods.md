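# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind the package, in the spirit of the model
documentation shipped with packages such as statsmodels or msprime.

## Two-stage association model

Per gene, stage one fits the linear prediction model
`PDUI = Σ Wᵢ Gᵢ + ε` on a training cohort, where `G` is the sample × SNP
dosage matrix of the gene's cis window and PDUI is the percentage of distal
poly(A) site usage index, the per-sample fraction quantifying 3′UTR
isoform choice. Four estimators are fit — ridge-BLUP, elastic net
(mixing 0.5), LASSO, TOP1 — and the one with the best five-fold
cross-validated R² (squared Pearson correlation of out-of-fold predictions)
is selected; ties break in the fixed order enet > lasso > blup > top1. The
selected coefficient vector, on raw dosage scale and with signs intact,
forms the diagonal weight matrix `W = diag(W₁ … Wₙ)`.

Stage two is a variance-component score test. With an intercept-only null
model (no covariates by design) and residuals `r = y − μ̂`,

    Q = rᵀ K_w r,   K_w = G W Gᵀ.

Under H₀, `Q ~ Σ λᵢ χ²₁` with `λ` the eigenvalues of `v · C K_w C`, where
`C` is the centering projection and `v` the null variance scale — the
phenotype sample variance (n−1 denominator) for quantitative traits, or
`μ̂(1−μ̂)` with `μ̂` the case fraction for binary traits (the intercept-only
logistic MLE). For the weighted-linear kernel the eigenvalue problem is
reduced to SNP space: with `Gc` the column-centered dosages and
`GcᵀGc = SᵀS` (eigen square root), the nonzero λ are the eigenvalues of
the p × p symmetric matrix `S W Sᵀ`, so cost scales with SNP count, not
cohort size.

### Signed weights, orientation, and tail probabilities

Because the trained weights keep their signs, `K_w` may be indefinite and
the null spectrum contains negative eigenvalues. The tail probability
`P(Σ λᵢ χ²₁ ≥ q)` is computed by exact characteristic-function inversion
(Imhof's integral, the same family of exact methods as Davies' algorithm,
and equally valid for signed λ). One subtlety: when the retained spectrum
has negative total mass (Σλ < 0 — e.g. a single-SNP gene whose trained
weight is negative), any true association pushes Q *downward*, so the upper
tail is powerless there; in that case the spectrum and the observed Q are
jointly negated before taking the tail. The rule depends only on the
kernel, never on the phenotype, so null p-values remain exactly uniform,
and the test reduces to the marginal score test for single-SNP genes of
either weight sign (verified to relative 1e-6 in the test suite).

Numerics of the inversion: the integrand `sin θ(u) / (u ρ(u))` oscillates
at frequency `q/2` under an envelope decaying only as `u^−(1+m/2)`, which
defeats plain adaptive quadrature on an infinite range when the number of
eigenvalues m is small. The integral is therefore split at `u = 1` (after
rescaling λ to unit spectral radius): the head is integrated adaptively
(target absolute error 1e-12), and the tail uses the identity
`sin θ = sin α cos(qu/2) − cos α sin(qu/2)` to produce two Fourier
integrals with smooth monotone amplitudes, evaluated by QUADPACK's QAWF
rule. Eigenvalues with `|λ| < 1e-10 · max|λ|` are dropped; a
single-eigenvalue spectrum dispatches to the exact scaled-χ²₁ tail;
p-values below 1e-12 are floored there. If the quadrature does not
converge, a Liu-type four-moment non-central χ² match is used and the
result is tagged `liu_fallback`. Against the exact χ²ₖ closed form (unit
weights) the inversion agrees to ~1e-13; against 10⁶-draw Monte Carlo it
agrees within Monte-Carlo error across mixed-sign spectra.

### Linear baseline

The linear APA-TWAS statistic combines per-SNP GWAS z-scores with the same
trained weights, `Z_apa = wᵀz / √(wᵀRw)`, `R` the dosage correlation (LD)
matrix of a reference genotype slice, and is tested two-sided against
N(0, 1). The `1/√(wᵀRw)` normalization is required for `Z_apa` to be a
z-score; without it no p-value exists.

### Kernel catalogue

Beyond the default weighted-linear kernel, the package provides linear,
quadratic `(1 + GGᵀ)²`, 2wayIX (main effects plus all pairwise SNP
products; computed via the closed form
`Σ_{k<l}(x_k x_l)(y_k y_l) = ((x·y)² − Σ x_k² y_k²)/2`), IBS
(allele sharing `Σ (2 − |gᵢ − gⱼ|) / 2p`), and weighted IBS. Where an
MAF-derived diagonal weight matrix is needed, the squared Beta(MAF; 1, 25)
density is used — the standard variance-component-test convention; the
exact functional form is a convention choice, not an identity. All kernels
are symmetrized as `(K + Kᵀ)/2`; linear/quadratic/IBS/2wayIX kernels are
PSD, the weighted-linear kernel with signed weights may be indefinite by
construction.

## Weight-training choices

* Genotype columns are standardized inside every fitter and coefficients
  are mapped back to dosage scale, so exported weights apply to raw
  dosages. PDUI is used untransformed.
* BLUP is realized as ridge regression over all cis SNPs with the penalty
  selected from a log-spaced grid (1e-2 … 1e3, 8 points) by five-fold CV —
  the standard linear-kernel BLUP equivalent that keeps the module
  self-contained.
* The lasso/elastic-net penalty is chosen once per gene by an internal
  five-fold CV on the full sample (path-based, 20 penalty values); the
  outer five-fold CV that produces R²_cv then refits at that fixed penalty.
  A nested search would multiply cost roughly five-fold without changing
  the selection contract.
* Folds are near-equal seeded partitions; when sample ids are supplied,
  each sample's fold derives from a keyed hash of its id, making R²_cv
  invariant to sample reordering.
* A model whose *final* full-sample fit is entirely zero can still carry a
  small positive R²_cv (its fold fits were nonzero). If such a model wins
  selection the gene has no usable weights: the association stage returns
  p = 1 with a `zero_weights` flag, and calibration experiments count the
  gene as untested — association pipelines only test genes with a trained
  model. On pure-noise transcriptomes this affects roughly a quarter of
  genes at n = 300, p = 20.

## Simulation framework

* **Genotypes.** Per gamete, a latent AR(1) Gaussian chain (coefficient
  `ld_rho`, default 0.2) is thresholded at the upper MAF quantile; dosage
  is the sum over two independent gametes. MAFs are drawn uniformly from
  [0.05, 0.5] by default — the post-QC regime. This reproduces
  Hardy–Weinberg margins and tunable pairwise LD (`ld_rho = 0.99` gives
  adjacent-pair r² > 0.8); it does not reproduce coalescent-grade LD decay,
  allele-frequency spectra, or population structure, so power results
  transfer to real cohorts only qualitatively.
* **Architectures.** Additive values are `Σ wⱼGⱼ`, `wⱼ ~ N(0,1)`.
  Non-additive rules act on carrier indicators `c = 1{dosage ≥ 1}` —
  single: `c₁`; epistatic: `c₁·c₂`; heterogeneous: `max(c₁,c₂)`;
  compensatory: `c₁ XOR c₂` — with unit effect size, since heritability
  scaling absorbs any constant.
* **Heritability.** `σ²_g` is the *empirical* variance of the realized
  genetic value in each replicate; noise is drawn with
  `σ²_e = σ²_g(1−h²)/h²`, so `σ²_p = σ²_g + σ²_e` and the realized
  `var(g)/var(x)` converges to the target (within ±0.02 at n = 20,000).
* **Assumptions.** Pleiotropy: `PDUI = g + e₁` at `h2_apa` and
  `y = g + e₂` at `h2_pheno`, independent noise. Causality:
  `y = PDUI + e₂` with the *end-to-end* genetic fraction
  `var(g)/var(y) = h2_pheno`, i.e. `σ²_e₂ = σ²_g(1/h2_pheno − 1/h2_apa)`;
  cells with `h2_pheno > h2_apa` are infeasible under this chain and are
  logged and skipped by the experiment driver. How noise splits across the
  two stages is genuinely open; this is the reading where `h2_pheno` keeps
  its usual meaning as the trait's genetic fraction.
* **Binary traits.** The liability (the quantitative y) is thresholded at
  its empirical (1 − prevalence) quantile; prevalence defaults to 0.5
  (maximal case-control information) and is configurable.
* **Null design.** For type-I-error calibration, per-gene transcriptome and
  phenotype are iid N(0,1), independent of freshly drawn genotypes, and the
  *entire* pipeline (training, selection, both tests) runs on them. Null
  GWAS z-scores for the linear baseline are drawn from their exact null law
  `z ~ MVN(0, R)`.
* **Reproducibility.** All randomness flows from one scenario seed through
  `numpy.random.SeedSequence` spawning (selection / effects / APA noise /
  phenotype noise are separate streams); datasets are bit-identical across
  reruns.

## Experiment drivers and scales

Power experiments use a two-cohort design mirroring a
train-on-reference / test-on-cohort split: weights are trained on one
cohort's genotypes + PDUI, both tests run on an independently drawn test
cohort (the kernel test on individual-level phenotypes; the baseline on
marginal score z-statistics computed in the test cohort). Power is the
fraction of genes with p strictly below the Bonferroni threshold `α/m`,
with `m` the number of genes in the run. The shipped grids are
7 architectures × 6×6 heritabilities (pleiotropy, 252 cells),
7 × 5×5 (causality, 175 cells), and an extended
{0.10, 0.20, 0.40, 0.60, 0.80} grid.

The default calibration and power scales in the tests and the acceptance
script — 5,000 null genes at 300 samples × 20 SNPs; 500 genes per power
cell with train n = 300 / test n = 1,000 — were chosen as the smallest
scales at which the binomial acceptance bands are meaningful; the empirical
5% cutoff, type-I error, and power estimates all carry the corresponding
binomial standard errors.

## Known limitations

* No covariate adjustment anywhere (by design); confounded real cohorts
  need upstream residualization.
* Common variants only; no rare-variant weighting or burden aggregation.
* The genotype generator's LD model is AR(1); architectures with long-range
  or block LD are outside its reach.
* The weighted-linear kernel's orientation rule optimizes power for
  spectra dominated by one sign; a balanced mixed spectrum with opposing
  true effects remains a hard case for any single-tailed quadratic test.
* PLINK input is limited to the bed v1.00 SNP-major layout (the common
  case); VCF, phasing, and strand reconciliation are out of scope.
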