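# Methods

This note documents the statistical model, the estimation machinery, the
simulator, and the numerical and design choices behind `longgwas`.

## The random regression model

A longitudinal phenotype is a trait recorded repeatedly on the same
individual (test-day milk yield, blood pressure, growth).  The package
models the record of individual *i* at time *t* as

    y_i(t) = mu(t) + a_i(t) + p_i(t) + e_it,

where mu(t) is the population mean trajectory, a_i(t) the additive genetic
trajectory, p_i(t) the permanent environmental trajectory (the non-genetic
individual effect shared across that individual's records), and e_it white
residual noise.  Each trajectory is a regression on normalized Legendre
polynomials of time standardized to [-1, 1]:

    mu(t)  = sum_{k=0}^{nf}  b_k  phi_k(t),
    a_i(t) = sum_{k=0}^{nr1} a_ik phi_k(t),
    p_i(t) = sum_{k=0}^{nr2} p_ik phi_k(t),

with phi_k(x) = sqrt((2k+1)/2) P_k(x).  The normalization (the convention
standard in random-regression animal models) makes the basis orthonormal
on [-1, 1]; it rescales coefficients relative to unnormalized Legendre
polynomials but leaves fitted curves, test statistics and cumulative
effects unchanged.  "Order" always means the highest degree, so an
order-q term has q + 1 coefficients.

Stacked over the m records, y = Xb + Qa + Zp + e with

    var(a) = A (x) G,   var(p) = I (x) P,   var(e) = I sigma_e^2,

where A is the pedigree numerator relationship matrix, G and P the
(nr1+1)- and (nr2+1)-dimensional coefficient covariance matrices, and (x)
the Kronecker product.  The vector b holds the nf + 1 mean-curve
coefficients (plus any SNP-term coefficients during a scan).  With the
variance components fixed, BLUE/BLUP solutions come from Henderson's mixed
model equations (MME); A^{-1} is assembled directly from the pedigree by
Henderson's rules with the inbreeding adjustment, so inbred matings are
handled exactly.

## REML

Variance components maximize the residual log-likelihood

    logL = -1/2 [ (m - p) ln 2*pi + ln|V| + ln|X'V^{-1}X| + y'Py ].

Rather than average-information updates, the implementation maximizes this
objective directly with a quasi-Newton optimizer (L-BFGS-B, Nelder-Mead
fallback) over a log-Cholesky parameterization of (G, P) and log
sigma_e^2, which keeps every iterate inside the parameter space and is
robust for the modest parameter counts involved (13 parameters at orders
2/2/2).  Convergence follows the optimizer's relative-change criteria; the
fit is rejected if the final likelihood does not improve on the
initialization.  Initial values are scale-aware: sigma_e^2 starts at half
the phenotypic variance and G, P start diagonal, splitting the remainder
evenly.  Any variance estimated below 1e-8 times the phenotypic variance
is pinned at that floor so the MME stay well posed.

Two equivalent computational paths evaluate the likelihood:

* **Balanced kernel.**  When every individual shares one recording grid
  (the simulator's design), the eigendecomposition A = U D U' rotates the
  stacked model into n independent T-dimensional blocks with covariance
  Sigma_i = d_i Phi_a G Phi_a' + Phi_p P Phi_p' + sigma_e^2 I.  A
  generalized eigendecomposition of the two T x T kernels reduces each
  likelihood evaluation to elementwise work on an (n, T) array, so a full
  REML fit on 500 individuals x 10 records takes well under a second.
  BLUPs, prediction error variances (including the fixed-effect
  contribution) and scan statistics have closed forms in the rotated
  coordinates; the test suite verifies they equal the MME quantities to
  numerical precision.
* **Sparse MME.**  Arbitrary record patterns use the assembled MME; the
  REML likelihood is recovered from the factorization of the coefficient
  matrix via ln|V| + ln|X'V^{-1}X| = ln|C| + m ln sigma_e^2 + ln|A (x) G|
  + ln|I (x) P|, with ln|A| obtained for free as the sum of log Mendelian
  sampling variances.

AIC = -2 logL + 2k and BIC = -2 logL + k ln m count only the free variance
parameters, k = (nr1+1)(nr1+2)/2 + (nr2+1)(nr2+2)/2 + 1, the REML-standard
convention (counting fixed effects too is a deliberate non-feature since
REML likelihoods with different fixed structures are not comparable
anyway; order selection compares models with identical fixed parts).
`select_orders` fits a grid and picks the smallest BIC, ties resolved
toward fewer parameters.

## Time-varied SNP scans

Both scans plug in the variance components estimated once under the
reduced (no-SNP) model — the standard plug-in strategy of mixed-model
association tools — and test each SNP with the incremental Wald statistic

    W = [R(full) - R(reduced)] / sigma_e_hat^2  ~  chi^2_{df_w},

where R(model) = b'X'y + a'Q'y + p'Z'y is the reduction in sums of squares
of the model.  A per-SNP REML refit is available behind a flag but is not
the default.

* **fGWAS-C** adds the fixed term x_i SNP(t), x_i the dosage in [0, 2]
  and SNP(t) an order-nf Legendre curve (the SNP curve order equals the
  mean order by design); df_w = nf + 1.  Continuous imputed dosages are
  accepted.  Missing calls are mean-imputed per SNP.
* **fGWAS-F** adds one curve per observed genotype class.  The class
  curves are parameterized against the lowest observed genotype as
  reference (its curve is absorbed into mu(t) and reported as zero), which
  leaves the Wald statistic invariant and makes the additive/dominance
  decomposition below well defined; df_w = (#observed classes - 1)(nf+1),
  i.e. 2(nf + 1) when all three genotypes occur.  Records with missing
  calls are dropped for that SNP, and the reduced-model R is recomputed on
  the same subset so the incremental difference remains valid.  Dosage
  input is rejected with a pointer to fGWAS-C.

From the fGWAS-F class curves,

    add(t) = [SNP_AA(t) - SNP_aa(t)] / 2,
    dom(t) = SNP_Aa(t) - [SNP_AA(t) + SNP_aa(t)] / 2,
    sigma^2_{a,SNP}(t) = 2 p q [add(t) + dom(t)(q - p)]^2,

with p the sample frequency of the coded (ALT/second) allele.  The
dominance contrast is the midpoint convention, the only definition
invariant to how the class curves are identified against mu(t); under the
reference coding used here it coincides with subtracting add(t) from the
heterozygote curve, and a `dominance_convention` switch exposes the
alternative form explicitly.  Cumulative effects are sums of the fitted
curve over the integer time grid t_min..t_max (the accumulation vector
Q_c = sum_t [phi_0(t) .. phi_k(t)]).  The per-SNP "heritability" reported
is the grid mean of sigma^2_{a,SNP}(t) divided by the model-implied
phenotypic variance at t.

Monomorphic and sub-MAF SNPs (default MAF threshold 0.01) are flagged
untestable with W = 0, p = 1; a collinear SNP design raises a per-SNP
warning and the scan continues.

## Pseudo-phenotype baselines

The comparison strategies collapse each phenotyped individual to a scalar
computed from the reduced fit:

* accumulated EBV, EBV_i = Q_c' a_hat_i;
* deregressed proof, DRP_i = PA_i + (EBV_i - PA_i)/max(r2_i, 0.1) with
  PA_i the parent average of accumulated EBVs (unknown parent contributes
  zero) and reliability r2_i = 1 - PEV_i / (Q_c' G Q_c), PEV from the
  inverse-MME diagonal blocks.  This is a single-step parent-average
  removal rather than the full information-weighted deregression system;
  it captures the property the comparison needs (parent-average signal
  removed, Mendelian-sampling signal re-expanded) at desk scale, with the
  reliability floor capping variance inflation for weakly informed
  individuals;
* averaged estimated residual (the GRAMMAR-style two-stage response).

Each pseudo-phenotype is regressed on the SNP dosage, either with a
polygenic term u ~ N(0, A sigma_a^2) whose variance ratio is estimated by
a one-dimensional REML profile on the eigenbasis of A (the "-P" models),
or by ordinary least squares (the "-NP" models and the residual scan).
All baseline tests have one degree of freedom.

## The simulator

The generator emulates a dairy-style experimental design:

* **History.**  Wright-Fisher random mating at constant size 100 for 100
  generations from founder allele frequencies Uniform(0.1, 0.9).  The
  history only serves to induce drift and background relatedness; loci
  segregate independently because the methods under test use pedigree
  relationships, not LD.  (A thousand-generation history would change the
  allele-frequency spectrum slightly but nothing the tested methods
  consume.)
* **Recorded pedigree.**  One expansion generation forms the recorded
  founders (2 x n_dams individuals), followed by four generations in which
  n_sires randomly chosen males are mated to the n_dams females of the
  previous generation, two offspring (one male, one female) per dam.  The
  females of the four recent generations are the phenotyped cohort: 2,000
  at the default scale (500 dams), 500 under the desk profile (125 dams,
  13 sires, preserving the 1:10 sire:dam ratio).
* **SNPs.**  1,002 by default: index 0 the causal QTN, index 1 a
  null-effect SNP for type-I error, 1,000 background SNPs that generate
  the polygenic effects and are withheld from the exported genotypes.  A
  config with more SNPs than background + 2 exports the surplus as extra
  null markers (used for calibration experiments).  The QTN and null SNP
  start at frequency 0.5 and are re-dropped through the same stored
  parentage (bounded retries) if drift takes their cohort MAF below 0.1,
  so both stay testable in every replicate.
* **Phenotypes.**  Ten records per female on the integer grid 5..305
  (test-day-like; configurable), y_i(t) = mu(t) + x_i qtn(t) + a_i(t) +
  p_i(t) + e_it with a fixed quadratic mu(t).  The QTN curve is an order-2
  normalized-Legendre shape scaled so its sum over the 301-point grid is
  exactly 175.21 (the configured cumulative effect); the curve itself is
  never rescaled afterwards.  The polygenic trajectory sums centred
  background dosages times per-SNP random order-2 coefficient vectors;
  the permanent environmental trajectory uses per-individual random
  coefficients.  Scales are calibrated on the realized cohort so the
  time-averaged variance shares hit the configured partition — trait
  heritability 0.3 (QTN share qtn_h2 in {0.1%, 0.5%, 1%, 2%}, polygenic
  share 0.3 - qtn_h2), permanent environment 0.2, residual 0.5 — and the
  total phenotypic variance is set by qtn_h2 through the fixed QTN curve:
  sigma_P^2 = mean_t var(x) qtn(t)^2 / qtn_h2.  The permanent-environment
  share and the residual share are not separately specified by the study
  design; 0.2/0.5 is a typical test-day partition and is held fixed.

What the generator does **not** emulate: linkage and LD blocks, selection,
heterogeneous residual variance over lactation stages, seasonal or herd
fixed effects, genotyping error.  Passing tests therefore demonstrate the
estimators' behaviour under a correctly specified pedigree-based model
with unlinked markers; they do not establish robustness to LD structure
or model misspecification in real data.

`run_experiment` replicates the full comparison: per replicate
(seed = base seed + replicate index) it simulates a dataset, REML-fits the
reduced model, runs the requested scans on the QTN and the null SNP, and
aggregates power, type-I error and the mean/SD/RMSE of the cumulative
additive (and, for fGWAS-F, dominance) effect estimates against the truth.
Replicates whose REML fails are excluded and counted.

## Numerical choices and degenerate inputs

* Eigenvalues of A are floored at 1e-10; PSD covariance arguments are
  lifted onto the PD cone by eigenvalue flooring before inversion.
* The incremental Wald difference tolerates numerical noise of 1e-8
  (relative) before clipping at zero with a warning.
* Tied BIC values in order selection break toward fewer parameters.
* A phenotyped individual absent from the pedigree is appended as a
  founder with a warning.
* Time points outside the standardization domain, duplicate pedigree ids,
  pedigree cycles, empty scan tables and out-of-range p-values all raise
  immediately with the offending record named.

## Problem sizes used in the shipped experiments

The packaged acceptance script and test suite run the study at desk scale,
chosen as the standard configuration for a single-workstation replication:
cohorts of 300-1,000 phenotyped females, 10 records each, 100-200
replicates per scenario, REML orders (2, 2, 2) matching the generative
curves.  Calibration quantities (type-I error, variance partition,
unbiasedness) are scale-free and reproduce directly; statistical power at
the smallest QTN heritabilities is lower than at the full 2,000-cohort
scale, so power comparisons are reported at the higher heritabilities
where the desk-scale design retains sensitivity.

## Known limitations

* Heterogeneous residual variance classes over time are not supported.
* Genomic (marker-based) relationship matrices are out of scope; A is
  pedigree-based.
* The deregression is the simplified single-step form described above,
  not the full information-weighted system.
* The unbalanced-data REML path factorizes the full MME per likelihood
  evaluation and is intended for desk-scale datasets; very large
  unbalanced data would need a supernodal sparse Cholesky backend.
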