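# Methods

## The model

GWAS summary statistics report, per SNP, a univariate effect estimate and a
p-value.  For standardized genotypes and phenotype, the scaled estimate
`z_i = sqrt(n) beta_i` is asymptotically standard normal under the null, and
for a set of SNPs stacked into a vector, `z ~ N(0, Sigma)` with
`Sigma = x'x / n` the SNP-SNP correlation (LD) matrix of the region -- the
null is a *fixed-effect* null: every true effect is zero, and all structure
in `z` comes from LD.  `Sigma` is estimated from an external reference panel
and is assumed to approximate both study populations; no per-study panel is
supported.

Given score vectors `w` and `z` for the same gene window from two GWAS, the
cross-scoring index is the second cross-moment

    I = w'z      (deliberately not centered over the gene SNPs).

Under the null that the two GWAS are independent, rotating both vectors into
the eigenbasis of `Sigma` shows

    I  ~  sum_i lambda_i/2 [chi2_1]  -  sum_i lambda_i/2 [chi2_1],

a signed linear combination of chi-square variables governed entirely by the
eigenvalues `lambda_i` of `Sigma`.  The right tail of `I` measures coherence
(same-signed SNP effects in both traits), the left tail anti-coherence.
Special cases:

* one SNP: `I` is the product of two standard normals (the product-normal
  distribution, `(1+rho)/2 [chi2_1] - (1-rho)/2 [chi2_1]`);
* `Sigma = I_N`: `I` follows the variance-gamma distribution
  (`1/2 [chi2_N] - 1/2 [chi2_N]`), the no-LD null;
* `w = z`: the statistic `z'z` with the all-positive null
  `sum_i lambda_i [chi2_1]` is the classic LD-corrected gene enrichment test.

The **ratio statistic** `R = w'z / z'z` is the weighted-least-squares slope
of the decorrelated exposure scores on the outcome scores;
`Pr(R <= r) = F_{vz}(0)` where the mixture has, per eigenvalue, coefficients
`+lambda_i sqrt(1+r^2)(1+rho)/2` and `-lambda_i sqrt(1+r^2)(1-rho)/2` with
`rho = -r/sqrt(1+r^2)`.  In one dimension `R` is Cauchy
(`F(r) = 1/2 + arctan(r)/pi`), which serves as an analytic consistency
check.  `R` is not symmetric in the two traits: the *outcome* supplies the
denominator.  A gene is a causal-direction candidate when its ratio tail is
significant, the exposure passes the enrichment test, and the outcome does
not; confounders are not evaluated and must be excluded externally.

The **D statistic** `D = sum_i z_i` orients the aggregated gene effect.  Its
null is normal; two variance conventions are provided.  The default
`exact_sum` uses `V = 1' Sigma 1`, which is the variance of a sum of jointly
normal coordinates.  The alternative `paper_frobenius` uses
`V = trace(Sigma) = |C|_F^2` (with `C` the Cholesky factor), a convention
that appears in the original description of this test; the two agree exactly
for diagonal `Sigma` but differ whenever off-diagonal LD is present.  We
default to `exact_sum` because the affine-transform argument for the null of
a coordinate sum leads to `1' Sigma 1`; the Frobenius mode is kept as an
explicit compatibility switch rather than silently choosing one reading.

## Numerical evaluation of signed chi-square mixtures

No closed form exists for the cdf of `sum_i a_i chi2(n_i)` with mixed-sign
coefficients.  Three routes are implemented, selected automatically:

1. **Characteristic-function inversion** (Davies' approach, written in
   Imhof's explicit integrand form) with adaptive quadrature.  This is the
   fast default; its absolute error estimate is returned by the quadrature
   routine.  Terms with equal coefficients are merged (degrees of freedom
   add) before evaluation, which reduces, e.g., an equicorrelated
   100-dimensional spectrum to four terms.
2. **Ruben's series + gamma convolution.**  Splitting the mixture into its
   positive part `A` and negative part `B` gives
   `P(Xi > x) = E_B[S_A(x + B)]`, an integral of a *nonnegative* integrand,
   so relative accuracy survives arbitrarily deep tails.  `S_A` and the
   density of `B` are evaluated by Ruben's series of chi-square cdfs, using
   the recurrence `Q(s+1,t) = Q(s,t) + t^s e^-t / s!` so one incomplete-gamma
   evaluation serves the whole series.  Evaluated in double precision (tails
   down to ~1e-300); an mpmath variant (default 50 digits) sits beneath the
   double floor.  The series converges geometrically at rate
   `1 - min a / max a` and is abandoned for spectra spread wider than a few
   thousand terms' worth.
3. **Saddlepoint-tilted contour inversion** for wide-spread spectra: the
   inversion contour is shifted through the saddlepoint `s0` solving
   `K'(s0) = x`; on that contour the integrand's magnitude is of the order
   of the result itself, so double-precision quadrature yields ~1e-9
   *relative* accuracy at any tail depth and any coefficient spread.  The
   tilt degenerates as `x` approaches the mean (the `1/s` factor blows up),
   so within half a standard deviation of the mean route 1's result is used
   instead.

Route 1 is attempted first; the positive-integrand routes take over when the
returned probability falls below 100x the requested accuracy (default
1e-12, configurable) or the quadrature error estimate exceeds it.  Tail
probabilities are clamped to [0, 1], and a vanishing tail inside the support
is recomputed in arbitrary precision rather than reported as zero.  Left
tails are evaluated as right tails of the negated mixture, and complementary
pairs are computed directly (never as `1 - p`) wherever the small side is
needed, so extreme p-values keep relative accuracy.

The defaults (absolute accuracy 1e-12, 50 digits for the sub-double
fallback) resolve every quantity this method manipulates in practice -- the
cutoff analysis requires p-values near 1e-16, and the machinery remains
meaningful to ~1e-30.

## SNP normalization and harmonization

Two GWAS are joined on SNP id; the default allele policy (`strict`) keeps
only SNPs whose allele pairs match exactly, and `swap_flip` additionally
accepts swapped pairs with the second study's sign negated.  P-values are
moderated before scoring, because the multiplicative combination otherwise
lets one extremely well-powered study drag mild signals of the other to
nominal co-significance:

* `qq` (default): within each trait, p-values over the *shared* SNP set are
  replaced by the rank grid `(r+1)/(N+1)`.  Ranking is per trait but over
  the identical post-harmonization SNP set, so both studies end up with the
  same score-magnitude spectrum; with `N ~ 1e6` SNPs the strongest
  transformed p-value is ~1e-6.  Ties are broken by genomic coordinate, so
  output is deterministic.
* `cutoff`: p-values below a floor (default 1e-16, the value at which a
  0.05 partner can still reach combined significance 1e-8) are clipped.
* `raw`: no moderation.

Scores are `sign(beta) * sqrt(inv-chi2_1(1-p))`.  SNPs with a zero or
missing effect sign in either trait carry no direction information and are
dropped (counted and logged).  Genes are transcript spans extended by 50 kb
on both sides (configurable); every gene with at least one shared SNP in the
panel is tested, single-SNP genes through the product-normal reduction.

## LD structure

Panel genotypes (VCF or a plain dosage matrix) are mean-imputed per SNP,
standardized with denominator `n`, and `Sigma = x'x/n`.  Monomorphic and
panel-absent SNPs are dropped.  Negative round-off eigenvalues are clipped
to zero and eigenvalues below 1e-8 are excluded from *all* tests (the
regularization the direction test requires is applied uniformly; near-null
directions carry no signal).  The Cholesky factor is computed on
`Sigma + 1e-8 I` when `Sigma` is singular.  No MAF filter is applied by
default.  A random-effect null `h2 L + Sigma` with
`L = x'X X'x/(n p)` over flanking SNPs within the gene window is available
(`build_null_covariance`) with user-supplied `h2`; it is not wired into the
default tests, and no heritability estimation is performed.

## Pathways

Pathway members whose extended windows overlap on a chromosome (single
linkage, transitively) are fused into meta-genes and re-scored on the union
of their SNPs; this removes double counting of shared LD blocks.  The
pathway score qq-normalizes the genome-wide background of gene p-values
(fused members replaced by their meta-gene), maps each pathway (meta-)gene's
normalized p to a chi2_1 quantile, and tests the sum against chi2_n.  Genes
without a score are excluded from background and pathway alike.  Bonferroni
thresholds are reported as 0.05 / (families tested), following the
convention of reporting raw p-values alongside.

## Synthetic data

The generator provides the study conditions under which everything here is
tested:

* correlation structures: equicorrelated (the calibration study uses
  dimension 100 with off-diagonals 0.2 and 0.8, 1000 sample pairs), AR(1),
  and block-diagonal;
* score pairs `(w, z)` jointly normal with marginals `N(0, Sigma)` and
  per-SNP cross-covariance `rho Sigma` -- `rho = 0` is the null, and power
  is checked to be monotone in `rho` over {0, 0.25, 0.5} at dimension 20;
* complete toy studies: genotypes via latent-Gaussian thresholding at
  allele-frequency quantiles (frequencies uniform in [0.05, 0.5]; two
  latent haplotypes summed to a 0/1/2 dosage), phenotypes `y = X alpha +
  eps` with `alpha = 0` (null) or `alpha_i ~ N(0, h2/p)`, and per-SNP
  univariate regression betas and normal p-values, written in the same
  TSV/matrix formats the readers consume.

What the generator does *not* emulate: realistic demography or coalescent
LD, imputation error, allele-frequency-dependent effect sizes, sample
overlap between studies, case-control ascertainment.  Thresholded latent
Gaussians attenuate the target LD somewhat, which is immaterial here because
genotype realism only feeds the I/O and regression integration tests, not
the distributional claims (those are tested directly on `N(0, Sigma)`
scores).  Passing tests therefore establish the statistical machinery and
the pipeline plumbing, not robustness to real-data pathologies.

Desk-scale problem sizes were chosen once for the test fixtures (60-200
SNPs, 300-500 samples, 4-20 genes) as the smallest sizes at which every
stage -- harmonization, LD estimation, per-gene testing, fusion -- is
non-trivially exercised.

## Verification strategy

Every tail computation is checked along two independent routes: exact
analytic reductions (scaled chi-square, variance-gamma, Cauchy, the
`K_0(|x|)/pi` product-normal density) to 1e-10 or better, and seeded
1e7-draw Monte-Carlo oracles within 3 binomial standard errors on randomized
instances.  A Monte-Carlo comparison that lands marginally outside 3 SE is
repeated once with an independent batch: a fluctuation of the oracle does
not recur, a systematic error does.  Null calibration is asserted by
Kolmogorov-Smirnov uniformity (alpha = 0.01) of 1000 null p-values, and the
anti-conservativeness of the no-LD (variance-gamma) null under strong
correlation is asserted as a >2x inflation of the nominal 0.05 rate.

## Known limitations

* One reference panel serves both GWAS; population mismatch biases `Sigma`.
* No sample-overlap correction: overlapping cohorts inflate coherence.
* The fixed-effect null ignores polygenic background unless the
  random-effect covariance is supplied explicitly.
* The ratio test screens, but cannot exclude, confounding; its output is a
  candidate list, not a causal estimate.
* Mixtures combining a very wide eigenvalue spread with a requested
  accuracy tighter than ~1e-9 relative fall back to the tilted route, whose
  accuracy is limited by double-precision quadrature; the reported
  `achieved_accuracy` is honest about this.
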