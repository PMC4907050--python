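# Methods

## Problem and model

The package re-implements a genomic-selection analysis for large yellow
croaker (*Larimichthys crocea*) breeding: estimating heritability of growth
(body weight, body length) and meat-quality (muscle n-3HUFA percentage)
traits from genome-wide SNPs, predicting genomic breeding values (GEBV) with
two algorithms, quantifying predictive ability by replicated
cross-validation, extrapolating the accuracy curve to required training
sizes, and contrasting genomic prediction with single-marker GWAS.

All components share the linear trait model

    y_i = mu + sex_k + sum_j X_ij g_j + e_i

with genotypes coded 0/1/2 as counts of the coded allele `a`, a two-level
sex fixed effect (1 = male, 2 = female), and additive marker effects g_j.
When effects are estimated at the marker level, genotypes are standardized
as X'_ij = (X_ij − 2p_j)/sqrt(2p_j(1−p_j)), so each column has mean 0 and
variance 1 under Hardy–Weinberg proportions and |g_j| is comparable across
markers.

## Genotype QC and imputation

Markers are dropped when missing rate ≥ 0.20 (inclusive), MAF < 0.05, or the
1-df chi-square Hardy–Weinberg test gives p < 0.001.  The three rules are
applied to statistics computed once on the input cohort (order: missing →
MAF → HWE), so per-rule removal counts are unambiguous and filtering is
idempotent.  p_j is the coded-allele frequency ((2·n_aa + n_Aa)/(2·n_called));
MAF = min(p_j, 1−p_j).  The coded allele is the VCF ALT allele for VCF input
and whatever the file states for matrix-text input.

Missing genotypes are imputed in-repo: mean dosage 2p_j (default;
real-valued dosages are accepted downstream) or Hardy–Weinberg sampling of
0/1/2 at p_j.  LD-aware imputation is deliberately out of scope; at the
~12% missingness the design targets, mean-dosage imputation is adequate for
a methods re-implementation and keeps the pipeline free of external
phasing/imputation binaries.

## REML variance components

Heritability uses the single-random-effect model y = Wb + u + e,
u ~ N(0, K·σ_g²), e ~ N(0, I·σ_e²), with K the VanRaden genomic
relationship matrix.  The restricted likelihood is reduced to one dimension
exactly: the kernel is restricted to an explicit orthonormal complement of
the fixed design (this remains correct for low-rank kernels, e.g. kernels
built from small marker subsets, where eigendecomposing the projected n×n
matrix would leak design directions into the null space), eigendecomposed
once, and the profile over the log variance ratio ln(σ_g²/σ_e²) is
maximized by bounded scalar search on [−10, 10] with tolerance 1e-8 —
deterministic, no seed.  Kernel eigenvalues below −1e-8·max are an error;
small negatives above that are clamped to zero.  A profile that is flat in
the ratio (e.g. K = I, where only the total variance is identified) is
detected on a coarse grid and reported as a warning instead of an arbitrary
estimate.

Variance explained by a marker subset refits REML with a kernel built from
the subset only, and reports V_sub/V_A against the all-marker kernel.  The
ratio is deliberately not capped at 1: a subset enriched for causal markers
can exceed the variance the all-marker kernel attributes, because null
markers dilute the latter.  Both fits always include intercept + sex.

## GBLUP / RR-BLUP

The genomic relationship matrix follows VanRaden:
G = (X−P)(X−P)ᵀ / (2Σp_i(1−p_i)) with P = 2p_i.  GBLUP solves the mixed
model with shrinkage λ = (1−h²)/h² through the variance form
û = G(G+λI)⁻¹(y−Wb̂), which is the exact mixed-model-equation solution and
is defined even for singular G, so no ridge stabilizer is needed on the main
path (one is available as an option).  RR-BLUP solves the equivalent
marker-level ridge problem on column-standardized genotypes with
λ = p(1−h²)/h² (p = marker count), in its dual n×n form.

The two shrinkage constants are the unique pair making the two solvers'
GEBV identical, which requires the kernel on the standardized-genotype
scale, G = X'X'ᵀ/p.  The classical centered kernel above coincides with it
only when all markers share one allele frequency, so `build_g_matrix`
offers both scalings: `vanraden` (default, the formula the field prints)
and `standardized` (used wherever exact GBLUP/RR-BLUP equivalence is
asserted).  Candidate GEBV come either from marker effects (X'_cand·ĝ,
standardized with training-cohort frequencies) or from the cross-kernel
block G_cand,train(G+λI)⁻¹(y−Wb̂); the two routes agree to numerical
precision.

The h² plugged into either solver is re-estimated by REML on each training
split, never a global constant.

## emBayesB

Marker effects get the spike-and-slab prior
π(g) = (1−γ)δ₀ + γ·(λ/2)e^(−λ|g|).  Fitting is expectation–maximization by
iterated conditional expectation: markers are visited in fixed input order;
for each, the conditional posterior given current residuals is closed-form —
the slab part is a two-sided truncated-normal mixture, the inclusion
probability comes from the slab/spike marginal-likelihood ratio — and the
effect is replaced by its posterior mean.  After each sweep: fixed effects
are re-fit by least squares on y − X'g; γ is re-estimated as the mean
inclusion probability (clamped to [1e-6, 1−1e-6]); λ is re-derived from the
genetic-variance budget; σ_e² is set to the mean squared residual.
Convergence: max |Δg| < 1e-6 (default), cap 2000 sweeps.

Because the slab variance is 2/λ², equating the prior marker-explained
variance γ·p·2/λ² to the budget σ_g² = h2_init·var(y_adj) gives
λ = sqrt(2γp/σ_g²), recomputed each sweep from the current γ.  h2_init only
sets this budget; GEBV correlate >0.9 across h2_init ∈ [0.4, 0.6] on sparse
synthetic cohorts, consistent with the robustness claimed for the EM scheme.
Defaults: gamma_init = 0.01; the seed parameter is accepted but unused (the
core algorithm is deterministic; two runs are bit-identical).

Correctness is anchored to an independent quadrature oracle: at convergence,
every effect must equal the numerically integrated posterior mean of its
exact per-marker conditional (others held fixed) within 1e-3 — the update
equations are validated against the model, not transcribed from a reference
implementation.  The numerically delicate pieces (log Φ, Mills ratios,
likelihood-ratio exponents) are computed in log space with asymptotic tails.

## GWAS

Plain per-marker OLS of y on (intercept, sex dummy, raw dosage), t-test on
the dosage coefficient with n−3 df (n−2 in single-sex cohorts); markers
collinear with the design are flagged untestable rather than erroring.  No
relatedness correction is applied — matching the analysis being emulated —
so p-values are inflated under family/population structure; significant
markers cluster in LD blocks by design, and no clumping or multiple-testing
correction is performed.  Per-trait raw thresholds default to 1e-5 (body
weight), 1e-6 (body length), 1e-4 (n-3HUFA).  The vectorized closed-form
scan is tested against per-marker statsmodels OLS to 1e-10.

## Cross-validation and comparison

Repeated random splits (not k-fold): per replicate, n_train individuals are
drawn uniformly, the rest are the test set, and all methods consume
byte-identical splits (asserted by hash).  Predictive ability is the
Pearson correlation r(ĝ, y) of GEBV with raw observed phenotypes (a
sex-adjusted option exists, off by default).  Summaries report the mean and
SE (sd/√n_replicates) over 20 replicates per training size; methods are
compared per size with two-sided paired t-tests, dropping incomplete
replicates pairwise.  Splits are shared across methods within a size level,
not across levels.

## Accuracy curve

Ability converts to accuracy r(ĝ,g) = r(ĝ,y)/h.  Accuracy vs training size
follows r = sqrt(Nh²/(Nh²+M)); linearizing with y = (1−r²)/r², x = 1/N gives
the zero-intercept line y = kx, k = M/h², fitted unweighted by least squares
through the origin on the mean abilities (fitting on means reproduces the
published constants; a per-replicate option exists).  The h² used is the
full-cohort REML value.  Required training size for target accuracy r* is
N* = (r*²/(1−r*²))·k rounded half-up — the rounding that reproduces all four
published required sizes, including the half-case 1245.5 → 1246.

## Synthetic cohorts

The simulator generates what the analysis assumes: marker frequencies
uniform on [0.05, 0.5]; Hardy–Weinberg genotypes; first-order LD by
haplotype copying (each haplotype repeats the previous marker's allele with
probability ρ); missingness completely at random; alternating sexes
(balanced at any n); sparse QTLs drawn without replacement with
double-exponential effects by default (normal as a misspecification
alternative); residual variance set so var(TBV)/(var(TBV)+σ_e²) hits the
target h².  True breeding values use pre-missingness genotypes, so data
quality never contaminates the truth.  Realized h² is reported as
var(TBV)/(var(TBV)+var(e)), the quantity REML estimates — fixed-effect
variance is deliberately excluded from the denominator.

Presets mirror the study cohorts: growth traits n=500 with h² 0.60/0.59,
n-3HUFA n=176 with h² 0.44 and 10 QTLs (the trait the study argued is
oligogenic), intercepts/sex effects/phenotypic SDs from its summary table
(e.g. body weight: 202.2 g male mean, +45.2 g female, SD ≈ 88 g).  The
marker panel is scaled to p = 2000 — a problem size chosen so the full
pipeline runs in seconds — with preset LD ρ = 0.985.  That ρ is calibrated
to the study's own observable: its fitted effective locus counts were
~1.3–1.6% of its ~30k markers, so a 2000-marker panel with matching
redundancy has ~30 effective segments (mean LD-block length 1/(1−ρ) ≈ 67
markers).  A zero-LD panel would not emulate the study: with 2000
independent segments, GBLUP ability could not track the accuracy curve at
the simulated QTL count.  The bare `SimulationConfig` default is ρ = 0,
the neutral primitive for method-level tests.

What passing tests on these cohorts do **not** show about real data: the
simulator has no family structure, selection, or recombination map; LD is
stationary first-order; missingness is MCAR rather than coverage-driven;
QTL effects are exactly additive.  Conclusions about relative method
performance under those violations require real genotypes.

## Numerical choices and limitations

- Monomorphic markers: error by default in standardization/G construction;
  training splits inside CV may contain markers monomorphic-in-split, whose
  standardized columns are zeroed (they carry no information in that split).
- h² estimates plugged into solvers are clipped to [0.01, 0.99].
- Paired t-tests with zero-variance nonzero-mean differences report t = ±inf,
  p = 0, flagged degenerate; all-zero differences give t = 0, p = 1.
- Ties in top-|effect| marker selection break by (chromosome, position).
- Chromosome labels are opaque strings; numeric labels sort numerically
  first, others lexically after.
- Single-kernel additive model only: no dominance/epistasis, no multi-kernel
  or single-step variants, no MCMC BayesB, no kinship-corrected GWAS.
- The per-trait QC-cohort subsetting that produced different retained-SNP
  counts per trait in the original analysis is not specified there; QC here
  is applied per analysis cohort, reproducing the mechanism but not those
  counts.
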