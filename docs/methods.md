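# Methods

This note records the models implemented in gwaskit, the defaults that
matter, what the synthetic data do and do not emulate, and the design
choices made where the design was genuinely open.  No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Genotype simulation

Panels are generated as independent LD blocks.  Within a block each
haplotype is a stationary two-state Markov chain: the allele at variant
j+1 is copied from variant j with probability ρ and otherwise redrawn as
Bernoulli(MAF).  Because the chain is stationary, allele frequencies are
preserved exactly and the genotype-scale correlation between variants at
lag k is exactly ρᵏ — a first-order autoregressive LD profile on the
dosage scale itself.  We adopted this construction after measuring that
latent-Gaussian schemes (thresholded haplotypes, or binomial quantile
mapping of an AR(1) Gaussian) attenuate the genotype correlation far below
the latent parameter (r² ≈ 0.5–0.6 when the latent ρ = 0.9), which would
make LD-dependent quantities such as LD scores uncalibratable against
closed forms.  The cost of the Markov construction is that the MAF is
constant within a block (drawn once per block from `maf_range`); blocks
are short (default 5–10 variants over 25–50 kb), so this is a mild
restriction.

ρ may be a (lo, hi) range, drawing one value per block.  This matters for
LD-score regression: with a single ρ the LD scores barely vary and the
slope/intercept decomposition is ill-identified; a spread of ρ across
blocks produces ℓ ∈ [1, ~8] and a well-conditioned regression.

Chromosome X uses a single haplotype for males with dosages coded 0/2 (no
dosage compensation), 0/1/2 for females.

Population stratification is emulated by splitting individuals into two
equal subpopulations whose block allele frequencies drift apart with
between-population variance `fst·p(1−p)` (drift drawn per block,
independent of the block's ρ).  Because the drift is independent of local
LD, the induced association inflation is uncorrelated with ℓ and loads on
the LD-score intercept, which is the diagnostic the confounding tests
exercise.  Note the drift term has a 1-degree-of-freedom tail per block;
very large `fst·shift²` settings make single blocks dominate the scan, so
the tests use mild settings (fst ≤ 0.01) with many small blocks.

## Liability-threshold phenotypes

Liability is

    L = a·S + c_E·E + c_sex·(S×E) + shift·U + ε,  a = √h²_liab,

with S the empirically standardized polygenic score over `m_causal`
randomly chosen variants (effects i.i.d. normal), E an exposure
(none; Bernoulli(q_sex); or Normal(q_sex, 1)), c_sex ∈ {c_m, c_f} a
sex-specific interaction coefficient, and U the centered ±½ subpopulation
offset.  The residual variance is set per sex so the total liability
variance is one in expectation; the realized variance is checked by tests
(tolerance [0.97, 1.03] at n = 50 000) but never forced.  Exceeding unit
systematic variance raises an error with the offending variance.  Cases
are individuals whose liability exceeds Φ⁻¹(1−K_sex).

The exposure parameterization (Bernoulli rate or Gaussian mean per sex)
and the i.i.d.-normal causal effects are this package's own choices; the
defaults used throughout the studies (h² = 0.15–0.2, K = 0.09 per sex,
binary exposure with rate 0.3, main environmental effect 0.3) are round
numbers in the range reported for common neurological traits.

Under this model the marginal per-variant effect in sex k is proportional
to a + c_k·E[E_k]: a female-only interaction with positive-mean exposure
scales every causal effect by a common factor, so female marginal h²
exceeds male h² while the cross-sex effect correlation remains exactly
one.  This is the mechanism the G×E study quantifies.

Ages are Uniform(20, 80); onset ages for prevalent cases are
Normal(45, 15) truncated to [5, current age].  These distributions are
package choices (no external onset distribution was available) and only
shape the time-to-event labels, not the association statistics.

## Association scans

The binary-trait scan is the logistic-regression score test: one null fit
of case status on covariates, then per-variant score statistics computed
in closed form (effect = U/V, se = 1/√V).  This is exact vectorization of
the additive logistic model, not an approximation to it, and scales to
10⁵ variants in seconds.  The quantitative scan is per-variant OLS after
residualizing on covariates, with per-variant residual variance and a
t-distribution reference — using a shared residual variance would shift
all z-scores by a common factor and demonstrably breaks the uniformity of
null p-values at 10⁵ variants.  Monomorphic variants are flagged missing,
never dropped.

## N-weighted meta-analysis

Z_meta = Σᵢ wᵢZᵢ / √(Σᵢⱼ wᵢwⱼC_ij) with wᵢ = √Nᵢ.  The cohort-correlation
matrix C defaults to identity; `estimate_cohort_correlation` estimates
off-diagonals as the correlation of Z across variants where both cohorts
are null (|Z| < 1.96), the cross-trait-intercept convention.  The
effective sample size is reported as (Σw)²/(w′Cw)·mean(Nᵢ) over cohorts
carrying the variant, which reduces to ΣNᵢ for independent equal-size
cohorts.  Allele alignment attempts swap, then strand complement;
palindromic variants are matched by frequency proximity (|Δf| < 0.2) and
otherwise dropped with a count.  Genomic control divides χ² by
λ = median(χ²)/0.4549 only when λ > 1 (no deflation).

## Risk loci

Clumping is greedy by ascending p among p < p₁ candidates (ties broken by
chromosome, then position); members require p < p₂, distance ≤ 500 kb and
r² > 0.05 with the index.  Clumps merge into loci when spans overlap or
sit closer than 500 kb, transitively; "gap" is measured between member
spans.  Stepwise selection uses the standardized-genotype summary-statistic
joint model: marginal standardized effects z/√N, joint effects R⁻¹z/√N
over the selected set with se √([R⁻¹]jj/N), candidates entering at joint
p < 5×10⁻⁸ subject to r² < 0.9 with selected variants inside a 10 Mb
window; LD outside the window is treated as zero.  Singular LD submatrices
skip the candidate with a warning.  The equal-residual-variance
approximation underlying the joint model is standard for summary-statistic
conditional analysis.

## LD-score regression

ℓ_j sums the bias-adjusted r̃² = r² − (1−r²)/(n−2) over a 1 Mb window
(banded computation).  The regression is two-step — intercept estimated on
χ² < 30, then fixed while the slope is re-estimated on all variants — with
weights 1/(max(ℓ,1)·max(1, fitted χ²)²) iterated twice.  Standard errors
come from a delete-one jackknife over 200 contiguous blocks (the full
two-step fit is re-run per deletion).  With `weight_iterations=0` the
weights are the fixed 1/ℓ scheme, under which the fit is exactly
equivariant under a constant χ² shift — the form in which that regression
identity is tested.  h²_obs = slope·M/N̄; the liability conversion uses the
standard ascertainment formula and is applied multiplicatively to the
jackknife se.  Negative h² estimates are reported, not truncated, so
difference tests remain unbiased.  The cross-trait regression of Z₁Z₂ on ℓ
yields the genetic covariance; its intercept absorbs sample overlap; the
rg jackknife re-runs all three regressions per block.  rg is flagged
undefined when either fitted h² ≤ 0.

For chromosome X the moment estimators are used directly:
h²_k = (χ̄²_k−1)·M_eff/N_k with M_eff = M/mean(ℓ) of the X reference (a
package choice — the estimator of M_eff was open), and the Z-product
cross-sex correlation, which assumes independent male and female samples.
The clipped value in [−1, 1] is reported together with the raw one.

## G×E study and ABC

`simulate_sex_stratified_study` shares one genetic architecture across
sexes, applies sex-specific exposure/interaction, runs per-sex scans, and
estimates the (h²_m, h²_f, r_g) triple with the moment estimators plus the
liability conversion — these are much cheaper and less noisy at small M
than the full regression, which matters inside ABC loops.

`abc_model_comparison` draws parameters from independent uniform priors,
simulates a study per draw on a genotype panel shared within each model
(phenotypes and effects redrawn per draw), and measures the distance to
the observed triple as the se-scaled Euclidean (diagonal Mahalanobis)
norm.  The acceptance threshold is a quantile (`tolerance`) of the
distances pooled across models, so acceptance rates are directly
comparable and their ratio approximates the Bayes factor; a zero-acceptance
model is floored at 1/(n_draws+1) and flagged.  Per-model RNG streams are
keyed by (seed, model name), making results invariant to model order —
Bayes factors are then exactly antisymmetric under model swap.  The
default reduced scale (M = 250, N = 2 500/sex, 120–150 draws) lets a
20-repetition selection experiment run in a few minutes; the observed
triple used in the selection experiment (0.13 vs 0.32 with rg 1.0) is of
the separation reported for sex-differential heritability of the
motivating trait.  The posterior for c_f/c_m is summarized by its median
and percentile credible interval over accepted draws; when the accepted
c_m posterior hugs zero (5th percentile below 5% of the prior span) the
ratio is unbounded above and a one-sided lower bound is emitted instead.

The published Bayes factors and interaction-ratio for the motivating study
depend on its real observed summaries and unpublished simulation settings
and are deliberately not reproduction targets; the package reproduces the
phenomenon and the inferential machinery.

## Mendelian randomization

Instruments: exposure p < 5×10⁻⁸, greedy LD pruning to pairwise r² < 0.01
(variants absent from the panel are kept, as their LD cannot be assessed),
palindromic variants with exposure frequency in [0.42, 0.58] dropped — the
band quantifies "ambiguous frequency" and is a package choice.  IVW is the
weighted mean of Wald ratios with first-order weights β²_exp/se²_out
(equivalently zero-intercept WLS), fixed-effect se, Cochran's Q reported.
Egger frees the intercept after orienting exposure effects positive; its
se uses multiplicative overdispersion floored at 1 and a t reference.
Steiger filtering compares r² ≈ Z²/(Z²+N) between sides and keeps ties.
BH FDR is delegated to statsmodels.

## Risk prediction

`resample_population` draws stratum sizes multinomially from the
demography proportions, ages uniformly within bins, case status Bernoulli
at the stratum cumulative incidence, resampling source cases with onset
before the drawn age (error naming the stratum when impossible) and
controls of the same sex.  Synthetic PCs are standard-normal noise — no
population structure is simulated in the prediction cohort, so γ·PC acts
purely as a covariate-dimension control.  Folds are stratified on case
status (10 by default).

The interaction GLM is a maximum-likelihood logistic fit of the full
PRS×sex×age specification with 20-year age-bin dummies (reference: the
youngest bin present); β₃/β₅/β₆/β₇ are therefore coefficient groups, one
per non-reference bin.  Separation and non-convergence are converted to
errors.  OR per PRS sd at the reference stratum is exp(β₁·sd(PRS)) by
construction.  Nagelkerke's R² is computed on log-likelihoods to avoid
underflow.  Five-year landmark labels exclude prevalent cases at the
landmark and individuals censored before landmark+5 without an event —
the censoring convention was open and is documented here.  Evaluation
uses the rank-statistic ROC AUC with bootstrap se, step-interpolated PR
AUC (average precision), and the OR per score sd from a univariate
logistic refit.  Any learner exposing `fit`/`predict_scores` plugs into
`cross_validated_scores`; the shipped nonlinear learner is a
gradient-boosted tree ensemble, which the tests require to beat the
linear GLM on data generated with PRS×age and threshold nonlinearities.

## What passing tests do and do not show

The generators produce idealized data: exact AR(1) LD with block-constant
MAF, Gaussian liabilities, i.i.d. causal effects, no relatedness, no
imputation error, no genotyping batch effects, and demography tables
given rather than estimated.  Passing recovery tests therefore shows the
estimators are correctly implemented and calibrated under their own model
assumptions — not that they are robust to the violations real cohorts
exhibit (MAF-dependent architecture, long-range LD, cryptic relatedness,
phenotype misclassification).  Quantities tied to inaccessible real data
(locus counts, published h²/rg values, AUCs, Bayes factors) are treated
as structure to reproduce, not numbers to match.

## Problem sizes and numerics

Default study sizes (M = 2000, N = 20 000 for heritability recovery;
N = 2 500/sex, 120 draws per model for ABC; n = 50 000 for the GLM
recovery) were chosen so the full suite and the acceptance script each
complete in well under half an hour on a single CPU while leaving the
Monte-Carlo error comfortably inside the stated tolerances.  Seeds control
all randomness; sub-seeds are drawn below 2³¹.  Ties: clump p-ties break
by chromosome then position; Steiger ties are kept; the BH step-up uses
statsmodels' monotonicity enforcement.  Degenerate inputs (monomorphic
variants, constant PRS, single-class labels, non-PSD cohort correlation,
mean χ² ≤ 1 in the X rg) raise or flag rather than silently proceeding.
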