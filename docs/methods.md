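# Methods

## The model

The package estimates the relative contribution of risk-factor
categories to a continuous outcome y (typically a z-score). Predictors
play one of two roles:

* **single predictors** x_{1,j} — covariates kept as-is in the final
  model (possibly grouped, e.g. two dummies coding one three-level
  socio-economic-status variable);
* **category members** x_{k,j}, k ≥ 2 — correlated measurements of one
  construct, combined into a weighted risk score
  z_k = Σ_{j=1}^{m_k} w_{k,j} x_{k,j} with Σ_j w_{k,j} = 1.

### Step 1 — learning the weights

On the training split the model

y = γ₀ + Σ_j γ_{1,j} x_{1,j} + Σ_k Σ_j γ_{k,j} x_{k,j} + ε

is fitted by ridge regression with per-coefficient penalty factors:
minimize

(1/(2n)) Σ_i (y_i − γ₀ − x_iᵀγ)² + λ Σ_j pf_j γ_j²,

with pf = 0 for single predictors and pf = 1 for category members. This
objective is the solver's public contract and is solved in closed form
via the normal equations (XᵀX/n + 2λ·diag(pf))γ = Xᵀ(y−ȳ)/n on centered
data. It deliberately does **not** emulate any particular library's
internal rescaling or λ parameterization: a plain, explicitly stated
objective can be verified against closed forms and a generic numerical
optimizer, which the test suite does to 10⁻⁸.

λ is chosen by k-fold cross-validation (default 10) minimizing mean
out-of-fold squared error over a descending log-spaced grid (default 100
points from λ_max = max_j |x_jᵀ(y−ȳ)|/n over penalized j down to
λ_max·10⁻⁴; ties resolve to the larger λ). The minimum-mean-error rule
rather than a one-standard-error rule is used; it is the common default
and is configurable in principle through the grid. Because folds are
random, the CV + refit cycle is repeated (default 20×, re-randomizing
only the folds) and the coefficient vectors averaged elementwise.

Each category's averaged coefficients γ̂_k are normalized by their
signed sum, w_{k,j} = γ̂_{k,j} / Σ_l γ̂_{k,l}, which guarantees
Σ_j w_{k,j} = 1; if all γ̂_{k,j} = 0 (|γ̂| ≤ ζ = 10⁻¹²) the uniform
fallback w = 1/m_k applies. Note that sum-to-one does **not** confine
individual weights to [−1, 1]: sign-mixed coefficients such as (3, −1)
normalize to (1.5, −0.5). The signed-sum denominator is unstable when
coefficients nearly cancel, so |Σγ̂| < 10⁻⁸·Σ|γ̂| triggers a guard: the
category falls back to uniform weights and the replicate is flagged.

### Step 2 — decomposing explained variance

In the test split, raw scores are divided by their interquartile range
(linear-interpolation "type 7" quantiles; the IQR reference sample is
the test split itself by default, configurable to the whole replicate).
The scaled scores z̃_k and the single predictors enter an OLS model; its
R² is decomposed over regressor units u (each ungrouped single, each
dummy group, each score) with the LMG measure

share(u) = Σ_{T ⊆ U∖{u}} |T|!(p−|T|−1)!/p! · [R²(T∪{u}) − R²(T)],

the Shapley value of the set function R²(S). The production path
enumerates 2^p unit subsets (p ≤ 20), computing every subset R² from one
precomputed set of centered cross-products; the literal p!-orderings
average is kept as an independent test oracle (p ≤ 7) and the two agree
to 10⁻¹⁰ on random fixtures. Shares are nonnegative (each increment is
an R² increase) and sum to the full-model R²; tiny negative increments
from floating-point noise are clipped at 0. Rank-deficient subsets —
possible when bootstrap resampling degrades conditioning — use
minimum-norm solutions, for which R² (a projection) remains well
defined.

### Bootstrap aggregation

The two steps run B times: replicate 0 on the original sample,
replicates 1..B−1 on with-replacement resamples, each split 60/40 into
train/test (sizes by round-half-away-from-zero). Per-quantity summaries
are medians and (α/2, 1−α/2) percentile bounds across unflagged
replicates. For coefficients a two-sided bootstrap p-value is reported:
p = 2·min(f⁺, f⁻) with f± the fraction of replicate coefficients ≥ 0 /
≤ 0, floored at its minimum attainable value 2/B_eff. This
sign-crossing reading of the percentile bootstrap is an interpretation
(it is labelled as such in the output manifest); contribution shares are
nonnegative by construction, so their CIs cannot be used for
significance and no p-value is attached to them.

Degenerate replicates — a score with zero IQR, a rank-deficient test
design — are flagged, excluded from summaries and counted in the
manifest; a run aborts if more than half the replicates are flagged.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_bootstrap` B | 200 | bootstrap replicates incl. the original sample |
| `train_fraction` | 0.6 | share of each replicate used to learn weights |
| `cv_folds` / `cv_repeats` | 10 / 20 | CV folds for λ; fold re-randomizations averaged |
| `n_lambda`, `lambda_min_ratio` | 100, 10⁻⁴ | penalty-grid geometry |
| `ci_level` | 0.95 | percentile-CI level |
| `standardize_on` | `"train"` | reference sample for standardization (see below) |
| `iqr_on` | `"test"` | reference sample for the score IQR |
| `seed` | 0 | master seed; every replicate derives its streams from (seed, replicate) |

All predictors except SNP allele counts are standardized to mean 0 and
SD 1 (ddof = 1) so the ridge penalty treats members comparably; SNPs
stay on their 0/1/2 scale and are centered implicitly by the solver. By
default the standardization statistics are estimated on each replicate's
training split and frozen for its test split, which avoids train/test
leakage; `standardize_on="full"` instead standardizes once on the
original table before any resampling, for workflows that standardize
up front. The two options differ only in where the statistics come
from. A training column with zero SD (a rare binary indicator can be
resampled into constancy) is mapped to all-zeros, its ridge coefficient
is thereby forced to 0, and the replicate is flagged.

## The synthetic generator

`riskshare.synthetic` draws cohorts from a Gaussian copula: within each
category the latent variables are equicorrelated with correlation ρ_k,
categories are mutually independent, and single predictors may carry
their own latent correlation matrix. Marginals are produced by affine
maps (continuous), quantile thresholding (binary prevalences) and the
Binomial(2, allele-frequency) quantile function (SNP allele counts).
The outcome is linear *on the latent scale*, y = Σ_j effect_j z_j + ε,
then standardized to a sample z-score. Keeping effects on the latent
scale makes the joint covariance of predictors and outcome available in
closed form, so `true_contributions` computes the population LMG shares
analytically: each category is represented by its best-linear-combination
score (the population regression of y on that block alone, uniform when
the block carries no signal, mirroring the pipeline's fallback) and the
same Shapley algebra used empirically is applied to the implied
covariance matrix.

What the generator does *not* emulate: realized correlations of
discretized (binary/SNP) variables are attenuated relative to the latent
ρ_k; for such members the analytic shares are the latent-scale ideal
that realized data approach from below, while for continuous members
latent and realized variables coincide up to an affine map and the
analytic shares are exact targets. No linkage-disequilibrium structure
among SNPs, no spatial exposure model, no nonlinearities and no
missingness are modeled — passing recovery tests therefore demonstrates
correctness of the estimation machinery under the generator's
assumptions, not robustness to real-data pathologies.

The packaged `salia_template` mirrors published descriptive statistics
(means, SDs, prevalences) of an elderly-women cohort with lung-function,
genetic, obesity, smoking and air-pollution variables; its effect sizes
are set so the outcome variance decomposes qualitatively as observed for
lung function (genetics largest, obesity/smoking next, air pollution
small, total explained variance near 20%). Its defaults use 15 SNPs
rather than the original 278, since without LD structure extra
independent loci only scale computation, not realism. The template's
SES dummies are two binaries with negative latent correlation (−0.6) —
an approximation to mutually exclusive levels of one categorical
variable; exact multinomial dummy coding is not attempted.

## Numerical and design choices

* **Quantiles**: linear interpolation between order statistics
  everywhere (score IQRs, percentile CIs); the convention changes IQR
  values, so one is fixed repo-wide.
* **Split sizes**: round half away from zero on fraction·n.
* **Reproducibility**: every random draw of replicate b flows from
  SeedSequence(seed, (b, stream)); replicates are independently
  reproducible and parallelizable (`n_jobs`), and two runs with the same
  seed write byte-identical result CSVs.
* **Missing data**: complete-case analysis at table validation; rows
  dropped with a logged count. No imputation.
* **Zero-signal grid anchor**: a response empirically orthogonal to all
  penalized columns yields λ_max ≈ 0; the anchor is floored at 10⁻¹² so
  the grid stays positive and the fit degenerates gracefully to OLS-like
  behavior.
* **Problem sizes in tests**: the recovery and calibration suites use
  cohorts of n = 2000/1000 with B = 100 and 20 independent runs —
  large enough that median shares separated by ≥ 0.05 rank correctly
  with high probability, small enough to keep the default test run in
  the minutes range.

## Known limitations

* Linear models only; the explained-variance decomposition does not
  generalize readily to GLMs, so binary outcomes are out of scope.
* Only ridge (elastic-net mixing α = 0) weights are supported; other
  learners for the weights are deliberately not offered.
* The LMG subset enumeration is exponential in the number of units
  (capped at 20, i.e. ~10⁶ subsets); designs with many single
  predictors should group them.
* Percentile intervals only — no BCa or studentized bootstrap.
* The bootstrap p-value definition is an interpretation (see above),
  not a canonical quantity.
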