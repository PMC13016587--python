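# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the limits of what the test suite demonstrates.

## Discovery-stage model

**Scales.** Beta values β ∈ (0,1) are the native methylation fraction;
they are bounded and heteroscedastic (variance shrinks near 0 and 1).
Testing therefore runs on M-values, M = log2((β+ε)/(1−β+ε)) with
ε = 1e-4; the offset keeps boundary values finite and the inverse
transform is exact on [ε, 1−ε]. Effect sizes are reported on the beta
scale as Δβ = mean(test) − mean(control) because a difference in
methylation fraction is the interpretable quantity.

**Probe QC.** A probe is retained when its detection p-value is strictly
below 0.01 in every sample, it does not overlap a SNP with MAF ≥ 0.01,
and it is not on chrX/chrY. Removal attribution in the filter report is
first-match in the order detection-p → SNP → sex chromosome; the order
affects only the report, never the retained set, and the filter is
idempotent.

**Cell composition, two arms.** Blood methylation is a mixture over
leukocyte types, and composition is the dominant variance source; both
arms therefore carry composition covariates.

- *Reference-free* (arm A): the beta matrix is factorised as
  profiles × loadings with profiles clipped to [0,1] and loadings
  non-negative, by alternating least squares (profiles: clipped linear
  solve; loadings: per-sample NNLS). Initialisation is from the top-K
  singular vectors, so the result is deterministic; a step that would
  increase reconstruction RMSE is rejected, making the recorded RMSE
  sequence non-increasing by construction. K = 5 matches the five major
  leukocyte compartments. Loadings enter the design unnormalised, as
  latent components (all K of them — they are not collinear with the
  intercept).
- *Reference-based* (arm B): per-sample NNLS against labelled
  compartment profiles (B, NK, CD4T, CD8T, Neu), renormalised to sum to
  one. Because the fractions sum to one, the last compartment is dropped
  when they enter an intercept-bearing design. The overlap requirement is
  at least K+1 probes (K+1 unknowns per sample after the implicit
  sum constraint).

**Covariate discovery and surrogate variables.** Sample metadata is
screened against the top 5 PCs of the per-probe-centred M matrix: a
numeric variable enters when its simple-regression F-test against any
screened PC has p < 0.01; categorical variables use one-way ANOVA. The
group variable is never selectable. Surrogate variables are the right
singular vectors of the residual matrix after regressing each probe on
the known design; their number is set by parallel analysis — a singular
value's *variance fraction* must exceed the 95th percentile of the
matching fractions from 20 row-permuted, re-projected residual matrices.
Two details matter for calibration: permuted matrices must be re-projected
through the same residual operator (otherwise the observed spectrum is
biased upward relative to permutations), and the comparison must use
variance fractions, not raw singular values (re-projection shrinks the
permuted matrix's total variance). With both in place, pure-noise inputs
yield zero SVs in ≈95% of runs. SVs with p < 1e-6 or η² > 0.5 against
the group are excluded (η² is the R² of SV ~ group, identical to the
squared point-biserial correlation for a binary group); screening
happens before the cap. Adjustment terms (covariates + SVs, group and
intercept excluded) are capped at floor(0.25·n); when over the cap,
composition terms and screened covariates (ordered by strength of PC
association) are kept first, then SVs by eigenvalue rank.

**Moderated testing.** Per probe, OLS on M-values against the arm design;
residual variances are shrunk toward a prior via the standard
moment-matching estimator on log s²: with e = log s² − ψ(d/2) + log(d/2),
the prior df solves ψ′(d₀/2) = var(e) − ψ′(d/2) (Newton inversion of the
trigamma) and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)); when the excess
variance is non-positive, d₀ = ∞ and every probe shares s₀². The
moderated t uses d₀ + d degrees of freedom. Degenerate probes (zero
residual variance) report t = 0, p = 1. Forcing d₀ = 0 recovers the
ordinary per-probe t; forcing d₀ = ∞ gives the fully pooled prior
variance — both limits are exposed for testing.

**Calling.** BH step-up q-values per arm; genomic inflation
λ = median(χ²₁(p))/0.4549 (computed from p-values so it is arm-agnostic);
the strict rule is q < 0.05 AND |Δβ| > 0.1 (an empty result is a valid
outcome). A consensus DMP needs p < 0.05 in both arms, concordant
non-zero Δβ sign, |Δβ| > 0.10 in *both* arms (the stricter per-arm
reading; configurable), and TSS200/TSS1500 annotation. Promoter classes
are defined by |distance to TSS|: ≤200 bp (TSS200) and 200–1500 bp
(TSS1500); the stored distance keeps its sign but classification uses
the magnitude only.

**Variance partitioning** uses marginal ΔR² per factor group
(R²(full) − R²(without the group's columns), clipped at 0, averaged over
probes; residual = 1 − R²(full)). Marginal ΔR² is order-independent but
not additive across correlated terms: variance shared between, say,
composition and a covariate is attributed to neither. The "one driver
takes everything" limit therefore holds only when the remaining terms are
orthogonal to the driver.

## Synthetic data: what it emulates and what it does not

The discovery generator draws, per probe, a base methylation level and
per-cell-type deviations on the logit scale (60% of probes are cell-type
informative, deviation SD 2.0 in log2-odds units); per-sample cell
fractions come from a Dirichlet centred on typical blood proportions
(Neu 0.55, CD4T 0.18, CD8T 0.12, B 0.08, NK 0.07) with concentration 10.
These values were chosen so that, as in real blood arrays, composition
dominates the variance decomposition (≈0.45–0.47 of M-value variance in
the default configuration, against ≈0.02 for the group term). Observed
betas are Beta-distributed around the mixture mean with precision 300
(SD ≈ 0.026 at β = 0.5), truncated to (1e-6, 1−1e-6). Sex (balanced) and
hemoglobin (N(13.9, 1.5²)) affect 2% of probes each on the M scale.
Spikes add a fixed Δβ (+0.125 by default, 20 CpGs) to the test group at
QC-clean promoter probes whose group means stay inside (0,1); an
infeasible spike is rejected with an error. QC blemishes (1% detection
failures, 1.5% SNP overlap, 2% sex-chromosome placement) exercise the
filter. The default 20,000 probes keep suites fast; probe count is a
plain knob. Within-group beta-value SDs are calibrated only to make
spike-scale effects detectable at n = 16+16, not to reproduce any real
dataset's variance; the generator also omits probe-chemistry differences,
chip/batch layout, and raw-intensity artefacts.

The cohort generator emits exactly the configured number of patients per
WMH/lacune/microbleed combination (default: 53/221/24/5/201/81/1/180,
sum 766; a multinomial-sampling mode is optional) and draws the 19
analysis variables per SVD stratum from the configured (mean, SD) —
normal marginals, conditionally independent given the stratum, with the
percent-methylation marker clipped to [0,100]. Missingness is MCAR at
3.8% over the analysis variables (flags are never missing); the truth
record stores every blanked cell's value. Because the variables are
conditionally independent, imputation can beat column-mean imputation
only through the stratum signal; on columns generated independently of
everything, the column mean is already optimal and any model can only
match it to within estimation noise — the tests assert exactly that. The
cell-type panel draws monocyte/T/B/buffy-coat percent methylation from
(6.95, 5.46), (41.04, 10.23), (36.79, 10.80), (26.10, 9.80), clipped at
0 (left-censored normal; the monocyte mean shifts up by ≈0.26).

Passing tests on these generators demonstrate internal correctness and
calibration of the machinery — not that the pipeline would make the same
calls on real arrays, whose noise is heavier-tailed and whose covariates
are correlated.

## Validation stage

Imputation is iterative conditional modelling (sklearn's chained-
equations imputer) with either a tree-ensemble conditional model
(default, 20 trees — in the spirit of random-forest imputation) or a
Bayesian-ridge linear model; columns are standardised first so the shared
ridge penalty treats binary flags and large-scale blood tests evenly,
imaging flags are used as predictors but never imputed, and everything is
deterministic given the seed. Group comparisons use the pooled
independent t-test (Welch also computed) and the Pearson chi-squared test
with a Fisher-exact fallback when a 2×2 expected count is below 5 (the
"auto" default; forcing either is configurable, since published
categorical p-values of exactly 1.000 usually indicate an exact test).

The risk model is binary logistic regression fitted by IRLS with step
halving, which makes the log-likelihood non-decreasing by construction;
quasi-perfect separation is flagged, not raised. The base model starts
from all 18 candidate terms (age, sex, three risk factors, 13 blood
tests) and backward-eliminates at p < 0.05 — a choice made because a
published model of this kind typically retains only a couple of terms
but the selection procedure is rarely stated. The augmented model adds
the methylation marker to the retained set. AUC is the Mann–Whitney
concordance (ties 0.5) with a DeLong-style CI from placement values, and
is in-sample, matching how single-model AUCs are usually reported without
a stated split. Multinomial contrasts (isolated-X and coexistence-X vs
no-SVD) use statsmodels' MNLogit; a category below 10 patients is
skipped with a note (the isolated-microbleed contrast, n = 5 by default,
always is), and with two categories the fit equals binary logistic
regression to numerical precision.

Marker utilities: the pyrosequencing positivity screen selects a gene iff
its *minimum* group mean exceeds 5% strictly; ΔCt = Ct(target) −
Ct(reference), so larger ΔCt means lower relative expression.

## Numerical choices and degenerate inputs

- M-value base: log2, the field's convention.
- ALS: tol 1e-6 on the RMS reconstruction change, max 500 iterations by
  default; exact low-rank inputs need tighter settings (tol ≤ 1e-13,
  more iterations) to reach machine-precision reconstruction, since the
  alternating scheme converges linearly.
- Trigamma inversion: Newton from x = 0.5 + 1/y, with asymptotic
  branches for extreme arguments.
- λ rejects p = 0 with guidance to floor p-values (the χ² quantile is
  infinite); as a median-based statistic its sampling SE at 5,000 probes
  is ≈0.04, so calibration bands are applied to seed averages.
- BH is the exact step-up with stable tie handling, clipped at 1.
- Zero-variance metadata columns are skipped with a reason; constant
  matrices are rejected by PCA; empty amplicons, empty groups, single-
  class outcomes, fully missing columns and rank-deficient designs all
  raise informative errors.
- Cap tie-breaking is deterministic: (priority, lexicographic name).

## Known limitations

- The two arms share one beta matrix and differ only in composition
  covariates; they do not reproduce the normalisation differences of any
  published preprocessing toolchains.
- Reference-free loadings are identified only up to the usual
  factorisation ambiguities; recovery is assessed on the identifiable
  subspace (fractions sum to one, so their centred matrix has rank K−1).
- Marginal-ΔR² variance fractions under-attribute shared variance.
- In-sample AUC is optimistic relative to held-out evaluation.
- The generators' normal, conditionally independent cohort variables and
  Beta-noise arrays are idealisations; see the synthetic-data section.
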