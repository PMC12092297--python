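# Methods

## Data model

The pipeline consumes three delimited-text streams:

* **word bags** — `participant_id, date, word, count`: one row per
  unique lower-case token typed on that day. Bags are unordered, so the
  underlying text cannot be reconstructed; a day with no rows is a
  no-typing day and is treated as *missing*, never as zero usage
  (conflating the two would bias every percentage feature toward 0).
* **survey items** — `participant_id, timepoint_day, item_id, value`:
  flash-survey responses at roughly ten scheduled timepoints spanning
  days 7–180; absent rows encode missing items (planned or otherwise).
* **supporting tables** — the survey schedule (timepoint → calendar
  date per participant), a device log (for OS-switch removal), and
  per-activity completion rates (for the missingness diagnostic).

## Language features

Category lexicons are sets of literal tokens plus prefix patterns (one
trailing `*`, anchored at the word start — the convention of
word-count text analysis software; no mid-word wildcards). A bag's
category score is `100 * matched / total` with each word counted at
most once per category. Weighted lexicons score
`intercept + sum(weight_t * count_t / total)`; the linear
relative-frequency form is the standard convention for lexicon-based
trait estimates. A raw `word_count` feature is carried alongside (it
feeds the 10,000-word mask and is also available, standardized, as a
candidate feature). Features are z-scored with the sample (n−1)
standard deviation; inside the split workflow the scaling parameters
are fitted on the identification half only and reused on the
validation half, so no information leaks across the split. The bundled
lexicons under `src/langmark/lexicons/` are small synthetic toys whose
vocabulary matches the cohort generator; they stand in for proprietary
dictionaries and published trait models, which are deliberately out of
scope.

## Measurement model

Each symptom domain gets one pooled confirmatory factor model
`x_k = nu_k + lambda_k * eta + eps_k` with `eta ~ N(0,1)` and
independent uniquenesses, fitted by maximum likelihood with casewise
marginalization over each row's observed items (FIML). Pooling rows
across timepoints enforces loading invariance over the study. The
factor variance is fixed at 1 (rather than fixing a loading) so scores
share a standardized scale across domains, with the first loading
constrained positive. Optimization is quasi-Newton over
`(nu, lambda, log theta)` with five jittered starts; convergence is a
gradient norm small relative to the log-likelihood magnitude. Scores
are regression-method estimates restricted to each row's observed
items, hence shrunken (`var(eta_hat) <= 1`); rows observing no item
score missing. The estimator choice (ML, regression scores) is this
package's default, adopted as the field-standard pairing.

## Preprocessing rules

All thresholds are strict inequalities and are exposed in the pipeline
configuration: features with **> 90%** zeros among non-missing cells
are dropped (missing days do not count as zeros); daily word counts
**> 10,000** are set missing (count only — same-day percentage
features stand); participants with **≥ 2** distinct operating systems
within 180 days of their first device-log entry are removed
(participants absent from the log are kept with a warning); feature
pairs with pairwise-complete Spearman correlation **> 0.85** are
joined into redundancy components, and each component keeps the member
with the largest mean |Spearman| against the domain scores — an
explicit priority list can override this (the "conceptually most
interpretable" judgment), with remaining ties broken lexicographically
so the pipeline is deterministic. Marker observations are the mean of
the day-prior and day-of feature values; when one day is missing the
available day is used (discarding it would waste data and bias toward
heavy typists), and only two missing days yield a missing marker. The
missingness diagnostic correlates per-participant mean severity with
per-activity completion rates and flags the data MAR-plausible when
every |r| < 0.1.

## The bivariate mixed model

For one (feature, domain) pair the model is the correlated
random-intercept / correlated-residual form given in the README. Fixed
effects default to one overall mean per variable, matching the plain
bivariate-correlation formulation; an optional timepoint-specific
symptom mean absorbs the shared declining trend (its effect: slightly
smaller within-residual variance; the default leaves it off, and both
behaviors are tested). Residuals are independent across timepoints —
the fitted model has no serial correlation, and the generator's AR hook
exists precisely to probe that misspecification.

Estimation maximizes the exact Gaussian likelihood of each
participant's observed components. Internally the Woodbury identity
reduces every participant to a 2×2 core, and participants with the same
counts of (both / symptom-only / feature-only) timepoints share
sufficient statistics, so one likelihood evaluation costs O(#distinct
missingness-count groups). A dense-covariance evaluation
(`loglik_direct`) exists solely as an independent oracle and agrees
with the structured path to ~1e-13 in tests. Covariances are
log-Cholesky parameterized; starts come from method-of-moments
between/within covariances — for complete balanced panels this start
is the exact MLE (the likelihood factors into independent within- and
between-Wishart pieces), which the optimizer polish confirms. The
convergence criterion is a gradient norm small *relative to* the
log-likelihood magnitude (default 1e-8 relative), the practical analog
of an absolute tolerance under finite-difference gradients. Standard
errors come from the central-difference observed information matrix,
mapped to the correlations by the delta method (the gradient of
`rho = t/sqrt(t^2+u^2)` in the Cholesky parameters is analytic);
p-values are two-sided Wald. Estimated |rho| ≥ 0.999 is flagged as a
boundary fit and its SE reported missing rather than a meaningless
delta-method value. A likelihood-ratio alternative (`lrt_rho`) refits
with the relevant off-diagonal pinned to zero and refers twice the
log-likelihood gap to chi-square(1).

`fit_blmm_pairs` fits every (feature, domain) pair simultaneously with
a vectorized quasi-Newton loop over the stacked sufficient statistics;
it is numerically equivalent to the single-panel fitter (tested to
1e-4 on estimates and 0.1% on SEs) and is what makes 400-pair screens
and thousand-replicate calibration studies run in seconds.

## Split-half selection and change evaluation

The split is at the **participant** level (an observation-level split
would leak repeated-measures dependence across halves; the package
treats this as the only defensible reading of an "equal split of the
aggregated data"). Each pair contributes two tests — cross-sectional
(`rho_b`) and longitudinal (`rho_w`). Identification: BH-FDR across
the full feature × domain × type family, candidates at adjusted
p < 0.05 (strict, per the stated rule). Validation: Bonferroni with
the family equal to the candidate set, again strict. Reported
estimates for validated markers come from the validation half.
Non-converged fits are excluded from the families with a logged count.

Change evaluation takes the first and last scheduled surveys as
endpoints (configurable; calendar labels like "one week"/"six months"
are cosmetic). Worsening is a strictly positive score difference,
improvement strictly negative; zero differences and missing endpoints
are excluded from both truth and prediction. A marker's predicted
class is the sign of `validated correlation × marker change`, so
negatively associated markers are inverted — inverting a predictor
swaps its sensitivity and specificity, an identity the tests verify.
Because the positive-class convention of printed screening tables is
ambiguous, `evaluate_markers(..., both_conventions=True)` reports the
metrics under both conventions. PPV obeys
`ppv = sens·π / (sens·π + (1−spec)(1−π))` exactly, with π the
worsening prevalence.

## Synthetic cohort generator

The generator is the study-design mirror of the fitted model:
severity `trend_j + b_id + e_ijd` and latent category values
`b_ic + e_ijc`, with planted (category, domain) pairs sharing
intercept correlation `rho_b` and occasion correlation `rho_w`
(validated jointly positive definite; the two-variable panel generator
also admits the |rho| = 1 boundary by direct construction). Defaults
emulate the target study conditions: 10 timepoints over days 7–180, a
linearly declining severity trend (+0.5 to −0.5 latent units), three
items per domain with loadings (0.8, 0.7, 0.6), the third item
administered at alternating timepoints (planned missingness), 15%
item-level and 20% word-day missingness (MCAR by default — the
missingness diagnostic is what licenses that — with an optional MAR
mode linking dropout to current severity for robustness experiments),
and Poisson(150) words per day, near the reported typing median.
Word bags are drawn from a category-mixture multinomial whose logits
shift by `0.8 × latent value` (a softmax link — the simplest monotone
connection between the latent feature and category usage), with a
large neutral "other" category holding each planted category near a 5%
share; bags are generated for the day before and day of each survey.
One seed drives fixed-order derived streams (latents, items, words,
missingness, enrollment), so identical seeds give byte-identical
tables and enabling one stream never perturbs another.

What the generator does **not** emulate: real lexical diversity,
autocorrect or app telemetry, serial correlation (unless the AR hook is
turned on), and measurement non-invariance. Passing tests therefore
demonstrate the statistical machinery under the model's own
assumptions, not robustness to every way real smartphone data violate
them. Note also that features recovered *through* word bags carry
multinomial sampling noise, so pipeline-level correlation estimates are
mildly attenuated relative to the planted latent values; calibration
claims about the estimator itself are made on directly simulated
panels.

## Problem sizes and numerical choices

The calibration studies run at: parameter recovery — 100 replicates of
400 participants × 8 timepoints with 20% missing cells; type-I error —
1000 replicates of 200 × 6; the split-half screen — 200 replicates of
a 40-feature × 10-domain grid (3 planted pairs at rho_b = 0.6,
rho_w = 0.4, chosen so a 50-participant half has high power) with 100
participants × 5 timepoints; measurement recovery — 2000 pooled rows
with 25% item missingness and item noise sd 0.4 (at that noise the
theoretical score–truth correlation is 0.95; with unit-variance items
at the same loadings it cannot exceed 0.88, so validity checks pin the
noise explicitly). The bundled pipeline fixture uses 60 participants —
small enough to run everywhere, large enough to exercise every stage.
Optimizer tolerances: relative gradient 1e-8 (single fits), 1e-6
(batched screens); Hessian steps 1e-4 relative; BH/Bonferroni are
exact algebraic transforms with no tolerance.

## Known limitations

* Inference is asymptotic (Wald/delta method); very small cohorts or
  near-boundary correlations deserve the likelihood-ratio test or
  profile intervals, which are only partially provided (`lrt_rho`).
* No random slopes, covariate adjustment, or multivariable prediction
  combining markers; associations are deliberately unadjusted and
  single-marker, matching the workflow being reproduced.
* The measurement layer is one factor per domain with ML for
  continuous items; ordinal-item estimation and invariance testing are
  out of scope.
* No imputation: missingness flows into the likelihood, which is valid
  under MAR — the diagnostic can only flag gross MAR violations, not
  rule them out.
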