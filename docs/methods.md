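# Methods

This note documents the models, estimators and numerical choices behind
`salivamics`, what the synthetic-data generator does and does not emulate,
and the known limitations of the procedures it implements.

## Data model and processing states

Each omics layer is a feature-by-sample abundance matrix. Raw abundances are
strictly positive; missingness is modeled as missing-not-at-random (MNAR)
left-censoring — a value is absent because it fell below a detection
threshold, not at random. The matrix carries a processing-state flag and the
pipeline enforces the fixed order raw → normalized → imputed; every operation
declares which state it accepts, so imputation cannot precede normalization
and differential statistics cannot run on matrices that still contain
missing cells. Whether one should normalize before or after imputing is not
uniquely determined; this package fixes normalize → impute and records the
choice in each matrix's parameter sidecar.

## Preprocessing

**Log + median normalization.** Observed cells are log-transformed (base 2
by default, so downstream fold changes read directly as log2FC) and each
sample column is shifted so its median of observed values equals the grand
median of all pre-shift column medians. The grand-median target makes the
operation idempotent. All-missing columns are an error by default
(`on_empty_column="pass"` leaves them untouched); they are never silently
reduced to NaN medians.

**Downshift imputation.** For each scope unit — per sample column by
default, the convention of proteomics expression platforms; per-feature and
global scopes are available — the observed mean μ and SD σ are computed and
each missing cell is replaced by an independent draw from
Normal(μ − 1.8σ, (0.3σ)²). The defaults 1.8 and 0.3 are the platform-standard
values for left-censored proteomics intensities. Draws are consumed in
row-major (feature, sample) order of the missing cells under a caller-supplied
seed, so imputation is bit-reproducible. Scope units with fewer than three
observed values are an error (σ is unstable); features with zero observed
values are dropped with a warning rather than imputed from undefined moments.

## Differential statistics

**Moderated t-tests.** Per feature, a two-group means model gives the pooled
residual variance s² on d = n₁+n₂−2 df. The moderation prior (d₀, s₀²) is
estimated across features by method-of-moments on log s²: writing
e = log s² − ψ(d/2) + log(d/2), the excess of Var(e) over ψ′(d/2) determines
d₀ via the trigamma inverse (Newton iteration), and s₀² follows from the mean
of e. This is the standard empirical-Bayes construction behind moderated
t-statistics; the implementation reproduces Bioconductor limma's estimates to
machine precision on shared fixtures (a test runs limma through Rscript as an
independent oracle). The posterior variance is
s̃² = (d₀s₀² + d·s²)/(d₀+d) and t = Δx̄/(s̃·√(1/n₁+1/n₂)) is referred to a t
distribution on d₀+d df. When the moment estimate shows no excess dispersion,
d₀ = ∞: variances pool completely to s₀² and a normal reference is used.
Zero-variance features borrow s₀² rather than producing infinite t. Setting
d₀ = 0 recovers the ordinary pooled t-test exactly (tested). The sign
convention is: positive log2FC/t means higher abundance in the second-named
group of the contrast; the one-vs-all contrast CN vs MCI+AD is a two-group
comparison after relabeling.

**FDR.** Benjamini–Hochberg step-up, applied within each (layer × contrast)
or (layer × trait × stratum) family. The family definition is a package
choice; nothing narrower than per-layer is defensible given how the tables
are reported.

**Summary-statistics tests.** One-way ANOVA from printed group
means/SDs/sizes uses SSB = Σnⱼ(x̄ⱼ−x̄)² (size-weighted grand mean) and
SSW = Σ(nⱼ−1)sⱼ², identical to ANOVA on any raw data realizing those
summaries (tested against a direct computation). The chi-square test on
count tables is Pearson's without continuity correction. These reproduce the
published cohort-table p-values (0.637 sex, 0.002 APOE4, 0.008 vitamin B12)
from the printed summaries alone.

## Trait correlations

Every analyte is correlated with a continuous trait over the samples where
the trait is observed, optionally restricted to controls or to cases
(MCI+AD) — the stratification used for age. Spearman uses average ranks for
ties; p-values use the t approximation t = r√((n−2)/(1−r²)) on n−2 df for
both methods (exact small-n permutation p is not implemented). Both Spearman
and Pearson are exposed because the study's prose and its correlate tables
use the two labels interchangeably; the discrepancy is surfaced rather than
resolved. Constant features yield an undefined correlation and are flagged
and excluded from the FDR family. Records are emitted in increasing order of
p, matching the reported-table convention.

## Correlation-network modules

Per layer, the unsigned adjacency aᵢⱼ = |cor(xᵢ,xⱼ)|^β is built for each
power β in 1..20; connectivity kᵢ = Σⱼaᵢⱼ is binned into ~10 equal-width
bins and log₁₀ frequency is regressed on log₁₀ mean connectivity, giving the
signed scale-free fit −sign(slope)·R². The chosen β is the smallest with
signed R² ≥ 0.85, else the arg-max with a warning. (Equal-width, not
equal-occupancy, bins: equal-occupancy binning makes every bin frequency
identical by construction and degenerates the regression.)

The topological overlap dissimilarity is
1 − (ℓᵢⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ), ℓ = A², zero diagonal, verified
against a triple-loop oracle to 1e−10. Modules come from average-linkage
hierarchical clustering with a fixed cut at 0.99 of the merge-height
*range* (min + 0.99·(max−min)); branches smaller than 20 features are left
grey (unassigned) and the rest are named by size rank in the conventional
color order. The range-based cut is deliberate: at high powers the whole
dissimilarity matrix compresses toward 1 and a cut at a fraction of the
absolute height lands below every merge, shattering the tree; a cut relative
to the merge-height range is invariant to that compression. This fixed-height
rule is a documented simplification of dynamic branch cutting — module
boundaries, not label-for-label equality with any particular implementation,
are what the tests assert (planted two-block recovery reaches ARI ≥ 0.8 on
10/10 seeds). Module merging by eigenfeature similarity is available but off
by default.

Eigenfeatures are the first right singular vector of the standardized
member×sample block, sign-oriented so the mean member correlation (mean kME)
is non-negative; variance explained is the first squared singular value over
the total (always ≥ 1/module size). kME is each member's Pearson correlation
with its module eigenfeature; the top five by kME are reported as hubs, ties
broken by feature id. Module–trait tables use Pearson correlation with the
t-approximation p; binary traits enter as 0/1 and diagnosis as the ordinal
severity code CN=0, MCI=1, AD=2; modules with MMSE p < 0.001 are flagged.
The microbiome layer runs the same procedure on its 51-sample subset.

## Ensemble marker ranking

Markers separating controls from cases are ranked by stability selection
over three methods × 100 repeats (the default; analyses in this repository's
acceptance checks use 25 repeats, a supported scaling): an L1-penalized
logistic model (penalty picked by 3-fold cross-validation on the subsample;
importance = |coefficients|, exact zeros never qualify) and two
gradient-boosted tree variants (split-gain importances) with distinct
resampling regimes — 5/6 random subsamples for the first two methods, a 75%
training split for the third. Each run records its top-k (default 20)
features; counts are summed over methods and repeats, and the overall rank
is by descending total count with ties broken by mean within-run importance
rank, then feature id. Tree hyperparameters (50 trees, depth 3) are
config-exposed; none are prescribed by the source workflow. A method failing
on a subsample skips that (method, repeat) with a log entry. The per-run
top-k reported in figures elsewhere is sometimes 10 rather than 20; both are
config choices and reports state which was used.

Univariate statistics (log2FC, unpaired t, AUC) accompany the ensemble rank.
AUC is the tie-aware rank statistic P(score_case > score_control) + ½P(tie),
exactly equal to brute-force pair counting (tested, including ties); the
orientation-free AUC* = max(AUC, 1−AUC) is used for ranking, the raw AUC
retained.

## Panels

Panels are built greedily from a candidate pool (default: top 37 of the
ranking table). Panel score = AUC of leave-one-out cross-validated logistic
probabilities: for each sample, the model is fit on the remaining n−1
(features standardized with training-fold statistics only — per-fold
standardization is a package choice, making results invariant to affine
rescaling) and the held-out probability is that sample's score. Logistic
fits use Newton/IRLS with a ridge of 1e−6 on the slopes so quasi-separated
fits stay finite, step-halving on the penalized deviance, and log-odds
clipped at ±35; probabilities agree with an unpenalized reference
implementation to <1e−3. The search starts from the best univariate-AUC*
candidate and adds, per step, the candidate giving the largest LOOCV-AUC
gain, only if strictly positive (ε = 0), stopping at four markers; AUC ties
break toward the smaller coefficient-norm panel, then feature id.
Sensitivity at specificity uses the conservative convention: the maximum
sensitivity among ROC points with specificity ≥ target, no interpolation.

**Honesty of the panel AUC.** LOOCV probabilities remove resubstitution
optimism from a *fixed* panel's AUC, but the greedy search still maximizes
the LOOCV criterion over ~37 candidates per step, so the selected panel's
AUC retains selection bias: on pure-noise candidates the procedure converges
to a mean panel AUC around 0.70 (versus a resubstitution AUC well above it).
Two further null facts worth knowing: a single noise feature's LOOCV
logistic AUC is centred near 0.36, not 0.5 — the known below-chance
anti-learning artifact of cross-validating a null classifier — while at
panel dimensionality (four features) the permuted-label LOOCV AUC is centred
near 0.43. Nested cross-validation, which would remove the selection bias,
is deliberately out of scope: the package mirrors the source workflow's
design and reports it as a limitation.

## Synthetic cohort generator

The generator emulates what the downstream analysis assumes, not raw mass
spectra: cohort metadata (exact group sizes 40/20/20; sex, age, MMSE, APOE4
and plasma covariates drawn from group-conditional marginals matching the
published cohort table; pTau181 from per-group truncated normals
3.2(1.3)/4.8(2.2)/6.6(2.6) pg/mL; homocysteine and cholesterol marginals are
plausible elderly-cohort choices since no table states them) and three
abundance layers built on the log2 scale as latent-factor blocks plus
planted single markers plus independent noise, then exponentiated so the
pipeline's log transform recovers Gaussian structure. Feature baselines are
N(20, 2) log2 units with per-feature scales U(0.8, 1.6).

Three structures are planted per layer. (1) Modules: members load 0.8 on a
latent factor; the first module's factor is linked (0.7) to the negated
disease-severity code (abundance falling with disease) and the second's
(0.5) to the pTau proxy. (2) Single markers with monotone CN→MCI→AD mean
shifts (default profile 0, 0.5, 1.0 SD; alternating signs). (3) pTau
correlates with loading 0.6 on the standardized pTau column. Marker noise is
centered within groups and correlate noise is residualized against the
trait, so the *achieved in-sample* group means and correlations equal the
configured values exactly — the ground-truth manifest states achieved, not
merely target, structure, which makes it a sharp test oracle. The latent
link strengths were calibrated once so the emergent post-censoring,
post-imputation quantities land where a cohort of this size reports them:
module–MMSE correlations ≈ 0.4–0.53 and top-20 analyte–pTau correlations
≈ 0.43–0.51.

Censoring is hard MNAR left-truncation: each feature draws a censoring
quantile — below 0.5 with probability equal to the layer's completeness
target (0.61 proteins, 1.0 metabolites, 0.52 microbiome), otherwise in
[0.5, 0.9) — and values below the feature's empirical quantile at that level
are masked. This yields ~61% of protein features detected in ≥50% of
samples, and it attenuates planted correlations for heavily censored
features after imputation — a realistic effect the test suite accounts for
(planted pTau correlates reach the top-|ρ| decile ≥90% of the time on the
lightly censored metabolite layer, ≥80% on the censored protein layer).

One master seed spawns named child streams (cohort; one per layer; one per
layer's censoring) via `numpy.random.SeedSequence`, so layers regenerate
independently and all outputs are bit-reproducible. The microbiome layer is
restricted to a 51-sample subset (22 CN / 13 MCI / 16 AD at default sizes)
and reuses the same abundance model; count/compositional realism, batch
effects, taxonomy and spectral simulation are non-goals.

What passing tests on this generator do **not** show: robustness to
compositional microbiome structure, to batch effects, to non-Gaussian
abundance noise, or to missingness mechanisms other than hard
left-censoring; and covariate *joint* structure (e.g. pTau × APOE4) is not
modeled, only marginals.

## Problem sizes used in checks

Recovery and calibration checks run at the study's own scale (n = 80, 751
protein features) with 10 seeds where a success rate is asserted. The
ensemble ranker's resampling checks use 25 repeats per method; the null
calibrations use 500-feature simulations; imputation moment checks use 10⁴
draws. These sizes make every suite deterministic and quick while keeping
standard errors well inside the asserted tolerances.

## Known limitations

- Fixed-height (static) branch cutting instead of dynamic hybrid cutting;
  fine for well-separated modules, coarser for nested module structure.
- The Spearman p-value is the t approximation; exact permutation p for tiny
  n is not implemented.
- The greedy panel AUC carries selection bias (see above); panels should be
  confirmed on held-out cohorts.
- The ensemble ranker's hyperparameters are sensible defaults, not tuned;
  rankings are meant for stability screening, not effect estimation.
- Imputed values are treated as observed downstream (no uncertainty
  propagation), matching the platform convention the pipeline mirrors.
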