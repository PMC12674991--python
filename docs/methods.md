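# Methods

## Model

TransComp-R treats each mouse disease cohort's principal components as
candidate disease axes and asks whether human subjects, projected onto
them, separate by diagnosis. The statistical model at the core is a
binomial GLM with logit link,

    logit P(AD_j = 1) = β0 + β1 · t_ij  (+ γ_sex sex_j + γ_age age_j),

where `t_ij` is subject *j*'s score on mouse PC *i*. Selection of which
PCs to test is done first by LASSO stability selection over all cohorts'
PCs jointly; inference on a selected PC is the likelihood-ratio test of
the single-PC model against its covariates-only null.

## Preprocessing

* Human subjects are filtered to the analyzed brain region
  (case-insensitive match, default `hippocampus`) and an inclusive age
  floor (default 65: subjects *below* 65 are removed). Subjects with
  missing age are removed.
* Both matrices are log2-transformed with a configurable pseudocount
  (default 1.0; the field does not standardize one, and matrices
  already on log scale are passed through untouched via the `state`
  flag).
* Gene rows are restricted to one-to-one homolog pairs present in both
  matrices, in homolog-map order. Many-to-many homologs are dropped on
  both sides rather than collapsed — keeping a representative would
  assert an ortholog assignment the data cannot justify.
* Each gene is z-scored (sample sd, ddof = 1) within its own species'
  matrix, after the human subsetting so scores reflect the analyzed
  cohort. Zero-variance genes are dropped together with their homolog
  partners so row *i* always means pair *i*.

## PCA and projection

Each cohort (one disease model's mice plus all controls) is re-centered
per gene and decomposed by SVD; at most n−1 components carry variance.
The retained count is the smallest k reaching the cumulative-variance
threshold (default 0.80). Human projection subtracts the *mouse
subgroup's* per-gene center before multiplying by the loadings: the
human matrix is separately z-scored so its means are ≈0, and using the
mouse center makes "project the mouse subgroup itself" reproduce the
PCA scores exactly — the strongest testable contract for the
projection.

SVD signs are arbitrary, so each retained PC is oriented so that the
mean human AD score is ≥ the mean control score; the flips are recorded
in the run manifest. Orientation gives "toward AD" a fixed meaning for
GSEA and plotting and has no effect on selection or inference, which
are sign-invariant.

Variance explained in human by mouse PC `q_i` is the quadratic form
`‖X q_i‖² / Σ_j ‖X q_j‖²` over the retained set (X = human
subjects-by-genes matrix, uncentered — its gene columns are z-scored),
so the fractions sum to one by construction.

## Stability selection

All cohorts' retained PCs form one design matrix (PC columns
standardized so a single penalty is comparable across them), plus
optional unpenalized covariates: sex coded 0/1, age z-scored. Four
covariate configurations are run: none, sex, age, sex+age. Per round, a
fresh class-stratified 5-fold assignment is drawn; the penalty is
chosen by minimizing summed cross-validated binomial deviance over a
30-point log-spaced grid from the smallest all-zero penalty down two
decades; the model is refit on all subjects at that penalty; a PC
counts as selected in that round iff its refit coefficient is nonzero.
A PC is
*selected* overall if its count exceeds half the rounds strictly
(frequency > 50 on a 0–100 scale), *consistent* if selected under all
four configurations. PCs selected under any configuration are carried
to the GLM stage.

Covariates are unpenalized by default so demographics are controlled
rather than competed away (`penalize_covariates=True` switches). The
CV-minimum rule (not one-standard-error) maximizes sensitivity at
n = 42.

The L1 solver is an IRLS + coordinate-descent path solver with
per-feature penalty factors (scikit-learn's L1 logistic cannot leave
individual features unpenalized), warm-started along the path with an
active-set strategy. It matches scikit-learn/liblinear to ~1e-5 in the
all-penalized case (tested). Probabilities are clipped at 1e-5 during
IRLS; coefficients beyond |β| > 1e3 stop refinement (quasi-separated
region where the penalized optimum is effectively unbounded).

## Per-PC GLM

statsmodels binomial GLM. The headline significance is the
likelihood-ratio p of the covariate-free single-PC model against the
intercept-only null (α = 0.05); the sex+age-adjusted model is reported
alongside. Perfect separation (statsmodels' detection, or a fitted
|coefficient| > 1e3) is flagged and p reported as NA. Multi-PC GLMs are
deliberately not fitted: scores of matched PCs from different cohorts
are nearly collinear (they are projections onto almost the same latent
direction), so joint coefficients are uninterpretable; pairwise
correlations and VIFs (1/(1−R²)) are reported as a diagnostic instead.

## Preranked GSEA

Classic weighted Kolmogorov–Smirnov statistic on a PC's human-gene
loadings, ranked descending with lexicographic tie-breaks. The running
sum gains `|loading|^w / Σ_hits |loading|^w` (w = 1) at set members and
loses `1/(N − n_hits)` elsewhere; the ES is the signed extremum, ties
in magnitude resolving positive. The null permutes gene labels — random
same-size sets — since preranked input has no sample replicates to
permute. p-values are one-sided within the observed sign with a +1
pseudocount; NES divides by the mean |null ES| of the same sign; a set
with no same-sign nulls gets p = 1/(nperm+1) and a flag. No further
p-value floor is applied. BH adjustment runs across the sets of one
collection per call, so KEGG-style and Hallmark-style collections are
adjusted separately; significance is adjusted p < 0.25. Set sizes are
bounded to [5, 500] after intersection with the ranked universe. The
leading edge is the set members at or before the running-sum maximum
(positive ES) or at or after the minimum (negative ES); overlaps across
PCs are reported as a full inclusion–exclusion partition.

A multilevel split-sampling p-value scheme (as in fgsea) would resolve
smaller p-values per permutation budget; plain permutation with a large
nperm is used here and the resolution floor 1/(nperm+1) documented.

## Sex-stratified comparison

Subjects split into female/male × AD/control; all six pairwise
Mann–Whitney tests are run per PC, BH-adjusted as one family per PC
(α = 0.05), with the four biologically framed pairs flagged. The U null
is enumerated exactly over all C(n1+n2, n1) group assignments of the
pooled values whenever the smaller group has ≤ 8 subjects — stratified
groups are small and enumeration handles ties exactly — and scipy's
tie-corrected normal approximation (continuity-corrected) is used
otherwise. Two-sided p = min(1, 2·min(P(U ≤ u), P(U ≥ u))). The two
paths agree to ~0.01 at the boundary size on continuous data. Group
summaries report mean and interquartile range. A pair with a group of
fewer than two subjects is reported NA and excluded from the BH family.

## Synthetic world

The generator draws log-scale expression from a Gaussian factor model
X = S W + μ + ε shared across species over homolog-paired genes.
Defaults state the emulated study: 2000 genes, 3 mice per condition
(all male), 24 control + 18 AD humans with sexes in the 11F/13M and
9F/9M proportions of the emulated cohort, ages uniform 65–95, noise sd
1, 4 latent factors with 20% loading sparsity.

* The **translatable factor** is shifted by δ_m = 3 in T2D and ADxT2D
  mice and by δ_F = δ_M = 2 in human AD (per sex, so δ_M = 0 expresses
  a female-only effect). Its baseline mouse score sd is 0.2: the
  metabolic axis is modeled as quiescent in mice unless disease drives
  it. Without this damping every cohort's PCA — including the AD-only
  cohort's — would inherit the human-outcome-linked direction as
  ordinary background variance and all three models would "translate".
* The **AD-only factor** is shifted by δ_m in AD mice and is absent
  from humans (human scores zero), so AD-cohort components exist but do
  not predict human disease.
* A **planted set** of 50 genes carries boosted positive loadings
  (|N(0,1)|·3) on the translatable factor; 19 equal-size decoy sets are
  random draws from the gene universe.

What a green test establishes: the pipeline recovers exactly this kind
of structure — a low-rank shared factor with a mean-shift disease
effect, Gaussian noise, no batch or probe effects, no count statistics.
It does not establish performance under microarray probe artifacts,
RNA-seq overdispersion, confounded demographics, or many-to-one
homology. One small-n caveat is intrinsic and visible in the recovery
reports: with 6 samples and 2000 genes a cohort's trailing PCs are
noisy mixtures, so an AD-cohort PC can partially align with the
translatable axis and reach GLM significance at some seeds — the same
phenomenon as a selected-then-discarded AD PC in real data. The robust
property, asserted in the acceptance suite, is that the metabolic
cohorts' translatable PCs are recovered; the matched T2D and ADxT2D PCs
are near-collinear in human score space, so the LASSO may put its votes
on either.

## Numerical choices

* Sample sd (ddof = 1) throughout; log2 pseudocount 1.0.
* Cumulative-variance rule: smallest k with cumvar ≥ threshold, capped
  at n−1.
* Ranking tie-breaks are lexicographic on gene id everywhere a sort
  order is exposed (GSEA ranking, extreme-loading lists), making every
  ordering deterministic.
* LASSO path: 30 lambdas, min-ratio 0.01, IRLS tol 1e-6; CV deviance
  ties resolve to the larger penalty.
* Master seeds are split via `numpy.random.SeedSequence` into
  independent per-stage and per-covariate-model streams, so changing
  e.g. the GSEA permutation count does not perturb the fold draws, and
  a fixed seed reproduces every artifact bitwise.

## Limitations

* Accession download/parsing is out of scope; inputs are generic TSV
  (gene-level, pre-collapsed probes) plus GMT collections.
* The pooled-design LASSO (all cohorts' PCs in one model) is one of two
  defensible readings of the method; per-cohort selection would avoid
  cross-cohort vote-splitting at the cost of never comparing cohorts
  head-to-head.
* Elastic-net/ridge variants, sample-permutation GSEA, batch
  correction and mild-cognitive-impairment outcomes are not
  implemented.
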