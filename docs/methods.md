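# Methods

This note records the statistical procedures, the synthetic-cohort model
behind every test, and the choices made where the design was genuinely
open.

## Cohort model and marker registry

A cohort is a participants × markers real matrix with an explicit
missingness mask, plus per-participant clinical annotation: the Frascati
NCI class (`none` / `ANI` / `MND` / `unknown`, with the derived NCI flag
true for ANI or MND) and periventricular / deep Fazekas white-matter-
hyperintensity scores (integers 0–3, missing when no MRI rating exists).

The canonical registry holds 59 markers: for each T lineage (CD4, CD8)
the lineage itself (% of lymphocytes and absolute count) plus 11
activation / exhaustion / senescence / differentiation phenotypes
(HLA-DR+, CD38+, HLA-DR+CD38+, HLA-DR+CD38−, PD-1+, CD57+, CD57+CD28−,
CD57+CD28−CD27−, naive CD45RA+CD27+, central-memory CD45RA−CD27+,
effector-memory CD45RA−CD27−), each as percent and count (24 per
lineage); three NK phenotypes (HLA-DR+, CD56−, CD57+) as percent and
count; four soluble markers (sCD163, sTNFRI in pg/mL; tPA, sEPCR in
ng/mL); and the total lymphocyte count. Percent markers live in
[0, 100]; counts and concentrations are non-negative.

## Preprocessing

1. **Missingness filter.** A marker is discarded when its missing
   fraction strictly exceeds 10% (the threshold is configurable; the
   inequality is strict, so exactly 10% is retained).
2. **Two-nearest-neighbour imputation.** Each missing cell is replaced
   by the mean of that marker in the two nearest neighbour patients.
   Distance between patients is Euclidean over the markers observed in
   both, after z-scoring each marker by its observed mean/SD, divided by
   √(number of shared markers) so overlaps of different sizes compare
   fairly. Neighbours must have the target marker observed. Markers are
   on wildly different scales (percent vs cells/µL vs pg/mL), so some
   scaling is mandatory; z-scoring is the simplest defensible choice.
   Neighbours are sought among patients (rows), not markers; the
   alternative reading is possible but patient-space distances are the
   standard KNN-imputation convention.
3. **Correlation dedup.** Pearson correlations are computed on the
   imputed matrix; pairs with |r| strictly above 0.95 define a graph,
   and within each connected component only the marker with the largest
   |t| (two-sided pooled-variance Student t between NCI+ and NCI−) is
   retained. Working per component rather than per pair makes the
   result independent of pair-processing order. Patients with unknown
   NCI class are excluded from the retention t-tests.

Each stage is idempotent on its own output and reports every decision
(dropped markers with fractions, imputed cells with neighbour ids, kept
/ removed pairs with |r| and both t statistics).

## Screening

Each marker is tested with a Kruskal–Wallis test (midrank ties,
chi-square reference distribution) across the three outcome classes
none / ANI / MND; a two-level grouping (NCI− vs NCI+) is available,
which reduces KW to the Mann–Whitney test. The degenerate all-values-
identical case is defined as H = 0, p = 1. Benjamini–Hochberg step-up
adjustment (q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, clipped at 1) spans all markers
surviving preprocessing; a marker is selected when q ≤ α (default
0.05).

Per-marker two-group comparisons use Student's t (pooled variance) when
both groups pass Shapiro–Wilk at α = 0.05, otherwise Mann–Whitney with
normal approximation and tie/continuity correction; groups with zero
variance are treated as non-normal since Shapiro–Wilk is undefined
there. The white-matter analysis dichotomizes each Fazekas score into
0–1 vs 2–3, compares the marker between those groups, and reports the
Spearman correlation between the two scores (pairwise-complete); an
empty dichotomized group renders that comparison not-computable rather
than an error.

## Classification

LDA with pooled within-class covariance S, ridge-stabilized as
S + ridge·tr(S)/p·I (default ridge 1e-6 — only relevant when the subset
size approaches the class sizes): w = S⁻¹(μ₁−μ₀), decision threshold
wᵀ(μ₀+μ₁)/2 − log(π₁/π₀) with empirical class priors by default;
boundary ties go to class 0 (no impairment). Note the trace-based ridge
makes the rule invariant to marker rescaling only approximately;
differences are negligible at ordinary unit changes but can matter at
extreme (10⁴-fold) variance ratios.

Evaluation is by repeated stratified 2-fold cross-validation: per
repeat, a random stratified partition; fit on each fold, predict the
other; accuracy is the pooled correct fraction across the repeat's
folds (unbiased with unequal fold sizes), sensitivity the correct
fraction among NCI+ and specificity among NCI−; means are taken over
repeats (default 30).

## Genetic-algorithm panel search

Binary chromosomes (bit = marker included); fitness = mean CV accuracy
minus 0.005 per included marker, so among equally accurate panels the
smaller always wins. Tournament selection (size 3), uniform crossover
(probability 0.8), per-bit mutation 1/p, elitism 1, population 100, 50
generations; empty chromosomes are repaired by activating one random
bit. During the search the CV uses 5 repeats with partitions seeded
identically for every subset (comparable fitness values, cacheable);
the protocol's final step re-evaluates every distinct final-generation
subset pooled over 4 independent runs with 30 runs of 2-fold CV on a
seed stream independent of the search, and ranks by re-evaluated
accuracy (ties: smaller panel, then marker ids). All hyperparameters
are ordinary textbook defaults and configurable; no result should hinge
on their exact values.

## Profiling

Profiling uses the percentage markers plus the four soluble
concentrations (absolute counts fluctuate more over time and would
dominate raw Euclidean distances); columns are z-scored and
zero-variance columns dropped. Patients are clustered on Euclidean
distance, markers on 1 − |Pearson r| (treated as a plain dissimilarity),
both with Ward's minimum-variance linkage (Lance–Williams update on
squared dissimilarities — applying Ward to the non-Euclidean marker
dissimilarity is the usual pragmatic choice in this field's heat-map
pipelines).

Clusterability: Hopkins statistic H = Σu/(Σu+Σw) with m = ⌊0.1·n⌋
sampled rows, u the nearest-neighbour distances from uniform points in
the per-dimension bounding box to the data and w from sampled rows to
the remaining data; H ≈ 0.5 under spatial randomness, → 1 for
clusterable data.

Cluster number: mean silhouette width (singletons scored 0) and the
Tibshirani gap statistic with B = 50 uniform bounding-box references
(each clustered by the same Ward pipeline), Gap(k) = mean_b log W*ₖᵦ −
log Wₖ, sₖ = sd_b·√(1+1/B), choosing the smallest k with Gap(k) ≥
Gap(k+1) − sₖ₊₁ over k ∈ 2..10. Both criteria are reported; when they
disagree the gap choice is final (the silhouette of high-dimensional
Ward trees often peaks at k = 2 even under clear finer structure, and
the gap's reference-based calibration is the better-behaved criterion
here). References are drawn in the raw bounding box, not PCA-rotated.

Labels 1..k are assigned by decreasing cluster size (ties by first
patient index) — note this means assigned numbers need not match any
externally defined profile numbering. The heat map orders patients and
markers by their dendrogram leaf orders and is exported with the
ordered z-score matrix as TSV.

## Enrichment

Profile-vs-outcome association uses the 2×2 table (profile membership ×
NCI flag) with the two-sided Fisher exact test (probability-mass
criterion, not doubling). The odds ratio is ad/bc with the
Haldane–Anscombe +0.5 added to every cell if and only if some cell is
zero — this keeps estimates finite while leaving clean tables exact,
and reproduces the characteristic pattern of a large finite OR with a
confidence interval crossing 1 when one margin is nearly empty — and a
Woolf log-normal confidence interval on the (possibly corrected) cells.
Profile characterization compares every marker between profile members
and the rest (t / Mann–Whitney as above, ranked by p), and against
external reference moments via Welch's t from summary statistics
(mean, SD, n), the only form in which general-population reference
values are typically available.

## Synthetic cohorts

The generator plants exactly the structure the pipeline is meant to
find, calibrated to the published group statistics.

**Profile cohort** (default 240 = 6 × 40). Each of six latent profiles
draws its markers from clipped normals — equicorrelated (ρ = 0.1)
within each lineage block, independent across blocks — with per-profile
(mean, SD) overrides and a common baseline elsewhere. All published
per-profile moments are used verbatim (e.g. quiescent-profile %CD57+ T4
2.2 ± 1.9 vs 8.8 ± 8.1 elsewhere; CD8-activated profile %CD38+ T8
57.3 ± 13.3; low-CD4 profile CD4 count 576 ± 250; sCD163 974 ± 466; tPA
16.4 ± 9.8; CD4-activated profile %HLA-DR+ T4 44.9 ± 13.7). Because a
single ~1-SD shifted marker among ~30 dimensions is not a recoverable
cluster for any method, each profile additionally carries coherent
unpublished shifts of ~1–2.5 baseline SDs on related same-lineage
markers with slightly tightened SDs, emulating the homogeneous blocks
visible in double-clustered heat maps; these auxiliary shifts were
fixed once, after pilot calibration of the separation scale, and are
part of the generator's definition. NCI status is Bernoulli per
profile, default (0.60, 0.20, 0.53, 0.20, 0.20, 0.20) — the quiescent
and low-CD4 profiles enriched — with MND given NCI at 9/25. Sporadic
2% MCAR missingness; two high-missingness markers (rate 15%, drawn
among count markers only so the percentage-based profiling structure
survives the QC drop); one duplicate marker column appended as a
0.97-correlated noisy copy of %CD38+ T8 (noise redrawn, bounded
retries, until the sample |r| ≥ 0.95).

**Neurocognition substudy** (default 40 NCI− vs 25 NCI+). The six
discriminating markers are drawn group-conditionally from the published
moments — %CD8 (51.8 ± 11.1 / 46.0 ± 11.1), %HLA-DR+ T4 (27.5 ± 13.5 /
19.0 ± 8.4), HLA-DR+ T8 count (473 ± 263 / 290 ± 219), HLA-DR+CD38+ T8
count (169 ± 136 / 106 ± 102), CD57+CD28− T4 count (223 ± 170 /
108 ± 93), CD57+CD28−CD27− T8 count (170 ± 148 / 82 ± 83) — and all
other registry markers from baseline. A `plant_effects=False` variant
yields null cohorts for FDR-control checks.

**Fazekas scores.** A shared latent Gaussian, thresholded at the
cut-points of the configured marginals (periventricular
12/54/25/9%, deep 9/59/16/16%), with latent correlation 0.9 between
the two scores and a negative coupling (default 0.6) to the normal
scores of %HLA-DR+ T4, calibrated so the 0–1 vs 2–3 group gap matches
the published ~1-SD difference. Using rank-based normal scores keeps
the latent exactly standard normal, so the marginals hold regardless of
the marker's clipped, mixed distribution. Nine random participants are
left unrated, matching the 56-of-65 rating coverage.

**Baselines** for unpublished markers are plausible values for treated
PLWH and only carry realistic scale. Percentage and count variants of
a phenotype are drawn marginally: the published moments are emulated,
the deterministic percent × parent-count identity is not. Clipping at
physiological bounds shifts strongly skewed means slightly (e.g. a
2.2 ± 1.9 percent marker clipped at 0 gains ~0.12); tests account for
this.

**What passing tests do and do not show.** The generator is
multivariate normal (clipped) with block-equicorrelation; real
cytometry panels are skewed, heteroscedastic and more intricately
correlated. Recovery results therefore demonstrate correctness of the
pipeline's statistics under its own assumptions, not field performance.
One concrete consequence: with normal data at the published effect
sizes (the weakest discriminating markers have d ≈ 0.5), BH selection
at n = 65 recovers only the stronger markers per cohort, whereas the
original study reported all six with adjusted p just under 0.05 —
plausible under skewed real data where rank tests exceed their
normal-theory power. The six-marker classifier accuracy, by contrast,
is reproduced within a point or two of the published 77%.

## Problem sizes and numerical choices

Simulation-backed checks use 8–25 seeds per property and cohorts of
65–240 patients (10,200 for marginal checks of the ordinal score
generator); these sizes give the test suite a desk-scale footprint
while keeping Monte-Carlo bands tight enough to be meaningful.
Deterministic seeding throughout (NumPy `default_rng`); GA fitness
memoized per subset; gap references re-clustered per draw. Tolerances:
statistical examples to printed precision; cross-checks against
independent implementations at 1e-6–1e-12; stochastic recovery bounds
as stated per test.

## Known limitations

- No covariate adjustment anywhere (age, sex, education); the original
  analysis treated confounding in a side analysis that is out of scope.
- The CV protocol estimates accuracy for panels chosen by the same CV
  criterion; without an outer validation loop the GA-selected panel's
  accuracy is optimistically biased (a limitation shared with the
  original protocol).
- Fisher/odds-ratio enrichment treats profiles as fixed; uncertainty in
  the clustering itself is not propagated.
- The 1 − |r| marker dissimilarity is not Euclidean; Ward heights on it
  have no variance interpretation (ordering is still well-defined).
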