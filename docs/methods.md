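# Methods

This note documents the models and procedures implemented in `dietmg`, the
design choices made where several reasonable options existed, what the
synthetic-data generators do and do not emulate, and the package's known
limitations.

## Dirichlet multinomial mixtures and Laplace model selection

Count rows (food-item nutrient vectors, or per-sample CAZy family
pseudo-counts) are modelled as a finite mixture of Dirichlet-multinomial
components. Fitting is by EM: responsibilities in the E-step, mixture
weights and per-component Dirichlet parameters in the M-step, the latter by
a responsibility-weighted Minka fixed-point iteration (a few inner
iterations per EM step; the outer loop re-enters the update until the joint
fit converges). Alphas are capped at 1e4 — beyond that the component is
effectively multinomial and the likelihood only creeps logarithmically —
and EM runs restart from random hard splits (3 restarts for K > 1), keeping
the best likelihood.

The number of components K minimises a Laplace approximation to the
negative log model evidence. The Dirichlet-multinomial likelihood is nearly
flat along each component's overall-concentration direction, so the bare
observed information has a near-zero eigenvalue there and the plain Laplace
determinant rewards that flatness, favouring spurious extra components. We
therefore use the MAP form with a weak Gaussian prior on log α
(variance 25): the score is
`−log L − log prior + ½ log det(H + τI) − (d/2) log 2π`,
with the per-component Hessian w.r.t. log α computed analytically
(diag + rank-one structure), prior curvature τ = 1/25, and the mixture
weights contributing the multinomial information determinant
n^(K−1)·Πw. The prior variance is wide enough that tight nutrient clusters
(α ~ 1e3–1e4) are not unduly penalised yet the weakly identified direction
stays pinned. Ties in the hard assignment break toward the lowest component
index; K candidates exceeding the row count are skipped with a warning.

## Food tree and UniFrac

The tree has root (level 1), the five broad classes (level 2: animal-based,
plant-based, alcohol, fats, others), the database hierarchy (levels 3–4)
and DMM nutrient subcategories (level 5), with items as leaves. Nutrient
vectors are integerised for the DMM by rounding grams-per-100 g × 10;
energy is excluded from the composition vector because it is a linear
combination of the macronutrients. Rows that integerise to all zeros
receive one pseudo-count so the fit stays defined. Singleton level-4
categories become a single level-5 node.

Branch lengths default to 1 (purely topological distance) and are
configurable; no data here motivates non-unit lengths. Diet profiles are
binary presence over leaves — any consumption > 0 g across the four diary
days — because the unweighted metric ignores amounts. UniFrac itself is
computed by scikit-bio; the test suite keeps an independent brute-force
branch-enumeration oracle. The meat/plant ratio is
log2((animal grams + c)/(plant grams + c)) with pseudocount c = 1 g;
alcohol, fats and others enter neither sum.

## FSA-NPS scoring

Point-attribution breakpoints ship as an editable YAML config
(energy kJ 335…3350 → 0–10; sugars 4.5…45 g; saturated fat 1…10 g; sodium
90…900 mg; fiber 0.9…4.7 g; protein 1.6…8.0 g; fruit/veg 40/60/80% →
1/2/5). The item score is the unfavorable sum minus the favorable sum,
spanning −15…+40; class bounds are strict `score < bound` (A < 0, B < 3,
C < 10, D < 18 for foods; A < 1, B < 2, C < 5, D < 9 for drinks), so a
score of exactly 40 is class E on both scales. The diet index weights each
*portion* by its energy (per-100 g energy × grams/100), making the index
invariant to splitting a portion in two. The main-meal quality ratio counts
items (not grams) and uses classes A vs E by default; both choices are
configurable arguments.

## MSP subspecies

Detection is strict: median core coverage > 2. The accessory presence band
is the 2.5–97.5% quantile interval of that sample's core-gene coverages
(core genes are the coverage reference for each sample × MSP). Coverage
above the band flags a multi-copy/conserved gene; the default codes it
present — the gene is evidently there — with a config switch to code absent,
and both paths are tested. A degenerate band falls back to coverage > 0
with a warning.

Clustering is PAM (deterministic greedy BUILD + SWAP) on the Jaccard
distance between accessory profiles, k = 2…k_max on the full matrix; the k
maximising mean silhouette width is selected unless that maximum is below
the floor of 0.25, in which case the MSP is left unsplit (k = 1). MSPs
with fewer than 10 detected samples are never split. Stability follows the
subset-bootstrap convention: refit on random 2/3 subsets without
replacement and record each full-fit cluster's mean best-match Jaccard
across refits (threshold 0.6 flags unstable clusters). By default the
bootstrap runs only for the selected k — silhouette, not stability, drives
model selection, and per-k bootstraps would multiply runtime without
changing the partition; a flag restores per-k bootstrapping.

Subspecies abundance attributes each detected sample's MSP abundance
(median core-gene abundance) wholly to its assigned subspecies; undetected
samples get 0, so the per-sample sum over an MSP's subspecies equals its
abundance exactly on detected samples.

## Ordination, PERMANOVA and co-inertia

√JSD uses natural logarithms with a 1e-6 pseudocount replacing zeros before
per-sample normalisation. PCoA is the classical double-centered
eigendecomposition, dropping negative eigenvalues from both axes and
variance fractions; the centering statistics are retained so new
individuals can be projected from their distances to the training samples
(Gower's supplementary-point formula — projecting a training sample's own
distance row reproduces its coordinates exactly, which the tests assert).
A joint-PCoA mode (ordinate everyone, then split) is available by simply
computing the PCoA on all samples before fitting co-inertia.

PERMANOVA uses the trace form: G the double-centered squared-distance
matrix, H the hat matrix of the covariate design (dummy-coded categories or
a centered continuous column), R² = tr(HG)/tr(G),
pseudo-F = (SSA/df1)/(SSR/df2), p = (1 + #{F* ≥ F})/(1 + n_perm). This
admits the continuous covariates needed by the per-node scan, which sums
leaf (subspecies) abundances up a taxonomy and retains every lineage with
at least one node above 2% R², deliberately without a significance filter.

Co-inertia decomposes the cross-covariance of the column-centered PCoA
blocks (uniform row weights) by SVD; RV is computed from the centered
blocks. Defaults retain 7 co-inertia axes and use 5 components for the
regressions, matching the pipeline's reported choices. Individuals with
one block are projected by centering with the training means and applying
that block's loadings. The H₂/CH₄ ratio is computed with +1 on both gases
before division to guard zeros (configurable).

## Functional analysis

Family abundances are renormalised per sample within each annotation
universe (CAZy, hydrogenase), so rows are compositional. CAZotype DMM runs
on pseudo-counts (relative abundance × 1e4, rounded — the same
integerisation convention as the food tree). The correlation network keeps
cross-table Spearman pairs with |rho| strictly above the threshold (0.4
default); within-table edges are off by default. LDA standardises features
(making scores scale-invariant), pools the within-class covariance with a
small ridge (stronger, with a warning, when the matrix is ill-conditioned —
compositional closure makes it exactly singular), and reports each
feature's |loading| signed by its class-mean difference, so positive scores
mark severe-enrichment; a log10-style magnitude column is kept for display.

## Synthetic cohorts: what they emulate, and what they do not

The generators reproduce the *statistical design* of a diet–microbiome
cohort, not its biology:

- Food items carry a 4-level hierarchy with 2–3 distinct Dirichlet nutrient
  components inside larger level-4 categories (within-component
  concentration 400, i.e. tight clusters), drink flags and fruit/veg
  percentages. Nutrient values are internally consistent (saturated ≤ total
  fat, fructose ≤ monosaccharides ≤ sugars ≤ carbohydrate) but are not
  calibrated to any real food database.
- Diaries hold 4 days × (3 main meals + 0–2 snacks); item choice follows a
  softmax tilted by the subject's meat/plant latent (±1 direction for
  animal/plant classes) and quality latent (standardised FSA-NPS score);
  grams are log-normal and each day is rescaled to a plausible energy
  target (N(2200, 300) kcal clipped to [1200, 3800]), so generated cohorts
  pass the 800–4500 kcal screen by construction.
- Metagenomes plant one subspecies per detected sample × MSP as a disjoint
  accessory block at core-level coverage; other blocks stay at zero. About
  10% of sample × MSP pairs are undetected (median core coverage ≤ 2).
  When a truth object is supplied, subspecies choice and MSP abundance tilt
  with the meat/plant and quality latents, coupling the metagenome to diet.
- Clinical severity (1–4, cohort-like proportions ≈ 27/13/26/34%) is a
  quantile-binned monotone function of the quality latent plus noise; the
  log2 H₂/CH₄ ratio is linear in the latents plus noise.
- Functional profiles couple one hydrogenase group and eight
  animal-carbohydrate CAZy families to a gas-metabolism latent
  (log-linear, slope 0.8, log-noise 0.35). The coupled families sit ~2.5
  log-units below the bulk so their swings barely move the universe total:
  in small within-universe compositions, closure otherwise induces spurious
  |rho| > 0.4 correlations between the driven group and unrelated families.
  Severity labels follow a logistic in the same latent, and optional
  planted CAZotypes give sample clusters distinct marker-family profiles.

Passing tests on these cohorts demonstrates that each estimator recovers
the structure it targets at realistic sample sizes (40–200), with correct
calibration where a null is planted. They do not demonstrate robustness to
real-data pathologies: uneven sequencing depth, compositional artifacts
beyond the planted families, diary under-reporting, food-database
missingness, or confounded gradients.

## Numerical choices and degenerate inputs

- EM convergence: relative log-likelihood change below max(1e-6·|ll|, 1e-3),
  or a dip (partial M-steps can cause tiny non-monotone steps; the best
  iterate is kept), capped at 80 iterations.
- PAM is deterministic given the distance matrix; only the bootstrap
  subsampling consumes the seed.
- Both-empty accessory profiles get Jaccard distance 0 with a warning;
  all-zero abundance rows are an error for √JSD; empty diet-profile pairs
  are an error for UniFrac.
- Permutation p-values use the add-one convention and a 1e-12 slack on the
  F comparison; degenerate zero-residual partitions return F = ∞ so the
  permutation tail stays well-defined.
- Constant covariates (PERMANOVA), constant features (axis correlations,
  networks) and score-range violations raise or are skipped with warnings,
  as documented per function.

## Pipeline problem sizes

The demonstration pipeline runs 60 subjects, 120 food items, 4 MSPs (2–3
planted subspecies each), 60 CAZy families and 12 hydrogenase groups —
small enough to execute in seconds while every stage's planted structure
remains recoverable, which is what the acceptance checks measure. The
acceptance script uses 20-seed replications for recovery rates, 500
replicates × 199 permutations for PERMANOVA calibration, and a 150-subject
cohort (100 train / 50 test) for the coupling analysis.

## Known limitations

- The DMM evidence is an approximation; very small categories (< 4 rows)
  rarely justify K > 1, so level-5 granularity is conservative at small n.
- The per-node PERMANOVA scan tests nodes marginally; nested nodes share
  leaves and their R² values are not independent.
- LDA ranks features by a regularised discriminant on compositional data;
  with few samples a noise feature can occasionally out-rank a truly
  enriched one (observed at roughly the 1-in-40 seed level in the planted
  setting).
- Subspecies calling assumes accessory blocks are present-or-absent at
  core coverage; partial-coverage strains (block at half depth) would blur
  the Jaccard separation and are not simulated.
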