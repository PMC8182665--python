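# Methods

`herdclust` implements a two-stage analysis for dairy populations kept in
small herds: (1) clustering of herds described by mixed-type
social-ecological survey variables, and (2) a pedigree test-day genetic
evaluation in which herd *clusters* replace single herds in the
contemporary-group (CG) definition. This note documents the models, the
numerical choices, and what the synthetic data do and do not emulate.

## Stage 1 - herd clustering

### Survey representation and editing

A survey is a herd x variable table with a per-variable type declaration
(quantitative, nominal, ordinal, symmetric or asymmetric binary); types are
never inferred from data. Before clustering, variables with limited
variation (fewer than 2 observed levels, or a dominant level covering >= 95%
of herds, or zero variance) are dropped, and of every quantitative pair with
|Pearson r| > 0.95 the later column is dropped. Both thresholds are
arguments; every removal is logged with its reason so the editing is
auditable. Quantitative columns are z-transformed (sample mean 0,
variance 1).

### Gower dissimilarity

d(i,j) = sum_k w_k delta_ijk d_ijk / sum_k w_k delta_ijk, where
quantitative variables contribute range-normalized absolute differences,
ordinal variables are rank-normalized to [0, 1] and then treated as
quantitative (the daisy convention), nominal and symmetric binary variables
contribute simple mismatch, and asymmetric binaries exclude joint-absence
pairs (delta = 0). Missing values are handled by pairwise deletion
(delta = 0); a herd pair with no comparable variable raises an error naming
the pair rather than producing a silent NaN. The "absent" state of an
asymmetric binary is the first declared level.

### The four clustering strategies

* **AHC** - Ward agglomeration in the ward.D2 convention (Lance-Williams
  update on squared dissimilarities), via scipy's linkage on the condensed
  Gower matrix. Tests verify the heights against a naive O(n^3)
  reimplementation of the recurrence.
* **PAM** - Kaufman-Rousseeuw BUILD seeding followed by first-improvement
  SWAP in index order. Because a swap-local optimum occasionally differs
  from the global optimum even in the canonical implementations, the result
  is refined by exhaustive enumeration whenever C(n, k) <= 20,000, which
  makes the desk-scale result provably optimal while leaving larger
  problems to the standard local search.
* **FZC** - fuzzy clustering of the dissimilarity matrix minimizing
  sum_v [sum_ij u_iv^r u_jv^r d(i,j)] / [2 sum_j u_jv^r]. Memberships are
  updated by the closed-form stationary rule; any update that would raise
  the objective is damped toward the previous iterate, so the objective
  history is nonincreasing by construction. Default exponent r = 1.1
  (nearly crisp), tolerance 1e-8, at most 10,000 iterations, seeded
  uniform-perturbation initialization. Crisp partitions are row-wise argmax
  with ties to the lowest cluster index.
* **CoVAHC** - clustering of *variables* followed by Ward AHC of the herds
  on the synthetic-variable scores. Variable groups are merged
  agglomeratively, always taking the pair whose merge loses the least
  homogeneity. Homogeneity is the sum of squared Pearson correlations
  (quantitative members) and correlation ratios (qualitative members) with
  the group's synthetic variable - the first principal component of the
  mixed-data matrix built from population-standardized quantitative columns
  and centered level indicators scaled by 1/sqrt(level frequency). With
  that scaling the homogeneity equals the leading eigenvalue of the group's
  matrix, which is what the merge search evaluates; the score/eigenvalue
  identity is asserted in tests against a direct ANOVA/correlation
  computation. The synthetic-variable sign is fixed so the loading on the
  group's first column is nonnegative. Ordinal variables enter as ranks,
  binary variables as two-level qualitatives; missing values are mean/mode
  imputed with a warning (the merge search needs a complete matrix).

**Number of synthetic variables.** Homogeneity losses grow along any nested
merge sequence, so "stop before the largest drop" degenerates to retaining
two clusters for every dataset. The default is instead the Kaiser-Guttman
rule on the full mixed-data PCA - retain as many synthetic variables as
there are eigenvalues above the average eigenvalue. In simulations with a
planted cluster structure this recovers the true dimensionality of the
cluster-mean space; the value is overridable by argument.

### Model selection by average silhouette width

For every method and k = 2..10 the partition is scored by the average
silhouette width s(i) = (b(i) - a(i)) / max(a(i), b(i)), singleton clusters
scoring 0 by convention; k = 1 and k = n give an all-zero report with a
warning. All four methods - including CoVAHC - are scored **on the Gower
matrix**, so the argmax over the whole method x k table compares like with
like. CoVAHC silhouettes in its own synthetic-score geometry are reported
in an extra `covahc_scores` row but never used for selection, for two
reasons: the values are not on the Gower scale, and principal-component
scores systematically understate the isolation of very small clusters (a
singleton's separating direction carries ~1/n of the total variance), which
biases score-space selection against partitions that isolate them. Ties in
the argmax go to the smaller k (parsimony), then to method order. A method
failing at some k leaves that cell missing instead of crashing the sweep.
Herds with strictly negative silhouette are reported as misclassified,
worst first.

## Stage 2 - trait comparison and genetic evaluation

### Mixed-model engine

All models run through one Henderson mixed-model-equations engine:
y = Xb + sum Z_j u_j + e with u_j ~ N(0, sigma_j^2 G_j), G_j the identity
or a pedigree relationship matrix given by its sparse inverse, and
R = sigma_e^2 diag(1/w) (weights are used only by the quasi-likelihood
working variates). Fixed designs use treatment coding; columns that remain
linearly dependent are detected by order-preserving QR rank detection (the
intercept and leading factors always win over later aliases), removed with
a warning naming them, and the null-space basis of the full design is kept
so least-squares means can test estimability exactly.

Random terms whose coefficient block is diagonal (iid, one level per
record - permanent environment, the iid animal term of the trait models,
service sire) are absorbed analytically; only the largest such term is
absorbed because two overlapping terms have non-diagonal cross-products.
The remaining dense system (fixed effects plus pedigree-structured terms)
is solved by Cholesky factorization, and the diagonal of the inverse
coefficient matrix - needed for EM traces, prediction error variances and
standard errors - is recovered from the same factorization. The dense
inverse bounds the practical scale at roughly 10^4 non-absorbed equations.

Variance components are estimated by EM-REML with the classical updates
sigma_j^2 <- (u_j' G_j^-1 u_j + sigma_e^2 tr(G_j^-1 C^jj)) / q_j and
sigma_e^2 <- (y'y - sol'rhs)/(n - rank X), which keep the restricted
likelihood nondecreasing. Because plain EM is notoriously slow for the
additive-genetic component, each EM step is extrapolated along the update
direction with an adaptive step length and the extrapolation is kept only
when the restricted likelihood does not drop (guarded over-relaxation), so
monotonicity is preserved either way; convergence is judged on the size of
the *plain* EM step (default relative tolerance 1e-6, configurable).
Components collapsing to zero are floored at 1e-8 x var(y) with a warning.
The engine reproduces statsmodels MixedLM REML estimates to ~5 significant
digits on random-intercept data (asserted in tests).

### Trait models

Test-day traits: y = mu + breed + year-season of calving + lactation + HC
+ f(DIM) + b*CA + animal + e, with f a fixed third-order Legendre
regression on days in milk standardized from the DIM window (default
5-365 d; values outside are clamped with a warning) and an *independent*
random animal effect (no pedigree - the pedigree enters only in the
genetic evaluation). Calving seasons are Dec-Feb / Mar-May / Jun-Aug /
Sep-Nov, December counting toward the following year's winter. SCS =
log2(SCC / 100,000) + 3.

Fertility traits: CFI (calving to first insemination, days) is Gaussian
with fixed breed, insemination month, lactation, HC, semen type and an age
covariate, plus random animal and random service sire; sires with a single
record are retained and shrunken, never dropped. SFI (first-insemination
success, 0/1) uses the same design with a logit link fitted by penalized
quasi-likelihood: working variates z = eta + (y - mu)/(mu(1-mu)) with
weights mu(1-mu) are iterated around the linear solver, the working
residual variance fixed at 1. PQL is known to bias variance components
toward zero for small clusters; full Laplace/adaptive quadrature is out of
scope. Herd clusters whose binary outcomes are constant are complete
separations on the link scale; they are detected and reported, not
silently estimated.

Least-squares means are marginal means over an equal-weight reference grid
of all fixed factors with covariates at their observed means. Levels whose
reference row is not orthogonal to the design null space are flagged
non-estimable, not imputed. Pairwise comparisons are unadjusted Student's
t tests at alpha = 0.05 with a compact letter display (maximal runs of
mutually non-significant levels in estimate order); a Tukey studentized-
range adjustment is available but off by default, matching the common
reporting convention for such tables.

### Genetic evaluation

The repeatability test-day model y = mu + breed + year-season + lactation
+ CG + f(DIM) + b*CA + a + pe + e is solved with a ~ N(0, sigma_a^2 A)
via Henderson's A-inverse rules with inbreeding from the Meuwissen-Luo
recursion (verified against the tabular method in tests), and pe the cow
permanent environment. CG schemes: HTD (herd x test day), HCTD (cluster x
test day), HTM (herd x calendar test month), HCTM (cluster x test month).
Groups below the minimum size (default 3 records) are handled by a policy:
`drop` (default) removes their records, `merge` pools them with the
time-adjacent group of the same unit, `keep` leaves them. Both the number
of generated groups and the number retained after the policy are reported;
the coarsening identity #HCTD <= #HTD holds for the generated counts.

Reliability is r^2 = 1 - PEV / sigma_a^2 with PEV from the inverse
coefficient matrix; an optional flag divides by (1 + F_i) sigma_a^2
instead. "Sires with daughter records" are sires with at least one
daughter holding at least one retained record. The scheme comparison
re-estimates variance components per scheme by default (heritability
differences between schemes are part of the phenomenon), with an optional
common-vc mode for design-only comparisons; h^2 standard errors, when
requested, come from the numerically differentiated curvature of the
restricted likelihood with a delta-method transform.

## Synthetic data

The generators are the package's study conditions; every generator is
seed-deterministic and returns the planted truth next to the data.

* **Survey**: default 30 herds in 4 clusters of sizes 13/5/1/11, 23
  quantitative + 83 qualitative informative variables, plus 3 + 8 planted
  removable columns (constants, exact duplicates, dominant levels) so the
  editing step's 117 -> 106 contract is exercised. Cluster separation is
  symmetric by construction: qualitative preferred levels are spread over
  clusters as evenly as the level count allows, and quantitative
  cluster-mean patterns are random permutations of an equally spaced grid
  with jitter, scaled so the between:within variance ratio equals the
  qualitative tilt odds - one separation parameter (default 3.0, i.e.
  within-cluster agreement ~0.75-0.9 per variable) with the same meaning
  for both variable kinds. What this does **not** emulate: real surveys
  have blockwise-correlated variables, systematically missing answers, and
  clusters of very unequal tightness; passing recovery tests therefore
  show correctness of the machinery under clean planted structure, not
  field performance.
* **Pedigree**: paternal half-sib families (founder sires, unknown dams);
  daughter BV = sire BV / 2 + Mendelian sampling N(0, 3/4 sigma_a^2). Only
  two generations - deliberate, since sigma_a/sigma_pe separation needs
  families, not depth.
* **Test-day records**: one recording day per herd per month; each cow's
  records follow her herd's schedule at ~2-month DIM spacing through a
  third-order Legendre lactation curve. The CG environment is cluster x
  test-month (SD 2.0 kg) plus herd x test-day (SD 0.5 kg): the
  cluster-shared component is the explicit mechanism by which herd-cluster
  CGs outperform herd CGs when herds are sparse, and both SDs are
  configurable. Default variances sigma_a^2 = 3, sigma_pe^2 = 2,
  sigma_e^2 = 5 (h^2 = 0.30, repeatability = 0.50). Breed is assigned per
  cow (90/10 mixture by cluster) so the breed effect stays estimable next
  to the CG effects.
* **Fertility**: per-cluster shifts on CFI (days) and on the SFI logit;
  ~35% of cows contribute a second lactation record, which is what
  separates the cow effect from the residual.

## Problem sizes used in the validation suite

Oracle-equivalence checks run on 100+ random instances (n <= 8 for
exhaustive PAM, n <= 30 for silhouettes, n = 7 for Ward, pedigrees <= 50
animals). Planted-structure recovery uses 50 survey seeds at the default
default survey shape. Parameter recovery runs 20 seeds of 1000 cows x 5 records in
10 herds (the CG count, not the cow count, dominates the dense solve);
EM-REML is stopped at a relative tolerance of 3e-4 or 40 iterations there,
which changes h^2 by well under 0.01 relative to full convergence. The
directional CG comparison uses 15 sires x 20 daughters over 25 herds,
giving a median of ~3 records per herd-test-day, and evaluates both
schemes at the true variance components so the comparison isolates the CG
design.

## Known limitations

* PEV and EM traces use dense factorizations: fine to ~10^4 non-absorbed
  equations, not for national evaluations.
* PQL for SFI carries the usual downward variance bias; LSM letters for
  SFI are on the logit scale (a response-scale column is provided).
* The fuzzy solver finds a local optimum of a non-convex objective; the
  damped updates guarantee monotonicity, not global optimality (checked
  against 1000 random feasible memberships in tests).
* ASW-based selection of k cannot reliably reward clusters of size 1 (their
  silhouette is 0 by convention); with the default 13/5/1/11 shape the
  sweep still selects k = 4 in >= 90% of seeds, but the margin over k = 3
  is structurally small.
* No imputation, no variable-type inference, no genomic terms, no
  random-regression (the DIM curve is a fixed regression).
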