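# Methods

This note documents the statistical machinery in `permapart`, the design
choices taken where the methodology is genuinely open, and what the
simulation-based tests do and do not establish.

## Distance model and sequential decomposition

The engine (`permapart.permanova`) operates on a symmetric dissimilarity
matrix D.  Gower centering, A = −D∘D/2, G = (I − 11ᵀ/n) A (I − 11ᵀ/n),
yields an inner-product matrix whose trace equals the total sum of squares
(1/n) Σ_{i<j} d²ᵢⱼ.  The design matrix is assembled term by term in
declared order — intercept, then technical confounders, then candidates —
with treatment coding against a declared reference level for categoricals,
raw values for numeric variables, and elementwise products of the parent
blocks for two-way interactions.  A sequentially grown orthonormal basis
(modified Gram–Schmidt, two passes, relative tolerance 1e-8) spans the
cumulative designs; columns aliased by earlier terms drop out, reducing the
term's degrees of freedom (a fully aliased term is reported with df 0, not
an error).  Term k's sequential (Type I) SS is the increment in tr(H G)
between cumulative projectors, the residual SS is tr(G) minus the full
model's share, and pseudo-F uses the full-model residual mean square.
Marginal (Type III) tests are deliberately out of scope.

Inference is by unrestricted joint row/column permutation of the distance
matrix, recomputing every term's F per permutation, with the +1/+1
convention p = (1 + #{F* ≥ F_obs})/(1 + B); B defaults to 999 and the seed
is recorded in every result.  An explicit permutation array can be supplied
instead, which the tests use for exact enumeration at n ≤ 7.  For
longitudinal pooled models the repeated measures violate exchangeability;
the pooled model is still fitted with free permutation (the R² partition is
unaffected; permutation p-values there should be read descriptively).  This
is a documented limitation, not a bug.

`aicc` scores a model as 2k + n·ln(RSS/n) + 2k(k+1)/(n−k−1), where k counts
retained design columns including the intercept and RSS is the distance
model's residual SS.  A variant in which the sample-size term enters
additively (2k + n + ln(RSS/n) + …) is available behind `literal=True`;
it is nearly insensitive to fit quality and is retained only for
comparison, never for selection.  Backward elimination evaluates every
currently droppable candidate (interactions before their main effects — a
main is frozen while an interaction references it), accepts the single best
removal only if it improves AICc by ≥ 2, and stops otherwise.  Ties go to
the larger-df term, then lexicographic order.  Permutation p-values are
computed for the final model only; the trace stores (terms, k, n, RSS,
AICc) per step and can be replayed exactly.

A consequence of the ≥ 2-unit rule worth knowing: removing a 1-df null term
buys only ≈ 2 + Δcorrection − χ²₁ units in expectation, so binary null
covariates are frequently *retained*; multi-level null factors (≥ 5 df)
are reliably eliminated.  The selection-recovery experiments therefore use
multi-level nulls, which is also the realistic case (plates, extractors,
centres).

## Dispersion, batch similarity, dyads

`permdisp` follows the centroid-based homogeneity-of-dispersion procedure:
a full principal-coordinates decomposition of G (all axes retained), with
each sample's squared distance to its group centroid computed as the
positive-eigenvalue contribution minus the negative-eigenvalue contribution
(Bray–Curtis is non-Euclidean), floored at zero before the square root.
Groups with a single member are dropped with a warning; an all-degenerate
configuration reports F = NaN, p = 1.  The one-way F on the centroid
distances is tested by permuting group labels over the fixed distances.

`within_batch_similarity_test` compares within-batch vs between-batch
pairwise community distances in a stratum by unpaired Wilcoxon rank-sum
(two-sided by default).  `family_dyad_analysis` compares each infant's
distance to its own parent against its distances to all other families'
same-role parents.  Both tests use overlapping pairs, so their p-values
inherit the usual dependence caveat of pairwise-distance Wilcoxon tests;
under simulation the dyad test is conservative (null false-positive rate at
or below nominal), which the acceptance tests verify.

## Community metrics

Bray–Curtis is computed on proportions (columns summing to 1), where
1 − Σ min equals the two-term form 1 − 2C/(S₁+S₂); a count-space variant
(`on="counts"`) applies the two-term form to raw counts and differs when
depths differ.  The abundance-based (quantitative) convention is used
throughout: a presence-based reading of the denominator would collapse the
measure to Sørensen and contradict the abundance-based numerator.
Aitchison distance is Euclidean distance between centered-log-ratio vectors
of counts + pseudocount (default 1); Pearson distance is 1 − r across taxa.

Alpha diversity is computed after a single rarefaction draw (multivariate
hypergeometric, i.e. subsampling without replacement) to the minimum sample
depth, seed recorded.  Shannon uses natural logs over nonzero proportions;
Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined even
when no doubletons exist; Pielou is H/ln S_obs, reported missing when
S_obs < 2; rarity is the sample skewness (third standardised moment with
an unbiased-variance denominator) of ln(1+x) over all taxa including
zeros — a clean, documented definition chosen in place of upstream
packages' quantile-trimmed variants.

## QC and metadata conventions

Depth filtering removes samples below 3000 reads at the 3w/6w/3m
timepoints and below 5000 reads later (strict <); it runs before the
unknown-annotation filter by default (order configurable; the two filters
commute except for samples failing both).  Samples whose unknown-annotation
read fraction strictly exceeds 20% are excluded, computed before the
unknown rows are removed.  Variable screening marks — never deletes —
categorical variables where all but one level has < 10 samples within a
(role, timepoint) scope, and variables with > 75% missingness there.  All
boundary rules are strict inequalities, matching their verbal definitions.
Missing values are NaN/None, never 0.  The three-class delivery variable
{CS+AB, VD+AB, VD−AB} is derived from birth mode and intrapartum
antibiotic exposure; a Caesarean record without antibiotics is rejected as
impossible in this cohort design.

## Differential abundance

Per prevalent taxon (> 10% of samples, strict), the cascade fits
count ~ covariate (+ adjustment) with log processed reads as offset:
negative binomial (MLE dispersion) first; Poisson when the NB optimiser
fails or its dispersion sits at a boundary (α outside [1e-6, 1e4]);
quasi-Poisson (Pearson-scaled standard errors) when the Poisson Pearson
χ²/df exceeds 1.5; otherwise ordinary least squares on ln(relative
abundance + half the taxon's minimum nonzero relative abundance).  These
fallback thresholds are this package's declared defaults — the upstream
tooling this mirrors does not publish its exact triggers.  p-values are
Wald against the normal reference; BH-FDR is applied across taxa within
one covariate contrast, and significance is p < 0.05 AND q < 0.1.  The
offset is the declared `reads` metadata variable when present, else the
table's column sums — relevant when testing a taxon subset, where subset
column sums would correlate with the effect under test.

## The synthetic cohort generator

`simulate_cohort` draws, per subject × retained visit, taxon log-abundances
baseline(taxon, age) + subject intercept + family intercept + planted
covariate effects + batch effect, softmaxes to proportions, perturbs with a
Dirichlet (concentration 60 by default; smaller = more compositional
noise), and draws a multinomial at a log-normal depth (median 16.8k reads,
σ = 0.45).  The baseline holds 12 named genera with early/late/adult
log-abundance anchors interpolated on log-age (Bifidobacterium-dominant
early, Bacteroides/Faecalibacterium rising, a distinct adult profile for
parents) plus randomly drawn filler genera.  Cohort-shape defaults follow a
large published birth cohort: 8 infant timepoints (3w–24m) with 25%
missing visits (~6 samples/infant), C-section rate 0.163 with intrapartum
antibiotics always present at CS and in 23.3% of vaginal deliveries, 49%
first-borns, parity vs older-siblings indicator collinear up to a 2% flip,
age-dependent defecation frequency and stool consistency, mother/father
spot-sample inclusion 0.73/0.57, and extraction batches of ~78 samples
assigned in collection order (so batch, platform and extractor are
interlinked with age, as in real logistics).  Batch effects are
multiplicative log-normal shifts on a random 20% taxon subset per batch.
All randomness flows through named substreams (profile, covariates, visits,
composition, depths, batch) spawned from one seed, so cohorts are
bit-reproducible.

Planted effects come in tiers none/small/medium/large with log-fold-changes
0 / 0.5 / 0.9 / 1.1 applied to disjoint trajectory-balanced taxon triples;
these magnitudes were fixed once by Monte-Carlo calibration with
`expected_r2` (a noise-free-depth simulation run through the engine) so
the induced Bray–Curtis R² lands near 0.5% / 2% / 6%.  The frozen
reference (`tests/data/expected_r2_reference.json`, regenerated by
`scripts/make_fixtures.py`) stores per-(tier, timepoint) means over five
seeds with a 4·SD tolerance band.  Note that a null binary covariate's
recovered R² floor is ≈ 1/(n−1), so "none" reads ~0.4–0.5% at n ≈ 225; the
tiers are separated well beyond that floor.

What the generator does *not* emulate: phylogenetic structure, sequence-
level artefacts, zero-inflation beyond what the DM model produces,
covariate effects on parents, within-subject temporal autocorrelation
beyond a static subject intercept (its scale is a free parameter, default
0.7), and real cohorts' unmeasured confounding.  Passing the simulation
suite therefore demonstrates the *methods* behave as specified (calibrated
type-I error, unbiased recovery, correct orderings), not that any specific
biological finding in real data would replicate.

## Problem sizes and numerical choices

The test and acceptance workloads use cohorts of 100–400 families,
B = 199–299 permutations, and 10–100 simulation replicates per check —
sizes at which the Monte-Carlo bands in the assertions are comfortably
wider than the sampling noise.  Aliasing tolerance is 1e-8 (relative);
distance symmetry tolerance 1e-12; Bray–Curtis values are clipped to
[0, 1] against rounding; permutation-F comparisons use a 1e-12 slack so
ties count as exceedances.  The pipeline writes distances at 17
significant digits (exact round-trip), records the config hash and seed in
every manifest, and reruns byte-identically.

## Known limitations

- Sequential SS only; no marginal tests, no restricted permutation blocks.
- The pooled longitudinal model's permutation p ignores repeated-measures
  structure (documented above).
- Dyad and batch-similarity Wilcoxon tests use dependent pairs
  (conservative in simulation, but not exact).
- The DA cascade's fallback thresholds are pragmatic defaults; taxa are
  fit independently (no longitudinal or compositional DA).
- `run_full` stages exchange data through written files but also cache in
  memory within one run; per-stage resumption re-reads only the files.
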