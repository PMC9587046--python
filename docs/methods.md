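# Methods

This note documents the statistical procedures `msgnet` implements, the
conventions it fixes where the field's practice varies, what the synthetic
generator does and does not emulate, and the problem sizes the shipped tests
and the acceptance script use.

## Units of analysis

A *sighting* is a single-species detection (location in planar metres, date,
individual count, one of four habitat classes: grassland, open bushland,
bushland, riverine). An *animal group* is a set of sightings chained by
pairwise distances ≤ 50 m (single linkage over one survey occasion); it is a
*mixed-species group* (MSG) when it holds ≥ 2 distinct species. Group
habitat is the modal member habitat with ties broken by the fixed habitat
ordering; the group location is the unweighted centroid. A
complete-linkage-style `clique` rule is available as a sensitivity switch.
Every group record is treated as independent; no deduplication of repeat
encounters beyond the caller's per-occasion partitioning is attempted.

## Scenario classification

* **Lion home range (LHR).** Minimum convex polygon at an isopleth
  (default 0.85): the ⌈(1 − isopleth)·n⌉ points farthest from the arithmetic
  mean centre are discarded (ties keep the earlier point; an epsilon guards
  binary-representation error in `1 − isopleth`), then the convex hull of
  the remainder is taken. Distance from the *mean* centre is the most common
  convention in home-range software, and isopleth 1.0 degrades exactly to
  the full convex hull. Group centroids on the polygon boundary count as
  inside.
* **NDVI tertiles.** Group-level NDVI values are split at their empirical
  1/3 and 2/3 quantiles (type-7 linear interpolation) into small / medium /
  large classes; values exactly on a boundary fall to the lower class. This
  yields three equal-sized classes (±2) whenever values are distinct. A
  fully degenerate distribution (all values equal) is an error, not a
  silent single class. Binning is at the group level, the unit of every
  downstream analysis.
* **Core/edge zone.** A group is `core` when its centroid lies inside the
  study boundary polygon and more than 2 km (configurable) from its
  outline, else `edge` — a proxy for human activity, which concentrates at
  the periphery.

## MSG-occurrence regression

Group type (MSG = 1) is modelled with a maximum-likelihood logit (Newton /
IRLS, convergence 1e-8) on treatment-coded factors with fixed reference
levels: habitat *bushland*, NDVI *medium*, LHR *outside*, zone *edge*.
Effects are reported as odds ratios with Wald 95% intervals — symmetric on
the log scale, matching how such intervals are conventionally printed —
and raw two-sided normal p-values; no multiple-testing correction is
applied across terms or species. Species-specific models restrict the units
to groups containing the focal species and by default drop the zone term
(null at the community level); a flag restores it. Zero-variance factors
and separation raise errors naming the term rather than returning huge
unstable estimates. Collinearity among the four factors is screened with
Cramér's V (Pearson chi-square without continuity correction; zero-margin
levels dropped with a warning).

## Association networks

Edge weights use Dice's index `w_ij = 2 N_ij / (N_i + N_j)` over the groups
of one scenario (five scenarios: inside/outside LHR, three NDVI classes),
on the node set of species present in *every* scenario so that networks are
comparable. Node measures:

* strength `s_i = Σ_j w_ij`;
* Y-measure (disparity) `Y_i = Σ_j (w_ij / s_i)²`, minimised at `1/k_i`
  for evenly spread associations;
* weighted clustering coefficient, default Barrat form
  `c_i = [1/(s_i (k_i−1))] Σ_{j≠h} ((w_ij + w_ih)/2) a_ij a_ih a_jh` with
  binary adjacency `a`; a geometric-mean (Opsahl-style) variant is a config
  switch, and outputs name the variant. The comparison logic is
  variant-agnostic.

Isolated nodes yield missing Y and clustering; single-neighbour nodes
missing clustering (an open triplet's clustering is 0, not missing).

**Scenario comparison.** The larger scenario is first downsampled uniformly
to the size of the smaller, each side is partitioned into k = 3 disjoint,
exhaustive random replicates, each replicate's network yields the mean of
each measure over the six focal species (giraffe, zebra, wildebeest,
Grant's gazelle, impala, Thomson's gazelle; configurable), and the 3-vs-3
aggregated values are tested with a two-tailed Welch t on natural logs
(the base cancels in t). The tiny per-side n is inherent to the 3-replicate
design. The log transform is backed by `check_lognormality`, which samples
margin-matched random matrices from the checkerboard chain — this package's
choice of "random networks with the same characteristics", recorded in the
report header — and Shapiro-Wilk-tests the log aggregated measures.
Aggregated values ≤ 0 make the log undefined and raise an error naming the
replicates; elementwise-identical samples return t = 0, p = 1 by
convention (the Welch statistic is 0/0 there).

DOT export draws an edge only when `w ≥ 0.05` and the pair co-occurred at
least twice, sizes node areas by occurrence counts, and styles
highlighted edges (significant vs habitat-explainable); filtering affects
display only, never analysis.

## Fixed-margin randomisation tests

The null model for dyadic association holds all binary group×species
matrices with the observed row and column sums equally likely; the
habitat-stratified variant additionally fixes each species' per-habitat
totals, so it asks whether a pair co-occurs more than expected *given*
where each species occurs. The chain move is the checkerboard swap: two
rows and two columns drawn uniformly, the 2×2 submatrix flipped iff it is a
checkerboard; in stratified mode proposals spanning two strata are
rejected, which preserves per-stratum column sums. "Steps" are swap
*attempts* — at these matrix sizes the classical 10⁷-step budget is only
feasible as attempts — and the realised acceptance rate is reported so
users can gauge effective mixing. Default schedule: burn-in 10⁵ attempts,
thinning 10³, 10⁴ samples (≈1.01·10⁷ attempts); a serial variant (observed
state counted as the first sample, no burn-in) is available behind a flag.
Both schedules are validated against an exact depth-first enumeration of
the null space on guard-sized instances (≤ 20 cells, or ≤ 5000 matrices;
stratified instances enumerate per-stratum blocks and convolve).

The test statistic is the pair's co-occurrence count — equivalent to Dice's
index under fixed margins — with the one-sided upper-tail add-one estimator
`p = (1 + #{samples ≥ observed}) / (n_samples + 1)`, which can never be 0
and matches the question "more often together than chance explains". Only
pairs co-occurring more than twice are tested (rarer pairs are skipped, not
errors), by default among the ten most frequently encountered species; no
correction across pairs is applied. A matrix with no successful swap during
burn-in is flagged frozen (all p = 1) with a warning.

## Assortative mixing

Pair-level similarity covariates from the species attribute table:
`sim_prey = −|J_i − J_j|` (Jacobs' lion prey-preference index, range of the
covariate [−2, 0]) and `sim_diet = −|m_i − m_j|` (dietary monocot
proportion, [−1, 0]); higher means more similar, and only differences
enter, so the fit is invariant to location shifts of either attribute. The
response is the Dice weight of every pair among attribute-complete species
— zeros retained, they are informative — modelled with a logit link by
maximising the Bernoulli-form quasi-likelihood (fractional responses
permitted; for 0/1 data this is ordinary logistic regression, and the
in-house IRLS fitter is unit-tested against an independent GLM
implementation). Both covariates enter one joint model by default;
single-covariate fits are a sensitivity flag. Inference does not use the
quasi-likelihood variance at all: significance comes from node-label
permutation (default 10⁴ shuffles of the species→attribute assignment,
covariates recomputed, model refitted), one-tailed with the add-one
estimator — a coefficient is significant when the observed value sits in
the top 5% of its permutation distribution. Point estimates are
deterministic; only p-values carry Monte-Carlo error. More than 1%
non-converging permutation fits aborts with diagnostics.

## Synthetic generator

The generator emulates the *statistical* structure of a rainy-season
ground survey on a 183 km² ranch — not animal movement. Defaults are the
study conditions: 951 groups; a 15-species pool with relative abundances
proportional to the reference per-species sighting counts (the three
species absent from some scenario are excluded from the pool); habitat
preference weights encoding the familiar grazer/browser/riverine split;
planted pairwise affinities mirroring the observed strong dyads
(zebra–wildebeest 1.8, Thomson's–Grant's 2.8, moderate giraffe and impala
ties); scenario odds ratios equal to the community-level estimates (LHR
1.69, small NDVI 1.82, large NDVI 1.64); and a baseline joining log-odds of
−4.55, calibrated so a default run reproduces the survey regime (~1.3
species per group, ≈1250–1300 sightings from 951 groups, MSG fraction
≈ 0.30).

Mechanics: group locations are uniform over the square landscape (optionally
with a minimum spacing, via grid-hashed rejection); NDVI and a "bushiness"
surface are fixed sums of Gaussian bumps whose spatial scale is kept well
below the home-range scale so scenario covariates are only moderately
collinear (pairwise Cramér's V ≈ 0.17–0.32 at study scale, matching the
moderate regime of such surveys); riverine habitat is a 350-m corridor; the
true home range is a convex hexagon touching one boundary (≈ one third of
the area). Each group draws a seed species (abundance × habitat weight at
its location), then every other species joins independently with
probability `logistic(α_j + a_seed,j + δ)`.

The scenario term δ is solved per group (vectorised bisection) so that
`logit P(MSG)` shifts by exactly the group's total planted β relative to
its baseline — i.e. the planted β *is* the group-level log odds ratio the
MSG regression estimates. Applying β directly to each species' joining
log-odds (available as `scenario_scale="joining"`) would inflate the
group-level odds ratio through the saturation of P(at least one joiner),
making "planted log 2" unrecoverable as 2 by any regression; defining the
plant on the estimand's own scale keeps parameter-recovery tests meaningful.
Sightings are exploded per member species with < 24 m jitter around the
centroid, so 50-m chaining recovers the planted grouping exactly whenever
centroids are > ~100 m apart. Individual counts (1 + Poisson) are carried
but never used by the matrix/network machinery, which is presence/absence
throughout.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: spatial point-process clustering of groups,
temporal autocorrelation and route structure, detection error,
distance-dependent detectability, within-season abundance drift, and
attribute-driven (Jacobs/diet) assortment unless explicitly planted. Lion
points are uniform in the true polygon with ~10% boundary excursions, a
caricature adequate only for exercising the MCP estimator.

## Numerical conventions and edge cases

* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; same seed, same platform-independent output.
* Dice weights with `N_i + N_j = 0` are 0; the weight matrix is validated
  symmetric in [0, 1] with zero diagonal.
* Occurrence-matrix rows containing none of the requested species are
  dropped (they carry no pairwise information and would break the
  row-sum ≥ 1 invariant).
* The logit fitters stop at step-size 1e-8 (MSG model) / 1e-10
  (assortment IRLS); the assortment working weights are floored at 1e-10.
* Quantiles are type-7 everywhere; boundary values fall to the lower class.
* Species identifiers are case-insensitive slugs; attribute joins fail
  loudly on mismatch.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run everything at sizes chosen
to make their Monte-Carlo error small relative to the asserted margins:
chain-vs-enumeration agreement at 10⁵ samples on ≤ 20-cell matrices (±0.02
on p); margin conservation over 10⁶ swap attempts on the 951×15 matrix;
type-I error of the dyadic test over 500 generator-null surveys (nominal
5%, accepted band 3–7%); power over 100 surveys with a planted affinity of
3 (≥ 80% detection) and 100 habitat-confounded surveys (unstratified
significant, stratified not, in the majority); MSG-regression coverage over
100 surveys of 1000 groups with planted odds ratio 2 (≥ 90% CI coverage);
assortment permutation validity over 500 shuffled-attribute networks
(3–7% rejection). The acceptance script runs one full 951-group pipeline
with 2×10³-sample dyad chains and 10⁴ assortment permutations.
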