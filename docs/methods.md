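# Methods

`salinet` reimplements, as a tested pipeline, the statistical workflow used
to study how lake bacterial communities respond to a salinity gradient:
diversity and core-community description, multivariate tests of
community–environment association, a phylogenetic null model for assembly
processes, Levins niche breadth, and ensemble co-occurrence network
inference with graph-null significance testing.  Because the original
sequencing data are not consumed here, every stage is exercised on a
synthetic community generator whose ground truth makes the statistical
behaviour of each method checkable.

## The synthetic community generator

The generator produces an OTU count table, a matching environmental table,
a phylogeny, and a ground-truth record, with the statistical structure the
downstream analyses assume.

**Design.** The default sampling design mirrors a four-lake gradient:
16/13/8/8 samples at salinities 0.47/0.74/2.48/6.22 permille.  Nutrient
covariates (TN, TP, NH4-N, DOC, COD) rise monotonically with salinity with
log-normal scatter (sigma 0.35 on the log scale) so that salinity and
nutrients are correlated but distinguishable, as in eutrophying saline
lakes; water depth, temperature and dissolved oxygen are uninformative.

**Phylogeny.** A pure-birth (Yule) tree (dendropy's constant-rate
birth–death sampler with death rate 0), tips relabelled `OTU_0001…` and
branch lengths rescaled to unit root-to-tip height so that evolutionary
rates are expressed per total tree depth.

**Niches.** Each taxon carries a Gaussian salinity response
`exp(-g(s) (s - mu_i)^2 / (2 sigma_i^2))`.  Optima `mu_i` evolve along the
tree by Brownian motion.  Two refinements matter:

* *Early-burst rates.*  With rate-constant Brownian motion on a Yule tree,
  sibling tips differ in optimum by nearly as much as the whole-pool
  spread divided by ~2, so whenever the pool spans the gradient the
  sigma ≈ 0.3 permille selection window cuts *across* terminal clades and
  the selected set is never phylogenetically tight — the phylogenetic
  turnover statistics then have no signal to find, at any sample size.
  The generator therefore uses the early-burst (ACDC) variant: the
  Brownian rate decays as `exp(-a t)` with depth `t` (default `a = 6`),
  concentrating niche divergence on deep branches.  Ecologically this is
  deep conservatism of salinity preference — fresh/saline transitions are
  rare, clade-level events — which is also the empirically supported model
  for this trait in bacteria.
* *Pool-spread conditioning.*  Under early-burst rates the realised spread
  of tip optima is dominated by a few deep branches and varies severalfold
  between trees.  A pool sampled along a salinity gradient contains taxa
  adapted across it by construction, so the generator optionally rescales
  tip deviations to a fixed standard deviation (default 2.5 permille around
  the root optimum), leaving the phylogenetic correlation structure
  untouched.

Tolerances `sigma_i` are log-normal (default median 0.35, log-sd 0.5 in the
demonstration configuration), giving a specialist–generalist continuum;
baselines `b_i` are normal.  The harshness factor `g(s) = s/(s + K)`
(half-saturation `K = 3` permille by default, disabled when `K` is unset)
makes filtering weak in fresh water and sharp in brine, the osmotic-stress
asymmetry that produces the observed gradient-wise patterns: diversity and
community niche breadth falling with salinity, and selection strongest in
the most saline lakes.

**Counts.**  Per sample, expected relative abundances are the product of
baseline, niche filter and log-normal noise (`noise_sd` on the log scale);
counts are multinomial at a uniform-random depth in `depth_range`.
Planted associations inject correlation `rho` into the standard-normal
latents of chosen taxon pairs (a Gaussian copula; pairs are disjoint so the
draw factorises into 2x2 blocks).  Acting on the log-scale latents, rather
than on counts, means compositional closure attenuates but does not erase
the planted signal.  Under niche filtering, pairs are planted among the
broad-tolerance third of the pool, because only taxa that co-occur across
the gradient can carry an association observable after the occupancy
filter.

**Named scenarios.**  Three frozen configurations define the benchmark
conditions used throughout the tests:

| scenario | purpose | key settings |
|---|---|---|
| `neutral_scenario` | null calibration | 100 taxa, 20 samples, no niche term, depths 1,000–2,000 |
| `selection_scenario` | homogeneous-selection positive control | 800 taxa, 2x10 samples at 0.5 and 6.0 permille, sigma = 0.3, early-burst conserved optima, depths 1,500–3,000 |
| `association_scenario` | network benchmarking | 60 taxa, 45 samples, flat environment and flat baselines, optional planted pairs, depths 5,000–10,000 |

The selection scenario needs a large pool (800 taxa) because the
standardised effect size of nearest-taxon turnover grows with per-sample
richness and with the number of taxa exclusive to one of the two
communities; at ~100 taxa the within-group median sits near -1.3 no matter
how strong the filtering.  The association scenario uses flat baselines so
that the planted pairs are the *only* real associations: with heavy-tailed
abundances, compositional closure induces genuine secondary correlations
and precision against the planted truth becomes ill-defined.  Within-group
salinity is constant: at sigma = 0.3 even modest within-lake salinity
scatter flips the within-group signal from homogeneous to *variable*
selection (different samples select different clades).

**What the generator does not emulate.**  Sequencing error, chimeras and
OTU-clustering artefacts; dispersal limitation and spatial structure;
temporal dynamics; true interaction dynamics (planted associations are
statistical, not mechanistic); absolute-abundance variation (totals are
multinomial depths).  Passing tests therefore show that the *statistics*
behave correctly under their assumptions, not that real lake data satisfy
those assumptions.

## Diversity and niche breadth

Rarefaction is a single seeded multivariate-hypergeometric draw per sample
to the minimum sample total (the shallowest-library convention).  Alpha
diversity: richness, Shannon `H = -sum p ln p` (natural log) and
Gini–Simpson `1 - sum p^2` — the Gini–Simpson variant is used because a
*decrease* toward saline lakes then reads as lost diversity.  The core
community at occupancy `c` is the taxa present in at least
`ceil(c * n_samples)` samples.  Bray–Curtis is computed on counts via
`1 - 2 sum min / (sum x + sum y)`.  Levins niche breadth
`B_j = 1 / sum_h P_jh^2` uses the individual sample as the habitat unit,
with `P_jh` the fraction of taxon j's total found in sample h; the
community value is the unweighted mean of `B_j` over taxa present in the
sample.  Whether an abundance-weighted community mean would be preferable
is an open choice; the unweighted mean is the simplest reading of
"average niche breadth of all members".

## Assembly null model

betaMNTD between communities A and B is
`0.5 [ sum_{i in A} f_iA min_{j in B} d(i,j) + sum_{j in B} f_jB min_{i in A} d(i,j) ]`
with `f` relative abundances (weighted mode, the default) or `1/richness`
(unweighted), and `d` cophenetic distances.  A taxon present in both
communities contributes zero.  The weighted mode agrees with
`picante::comdistnt` to machine precision; the unweighted mode differs
from picante by design, which pools nearest-taxon distances over both
communities instead of averaging the two community means.

betaNTI standardises observed betaMNTD against a taxa-shuffle null: tip
labels are permuted across the whole tree and every sample pair is
re-scored against the same shuffled tree, 999 times by default (199 in
test configurations; the standardised effect size does not depend on the
randomisation count beyond Monte-Carlo noise).  Pairs with zero null SD
(e.g. identical communities) are reported as undefined with a warning.
Classification: betaNTI > 2 variable selection, < -2 homogeneous
selection, otherwise (boundaries included) stochastic.

Phylogenetic signal is a Mantel test correlating cophenetic distances with
absolute differences in realised salinity optima (abundance-weighted mean
sample salinity per taxon), permutation p-value with the `(1+b)/(1+m)`
estimator.  This is a documented stand-in for an unspecified original
procedure; it tests exactly the premise the betaNTI interpretation needs
(closely related taxa have similar niches).

## PerMANOVA and the multivariate regression tree

PerMANOVA partitions `SS_total = (1/n) sum_{i<j} d_ij^2` into within- and
between-group components and tests
`F = ((SS_total - SS_within)/(g-1)) / (SS_within/(n-g))` by whole-label
permutation with the `(1+b)/(1+m)` estimator.  On Euclidean distances of
univariate data this pseudo-F equals the classical one-way ANOVA F, which
the tests verify to 1e-9 against `scipy.stats.f_oneway` (and against
scikit-bio's implementation), and the permutation p is checked against
exhaustive enumeration at n = 8.

The MRT is a multivariate regression tree in the De'ath tradition:
recursive binary partitioning of the Hellinger-transformed community
matrix (square-root relative abundances; switchable to raw proportions) on
environmental thresholds, minimising within-node sums of squares about
node centroids.  The split engine is sklearn's multi-output CART, whose
squared-error criterion is exactly that objective and whose thresholds are
midpoints of consecutive observed values.  Tree size is selected by
minimum 10-fold cross-validated relative error over the cost-complexity
pruning path (seeded fold assignment; ties go to the smaller tree — a
parsimony tie-break, not the 1-SE rule, which is reported alongside via
the CV standard error).  Note the CV size selection needs a handful of
samples per fold to prune reliably; the null-pruning behaviour is tested
at n = 30.

## Ensemble co-occurrence networks

The inference follows the ensemble / ReBoot tradition: an 80% occupancy
filter; five association measures on per-sample relative-abundance
profiles — Pearson and Spearman correlations (similarities), Kendall
distance `(1 - tau_b)/2`, Bray–Curtis distance, and symmetrised
Kullback–Leibler divergence (dissimilarities; KL adds pseudocount 1 to
counts and renormalises each taxon's profile); per measure, the 500 top-
and 500 bottom-ranked pairs are candidates and the candidate set is the
union across measures (ties broken lexicographically, so the set is
deterministic).

Edge support per measure: a permutation null that shuffles one taxon's
profile across samples (sides alternate between randomisations), and a
bootstrap over samples giving a 95% percentile CI; an edge–measure whose
permutation-null mean lies inside the bootstrap CI is unstable and
discarded.  The default two-tailed p-value standardises the observed score
by the permutation null's mean and SD and refers it to Student-t with
`n_samples - 2` degrees of freedom.  Two deliberate choices here:

* a parametric tail is necessary at all — the empirical estimator
  `(1+b)/(1+n_perm)` is bounded below by `1/(n_perm+1)`, and with ~1,700
  candidate edges Benjamini–Hochberg can then never accept a handful of
  true edges, at any permutation count (`q >= p_min * m / rank`);
* the t tail rather than a normal — at n = 45 the null of correlation-type
  statistics is t-like, and a normal fit underestimates far-tail p-values
  just enough to leak false accepts through the step-up threshold.

The empirical estimator remains available (`p_method="empirical"`) and is
what the calibration tests exercise.  Per-measure p-values of surviving
measures are merged with Simes (`min_i m p_(i) / i`), edges are accepted at
BH FDR alpha = 0.05 (alpha assumed; the source workflow states BH without a
level), and each edge's sign is a majority vote of surviving measures'
directions — co-presence when a similarity exceeds its null mean or a
dissimilarity falls below it — with exact ties discarded and counted.
Scores are not renormalised after permutation by default; the
compositionality-aware variant is out of scope here.

Directions are taken from the side of the permutation-null mean rather
than from top/bottom rank membership: the two agree for signed
correlations, and the null-mean rule stays well defined for pairs that
enter the candidate set through a different measure and for small
instances where every pair saturates both rank lists.

## Topology and graph nulls

Metrics on the unsigned skeleton: average degree `2E/N`, density
`2E/(N(N-1))`, average path distance (mean unweighted shortest-path length
over the largest connected component), and modularity from networkx's
deterministic greedy (Clauset–Newman–Moore) agglomeration; sign fractions
are reported separately.  Significance uses G(n, m) Erdős–Rényi graphs
with the observed node and edge counts (not G(n, p), since the reference
procedure fixes both counts): per metric, null mean, SD, z-score and an
empirical two-sided p with the `(1+b)/(1+n)` estimator.  Metrics fixed by
construction (density, average degree) have zero null SD and an undefined
z, reported as NaN with a warning; near-zero SDs from floating-point
accumulation are treated as zero.

## Pipeline

`run_pipeline` executes simulate/load → rarefy → alpha diversity and core
community → Bray–Curtis (+ PCoA coordinates for visualisation) → PerMANOVA
→ MRT → betaNTI → phylogenetic signal → niche breadth → Kruskal–Wallis and
Spearman correlation tables → co-occurrence networks → topology with ER
nulls.  Stage seeds are derived by hashing the master seed with the stage
name, so any stage can be rerun in isolation; the JSON report rounds
floats to 10 decimals and sorts keys, and is byte-identical across runs
with the same config and seed.  Networks are built per lake group *and*
pooled across the gradient: at 8–16 samples the standardised edge score is
capped near `1/SD_null`, so strict BH acceptance over thousands of
candidates requires many jointly-true edges, and desk-scale per-lake
networks are legitimately sparse or empty; the pooled network carries the
sign-fraction and topology summaries.

## Problem sizes and defaults

Demonstration and benchmark configurations run at desk scale as the
package's standard operating points: 400 taxa and depths 2,000–4,000 for
the gradient demonstration (the full-size study dimensions — 2,645 taxa,
depths ≥ 59,188 — remain the generator defaults and are reachable through
configuration), 999 permutations for PerMANOVA, 199 randomisations for
betaNTI and 200 permutation/bootstrap scores with 500-replicate graph
nulls in network test configurations (1,000 each are the library
defaults).  Calibration experiments use 10–50 seeds per condition.

## Known limitations

* The default demonstration run shows within-lake betaNTI trending more
  negative toward saline lakes, but medians rarely cross -2 at 8-sample
  groups with a generalist-rich pool; the strict homogeneous-selection
  signature is demonstrated by the dedicated selection scenario.
* One generator configuration cannot simultaneously maximise every
  pattern at desk scale; the demonstration defaults are a documented
  compromise (tolerance log-sd 0.5).
* Simes merging assumes positive dependence among measure p-values
  (satisfied in practice since all five measures respond to the same
  association), and the bootstrap stability filter is a heuristic
  reconstruction of ReBoot's unstable-edge rule.
* The MRT reports both the minimum-CV tree and its CV standard error but
  does not implement surrogate splits or the 1-SE rule.
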