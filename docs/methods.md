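# Methods

This note documents the models, estimators and numerical choices behind
`primpop`, and what the synthetic-data experiments do and do not establish.

## Data model and filtering

Genotypes are diploid alternate-allele counts in {0, 1, 2} with sentinel −9
for missing; VCF half-calls (`./1`) are treated as missing rather than
inventing an allele count.  The locus filters mirror the study design: a locus
is kept when it is typed in at least `min_group_presence` (default 0.8) of the
individuals of *every* group, is polymorphic in the pooled sample, and has
pooled minor-allele frequency ≥ `maf` (default 0.01), with missing genotypes
excluded from the frequency.  MAF is pooled rather than per-group, matching
the convention of SNP-ABC software.  Filtering is idempotent and
order-preserving.

## Differentiation and AMOVA

F_ST is Weir & Cockerham's (1984) θ.  Per locus the three variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed from sample sizes, allele frequencies
and observed heterozygosity; multi-locus estimates are the ratio of sums
Σa / Σ(a+b+c), not the mean of ratios.  Loci untyped in a population, or with
mean sample size ≤ 1, contribute nothing for the pair.  A "global" θ over all
populations at once is reported alongside Φ_ST, since legacy software labels
either one "F_ST".

AMOVA uses the squared-Euclidean-distance formulation on individual genotype
vectors.  With missing data, squared distances are computed over
pairwise-complete loci and rescaled by `n_loci / n_shared`.  Sums of squares
are partitioned into among-groups / among-populations-within-groups /
within-populations; variance components follow the standard unbalanced-design
coefficients, and Φ statistics are their ratios.  Permutation tests permute
(i) whole populations among groups for Φ_CT, (ii) individuals among
populations within groups for Φ_SC, (iii) individuals among all populations
for Φ_ST, with the +1-corrected p-value (#{perm ≥ obs} + 1)/(n_perm + 1) so p
is never 0.  Grouping strategies are ranked by percent variance among groups;
ties favour fewer groups.

PCA imputes missing genotypes with the locus mean and centers but does not
variance-scale columns (the `glPca`-style convention); axis percentages are
eigenvalue shares of the trace.  This convention materially affects the
percent-variance numbers, which is why it is pinned.

## Procrustes, PROTEST, and barriers

Procrustes similarity: both n×2 configurations are centered and scaled to
unit sum of squares; the optimal rotation comes from the SVD of the
cross-product, restricted to proper rotations by default (a reflection flag
exists; the published statistic does not state the reflection rule, and a
proper-rotation fit is the conservative choice).  t₀ = √(1 − D) with D the
residual sum of squares, so t₀ equals the sum of (sign-corrected) singular
values.  PROTEST permutes the rows of one configuration; ties count as ≥.

Geographic coordinates are used as planar (longitude, latitude) degrees — the
study region is small enough that projection distortion is negligible against
the genetic noise; any projection can be applied to the coordinate table
before analysis.

Monmonier barriers operate on the Delaunay triangulation and its Voronoi
dual.  Delaunay edges come from the triangulation; each is paired with its
crossing Voronoi ridge (co-circular point sets produce a zero-length ridge,
handled as a single shared vertex).  Barrier i seeds at the not-yet-crossed
population pair of maximal distance and grows from both ends of the seed's
Voronoi edge, alternating ends; each step crosses the eligible adjacent edge
of maximal distance, and a branch stops at the convex hull or at a Voronoi
vertex already on any barrier (so paths never self-intersect and no edge is
crossed twice).  Ties break lexicographically on population-pair labels,
making the output deterministic.  Support of a reference barrier (computed on
the element-wise mean of the bootstrap matrices) is the fraction of
locus-resampled matrices whose own k-barrier solution crosses *all* of its
edges — a strict matching rule, chosen because the original tool reports
support without defining one.

## Coalescent simulator

Histories are event lists over populations: stepwise size changes,
divergences (child lineages merge into the parent backward in time) and
admixture pulses (each target lineage independently joins donor A with
probability r, else donor B).  Within a population of diploid size N each
lineage pair coalesces at rate 1/(2N) per generation; times are continuous
generations (× generation time, default 1 year, for calendar ages).  There is
no intra-locus recombination and loci are unlinked; continuous migration is
out of scope (the study's scenarios use discrete events only).

Each locus carries exactly one mutation.  The genealogy of a site
*ascertained to be a SNP* is, in the low-mutation limit, the length-biased
tree: P(tree) ∝ L·f(tree) with L the total branch length.  The simulator
therefore samples genealogies by rejection with acceptance min(1, L/L_cap)
— L_cap is set from a 16-tree pilot plus 12 × 4N_root, leaving a truncated
weighted tail of order e⁻¹² — and then places the mutation on a branch with
probability proportional to its length.  This makes the derived-allele
spectrum of a constant-size panmictic sample exactly ∝ 1/i, which the test
suite verifies by χ² at 5×10⁴ loci.  Plain fixed-one-mutation placement on an
unbiased tree (the `ms -s 1` convention, whose spectrum is E[L_i/L] and
deviates from 1/i by a few percent at n = 10) is available with
`length_bias=False`.  Diploid genotypes pair consecutive simulated copies
within a population; copies are exchangeable, so this is a uniform random
pairing.  The hot path is a numba kernel with per-population lineage lists
(O(1) coalescent picks); determinism is per seed within a numba version.

## ABC

**Summaries.**  Per group: proportion of monomorphic loci, mean and variance
of unbiased gene diversity H = 2p(1−p)·n/(n−1).  Per group pair: multi-locus
W&C θ and Nei's (1972) standard distance −ln(J_xy/√(J_x J_y)) with gene
identities summed over loci.  Per ordered triple (t; A, B): the f3 statistic,
the mean over loci of (x_t−x_A)(x_t−x_B), negative when t is an admixture of
A- and B-like sources.  The set covers within-group, between-group and
admixture information while keeping dimensionality (108 for six groups) below
the retained-set size.  The exact menu of the original GUI tool is not
published; this set is the package's own and is pinned.

**Rejection.**  Summaries are standardized by the table's per-summary median
and MAD (× 1.4826; SD fallback when the MAD is 0; zero-variance summaries are
dropped with a warning), and the closest ceil(tolerance × rows) rows by
Euclidean distance are retained (tolerance 0.01 as in the study).  The
pipeline floors the retained count at 200 rows so the regression stages stay
identifiable on reduced tables.

**Scenario choice.**  Multinomial logistic regression (ℓ2, C = 1) of scenario
label on standardized summaries over the retained set, evaluated at the
observed point.  Confidence intervals are percentile bootstrap over retained
rows (200 resamples by default); the original tool's deviance-based CI is not
reproducibly described, so the bootstrap stands in.

**Parameter posteriors.**  Beaumont local-linear adjustment: weighted least
squares of each parameter on (summaries − observed) with Epanechnikov weights
in the rejection distance; adjusted draws are fitted-at-observed + residuals.
Parameters with bounded priors are regressed on a logit scale over the prior
support and back-transformed, keeping draws and HPD intervals inside the
support.  HPD intervals are shortest-window on the sorted adjusted sample;
the mode is a Gaussian-KDE argmax.  A singular design falls back to the
unadjusted rejection sample with a warning.

**Model checking.**  Parameters are redrawn from the adjusted posterior,
datasets re-simulated, and each summary's two-sided posterior-predictive tail
probability reported with the +1 correction; summaries with p < 0.05 are
flagged.

## Scenario batteries

Step 1 (three lineages, 5 diploids per population): the 13 candidate
topologies are the 3 rooted bifurcating trees with unsampled ancestors, the
trichotomy, the 6 origin-from-within chains and the 3 origin-from-within
fans; the fan with both L1 and L2 budding from L3 is scenario 13.  The
original supplementary enumeration is not available, so this complete and
symmetric enumeration is the package's own; a user battery can be supplied as
a YAML file (`battery_from_yaml`).  Step 2 (six groups) fixes the backbone —
G3 ancestral, G6 and G1 from G3, G2 an admixture pulse between G3 and G6
(rate ~ U(0.001, 0.999)) — and compares G4-from-G3-then-G5-from-G4 against
the swapped ordering.  Both step-2 scenarios also carry G3's size-change
events (recent bottleneck, ancient expansion) with identical priors: a
constant-size backbone cannot represent the root population's history, and
the shared misfit would otherwise leak into the ordering choice
(`root_size_changes=False` restores the constant-size variant).  Step 3 tests, per group, old expansion / recent
expansion / expansion–shrinkage / expansion–shrinkage–expansion, with
disjoint "recent" (10–5×10⁴ generations) and "old" (5×10⁴–10⁶) time windows
and order constraints between event times.  Default priors: sizes
log-uniform(10², 10⁶) diploids; event times uniform(10³, 10⁶) generations
unless a window says otherwise.  Priors are drawn independently and rejected
until order constraints hold.

Step-3 single-population runs use within-population summaries (monomorphic
proportion, mean/variance of H, mean/variance of the folded allele-frequency
spectrum), since the multi-group menu needs two units.

## Synthetic truth and what the experiments show

The default truth is step-2 scenario (a) with the inferred times
(t_G6 = 470k, t_G4 = 410k, t_G1 = 360k, t_G5 = 150k, t_G2 = 120k generations;
G3 expansion at 600k and bottleneck at 38k) and admixture rate 0.5.
Population sizes are not legible in the source figure and are configuration
choices, set once: N_G1 = 2×10⁴, N_G2 = 4×10⁴, N_G3 = 5×10⁴ (×1.5 before the
bottleneck — the inferred bottleneck is described as slight — and ×0.1 before
the expansion), N_G4 = 8×10⁴, N_G5 = 2×10⁴, N_G6 = 6×10⁴.  They are deliberately unequal: with equal sizes the two step-2
orderings generate *identical* data distributions (the "host" population of
the shared interval is exchangeable), so no method could recover the
generating ordering and the recovery experiment would be a coin toss.

Missingness: the generator draws per-locus missingness rates from a
Beta(0.8, ·) with mean 0.178 before masking genotypes.  RAD missingness
concentrates on poorly recovered loci; uniform i.i.d. missingness at 17.8%
would leave almost no locus typed in 80% of every group, which is
incompatible with the existence of the filtered empirical data set.  The
spec-level `inject_missingness` keeps the plain i.i.d. contract.

Populations within a group are panmictic (the demographic units are the
groups), so synthetic within-group F_ST ≈ 0 — unlike the real system, where
populations within groups are themselves differentiated.  Coordinates are
six-cluster templates with jitter, not field coordinates.  Passing tests
therefore demonstrate correctness of the estimators and recoverability of the
simulated history under the stated conditions; they do not certify the
original study's empirical values, which depend on its deposited data.

Recovery experiments share one reference table across replicates (battery and
priors are identical; only the pseudo-observed data change), and the observed
dataset is subsampled to the table's locus count so summary noise levels
match.  Table simulations carry observed-style missingness: per-locus
missingness patterns are drawn from a pool of donor replicates and applied to
each simulated dataset, so simulated summaries rest on the same
typed-gene-copy counts as the observation (the pseudo-observed-dataset
convention of SNP-ABC software); several donors are pooled because a single
donor's realization would be frozen into every table row and displace the
whole table.

A caution on the step-2 ordering: with every group's size a free
log-uniform(10², 10⁶) parameter, the alternative ordering can reproduce the
generating ordering's pairwise-drift geometry by re-fitting its times and
sizes, so the posterior evidence for the ordering is weak even though the two
orderings are sharply distinguishable at fixed parameters.  The
scenario-recovery experiment measures exactly this: its win rate quantifies
how often the generating ordering is preferred under the default wide priors,
and users analysing real data should expect the step-2 choice to hinge on how
informative their size priors are.

## Problem sizes and numerics

Default scaled-down sizes: reference tables of 10³–10⁴ rows per scenario and
300 loci per simulated dataset (the full-scale 10⁶-row tables of a production
run are a flag away: `build_reference_table(n_per_scenario=...)`); recovery
experiments use 20 replicates and 10⁴-row tables; the statistical test suite
uses 10⁴ coalescent replicates for closed forms, 5×10⁴ loci for the
site-frequency law, 2×10³ island-model loci (simulated with msprime, an
independent implementation) for the F_ST closed form, and 100 replicates for
HPD calibration.  Numerical tie-breaks and degenerate inputs: permutation
p-values are +1-corrected; monomorphic pairs yield θ = 0 by the 0/0 → 0
ratio-of-sums convention; a fully monomorphic AMOVA input is flagged
degenerate with all percentages 0; Nei distance caps at 10 when gene
identities vanish; barrier ties are lexicographic.

## Known limitations

- No continuous migration, no intra-locus recombination, no sequence-level
  mutation models (unlinked single-SNP data only).
- Reference tables at the shipped sizes give Monte-Carlo-noisy posterior
  probabilities; production analyses should raise `n_per_scenario`.
- The AMOVA distance treatment of missing data (pairwise-complete rescaling)
  is one of several defensible conventions; legacy GUI software does not
  document its own.
- Scenario-choice CIs are bootstrap, not the original deviance-based bands.
- The step-2 divergence-ordering choice is only weakly identified under the
  default wide size priors (see the caution above); the shipped recovery test
  reports this honestly rather than passing by construction.
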