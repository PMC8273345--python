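# Methods

This note documents the statistical procedures, the synthetic-community
model behind the test suite, the numerical conventions, and the design
choices that were genuinely open.

## The analysis

### Preprocessing

The pipeline operates on an integer taxa-by-samples count table and runs a
fixed stage order:

1. **Technical-replicate pooling.** Raw (non-normalized) counts are summed
   within each replicate group; the pooled sample takes the group's name.
   Pooling precedes every normalization step because replicate libraries
   are draws from the same extract and summing them only deepens coverage.
2. **Singleton/doubleton removal.** Taxa whose total count across *all*
   pre-pooling libraries is ≤ 2 are dropped (`max_total` configurable).
   This is the standard guard against sequencing-error taxa; totals are
   computed on the table as given.
3. **Rarefaction.** Every pooled sample is subsampled without replacement
   to a common depth (default: the smallest pooled library) via a
   multivariate-hypergeometric draw. Each sample's draw is seeded from the
   master seed plus a CRC of the sample id, so results are bit-reproducible
   and invariant to column order. Samples shallower than the target are
   dropped with a warning by default (`on_shallow="error"` raises).
4. **Relative abundance.** Counts become percent shares; each station
   column sums to 100 exactly. The ≤ 1e-9 floating-point residual is
   folded into the column's largest entry rather than its last one, so a
   structural zero can never become a spurious presence.
5. **Subcommunity split.** Samples are partitioned by (depth layer, size
   fraction) into four station-indexed views with a common station
   ordering. A station missing from one view simply shrinks that view's
   occupancy denominator.

### Lineages and rank aggregation

Each OTU carries a six-rank lineage (phylum → species). Unresolved ranks
are filled with parent-qualified sentinels, `unclassified_<deepest name>`:
two families' unresolved genera never merge, because merging them would
fabricate a cosmopolitan pseudo-taxon and inflate the abundance–occupancy
correlation. A mid-lineage gap truncates the lineage at the gap. Rank
aggregation sums member abundances, so station totals are conserved
exactly and a parent's occupied-station set is the union of its members'
sets (occupancy can only grow up the hierarchy). Sentinel taxa are
retained as first-class rows by default (they are real abundance mass);
`drop_unclassified` removes them from the statistical records.

### Abundance–occupancy statistics

* **Occupancy** is the count of stations with abundance > 0; all-zero taxa
  never enter a subcommunity's record set.
* **Mean relative abundance** averages over *all* stations, zeros
  included: absence is ecological signal. A taxon at 0.9% on one of nine
  stations has a mean of 0.1%, not 0.9%.
* **Low-abundance filter**: records with mean < 0.002% are removed
  (strict less-than; the boundary value is kept).
* **Categories**: generalists must exceed half the stations after rounding
  the station threshold up — at 9 stations that is 6 or more, the
  convention of field AOR studies; specialists occupy strictly less than a
  quarter (≤ 2 of 9). Both thresholds are exposed as fractions so other
  station counts generalize.
* **AOR strength** is Spearman's ρ with midranks; p-values use the
  two-sided t-approximation with n−2 degrees of freedom (exact at ρ = ±1,
  undefined and reported missing for constant input). Post-filter taxon
  counts are in the hundreds to thousands, where the approximation is
  excellent. The Benjamini–Hochberg family is all per-rank,
  per-subcommunity tests of one run (6 × 4 = 24 by default;
  `bh_family="per_subcommunity"` restricts it).
* **Niche-width index** is the OLS slope of ln(mean percent abundance) on
  occupancy, in ln-percent per station. Natural log: a base change only
  rescales every slope by a constant and cannot alter fold changes or the
  ANOVA.
* **Cross-rank comparison**: one-way ANOVA of the slopes with the four
  subcommunities as replicates per rank, Shapiro–Wilk on the group-mean
  residuals, Tukey HSD (Tukey–Kramer under unequal replication) via the
  studentized-range distribution, homogeneous-group letters from a greedy
  left-to-right insertion over ranks ordered by mean (groups fully
  contained in another are dropped), and the fold change of the slope
  between each pair of consecutive ranks, flagging whether the
  class → phylum change is the maximum.

### Diversity

Richness and Pielou's evenness (Shannon with natural log divided by
ln richness; undefined below two taxa) are meant for rarefied counts.
Faith's PD follows the root-inclusive convention — the summed branch
length of the minimal subtree connecting the present tips to the root —
with `include_root=False` giving the crown-group variant measured from the
most recent common ancestor. Bray–Curtis is Σ|x−y| / Σ(x+y). ANOSIM uses
midranked pairwise distances, R = (r̄_between − r̄_within)/(M/2) with
M = n(n−1)/2, and the add-one permutation estimator
p = (1 + #{R_perm ≥ R_obs})/(n_perm + 1), seeded and therefore
reproducible.

## The synthetic-community model

The generator exists so the whole pipeline can be validated against known
ground truth. Its defaults emulate a size-fractionated estuarine 16S
survey: 9 stations × 2 depths × 2 fractions, technical replicate pairs
with lognormal library sizes (floored so pooled pairs exceed the
13,339-read rarefaction target), 5,000 species under the scaled
773/354/177/94/29 genus-to-phylum hierarchy, singletons and doubletons
arising naturally from multinomial sampling.

Per subcommunity:

* **Abundance** is hierarchical lognormal: ln m_i sums independent
  Gaussian clade contributions at every rank (σ per rank) plus a
  species-level deviation with sd `hierarchy_noise`. Related taxa have
  related abundances.
* **Occupancy** is top-down niche filtering. Each clade, phylum down to
  genus, holds a station iff its suitability clears a per-rank margin:
  `chain_base[rank] + min(c,1)·(z_clade + u) > 0`, where c is the
  coupling, z_clade the clade's standardized log aggregate abundance and u
  clade-station noise. Children can only occur inside their parent's
  station set, so sibling species co-occur — without this nesting, a
  37-species genus would occupy all stations with certainty and every
  coarse-rank statistic would degenerate. Margins grow toward the phylum
  level (coarser clades are broader-niched); the dominant clade at each
  rank is ubiquitous, as dominant taxa are in coastal surveys. A species
  is then present within its genus' set with
  `logit p = α + c·(z_niche + w·ε)`, where z_niche is the lineage's shared
  abundance profile plus an `occupancy_tracking` share (default 0.8) of
  the species' own deviation — occupancy partly, not fully, tracks
  idiosyncratic abundance, which is what lets aggregation strengthen the
  AOR the way field data show.
* **The null is exact by construction.** Every niche term is scaled by the
  coupling, so at c = 0 clades hold every station and presence collapses
  to iid Bernoulli(logistic(α)): occupancy is independent of abundance
  *and* exchangeable across taxa, so the AOR test's t-approximation is
  correctly calibrated (measured rejection ≈ 0.06 at α = 0.05).
* **Regional abundance is conserved across occupancy.** A taxon's
  lognormal draw m_i is its regional mean share; an occupied station
  carries m_i·S/occ_i (times lognormal station noise). The zero-inclusive
  mean therefore estimates m_i whatever the occupancy, and specialists are
  locally denser than equally-abundant generalists. Without this
  convention the statistic would correlate with occupancy mechanically,
  even under the null, because occupancy enters both variables.
* **Counts** are per-replicate multinomial draws of each station's latent
  profile, with a lognormal replicate perturbation (`replicate_cv`).
  Depth and fraction effects multiply disjoint genus-level subsets of taxa
  with opposite signs, giving ANOSIM-detectable community separation.

### The rho oracle

`oracle_expected_rho` is the ground-truth target for recovery tests: a
single very large draw (default 10,000 species) of the same process,
pushed through the same record-building rules. Two scalings keep its
estimand identical to a smaller pipeline run: the clade counts are held
*fixed* at the base configuration's hierarchy (only the species count
grows), and both the 0.002% filter and the sequencing depth are rescaled
by n_species/n_large, because per-taxon shares shrink like 1/n. The oracle
also simulates the measurement — Poisson reads at the depth-equivalent
coverage with replicate-level overdispersion — since finite sequencing
depth removes rare taxa from the occupancy record and is part of what the
pipeline measures.

### Validation scenarios

Three named configurations freeze the conditions the test suite uses:

* `recovery_scenario_config` — 500 species, coupling 0.8, a moderate
  hierarchy (100 genera, …, 3 phyla: about five species per genus, so
  realized correlations are not dominated by a handful of genus-level
  draws). The oracle sits at ρ ≈ 0.74, in the strong positive-AOR regime;
  the count pipeline (averaging the four subcommunities' species-level ρ)
  recovers it within ±0.1 in ≥ 90% of seeds.
* `null_scenario_config` — coupling 0, one subcommunity; the species-level
  AOR test rejects at close to its nominal 5%.
* `hierarchy_scenario_config` — 15,000 species, `hierarchy_noise = 2`,
  and an explicit 29-phylum hierarchy with about five species per genus.
  The survey-scaled hierarchy at 500–5,000 species leaves only 1–6 phyla,
  which makes phylum-level regressions degenerate; this scenario keeps
  every rank estimable. Under it, genus-level ρ is at least the
  species-level ρ (species are noisy replicates of genus niches, and
  aggregation averages the noise away), the generalist fraction is
  non-decreasing from species to phylum, and the largest consecutive-rank
  fold change of the niche-width slope falls between class and phylum in
  the majority of seeds.

### What the generator does not emulate

Sequence-level reality (read errors, chimeras, primer bias, OTU-clustering
artifacts), environmental covariates, spatial autocorrelation between
stations, and phylogenetic signal beyond the taxonomic hierarchy (the tree
is the hierarchy with unit branch lengths). Passing tests therefore show
that the *statistics* behave correctly on data with the assumed structure,
not that the ecological conclusions transfer to any particular real
survey.

## Numerical conventions and edge cases

* All abundances are on the percent scale (0–100), matching the
  "< 0.002%" filter language.
* Spearman, slope and ANOSIM are invariant to taxon and station ordering;
  rarefaction is invariant to column order by per-sample seeding.
* Constant inputs (all taxa at full occupancy, a single present taxon,
  groups of one) yield missing statistics with a warning, never a crash.
* Fold changes are undefined (missing, with a warning) when consecutive
  slopes differ in sign or the finer one is zero.
* Taxonomy files may carry bootstrap confidences (`name(98)`) and a
  leading domain rank; both are stripped/dropped on read
  (`has_domain_prefix=False` keeps a six-rank file intact).
* The problem sizes used by the test suite (500–15,000 species, 50–200
  seeds per property) were chosen so the full suite completes at desk
  scale while each property retains clear statistical margin.

## Known limitations

* The Spearman p-value is asymptotic; for post-filter record sets smaller
  than ~10 taxa the test is reported but should be read with caution.
* BH correction treats the 24 per-run tests as independent, which rank
  aggregation violates in the conservative direction.
* ANOSIM permutes labels freely, ignoring any station-level pairing
  between depths.
* The generalist/specialist thresholds are occupancy-only; abundance-
  weighted niche-breadth measures (e.g. Levins' B) are out of scope.
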