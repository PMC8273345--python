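# aortax

Abundance–occupancy relationships (AORs) across taxonomic ranks for
size-fractionated bacterioplankton communities.

## The problem

In community ecology, a taxon's regional distribution (how many sites it
occupies) and its local abundance tend to be positively related. For
marine bacterioplankton surveyed by 16S rRNA amplicon sequencing, this
relationship can be asked at every taxonomic rank — species (99% OTUs),
genus, family, order, class, phylum — and for ecologically distinct
subcommunities: free-living (FL, 0.22–3 µm) versus particle-attached (PA,
3–200 µm) cells, in surface water versus the cold intermediate layer (CIL)
of a stratified estuary. `aortax` implements that analysis as a tested,
reusable pipeline for anyone with an OTU count table, a taxonomy table and
per-sample metadata from a multi-station survey.

For each subcommunity (depth × size fraction) and rank, the pipeline
computes, per taxon *i*:

* **occupancy** `o_i` — the number of stations (out of S, here 9) where the
  taxon has nonzero relative abundance;
* **mean relative abundance** `ā_i` — the average percent abundance over
  *all* S stations, zeros included; taxa with `ā_i < 0.002%` are excluded
  as chance occurrences;
* **habitat category** — generalist (occupancy > 50% of stations, i.e. ≥ 6
  of 9), specialist (< 25%, i.e. ≤ 2 of 9), or neither.

From the per-taxon records it derives:

* **AOR strength**: Spearman's ρ between `o` and `ā` (midranks for ties,
  two-sided t-approximation for p, Benjamini–Hochberg correction over the
  6 ranks × 4 subcommunities family);
* **niche-width index**: the OLS slope *b* of `ln ā_i = a + b·o_i`,
  per rank and subcommunity, plus fold changes of *b* between consecutive
  ranks, and a one-way ANOVA across ranks (subcommunities as replicates)
  with Shapiro–Wilk residual check, Tukey HSD and homogeneous-group
  letters;
* **diversity context**: observed richness, Pielou's evenness
  (Shannon/ln S_obs), Faith's phylogenetic diversity, Bray–Curtis
  dissimilarities, and ANOSIM tests of depth and size-fraction effects.

Preprocessing reproduces the standard amplicon workflow at table level:
technical-replicate pooling (raw counts), singleton/doubleton removal over
all libraries, seeded rarefaction to the smallest library (without
replacement), conversion to percent abundance, and the split into the four
subcommunities.

A first-class synthetic-community generator (`aortax.synthetic_data`)
produces count tables, taxonomies, metadata and trees with the survey's
shape — 9 stations × 2 depths × 2 fractions with technical replicate
pairs, uneven library sizes, and a 773-genera/354-families/177-orders/94-
classes/29-phyla hierarchy scaled to the requested species count — with a
*tunable* abundance–occupancy coupling and known ground truth, so every
statistic can be validated against what was simulated.

## Worked example

```bash
aortax simulate --out-dir demo/data --seed 7
aortax run --counts demo/data/counts.tsv --taxonomy demo/data/taxonomy.tsv \
           --metadata demo/data/metadata.tsv --tree demo/data/tree.nwk \
           --out-dir demo/out --seed 7
```

or, equivalently, in Python:

```python
from aortax import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig(
    counts="demo/data/counts.tsv", taxonomy="demo/data/taxonomy.tsv",
    metadata="demo/data/metadata.tsv", tree="demo/data/tree.nwk",
    out_dir="demo/out", seed=7))
print(results["rank_statistics"].head(5)[["rank", "depth", "fraction", "n_taxa", "rho", "p_adjusted", "slope"]])
```

which prints (seed 7, default generator):

```
      rank depth fraction  n_taxa       rho    p_adjusted     slope
0  species   CIL       FL    2215  0.792369  0.000000e+00  0.424117
1    genus   CIL       FL     156  0.875624  7.454959e-50  0.671903
2   family   CIL       FL      80  0.866177  7.892846e-25  0.654167
3    order   CIL       FL      40  0.863820  1.321960e-12  0.670675
4    class   CIL       FL      20  0.821050  1.219943e-05  0.698759
```

Reading: in the CIL free-living subcommunity, the AOR is strongly positive
at every rank (ρ ≈ 0.79–0.88, all significant after correction), and the
niche-width slope grows from 0.42 ln-percent per station at the species
level to ≈ 0.70 at the class level — abundance climbs faster with
occupancy once taxa are aggregated into coarser, ecologically broader
units. The run also writes `taxon_records.tsv` (per-taxon occupancy,
abundance, category), `rank_comparison.tsv` (ANOVA/Tukey/fold changes),
`diversity.tsv`, `anosim.tsv` and `bray_curtis.tsv` under `demo/out/`;
this run's ANOSIM separates depths at R = 0.96 and fractions at R = 0.27
(both p = 0.001).

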