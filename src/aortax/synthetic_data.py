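"""Synthetic bacterioplankton communities with known ground truth.

The generator emulates the processed form of a size-fractionated 16S survey:
9 stations x 2 depth layers (surface, cold intermediate layer) x 2 size
fractions (free-living, particle-attached), technical replicate library
pairs with uneven sizes, thousands of OTUs under a realistic six-rank
hierarchy, and a *tunable* abundance-occupancy coupling.

Model, per subcommunity:

* a species' regional mean relative abundance ``m_i`` is hierarchical
  lognormal: independent Gaussian contributions at every rank of its
  lineage (phylum down to a species-level deviation, ``hierarchy_noise``),
  so related taxa have related abundances;
* occupancy is top-down niche filtering: each clade, phylum down to genus,
  holds a station iff its niche suitability clears a per-rank margin,
  ``chain_base[rank] + min(coupling, 1) * (z_clade + u_clade_station) > 0``,
  where ``z_clade`` is the clade's standardized log aggregate abundance —
  children can only occur inside their parent's station set, so sibling
  species co-occur and coarse ranks keep real (non-saturating) occupancy
  variance.  A species is then present within its genus' set with
  ``logit p = alpha + coupling * (z_niche_i + w * eps)``, where ``z_niche``
  is the lineage profile plus an ``occupancy_tracking`` share of the
  species' own abundance deviation.  Every niche term vanishes with the
  coupling: at ``coupling = 0`` clades hold every station and presence
  collapses to iid Bernoulli(logistic(alpha)), independent of abundance and
  exchangeable across taxa — the exact null;
* regional abundance is conserved across occupancy: an occupied station
  carries ``m_i * S / occ_i`` (times lognormal station noise), so the
  zero-inclusive mean abundance of a taxon estimates ``m_i`` regardless of
  how many stations it occupies.  With ``coupling = 0`` occupancy is
  therefore independent of mean abundance *by construction*, which makes
  null-calibration tests of the AOR statistic meaningful;
* observed counts are per-replicate multinomial draws of each station's
  latent profile (library sizes lognormal, floored), with a lognormal
  replicate perturbation; depth and fraction effects multiply disjoint
  genus-level taxon subsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .aor_core import build_records, spearman_rho
from .io_tables import CountTable, SampleMetadata, write_count_table, write_metadata, write_taxonomy
from .preprocess import SubcommunityView
from .taxonomy import TaxonomyTable, normalize_lineage

logger = logging.getLogger("aortax")

#: Observed rank sizes of a 28,824-OTU coastal survey, the calibration shape.
PAPER_RANK_COUNTS = {"species": 28824, "genus": 773, "family": 354, "order": 177, "class": 94, "phylum": 29}

#: coarse -> fine order of the hierarchy levels above species
_HIER_RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass
class SyntheticConfig:
    """Parameters of the community generator; defaults are the study shape."""

    n_stations: int = 9
    depths: Tuple[str, ...] = ("surface", "CIL")
    fractions: Tuple[str, ...] = ("FL", "PA")
    n_species: int = 5000
    #: per-rank sd of the hierarchical lognormal abundance contributions
    abundance_sigma: Dict[str, float] = field(default_factory=lambda: {
        "phylum": 1.2, "class": 0.8, "order": 0.6, "family": 0.6, "genus": 0.8})
    #: sd of the species-level deviation from its genus niche center
    hierarchy_noise: float = 1.0
    #: how much of that species deviation the occupancy process sees (0 =
    #: occupancy tracks only the lineage niche, 1 = tracks full abundance)
    occupancy_tracking: float = 0.8
    #: strength of the abundance -> occupancy link (0 = independent);
    #: the default puts the large-n AOR near the 0.6-0.7 band typical of
    #: positive bacterioplankton AORs
    coupling: float = 1.0
    #: baseline species occupancy logit (within the genus' station set)
    occupancy_intercept: float = -2.0
    #: per-rank niche-suitability margin of a clade holding a station: larger
    #: = harder to exclude.  Coarser clades are broader-niched, so the margin
    #: grows up the hierarchy; under the null every clade holds every station
    chain_base: Dict[str, float] = field(default_factory=lambda: {
        "phylum": 2.5, "class": 2.0, "order": 1.5, "family": 1.2, "genus": 1.0})
    #: per-rank sd of clade-station niche noise (ranks above species) and the
    #: species-level idiosyncratic weight; multiplied by ``coupling``
    occupancy_rank_sigma: Dict[str, float] = field(default_factory=lambda: {
        "phylum": 0.4, "class": 0.7, "order": 1.0, "family": 1.3, "genus": 1.6, "species": 0.5})
    #: sd of lognormal noise on an occupied station's abundance
    station_noise: float = 0.3
    depth_effect: float = 1.5
    fraction_effect: float = 1.5
    #: fraction of genera shifted by each of the depth/fraction effects
    effect_fraction: float = 0.25
    #: per-library (pre-pooling) size law and floor; the floor keeps pooled
    #: replicate pairs above the 13,339-read rarefaction target
    library_size_log_mean: float = float(np.log(18000.0))
    library_size_log_sigma: float = 0.3
    library_size_min: int = 6700
    replicate_cv: float = 0.3
    n_replicates: int = 2
    sentinel_fraction: float = 0.05
    #: explicit clade counts per rank (genus..phylum); None = survey shape
    #: scaled to n_species.  Used e.g. by the rho oracle, which enlarges the
    #: species count at *fixed* clade structure so the estimand matches.
    rank_counts: Optional[Dict[str, int]] = None
    seed: int = 0

    def rank_targets(self) -> Dict[str, int]:
        """Distinct-clade count per rank: the survey shape scaled to n_species,
        clipped to stay monotone up the hierarchy."""
        if self.rank_counts is not None:
            return dict(self.rank_counts)
        s = self.n_species / PAPER_RANK_COUNTS["species"]
        targets: Dict[str, int] = {}
        ceiling = self.n_species
        for rank in ("genus", "family", "order", "class", "phylum"):
            t = min(max(1, round(PAPER_RANK_COUNTS[rank] * s)), ceiling)
            targets[rank] = t
            ceiling = t
        return targets

    def validate(self) -> None:
        if self.n_species < 1 or self.n_stations < 1:
            raise ValueError("n_species and n_stations must be >= 1")
        if self.library_size_min < 1:
            raise ValueError("infeasible config: library_size_min must be >= 1")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if not 0 <= self.sentinel_fraction <= 1:
            raise ValueError("sentinel_fraction must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def subcommunities(self) -> List[Tuple[str, str]]:
        return [(d, f) for d in self.depths for f in self.fractions]


def paper_shape_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default study-shaped configuration (9 stations, 2x2 design,
    5,000 species with the scaled rank hierarchy)."""
    return replace(SyntheticConfig(seed=seed), **overrides)


def recovery_scenario_config(seed: int = 0) -> SyntheticConfig:
    """Parameter-recovery scenario: 500 species under a moderate hierarchy
    (about five species per genus, so realized correlations are not dominated
    by a handful of genus-level draws) with the coupling calibrated so the
    large-n oracle sits in the strong-AOR regime (rho around 0.7)."""
    return replace(SyntheticConfig(seed=seed), n_species=500, coupling=0.8,
                   rank_counts={"genus": 100, "family": 40, "order": 17, "class": 8, "phylum": 3})


def null_scenario_config(seed: int = 0) -> SyntheticConfig:
    """Null-calibration scenario: coupling 0, one subcommunity — occupancy is
    iid Bernoulli, independent of abundance, so AOR tests should reject at
    their nominal level."""
    return replace(SyntheticConfig(seed=seed), n_species=500, coupling=0.0,
                   depths=("surface",), fractions=("FL",))


def hierarchy_scenario_config(seed: int = 0) -> SyntheticConfig:
    """Hierarchical-noise scenario for qualitative cross-rank patterns:
    species are noisy replicates of their genus niche profile
    (hierarchy_noise = 2) under a 29-phylum hierarchy with about five species
    per genus, so statistics are estimable at every rank including phylum."""
    return replace(SyntheticConfig(seed=seed), n_species=15000, hierarchy_noise=2.0,
                   depths=("surface",), fractions=("FL",),
                   rank_counts={"genus": 3000, "family": 1200, "order": 500, "class": 150, "phylum": 29})


@dataclass
class _Hierarchy:
    """Clade index per species at each rank above species, plus clade names."""

    clade_of: Dict[str, np.ndarray]   # rank -> int array over species
    names: Dict[str, List[str]]       # rank -> clade names
    species_ids: List[str]

    def lineage_names(self, i: int) -> List[str]:
        return [self.names[r][self.clade_of[r][i]] for r in _HIER_RANKS]


def _build_hierarchy(config: SyntheticConfig, rng: np.random.Generator) -> _Hierarchy:
    """Sequential random partitioning: each clade gets at least one child,
    remaining children pick parents uniformly, so rank sizes hit the scaled
    targets exactly."""
    targets = config.rank_targets()

    def _assign(n_children: int, n_parents: int) -> np.ndarray:
        arr = np.concatenate([np.arange(n_parents),
                              rng.integers(0, n_parents, size=n_children - n_parents)])
        rng.shuffle(arr)
        return arr

    parent = {child: _assign(targets[child], targets[par])
              for child, par in (("class", "phylum"), ("order", "class"),
                                 ("family", "order"), ("genus", "family"))}
    genus_of = _assign(config.n_species, targets["genus"])
    clade_of = {"genus": genus_of}
    clade_of["family"] = parent["genus"][genus_of]
    clade_of["order"] = parent["family"][clade_of["family"]]
    clade_of["class"] = parent["order"][clade_of["order"]]
    clade_of["phylum"] = parent["class"][clade_of["class"]]
    names = {
        "phylum": [f"Phylum{i + 1:03d}" for i in range(targets["phylum"])],
        "class": [f"Class{i + 1:03d}" for i in range(targets["class"])],
        "order": [f"Order{i + 1:04d}" for i in range(targets["order"])],
        "family": [f"Family{i + 1:04d}" for i in range(targets["family"])],
        "genus": [f"Genus{i + 1:04d}" for i in range(targets["genus"])],
    }
    width = max(5, len(str(config.n_species)))
    species_ids = [f"OTU{i + 1:0{width}d}" for i in range(config.n_species)]
    return _Hierarchy(clade_of, names, species_ids)


def _taxonomy_from_hierarchy(hier: _Hierarchy, config: SyntheticConfig,
                             rng: np.random.Generator) -> TaxonomyTable:
    n = len(hier.species_ids)
    truncate = rng.random(n) < config.sentinel_fraction
    depth = rng.integers(0, 5, size=n)  # how many leading ranks survive truncation
    lineages = {}
    for i, otu in enumerate(hier.species_ids):
        names = hier.lineage_names(i)
        if truncate[i]:
            names = names[: depth[i]]
        lineages[otu] = normalize_lineage(names)
    return TaxonomyTable(lineages)


def generate_taxonomy(config: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> TaxonomyTable:
    """A rooted six-rank hierarchy over the configured number of species;
    a ``sentinel_fraction`` of species carry truncated (sentinel) lineages."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 1]))
    hier = _build_hierarchy(config, rng)
    return _taxonomy_from_hierarchy(hier, config, rng)


def _species_log_abundance(hier: _Hierarchy, config: SyntheticConfig,
                           rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """ln m_i split into the shared clade-path part and the species deviation.

    Returns ``(shared, deviation)`` with ``ln m = shared + deviation``.  The
    shared part is the lineage niche profile; the ``hierarchy_noise``-scaled
    deviation is species idiosyncrasy that occupancy does *not* see, which is
    what lets aggregation strengthen the AOR the way field data show.
    """
    shared = np.zeros(config.n_species)
    for rank in _HIER_RANKS:
        sigma = config.abundance_sigma.get(rank, 0.0)
        if sigma > 0:
            contrib = rng.normal(0.0, sigma, size=len(hier.names[rank]))
            shared = shared + contrib[hier.clade_of[rank]]
    deviation = rng.normal(0.0, config.hierarchy_noise, size=config.n_species)
    return shared, deviation


def _effect_multipliers(hier: _Hierarchy, config: SyntheticConfig,
                        rng: np.random.Generator) -> Dict[Tuple[str, str], np.ndarray]:
    """Per-subcommunity abundance multipliers: disjoint genus subsets respond
    to depth and to size fraction with opposite-signed lognormal shifts."""
    n_gen = len(hier.names["genus"])
    genera = rng.permutation(n_gen)
    k = int(round(config.effect_fraction * n_gen))
    depth_gen = np.zeros(n_gen, bool)
    frac_gen = np.zeros(n_gen, bool)
    depth_gen[genera[:k]] = True
    frac_gen[genera[k:2 * k]] = True
    depth_species = depth_gen[hier.clade_of["genus"]]
    frac_species = frac_gen[hier.clade_of["genus"]]
    out = {}
    for depth in config.depths:
        d_sign = 1.0 if depth == config.depths[0] else -1.0
        for fraction in config.fractions:
            f_sign = 1.0 if fraction == config.fractions[0] else -1.0
            mult = np.ones(config.n_species)
            mult[depth_species] *= np.exp(d_sign * config.depth_effect / 2.0)
            mult[frac_species] *= np.exp(f_sign * config.fraction_effect / 2.0)
            out[(depth, fraction)] = mult
    return out


@dataclass
class GroundTruth:
    """Serialized alongside a dataset so recovery tests know the answer."""

    coupling: float
    regional_mean: pd.DataFrame       # taxa x subcommunity, percent
    latent_occupancy: pd.DataFrame    # taxa x subcommunity, station counts
    expected_rho: Optional[Dict[str, float]] = None

    def to_json(self, path) -> None:
        payload = {
            "coupling": self.coupling,
            "regional_mean": self.regional_mean.to_dict(orient="split"),
            "latent_occupancy": self.latent_occupancy.to_dict(orient="split"),
            "expected_rho": self.expected_rho,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            coupling=payload["coupling"],
            regional_mean=pd.DataFrame(**{k: payload["regional_mean"][k] for k in ("data", "index", "columns")}),
            latent_occupancy=pd.DataFrame(**{k: payload["latent_occupancy"][k] for k in ("data", "index", "columns")}),
            expected_rho=payload["expected_rho"],
        )


def _station_ids(config: SyntheticConfig) -> List[str]:
    return [f"st{i + 1}" for i in range(config.n_stations)]


def generate_latent_views(config: SyntheticConfig,
                          rng: Optional[np.random.Generator] = None,
                          hier: Optional[_Hierarchy] = None,
                          ) -> Tuple[Dict[Tuple[str, str], SubcommunityView], _Hierarchy, GroundTruth]:
    """Latent (pre-sequencing) percent-abundance views for every subcommunity.

    Station columns are normalized to sum to 100, matching what the count
    pipeline would converge to with infinite sequencing depth.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 2]))
    if hier is None:
        hier = _build_hierarchy(config, rng)
    S = config.n_stations
    stations = _station_ids(config)
    shared, deviation = _species_log_abundance(hier, config, rng)
    multipliers = _effect_multipliers(hier, config, rng)
    views: Dict[Tuple[str, str], SubcommunityView] = {}
    mean_cols, occ_cols = {}, {}
    for key in config.subcommunities():
        log_m = shared + deviation + np.log(multipliers[key])
        m = np.exp(log_m)
        m = 100.0 * m / m.sum()
        # the niche signal occupancy responds to: the lineage's shared
        # abundance profile plus a partial view of the species' own deviation
        z_niche = shared + config.occupancy_tracking * deviation + np.log(multipliers[key])
        z_niche = z_niche - z_niche.mean()
        c = config.coupling
        # top-down clade station sets: phylum -> ... -> genus, each nested in
        # its parent's.  A clade holds a station iff its niche suitability
        # clears a threshold; suitability rides on the coupling, so at c = 0
        # every clade holds every station (no clustering under the null).
        mask = np.ones((config.n_species, S), dtype=bool)
        for rank in _HIER_RANKS:
            clades = hier.clade_of[rank]
            n_clades = len(hier.names[rank])
            clade_abund = np.bincount(clades, weights=m, minlength=n_clades)
            zc = np.log(clade_abund)
            zc = (zc - zc.mean()) / (zc.std() or 1.0)
            u = rng.normal(0.0, config.occupancy_rank_sigma.get(rank, 0.0), size=(n_clades, S))
            base = config.chain_base.get(rank, 1.5) if isinstance(config.chain_base, dict) else float(config.chain_base)
            # chain strength saturates at coupling 1: the exclusion geometry is
            # then coupling-invariant, while it still vanishes as coupling -> 0
            holds = base + min(c, 1.0) * (zc[:, None] + u) > 0
            # the dominant clade at every rank is ubiquitous, as dominant
            # taxa are in coastal surveys; also keeps every station populated
            holds[int(np.argmax(clade_abund))] = True
            mask &= holds[clades]
        sp_w = config.occupancy_rank_sigma.get("species", 0.0)
        logit = (config.occupancy_intercept + c * z_niche)[:, None] \
            + c * sp_w * rng.normal(0.0, 1.0, size=(config.n_species, S))
        presence = mask & (rng.random((config.n_species, S)) < 1.0 / (1.0 + np.exp(-logit)))
        empty = ~presence.any(axis=0)
        presence[int(np.argmax(m)), empty] = True  # no station is ever barren
        occ = presence.sum(axis=1)
        occupied = occ > 0
        noise = np.exp(rng.normal(0.0, config.station_noise, size=(config.n_species, S))
                       - config.station_noise ** 2 / 2.0)
        abund = np.zeros((config.n_species, S))
        abund[occupied] = (presence[occupied] * noise[occupied]
                           * (m[occupied] * S / occ[occupied])[:, None])
        abund = abund * (100.0 / abund.sum(axis=0))
        df = pd.DataFrame(abund, index=hier.species_ids, columns=stations)
        views[key] = SubcommunityView(key[0], key[1], df, rank="species")
        name = f"{key[0]}_{key[1]}"
        mean_cols[name] = m
        occ_cols[name] = occ
    truth = GroundTruth(
        coupling=config.coupling,
        regional_mean=pd.DataFrame(mean_cols, index=hier.species_ids),
        latent_occupancy=pd.DataFrame(occ_cols, index=hier.species_ids),
    )
    return views, hier, truth


def _hierarchy_newick(hier: _Hierarchy) -> str:
    """The taxonomy hierarchy as a newick tree with unit branch lengths."""
    children: Dict[Tuple[str, int], list] = {}
    # map each clade to its parent clade via species membership
    for fine, coarse in (("class", "phylum"), ("order", "class"), ("family", "order"), ("genus", "family")):
        pairs = set(zip(hier.clade_of[fine], hier.clade_of[coarse]))
        for f_idx, c_idx in pairs:
            children.setdefault((coarse, c_idx), []).append((fine, f_idx))
    for i, g in enumerate(hier.clade_of["genus"]):
        children.setdefault(("genus", g), []).append(("species", i))

    def render(node) -> str:
        rank, idx = node
        if rank == "species":
            return f"{hier.species_ids[idx]}:1.0"
        inner = ",".join(render(c) for c in sorted(children.get(node, [])))
        return f"({inner}){hier.names[rank][idx]}:1.0"

    roots = ",".join(render(("phylum", i)) for i in range(len(hier.names["phylum"])))
    return f"({roots})root;\n"


def generate_dataset(config: SyntheticConfig):
    """Full pre-pooling dataset: replicate count libraries, taxonomy,
    metadata, newick tree and the GroundTruth record.

    Returns ``(CountTable, TaxonomyTable, SampleMetadata, newick_str, GroundTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 2]))
    views, hier, truth = generate_latent_views(config, rng=rng)
    tax = _taxonomy_from_hierarchy(hier, config, rng)
    stations = _station_ids(config)
    cols: Dict[str, np.ndarray] = {}
    meta_rows = []
    rep_tags = [chr(ord("a") + r) for r in range(config.n_replicates)]
    for key in config.subcommunities():
        depth, fraction = key
        latent = views[key].abundance.to_numpy()
        for s_idx, station in enumerate(stations):
            profile = latent[:, s_idx]
            if profile.sum() == 0:
                raise ValueError(f"infeasible config: station {station} has no occupied taxa")
            group = f"{station}_{depth}_{fraction}"
            for tag in rep_tags:
                sample = f"{group}_{tag}"
                q = profile * np.exp(rng.normal(0.0, config.replicate_cv, size=profile.size))
                q = q / q.sum()
                lib = max(int(np.round(rng.lognormal(config.library_size_log_mean,
                                                     config.library_size_log_sigma))),
                          config.library_size_min)
                cols[sample] = rng.multinomial(lib, q)
                meta_rows.append({"sample": sample, "station": station, "depth": depth,
                                  "fraction": fraction, "replicate_group": group})
    counts = pd.DataFrame(cols, index=hier.species_ids)
    counts.index.name = "taxon"
    table = CountTable(counts)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample"))
    newick = _hierarchy_newick(hier)
    return table, tax, meta, newick, truth


def oracle_expected_rho(config: SyntheticConfig, n_large: int = 10000,
                        threshold: float = 0.002, sequencing_depth: Optional[int] = 13339,
                        seed: Optional[int] = None) -> float:
    """Brute-force AOR strength on one very large draw of the survey process.

    Ground-truth target for recovery tests: draws an ``n_large``-species
    community with the *same clade structure* as ``config``, applies the
    detection process a finite sequencing depth implies (a taxon counts as
    present only where at least one read of it would be drawn), builds
    per-taxon records (zero-inclusive mean, occupancy, the low-abundance
    filter) for the first subcommunity, and returns Spearman's rho.

    Per-taxon shares shrink like 1/n, so both the filter threshold and the
    effective sequencing depth are rescaled so that the oracle truncates and
    detects at the same abundance quantiles as a run at ``config.n_species``.
    ``sequencing_depth=None`` skips detection (pure latent rho).
    """
    if n_large < 1000:
        raise ValueError("n_large must be large enough to average out draw noise")
    cfg = replace(config, n_species=n_large, seed=config.seed if seed is None else seed,
                  rank_counts=config.rank_targets(),
                  depths=(config.depths[0],), fractions=(config.fractions[0],))
    views, _, _ = generate_latent_views(cfg)
    view = views[(cfg.depths[0], cfg.fractions[0])]
    scale = config.n_species / n_large
    if sequencing_depth is not None:
        # simulate the measurement at the equivalent per-taxon read depth:
        # Poisson reads give both detection zeros and count noise on the mean
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 3]))
        depth_eff = sequencing_depth / scale
        frac = view.abundance.to_numpy() / 100.0
        # replicate-level lognormal overdispersion survives pooling of the
        # technical replicates at 1/sqrt(n_replicates) strength
        cv = config.replicate_cv / np.sqrt(max(config.n_replicates, 1))
        if cv > 0:
            frac = frac * np.exp(rng.normal(0.0, cv, size=frac.shape) - cv ** 2 / 2)
        reads = rng.poisson(depth_eff * frac)
        observed = pd.DataFrame(reads * (100.0 / depth_eff),
                                index=view.abundance.index, columns=view.abundance.columns)
        view = SubcommunityView(view.depth, view.fraction, observed, rank=view.rank)
    records = build_records(view, threshold=threshold * scale)
    rho, _ = spearman_rho(records["occupancy"].to_numpy(), records["mean_rel_abund"].to_numpy())
    return float(rho)


def write_dataset(out_dir, config: SyntheticConfig) -> Dict[str, str]:
    """Generate a dataset and write it in the file dialects the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, tax, meta, newick, truth = generate_dataset(config)
    paths = {
        "counts": str(out / "counts.tsv"),
        "taxonomy": str(out / "taxonomy.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "tree": str(out / "tree.nwk"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    write_count_table(table, paths["counts"], dialect="matrix")
    write_taxonomy(tax, paths["taxonomy"])
    write_metadata(meta, paths["metadata"])
    Path(paths["tree"]).write_text(newick)
    truth.to_json(paths["ground_truth"])
    return paths
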