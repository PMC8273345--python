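"""Lineage model and rank aggregation.

Operational taxonomic units clustered at 99% 16S similarity are treated as
the species-level taxa.  Every OTU carries a six-rank lineage
(phylum > class > order > family > genus > species); ranks the classifier
could not resolve are filled with *parent-qualified* sentinels
(``unclassified_<deepest classified name>``) so that unresolved taxa under
different parents never merge into a single cosmopolitan pseudo-taxon —
merging them would fabricate occupancy and inflate abundance-occupancy
correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("aortax")

#: Ranks ordered fine -> coarse; "consecutive" always refers to adjacency here.
RANKS = ("species", "genus", "family", "order", "class", "phylum")

#: The same ranks in lineage (coarse -> fine) order.
LINEAGE_ORDER = ("phylum", "class", "order", "family", "genus", "species")

SENTINEL_PREFIX = "unclassified_"
DEFAULT_ROOT = "Bacteria"


def rank_index(rank: str) -> int:
    """Position of ``rank`` in the fine-to-coarse order; raises on unknown rank."""
    try:
        return RANKS.index(rank)
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None


def is_sentinel(name: str) -> bool:
    return name.startswith(SENTINEL_PREFIX)


@dataclass(frozen=True)
class Lineage:
    """An ordered six-rank taxonomic path for one OTU.

    Invariant: once a rank is a sentinel, all finer ranks are sentinels of the
    same deepest classified name (no gaps inside a lineage).
    """

    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str

    def name_at(self, rank: str) -> str:
        if rank == "class":
            return self.class_
        return getattr(self, rank)

    def as_tuple(self) -> tuple:
        return (self.phylum, self.class_, self.order, self.family, self.genus, self.species)

    @property
    def deepest_classified(self) -> str | None:
        last = None
        for name in self.as_tuple():
            if is_sentinel(name):
                break
            last = name
        return last


def normalize_lineage(raw: Sequence[str], root: str = DEFAULT_ROOT) -> Lineage:
    """Normalize a list of rank names (coarse -> fine) into a full Lineage.

    Trailing missing ranks are padded with sentinels; an internal gap (empty
    string mid-lineage) truncates the lineage there, so everything below the
    gap becomes a sentinel of the last name before it.  Total: never raises.
    """
    names: list[str] = []
    deepest = root
    truncated = False
    for name in raw[:6]:
        name = name.strip() if isinstance(name, str) else ""
        if truncated or not name:
            truncated = True
            names.append(SENTINEL_PREFIX + deepest)
        else:
            names.append(name)
            deepest = name
    while len(names) < 6:
        names.append(SENTINEL_PREFIX + deepest)
    return Lineage(*names)


@dataclass
class TaxonomyTable:
    """Mapping of taxon id -> Lineage."""

    lineages: Dict[str, Lineage] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lineages)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages

    def __getitem__(self, taxon_id: str) -> Lineage:
        return self.lineages[taxon_id]

    def ensure_taxa(self, taxon_ids: Iterable[str], root: str = DEFAULT_ROOT) -> int:
        """Add fully-unclassified lineages for taxa missing an entry.

        Returns the number of lineages added (logged by the caller's reader).
        """
        missing = [t for t in taxon_ids if t not in self.lineages]
        for t in missing:
            self.lineages[t] = normalize_lineage([], root=root)
        if missing:
            logger.warning("%d taxa had no taxonomy entry; assigned fully-unclassified lineages", len(missing))
        return len(missing)

    def names_at(self, taxon_ids: Sequence[str], rank: str) -> pd.Series:
        """Rank-level name for each taxon id; species rank returns the id itself."""
        rank_index(rank)
        if rank == "species":
            return pd.Series(list(taxon_ids), index=list(taxon_ids))
        return pd.Series({t: self.lineages[t].name_at(rank) for t in taxon_ids})

    def to_frame(self) -> pd.DataFrame:
        rows = {t: lin.as_tuple() for t, lin in self.lineages.items()}
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(LINEAGE_ORDER))


def aggregate_to_rank(view, tax: TaxonomyTable, rank: str):
    """Collapse a species-level subcommunity view to a coarser rank.

    Abundance of a rank-level taxon at a station is the sum of its member
    species' abundances, so station sums (100%) are conserved exactly up to
    floating point.  Sentinel taxa are retained as first-class rows.
    """
    from .preprocess import SubcommunityView  # local import to avoid cycle

    rank_index(rank)
    if rank == "species":
        return SubcommunityView(view.depth, view.fraction, view.abundance.copy(), rank="species")
    missing = [t for t in view.abundance.index if t not in tax]
    if missing:
        raise KeyError(f"{len(missing)} taxa in view lack a lineage (e.g. {missing[0]!r})")
    names = tax.names_at(list(view.abundance.index), rank)
    agg = view.abundance.groupby(names.values, sort=True).sum()
    agg.index.name = view.abundance.index.name
    return SubcommunityView(view.depth, view.fraction, agg, rank=rank)


def rank_taxon_counts(tax: TaxonomyTable) -> pd.DataFrame:
    """Distinct taxon names per rank, with and without sentinel lineages.

    Species-rank counts are taxon ids (every OTU is its own species-level
    taxon); the "classified" species count excludes OTUs whose species rank
    is a sentinel.
    """
    frame = tax.to_frame()
    rows = {}
    for rank in RANKS:
        if rank == "species":
            total = len(frame)
            classified = int((~frame["species"].map(is_sentinel)).sum())
        else:
            col = frame[rank]
            total = col.nunique()
            classified = col[~col.map(is_sentinel)].nunique()
        rows[rank] = {"n_taxa": total, "n_classified": classified}
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(RANKS)]
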