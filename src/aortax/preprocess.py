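"""Table-level preprocessing of the OTU count matrix.

Fixed stage order: pool technical replicates (raw counts) -> remove
singleton/doubleton OTUs (totals over all pre-pooling libraries) -> rarefy
every pooled sample to a common depth -> convert to percent relative
abundance -> split into the four (depth x size-fraction) subcommunities.
Rarefaction is a seeded multivariate-hypergeometric draw (subsampling
without replacement), one draw per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from ._util import child_rng
from .io_tables import CountTable, SampleMetadata
from .taxonomy import rank_index

logger = logging.getLogger("aortax")


@dataclass
class SubcommunityView:
    """Station-indexed percent-abundance matrix for one depth x fraction cell."""

    depth: str
    fraction: str
    abundance: pd.DataFrame  # index: taxa, columns: station ids, percent units
    rank: str = "species"

    def __post_init__(self) -> None:
        rank_index(self.rank)

    @property
    def station_ids(self) -> list:
        return list(self.abundance.columns)

    @property
    def n_stations(self) -> int:
        return self.abundance.shape[1]

    @property
    def key(self) -> Tuple[str, str]:
        return (self.depth, self.fraction)

    @property
    def name(self) -> str:
        return f"{self.depth}_{self.fraction}"


def pool_technical_replicates(table: CountTable, meta: SampleMetadata) -> Tuple[CountTable, SampleMetadata]:
    """Sum raw counts within each technical-replicate group.

    The pooled sample is named by its replicate group; metadata collapses to
    one row per group.  Groups must be homogeneous in (station, depth,
    fraction).
    """
    frame = meta.frame.loc[[s for s in table.sample_ids if s in meta.frame.index]]
    missing = [s for s in table.sample_ids if s not in meta.frame.index]
    if missing:
        raise ValueError(f"samples without metadata cannot be pooled: {missing[:5]}")
    for group, sub in frame.groupby("replicate_group"):
        if sub[["station", "depth", "fraction"]].drop_duplicates().shape[0] > 1:
            raise ValueError(f"replicate group {group!r} mixes different (station, depth, fraction)")
    groups = frame["replicate_group"]
    pooled = table.data[frame.index].T.groupby(groups, sort=True).sum().T
    meta_rows = frame.groupby("replicate_group", sort=True).first()[["station", "depth", "fraction"]]
    meta_rows["replicate_group"] = meta_rows.index
    pooled_meta = SampleMetadata(meta_rows)
    return CountTable(pooled), pooled_meta


def remove_rare_otus(table: CountTable, max_total: int = 2) -> CountTable:
    """Drop taxa whose grand total across all libraries is <= ``max_total``.

    With the default of 2 this removes singleton and doubleton OTUs, the
    standard guard against sequencing-error taxa.  Totals are computed on the
    table as given, i.e. across all (pre-pooling) libraries.
    """
    if max_total < 0:
        raise ValueError("max_total must be >= 0")
    totals = table.data.sum(axis=1)
    keep = totals > max_total
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("removed %d taxa with total counts <= %d", n_dropped, max_total)
    return CountTable(table.data.loc[keep])


def rarefy(table: CountTable, depth: int | str = "min", seed: int = 0, on_shallow: str = "drop") -> CountTable:
    """Subsample every sample to a common depth without replacement.

    Each sample gets an independent multivariate-hypergeometric draw seeded
    from the master seed plus the sample id, so results are reproducible and
    independent of column order.  Samples with fewer reads than the target
    are dropped with a warning (``on_shallow='error'`` raises instead).
    """
    totals = table.sample_totals()
    if depth == "min":
        nonzero = totals[totals > 0]
        if nonzero.empty:
            raise ValueError("cannot rarefy: all samples have zero total")
        depth = int(nonzero.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be > 0")
    shallow = list(totals.index[totals < depth])
    if shallow:
        if on_shallow == "error":
            raise ValueError(f"samples shallower than depth {depth}: {shallow}")
        logger.warning("dropping %d sample(s) shallower than depth %d: %s", len(shallow), depth, shallow)
    cols = {}
    for sample in table.sample_ids:
        if sample in shallow:
            continue
        counts = table.data[sample].to_numpy()
        if totals[sample] == depth:
            cols[sample] = counts
        else:
            rng = child_rng(seed, sample)
            cols[sample] = rng.multivariate_hypergeometric(counts, depth, method="marginals")
    out = pd.DataFrame(cols, index=table.data.index)
    return CountTable(out)


def to_relative_abundance(table: CountTable) -> pd.DataFrame:
    """Convert counts to percent relative abundance; columns sum to 100 exactly."""
    totals = table.sample_totals()
    zero = list(totals.index[totals == 0])
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    abund = table.data.astype(float) * (100.0 / totals)
    # Fold the (<=1e-9) float residual into each column's largest entry: the
    # largest is never zero, so presence/absence structure is untouched.
    arr = abund.to_numpy()
    residual = 100.0 - arr.sum(axis=0)
    arr[arr.argmax(axis=0), np.arange(arr.shape[1])] += residual
    return pd.DataFrame(arr, index=abund.index, columns=abund.columns)


def split_subcommunities(abund: pd.DataFrame, meta: SampleMetadata) -> Dict[Tuple[str, str], SubcommunityView]:
    """Split a sample-level abundance matrix into the four subcommunity views.

    Requires pooled metadata (one sample per station/depth/fraction).
    Station ordering is identical across views; a station with no sample in a
    view is simply absent there (and that view's occupancy denominator is its
    own station count).
    """
    frame = meta.frame.loc[[s for s in abund.columns if s in meta.frame.index]]
    stations = sorted(frame["station"].unique())
    views: Dict[Tuple[str, str], SubcommunityView] = {}
    for (depth, fraction), sub in frame.groupby(["depth", "fraction"], sort=True):
        if sub.duplicated(subset=["station"]).any():
            dup = sub[sub.duplicated(subset=["station"])]["station"].iloc[0]
            raise ValueError(f"two samples map to station {dup!r} in {depth}_{fraction}")
        by_station = {row["station"]: sample for sample, row in sub.iterrows()}
        present = [st for st in stations if st in by_station]
        if len(present) < len(stations):
            logger.warning("%s_%s has %d of %d stations", depth, fraction, len(present), len(stations))
        mat = abund[[by_station[st] for st in present]].copy()
        mat.columns = present
        views[(depth, fraction)] = SubcommunityView(depth, fraction, mat, rank="species")
    return views
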