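"""Abundance-occupancy statistics, ecological classification, and the
cross-rank niche-width comparison.

For each subcommunity (depth x size fraction) and each taxonomic rank:

* occupancy = number of stations where a taxon has nonzero abundance;
* mean relative abundance = average percent abundance over ALL stations,
  zeros included (absence is ecological signal, not missing data);
* taxa with mean abundance < 0.002% are excluded as chance occurrences;
* taxa occupying > 50% of stations are habitat generalists, < 25%
  specialists, the rest "neither" (at 9 stations: >=6 and <=2);
* AOR strength = Spearman's rho between occupancy and mean abundance,
  Benjamini-Hochberg corrected across the family of per-rank tests;
* niche-width index = OLS slope of ln(mean abundance) on occupancy.

Slopes at each rank (the four subcommunities as replicates) feed a one-way
ANOVA with Shapiro-Wilk residual normality check and Tukey(-Kramer) HSD,
plus fold changes of the slope between consecutive ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import SubcommunityView
from .taxonomy import RANKS, TaxonomyTable, aggregate_to_rank, is_sentinel

logger = logging.getLogger("aortax")

CATEGORIES = ("generalist", "specialist", "neither")

RECORD_COLUMNS = ["taxon", "rank", "depth", "fraction", "occupancy", "n_stations", "mean_rel_abund", "category"]


def compute_occupancy(view: SubcommunityView) -> pd.Series:
    """Stations with abundance > 0 per taxon; all-zero taxa are dropped."""
    occ = (view.abundance > 0).sum(axis=1)
    return occ[occ > 0].astype(int)


def compute_mean_abundance(view: SubcommunityView) -> pd.Series:
    """Mean percent abundance over all stations of the view, zeros included."""
    return view.abundance.mean(axis=1)


def classify_category(occupancy: int, n_stations: int,
                      generalist_min_frac: float = 0.5,
                      specialist_max_frac: float = 0.25) -> str:
    """Habitat category from occupancy.

    Generalists must exceed the generalist fraction after rounding the
    station threshold up (at 9 stations with the 50% default: 6 or more
    stations, the convention of field AOR studies); specialists occupy
    strictly less than the specialist fraction (at 9 stations: 2 or fewer);
    everything else is "neither".
    """
    if not 1 <= occupancy <= n_stations:
        raise ValueError(f"occupancy {occupancy} outside 1..{n_stations}")
    if occupancy > np.ceil(n_stations * generalist_min_frac):
        return "generalist"
    if occupancy / n_stations < specialist_max_frac:
        return "specialist"
    return "neither"


def filter_low_abundance(records: pd.DataFrame, threshold: float = 0.002) -> pd.DataFrame:
    """Drop records with mean relative abundance strictly below ``threshold``
    (percent).  The boundary value itself is retained."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return records[records["mean_rel_abund"] >= threshold].copy()


def build_records(view: SubcommunityView, threshold: float = 0.002,
                  generalist_min_frac: float = 0.5, specialist_max_frac: float = 0.25,
                  drop_unclassified: bool = False) -> pd.DataFrame:
    """One record per retained taxon of a view: occupancy, mean abundance,
    category.  Sentinel (unclassified) taxa are kept by default — they are
    real abundance mass."""
    occ = compute_occupancy(view)
    mean = compute_mean_abundance(view)
    records = pd.DataFrame({
        "taxon": occ.index,
        "rank": view.rank,
        "depth": view.depth,
        "fraction": view.fraction,
        "occupancy": occ.values,
        "n_stations": view.n_stations,
        "mean_rel_abund": mean.loc[occ.index].values,
    })
    if drop_unclassified:
        records = records[~records["taxon"].map(is_sentinel)]
    records = filter_low_abundance(records, threshold)
    records["category"] = [
        classify_category(o, s, generalist_min_frac, specialist_max_frac)
        for o, s in zip(records["occupancy"], records["n_stations"])
    ]
    return records.reset_index(drop=True)[RECORD_COLUMNS]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman's rank correlation with midranks for ties.

    p-value from the two-sided t approximation with n-2 degrees of freedom
    (rho = +-1 gives p = 0).  Constant input has undefined rho: returns
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input to Spearman correlation; rho undefined")
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries (undefined tests) pass through as NaN and do not count
    toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def aor_strength(records: pd.DataFrame) -> Tuple[float, float, int]:
    """AOR strength for one rank in one subcommunity: Spearman's rho between
    occupancy and mean relative abundance over all retained taxa."""
    n = len(records)
    if n < 3:
        logger.warning("fewer than 3 records; AOR strength undefined")
        return (float("nan"), float("nan"), n)
    rho, p = spearman_rho(records["occupancy"].to_numpy(), records["mean_rel_abund"].to_numpy())
    return rho, p, n


def niche_width_index(records: pd.DataFrame) -> Tuple[float, float]:
    """Niche-width index: OLS slope of ln(mean percent abundance) on occupancy.

    Natural log; slope units are ln-percent per station.  A steeper slope
    means abundance climbs faster with occupancy, read as broader niche
    differentiation at that rank.
    """
    if len(records) < 3:
        logger.warning("fewer than 3 records; niche-width slope undefined")
        return (float("nan"), float("nan"))
    y = records["mean_rel_abund"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("zero/negative abundance reached the slope regression")
    x = records["occupancy"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        logger.warning("constant occupancy; niche-width slope undefined")
        return (float("nan"), float("nan"))
    res = stats.linregress(x, np.log(y))
    return float(res.slope), float(res.intercept)


def category_proportions(records: pd.DataFrame) -> Tuple[float, float, float]:
    """(generalist, specialist, neither) fractions over retained taxa."""
    if len(records) == 0:
        raise ValueError("no records")
    counts = records["category"].value_counts()
    n = len(records)
    return tuple(float(counts.get(c, 0)) / n for c in CATEGORIES)


def rank_statistics(views: Mapping[Tuple[str, str], SubcommunityView], tax: TaxonomyTable,
                    threshold: float = 0.002, generalist_min_frac: float = 0.5,
                    specialist_max_frac: float = 0.25, drop_unclassified: bool = False,
                    bh_family: str = "run") -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-rank, per-subcommunity AOR statistics for all views.

    Returns ``(records, stats)``: the per-taxon record table across every
    rank and subcommunity, and the 6-ranks x n-views statistics table (rho,
    p, BH-adjusted p, slope, intercept, category fractions).  ``bh_family``
    is either ``"run"`` (all tests of the run adjusted together, the
    default 6 x 4 = 24 member family) or ``"per_subcommunity"``.
    """
    if bh_family not in ("run", "per_subcommunity"):
        raise ValueError("bh_family must be 'run' or 'per_subcommunity'")
    all_records: List[pd.DataFrame] = []
    rows: List[dict] = []
    for key in sorted(views):
        view = views[key]
        for rank in RANKS:
            agg = aggregate_to_rank(view, tax, rank)
            recs = build_records(agg, threshold, generalist_min_frac, specialist_max_frac, drop_unclassified)
            all_records.append(recs)
            rho, p, n = aor_strength(recs)
            slope, intercept = niche_width_index(recs) if n >= 3 else (float("nan"), float("nan"))
            if n:
                frac_g, frac_s, frac_n = category_proportions(recs)
            else:
                frac_g = frac_s = frac_n = float("nan")
            rows.append({
                "rank": rank, "depth": view.depth, "fraction": view.fraction,
                "n_taxa": n, "rho": rho, "p_value": p, "p_adjusted": np.nan,
                "slope": slope, "intercept": intercept,
                "frac_generalist": frac_g, "frac_specialist": frac_s, "frac_neither": frac_n,
            })
    stats_df = pd.DataFrame(rows)
    if bh_family == "run":
        stats_df["p_adjusted"] = bh_adjust(stats_df["p_value"])
    else:
        for key, idx in stats_df.groupby(["depth", "fraction"]).groups.items():
            stats_df.loc[idx, "p_adjusted"] = bh_adjust(stats_df.loc[idx, "p_value"])
    records_df = pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame(columns=RECORD_COLUMNS)
    return records_df, stats_df


def fold_change_consecutive(slopes: Mapping[str, float]) -> pd.DataFrame:
    """Fold change of the niche-width slope between consecutive ranks.

    ratio = slope(coarser) / slope(finer) for the five adjacent pairs in
    fine-to-coarse order; the class->phylum pair is flagged when it is the
    maximal ratio.  A sign change or zero slope yields a missing ratio.
    """
    missing = [r for r in RANKS if r not in slopes]
    if missing:
        raise ValueError(f"slopes missing for ranks: {missing}")
    rows = []
    for finer, coarser in zip(RANKS[:-1], RANKS[1:]):
        a, b = float(slopes[finer]), float(slopes[coarser])
        if a == 0 or np.isnan(a) or np.isnan(b) or (a > 0) != (b > 0):
            logger.warning("fold change %s->%s undefined (zero or sign change)", finer, coarser)
            ratio = float("nan")
        else:
            ratio = b / a
        rows.append({"finer_rank": finer, "coarser_rank": coarser, "ratio": ratio})
    df = pd.DataFrame(rows)
    valid = df["ratio"].dropna()
    df["is_max"] = False
    if len(valid):
        df.loc[valid.idxmax(), "is_max"] = True
    return df


@dataclass
class RankComparison:
    """Cross-rank ANOVA of niche-width slopes with Tukey HSD follow-up."""

    slopes: pd.DataFrame           # columns: rank, depth, fraction, slope
    f_statistic: float
    anova_p: float
    shapiro_p: float
    tukey: pd.DataFrame            # columns: rank_a, rank_b, p_adjusted, significant
    letters: Dict[str, str]        # homogeneous-group letters per rank
    fold_changes: pd.DataFrame = field(default_factory=pd.DataFrame)  # per subcommunity

    def to_frame(self) -> pd.DataFrame:
        rows = [{"statistic": "anova_F", "value": self.f_statistic},
                {"statistic": "anova_p", "value": self.anova_p},
                {"statistic": "shapiro_p", "value": self.shapiro_p}]
        return pd.DataFrame(rows)


def _group_letters(ranks: Sequence[str], means: Mapping[str, float],
                   significant: Mapping[Tuple[str, str], bool]) -> Dict[str, str]:
    """Greedy homogeneous-group lettering over ranks ordered by mean.

    Two ranks share a letter iff they belong to a common group in which no
    pair is significantly different (insertion greedily left to right).
    """
    ordered = sorted(ranks, key=lambda r: means[r])
    groups: List[List[str]] = []
    for r in ordered:
        placed = False
        for g in groups:
            if all(not significant.get(tuple(sorted((r, o))), False) for o in g):
                g.append(r)
                placed = True
        if not placed:
            groups.append([r])
    # drop groups fully contained in another
    groups = [g for g in groups if not any(set(g) < set(h) for h in groups if h is not g)]
    letters: Dict[str, str] = {r: "" for r in ranks}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for r in g:
            letters[r] += letter
    return {r: "".join(sorted(letters[r])) for r in ranks}


def anova_across_ranks(slopes: pd.DataFrame, alpha: float = 0.05) -> RankComparison:
    """One-way ANOVA of niche-width slopes across ranks.

    ``slopes`` needs columns rank, depth, fraction, slope; the subcommunities
    act as replicates within each rank.  Unequal replicate counts are handled
    by Tukey-Kramer.  Shapiro-Wilk is run on residuals from the group means.
    """
    slopes = slopes.dropna(subset=["slope"])
    groups = {r: g["slope"].to_numpy(dtype=float) for r, g in slopes.groupby("rank") if len(g) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 ranks with >= 2 replicates each")
    ordered_ranks = [r for r in RANKS if r in groups]
    arrays = [groups[r] for r in ordered_ranks]
    f_stat, anova_p = stats.f_oneway(*arrays)
    residuals = np.concatenate([a - a.mean() for a in arrays])
    shapiro_p = float(stats.shapiro(residuals).pvalue)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    significant: Dict[Tuple[str, str], bool] = {}
    for i in range(len(ordered_ranks)):
        for j in range(i + 1, len(ordered_ranks)):
            p_adj = float(hsd.pvalue[i, j])
            pair = tuple(sorted((ordered_ranks[i], ordered_ranks[j])))
            significant[pair] = p_adj < alpha
            rows.append({"rank_a": ordered_ranks[i], "rank_b": ordered_ranks[j],
                         "p_adjusted": p_adj, "significant": p_adj < alpha})
    tukey = pd.DataFrame(rows)
    means = {r: float(np.mean(groups[r])) for r in ordered_ranks}
    letters = _group_letters(ordered_ranks, means, significant)
    folds = []
    for (depth, fraction), sub in slopes.groupby(["depth", "fraction"]):
        if set(sub["rank"]) >= set(RANKS):
            fc = fold_change_consecutive(dict(zip(sub["rank"], sub["slope"])))
            fc.insert(0, "depth", depth)
            fc.insert(1, "fraction", fraction)
            folds.append(fc)
    fold_df = pd.concat(folds, ignore_index=True) if folds else pd.DataFrame()
    return RankComparison(slopes.reset_index(drop=True), float(f_stat), float(anova_p),
                          shapiro_p, tukey, letters, fold_df)
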