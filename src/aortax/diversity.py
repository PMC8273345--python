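"""Alpha- and beta-diversity: richness, Pielou's evenness, Faith's PD,
Bray-Curtis dissimilarity and the ANOSIM permutation test.

Alpha metrics are meant to run on the rarefied count table so richness is
comparable across samples.  Faith's PD follows the root-inclusive
convention (branch lengths on the paths from the tree root to every present
tip); a crown-group variant measuring only from the most recent common
ancestor is available via ``include_root=False``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import rankdata

from .io_tables import CountTable

logger = logging.getLogger("aortax")


def observed_richness(counts: Sequence[float]) -> int:
    """Number of taxa with count > 0."""
    return int(np.count_nonzero(np.asarray(counts)))


def pielou_evenness(counts: Sequence[float]) -> float:
    """Shannon index (natural log) divided by ln(observed richness).

    Undefined (NaN) for fewer than two present taxa.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size < 2:
        logger.warning("evenness undefined for richness < 2")
        return float("nan")
    p = c / c.sum()
    shannon = -np.sum(p * np.log(p))
    return float(shannon / np.log(c.size))


def faith_pd(present: Iterable[str], tree: skbio.TreeNode, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a set of present tips.

    Sum of branch lengths of the minimal subtree connecting the present tips
    to the root (default) or to their most recent common ancestor
    (``include_root=False``).  An edge counts when its subtree contains at
    least one present tip.
    """
    present = set(present)
    if not present:
        return 0.0
    tip_names = {t.name for t in tree.tips()}
    unknown = present - tip_names
    if unknown:
        raise KeyError(f"tips not in tree: {sorted(unknown)[:5]}")
    # postorder: mark each node whether its subtree holds a present tip
    has_present: dict = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            has_present[id(node)] = node.name in present
        else:
            has_present[id(node)] = any(has_present[id(c)] for c in node.children)
    anchor = tree
    if not include_root:
        anchor = tree.lca([t for t in tree.tips() if t.name in present]) if len(present) > 1 else \
            next(t for t in tree.tips() if t.name in present)
    total = 0.0
    for node in anchor.postorder(include_self=False):
        if has_present[id(node)]:
            total += node.length or 0.0
    return float(total)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def bray_curtis_matrix(abund: pd.DataFrame) -> skbio.DistanceMatrix:
    """All-pairs Bray-Curtis over the columns (samples) of an abundance table."""
    ids = list(abund.columns)
    n = len(ids)
    mat = np.zeros((n, n))
    cols = abund.to_numpy().T
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(cols[i], cols[j])
    return skbio.DistanceMatrix(mat, ids=ids)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n_pairs = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (n_pairs / 2.0))


def anosim(dm: skbio.DistanceMatrix, labels: Sequence[str], n_perm: int = 999,
           seed: int = 0) -> Tuple[float, float]:
    """Analysis of similarity on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 midranked pairwise distances; the p-value is the add-one
    permutation estimator (1 + #{R_perm >= R_obs}) / (n_perm + 1).
    Deterministic for a fixed seed.  Every group needs >= 2 samples.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if dm.shape[0] != n:
        raise ValueError("labels do not match distance matrix size")
    uniques, counts = np.unique(labels, return_counts=True)
    if len(uniques) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if np.any(counts < 2):
        small = uniques[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    dist = dm.condensed_form()
    ranks = rankdata(dist)  # midranks
    iu = np.triu_indices(n, k=1)

    def within_mask(lab: np.ndarray) -> np.ndarray:
        return lab[iu[0]] == lab[iu[1]]

    r_obs = _anosim_r(ranks, within_mask(labels))
    rng = np.random.default_rng(seed)
    n_ge = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if _anosim_r(ranks, within_mask(lab)) >= r_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return r_obs, float(p)


def diversity_table(table: CountTable, tree: Optional[skbio.TreeNode] = None) -> pd.DataFrame:
    """Per-sample alpha diversity: richness, evenness and (with a tree)
    Faith's PD, from the (ideally rarefied) count table."""
    rows = []
    for sample in table.sample_ids:
        counts = table.data[sample]
        present = counts.index[counts > 0]
        row = {
            "sample": sample,
            "richness": observed_richness(counts),
            "evenness": pielou_evenness(counts),
        }
        if tree is not None:
            row["faith_pd"] = faith_pd(present, tree)
        rows.append(row)
    return pd.DataFrame(rows)
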