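"""Readers and writers for the tabular formats the pipeline touches.

Count tables come either as a plain taxa-by-samples TSV matrix or as a
mothur ``.shared`` file (samples as rows, ``label``/``Group``/``numOtus``
bookkeeping columns).  Taxonomy is the mothur two-column ``.taxonomy``
format with semicolon-delimited lineages and optional bootstrap-confidence
suffixes.  All abundance outputs are on the percent scale (0-100).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import skbio

from ._util import output_header
from .taxonomy import DEFAULT_ROOT, TaxonomyTable, normalize_lineage

logger = logging.getLogger("aortax")

DEPTHS = ("surface", "CIL")
FRACTIONS = ("FL", "PA")

_CONFIDENCE_RE = re.compile(r"\(\d+(\.\d+)?\)$")


class TableValidationError(ValueError):
    """A parsed table violates a structural contract."""


@dataclass
class CountTable:
    """Integer taxa-by-samples count matrix; the currency of preprocessing."""

    data: pd.DataFrame  # index: taxon ids, columns: sample ids, int64

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate taxon ids: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableValidationError("non-numeric counts present")
        if np.any(arr < 0):
            t, s = np.argwhere(arr < 0)[0]
            raise TableValidationError(f"negative count at taxon {df.index[t]!r}, sample {df.columns[s]!r}")
        if not np.allclose(arr, np.round(arr)):
            t, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise TableValidationError(f"non-integer count at taxon {df.index[t]!r}, sample {df.columns[s]!r}")
        self.data = df.astype(np.int64)
        self.data.index.name = "taxon"
        self.data.columns.name = None
        empty = self.data.columns[self.data.sum(axis=0) == 0]
        if len(empty):
            logger.warning("samples with zero total counts (kept): %s", list(empty))

    @property
    def taxon_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)


def read_count_table(path, dialect: str = "matrix") -> CountTable:
    """Read a count table from ``path`` in the given dialect.

    ``matrix``: rows are taxa, first column taxon ids, header row of sample
    ids.  ``mothur_shared``: rows are samples with ``label``, ``Group`` and
    ``numOtus`` columns; the matrix is transposed on read so both dialects
    yield identical in-memory tables.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableValidationError(f"cannot parse {path}: {exc}") from exc
    if df.empty or df.shape[1] < 2:
        raise TableValidationError(f"{path}: malformed header or empty table (line 1)")
    if dialect == "mothur_shared":
        expected = {"label", "Group", "numOtus"}
        if not expected.issubset(df.columns):
            raise TableValidationError(f"{path}: mothur shared file must have columns {sorted(expected)}")
        labels = df["label"].unique()
        if len(labels) > 1:
            raise TableValidationError(f"{path}: multiple OTU labels present: {labels}")
        df = df.set_index("Group").drop(columns=["label", "numOtus"]).T
        df.index.name = "taxon"
    elif dialect == "matrix":
        df = df.set_index(df.columns[0])
        df.index.name = "taxon"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableValidationError(f"{path}: non-numeric cell: {exc}") from exc
    return CountTable(values)


def write_count_table(table: CountTable, path, dialect: str = "matrix") -> None:
    path = Path(path)
    if dialect == "matrix":
        out = table.data.copy()
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")
    elif dialect == "mothur_shared":
        wide = table.data.T
        out = pd.DataFrame({"label": "0.01", "Group": wide.index, "numOtus": wide.shape[1]})
        out = pd.concat([out.reset_index(drop=True), wide.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_taxonomy(path, has_domain_prefix: bool = True, root: str = DEFAULT_ROOT) -> TaxonomyTable:
    """Read a two-column mothur-style taxonomy file.

    Bootstrap-confidence suffixes like ``Proteobacteria(100)`` are stripped.
    With ``has_domain_prefix`` (default, SILVA-style output) the leading
    domain rank is dropped so at most six ranks remain.
    """
    path = Path(path)
    lineages: Dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TableValidationError(f"{path}:{lineno}: expected 2 tab-separated columns")
            taxon_id, lineage_str = parts
            if taxon_id in lineages:
                raise TableValidationError(f"{path}:{lineno}: duplicate taxon id {taxon_id!r}")
            names = [_CONFIDENCE_RE.sub("", n.strip()) for n in lineage_str.strip().strip(";").split(";")]
            names = [n for n in names] if names != [""] else []
            if has_domain_prefix and names:
                names = names[1:]
            if len(names) > 6:
                raise TableValidationError(f"{path}:{lineno}: lineage has {len(names)} ranks (max 6)")
            lineages[taxon_id] = normalize_lineage(names, root=root)
    return TaxonomyTable(lineages)


def write_taxonomy(tax: TaxonomyTable, path, domain: Optional[str] = DEFAULT_ROOT) -> None:
    """Write a taxonomy table in the two-column semicolon-delimited format."""
    with open(path, "w") as fh:
        for taxon_id, lin in tax.lineages.items():
            names = list(lin.as_tuple())
            if domain:
                names = [domain] + names
            fh.write(f"{taxon_id}\t{';'.join(names)};\n")


@dataclass
class SampleMetadata:
    """Sample id -> (station, depth, fraction, replicate_group)."""

    frame: pd.DataFrame  # index: sample id; columns: station, depth, fraction, replicate_group

    def __post_init__(self) -> None:
        df = self.frame
        required = {"station", "depth", "fraction"}
        if not required.issubset(df.columns):
            raise TableValidationError(f"metadata missing columns: {sorted(required - set(df.columns))}")
        if df.index.has_duplicates:
            raise TableValidationError("duplicated sample rows in metadata")
        depth_map = {d.lower(): d for d in DEPTHS}
        frac_map = {f.lower(): f for f in FRACTIONS}
        try:
            df["depth"] = [depth_map[str(d).lower()] for d in df["depth"]]
        except KeyError as exc:
            raise TableValidationError(f"unknown depth {exc.args[0]!r}; allowed: {DEPTHS}") from None
        try:
            df["fraction"] = [frac_map[str(f).lower()] for f in df["fraction"]]
        except KeyError as exc:
            raise TableValidationError(f"unknown fraction {exc.args[0]!r}; allowed: {FRACTIONS}") from None
        if "replicate_group" not in df.columns:
            df["replicate_group"] = pd.Series(df.index, index=df.index)
        df["replicate_group"] = df["replicate_group"].fillna(pd.Series(df.index, index=df.index))
        # a replicate group names exactly one (station, depth, fraction) cell,
        # and each cell is covered by exactly one group
        cells = df[["station", "depth", "fraction", "replicate_group"]].drop_duplicates()
        if cells["replicate_group"].duplicated().any():
            g = cells.loc[cells["replicate_group"].duplicated(), "replicate_group"].iloc[0]
            raise TableValidationError(f"replicate group {g!r} spans multiple (station, depth, fraction) cells")
        if cells[["station", "depth", "fraction"]].duplicated().any():
            c = cells.loc[cells[["station", "depth", "fraction"]].duplicated(),
                          ["station", "depth", "fraction"]].iloc[0].tolist()
            raise TableValidationError(f"multiple replicate groups map to cell {c}")
        self.frame = df

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


def read_metadata(path, count_table: Optional[CountTable] = None) -> SampleMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise TableValidationError(f"{path}: metadata requires a 'sample' column")
    if df["sample"].duplicated().any():
        raise TableValidationError(f"{path}: duplicated sample row(s)")
    df = df.set_index("sample")
    meta = SampleMetadata(df)
    if count_table is not None:
        missing = [s for s in meta.sample_ids if s not in count_table.sample_ids]
        if missing:
            logger.warning("metadata samples absent from count table: %s", missing)
    return meta


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_newick(path) -> skbio.TreeNode:
    """Read a single-tree newick file; missing branch lengths default to 0."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if tree.length is None:
        tree.length = 0.0  # root edge: no warning, roots normally carry none
    if n_missing:
        logger.warning("%d branch lengths missing; defaulted to 0", n_missing)
    return tree


def write_records(records: pd.DataFrame, path, cfg_hash: str = "na") -> None:
    """Write a result table as TSV with a provenance header comment.

    Column order is preserved as given (stable); percent-scale fields are
    serialized on the percent scale.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(output_header(cfg_hash) + "\n")
        records.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
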