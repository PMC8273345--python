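import logging

import numpy as np
import pandas as pd
import pytest

from aortax.io_tables import CountTable, SampleMetadata
from aortax.preprocess import SubcommunityView
from aortax.taxonomy import Lineage, TaxonomyTable, normalize_lineage

logging.getLogger("aortax").setLevel(logging.ERROR)


@pytest.fixture
def tiny_counts() -> CountTable:
    data = pd.DataFrame(
        {"S1": [3, 0, 5], "S2": [1, 2, 0], "S3": [0, 0, 7]},
        index=["OTU1", "OTU2", "OTU3"],
    )
    return CountTable(data)


@pytest.fixture
def tiny_taxonomy() -> TaxonomyTable:
    return TaxonomyTable({
        "OTU1": normalize_lineage(["P1", "C1", "O1", "F1", "G1"]),
        "OTU2": normalize_lineage(["P1", "C1", "O1", "F1", "G1"]),
        "OTU3": normalize_lineage(["P2", "C2"]),
    })


@pytest.fixture
def simple_view() -> SubcommunityView:
    abund = pd.DataFrame(
        np.array([
            [40.0, 60.0, 0.0],
            [30.0, 0.0, 50.0],
            [30.0, 40.0, 50.0],
        ]),
        index=["OTU1", "OTU2", "OTU3"],
        columns=["st1", "st2", "st3"],
    )
    return SubcommunityView("surface", "FL", abund, rank="species")


def full_design_metadata(n_stations: int = 9, replicates: int = 2) -> SampleMetadata:
    rows = []
    for i in range(n_stations):
        for depth in ("surface", "CIL"):
            for fraction in ("FL", "PA"):
                group = f"st{i+1}_{depth}_{fraction}"
                for tag in "ab"[:replicates]:
                    rows.append({"sample": f"{group}_{tag}", "station": f"st{i+1}",
                                 "depth": depth, "fraction": fraction, "replicate_group": group})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample"))
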