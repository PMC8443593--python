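import numpy as np
import pandas as pd
import pytest

from habspec.core_tables import CountTable, TaxonomyMap


def make_table(counts: dict[str, list[int]], taxa: list[str], meta: dict | None = None) -> CountTable:
    """Small CountTable from {sample: column} dict and taxon row ids."""
    df = pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"), dtype=np.int64)
    if meta is None:
        meta_df = pd.DataFrame(
            {"zone": "z", "depth_layer": "d", "date": 0},
            index=pd.Index(df.columns, name="sample_id"),
        )
    else:
        meta_df = pd.DataFrame(meta, index=pd.Index(df.columns, name="sample_id"))
    return CountTable(df, meta_df)


@pytest.fixture
def toy_table() -> CountTable:
    """3 taxa x 3 samples with a singleton taxon and a shallow sample."""
    return make_table(
        {"s1": [5, 1, 0], "s2": [3, 0, 2], "s3": [2, 0, 0]},
        taxa=["tA", "tB", "tC"],
    )


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    lineages = pd.DataFrame(
        {
            "phylum": ["Proteobacteria", "Proteobacteria", "Bacteroidota"],
            "class": ["Gammaproteobacteria", "Gammaproteobacteria", "Bacteroidia"],
            "order": ["Woeseiales", "Woeseiales", "unassigned"],
            "family": ["Woeseiaceae", "unassigned", "unassigned"],
            "genus": ["Woeseia", "unassigned", "unassigned"],
        },
        index=pd.Index(["tA", "tB", "tC"], name="taxon_id"),
    )
    return TaxonomyMap(lineages)
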