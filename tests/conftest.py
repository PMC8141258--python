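import numpy as np
import pandas as pd
import pytest

from th17translate.io_formats import (
    CellCompendium,
    DEGTable,
    ExpressionMatrix,
    GeneSetCollection,
    PDTable,
)


def make_deg(genes, log_ratios, p=None, p_adj=None, study_id="s1", species="human"):
    n = len(genes)
    df = pd.DataFrame(
        {
            "gene": list(genes),
            "log_ratio": list(log_ratios),
            "p": list(p) if p is not None else [0.01] * n,
            "p_adj_fdr": list(p_adj) if p_adj is not None else [0.01] * n,
        }
    )
    return DEGTable(study_id=study_id, species=species, data=df)


def make_matrix(values, genes=None, samples=None, group="g"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_group={s: group for s in samples},
    )


def make_pd_table(endpoint_means, n_per_group=3, exposures=None):
    """endpoint_means: {endpoint: {group: mean}}; constant values per group."""
    exposures = exposures or {}
    rows = []
    for endpoint, by_group in endpoint_means.items():
        for group, mean in by_group.items():
            for i in range(n_per_group):
                rows.append(
                    {
                        "animal_id": f"{group}_{endpoint}_{i}",
                        "group": group,
                        "endpoint": endpoint,
                        "value": float(mean),
                        "trough_exposure": exposures.get(group, np.nan),
                    }
                )
    return PDTable(data=pd.DataFrame(rows))


@pytest.fixture
def gmt_collection():
    c = GeneSetCollection()
    c.add("TH17SIG", ["CXCL1", "CXCL2", "CXCL3", "IL8"], "th17 surrogate")
    c.add("OTHER", ["DUOXA2", "S100A7A", "CCL20"], "second list")
    return c


@pytest.fixture
def toy_compendium():
    rng = np.random.default_rng(42)
    ref = rng.standard_normal((60, 4))
    return CellCompendium(
        reference=pd.DataFrame(ref, index=[f"G{i}" for i in range(60)], columns=list("ABCD"))
    )
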