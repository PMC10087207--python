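import numpy as np
import pandas as pd
import pytest

from microsig.io import CountMatrix, ExpressionMatrix, ReferenceAtlas
from microsig.simulate import SimConfig, annotation_from_truth, simulate_atlas, simulate_counts


# a desk-scale version of the full study design: same sample layout,
# fewer genes, all planted classes represented
SMALL_CFG = SimConfig(
    n_genes=3000,
    n_core=60,
    n_contaminated=50,
    n_tissue_shared=40,
    n_macrophage=50,
    n_regional=60,
)


@pytest.fixture(scope="session")
def sim():
    counts, truth = simulate_counts(SMALL_CFG, seed=11)
    return counts, truth


@pytest.fixture(scope="session")
def sim_counts(sim):
    return sim[0]


@pytest.fixture(scope="session")
def sim_truth(sim):
    return sim[1]


@pytest.fixture(scope="session")
def sim_annot(sim_truth):
    return annotation_from_truth(sim_truth)


@pytest.fixture(scope="session")
def sim_atlas(sim_truth):
    return simulate_atlas(sim_truth)


@pytest.fixture()
def tiny_counts():
    counts = pd.DataFrame(
        {"s1": [1, 3, 5], "s2": [2, 4, 6]},
        index=["g1", "g2", "g3"],
    )
    meta = pd.DataFrame({"subgroup": ["a", "a"]}, index=["s1", "s2"])
    return CountMatrix(counts, meta)


def make_atlas(rows: dict, species=("human", "mouse")) -> ReferenceAtlas:
    """Atlas from {gene: {cell_type: fpkm}} applied identically per species."""
    cell_types = ("microglia", "astrocyte", "neuron", "oligodendrocyte", "endothelial")
    cols = pd.MultiIndex.from_product([list(species), list(cell_types)])
    df = pd.DataFrame(0.0, index=list(rows), columns=cols)
    for gene, cts in rows.items():
        for sp in species:
            for ct, v in cts.items():
                df.loc[gene, (sp, ct)] = v
    return ReferenceAtlas(df)


@pytest.fixture()
def expr_matrix():
    rng = np.random.default_rng(5)
    vals = pd.DataFrame(
        rng.gamma(2.0, 3.0, size=(40, 8)),
        index=[f"g{i}" for i in range(40)],
        columns=[f"s{j}" for j in range(8)],
    )
    return ExpressionMatrix(vals, "FPKM")
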