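import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from maturatlas.qc import log_normalize
from maturatlas.synthetic import GENE_CATEGORIES, SyntheticSpec, generate_dataset


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*anndata.*", category=FutureWarning)
        warnings.filterwarnings("ignore", category=pd.errors.PerformanceWarning)
        yield


def make_adata(counts, ages=None, cell_types=None, samples=None, sexes=None,
               genotypes=None, age_order=None) -> AnnData:
    """Assemble a raw-count AnnData with the metadata the pipeline expects."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"))
    ages = ["P65"] * n if ages is None else list(ages)
    order = age_order if age_order is not None else list(dict.fromkeys(ages))
    obs["age"] = pd.Categorical(ages, categories=order, ordered=True)
    obs["cell_type"] = pd.Categorical(cell_types if cell_types is not None
                                      else ["ct0"] * n)
    obs["sample_id"] = pd.Categorical(samples if samples is not None
                                      else ["s0"] * n)
    obs["sex"] = pd.Categorical(sexes if sexes is not None else ["M"] * n)
    obs["genotype"] = pd.Categorical(genotypes if genotypes is not None
                                     else ["control"] * n)
    var = pd.DataFrame(index=pd.Index([f"g{j}" for j in range(g)], name="gene_id"))
    for cat in GENE_CATEGORIES:
        var[cat] = False
    return AnnData(X=sp.csr_matrix(counts.astype(np.int32)), obs=obs, var=var)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic atlas shared across tests."""
    spec = SyntheticSpec(n_cell_types=4, n_genes=600,
                         cells_per_type_per_sample=10, seed=42)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    adata, _ = small_dataset
    return log_normalize(adata)
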