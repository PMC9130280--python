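import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

from atlasmap import SimulationConfig, generate_atlas_pair


@pytest.fixture(scope="session")
def small_pair():
    """A small noiseless reference/query pair shared across tests."""
    cfg = SimulationConfig(n_types=4, cells_per_type=60, n_genes=150,
                           markers_per_type=5, batch_log_fc_sd=0.0,
                           dispersion=5.0, seed=101)
    return generate_atlas_pair(cfg)


@pytest.fixture()
def toy_adata():
    """Tiny dense AnnData with explicit counts and a mito gene."""
    X = np.array([[5, 0, 1], [0, 3, 2], [4, 4, 0]], dtype=float)
    return AnnData(
        X=sparse.csr_matrix(X),
        obs=pd.DataFrame(index=["c1", "c2", "c3"]),
        var=pd.DataFrame({"mito": [False, False, True]},
                         index=["g1", "g2", "MT-g3"]),
    )
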