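import logging

import numpy as np
import pandas as pd
import pytest

from ccnet import synth
from ccnet.coexpr import CoexprParams

logging.getLogger("ccnet").setLevel(logging.ERROR)

# Standard study conditions: 3 species, 3 planted modules x 30 genes
# (seed genes included in the first module), 4 timepoints x 3 replicates,
# noise_sd = 0.3, trait_effect = 1.0.
STANDARD = dict(n_genes=90, timepoints=(1.0, 3.0, 6.0, 10.0),
                reps_per_timepoint=3, n_modules=3, module_size=30,
                trait_effect=1.0, noise_sd=0.3)
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def standard_bulk():
    return synth.generate_bulk_multispecies(seed=FIXTURE_SEED, **STANDARD)


@pytest.fixture(scope="session")
def noiseless_bulk():
    params = dict(STANDARD, noise_sd=0.0)
    return synth.generate_bulk_multispecies(seed=FIXTURE_SEED, **params)


@pytest.fixture(scope="session")
def background_bulk():
    """Default generator conditions including 30 pure-noise background genes."""
    return synth.generate_bulk_multispecies(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def sc_fixture():
    return synth.generate_singlecell(seed=7)


@pytest.fixture(scope="session")
def default_params():
    return CoexprParams()


def small_expr(matrix, genes=None, days=None) -> pd.DataFrame:
    """Genes x samples DataFrame from a plain array, for hand-built cases."""
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    cols = [f"s{j}" for j in range(matrix.shape[1])]
    return pd.DataFrame(matrix, index=genes, columns=cols)
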